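"""Generate a seeded two-class synthetic cohort and verify its coupling.

Patients carry brief windows in which a shared latent signal is mixed into a
"striatum-like" subset of regions with weight delta, so the expected pairwise
correlation inside an event is delta^2 / (1 + delta^2).
"""

import numpy as np

from impact import SynthConfig, generate_cohort

cfg = SynthConfig(n_per_class=6, T=132, R=48, delta=0.8, seed=7)
cohort = generate_cohort(cfg)

print(f"cohort: {len(cohort.subjects)} subjects, "
      f"{sum(s.label for s in cohort.subjects)} patients")
print(f"series shape per subject: {cohort.subjects[0].roi.values.shape}")

expected = cfg.delta**2 / (1 + cfg.delta**2)
vals = []
for s in cohort.by_label(1):
    for ev in s.events:
        w = s.roi.values[ev.start:ev.start + ev.length, list(ev.rois)]
        c = np.corrcoef(w.T)
        vals.append(c[np.triu_indices_from(c, k=1)].mean())
print(f"mean within-event pairwise correlation: {np.mean(vals):.3f} "
      f"(theory {expected:.3f})")
# The two numbers agree up to sampling error: the generator's coupling
# strength is analytically controlled, which is what downstream recovery
# tests rely on.
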