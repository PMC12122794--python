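"""Feature extraction on a cohort-shaped input: 137 volumes, 48 regions.

Discarding 5 stabilization volumes leaves T = 132; windows of 50 time points
with stride 25 give 4 windows of 48*47/2 = 1128 Fisher-z region-pair values.
"""

import numpy as np

from impact import RoiTimeSeries, build_subject_features, harmonize_roi_count

rng = np.random.default_rng(0)
raw = rng.standard_normal((137, 48))          # stand-in for parcellated BOLD
roi = RoiTimeSeries(raw[5:], [f"region_{i:02d}" for i in range(48)],
                    tr_seconds=3.48)

feats = build_subject_features(roi, subject_id="sub-001", n_ica=5,
                               window_width=50, stride=25, seed=0)
print(f"ROI stream : {feats.roi.values.shape}   (T x R, z-scored)")
print(f"ICA stream : {feats.ica.values.shape}   (T x C, unit variance)")
print(f"dFC stream : {feats.dfc.vectors.shape}  (windows x region pairs)")
print(f"window starts: {feats.dfc.window_starts}")

h45 = harmonize_roi_count(feats, 45)
print(f"after 45-region harmonization: dFC {h45.dfc.vectors.shape} "
      f"(45*44/2 = 990 pairs)")
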