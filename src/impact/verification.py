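"""End-to-end verification protocol on synthetic cohorts.

Bundles the standard recovery checks the package is validated with, at a
problem size a single CPU core handles in minutes: a 12-subject-per-class
cohort (T = 132, R = 20) with transient coupling of known strength, a
reduced hidden-32 model, and a fixed one-cycle training budget. Used by the
test suite and by ``scripts/acceptance.py``; all randomness derives from the
caller's seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .features import RoiTimeSeries, build_subject_features, \
    fit_ica_components
from .model import ImpactModel, ModelConfig
from .stats import bootstrap_ci
from .synthetic import SynthCohort, SynthConfig, generate_cohort
from .training import TrainConfig, compute_metrics, run_loocv, stack_streams, \
    train_model

__all__ = [
    "RECOVERY_COHORT", "SMALL_MODEL", "RECOVERY_RECIPE", "subseed",
    "recovery_features", "recovery_auc", "gradcam_localization_rate",
    "ica_recovery_min_corr", "bootstrap_coverage_rate",
]

RECOVERY_COHORT = dict(n_per_class=12, T=132, R=20)
SMALL_MODEL = dict(hidden_dim=32, n_heads=2, n_layers=1, dropout=0.1,
                   ffn_expansion=2, classifier_width=16, roi_dim=20,
                   ica_dim=5, conn_dim=190, max_rel_offset=16)
RECOVERY_RECIPE = dict(max_lr=1e-2, epochs=50, patience=25,
                       early_stopping=False, mixup_alpha=0.4)


def subseed(seed: int, *key: int) -> int:
    """Deterministic child seed below 2^31."""
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0]
               % (2**31 - 1))


def recovery_features(delta: float, seed: int):
    """Cohort plus per-subject features at the verification scale."""
    cfg = SynthConfig(delta=delta, seed=subseed(seed, 3), **RECOVERY_COHORT)
    cohort = generate_cohort(cfg)
    feats = [build_subject_features(s.roi, subject_id=s.subject_id,
                                    label=s.label, n_ica=5, window_width=50,
                                    stride=25, seed=subseed(seed, 4))
             for s in cohort.subjects]
    return cohort, feats


def _small_factory():
    cfg = ModelConfig(**SMALL_MODEL)

    def make(model_seed: int) -> ImpactModel:
        return ImpactModel(replace(cfg, seed=model_seed)).astype(np.float32)

    return make


def recovery_auc(feats, seed: int) -> float:
    """LOOCV AUC of the small model on the given cohort features."""
    folds = run_loocv(_small_factory(), feats,
                      TrainConfig(seed=subseed(seed, 5), **RECOVERY_RECIPE))
    return compute_metrics(folds).auc


def train_cohort_model(feats, seed: int) -> ImpactModel:
    """One model trained on the full cohort (for interpretability checks)."""
    model = ImpactModel(ModelConfig(seed=subseed(seed, 6), **SMALL_MODEL)
                        ).astype(np.float32)
    labels = np.array([f.label for f in feats])
    train_model(model, stack_streams(feats), labels,
                TrainConfig(seed=subseed(seed, 7), **RECOVERY_RECIPE),
                np.random.default_rng(subseed(seed, 8)))
    return model


def gradcam_localization_rate(cohort: SynthCohort, feats, seed: int,
                              model: ImpactModel | None = None) -> float:
    """Fraction of patients whose mean GradCAM saliency inside the injected
    event windows exceeds the mean outside."""
    from .interpret import gradcam_saliency

    if model is None:
        model = train_cohort_model(feats, seed)
    by_id = {f.subject_id: f for f in feats}
    patients = [s for s in cohort.subjects if s.label == 1]
    hits = 0
    for subj in patients:
        sal = gradcam_saliency(model, by_id[subj.subject_id], target_class=1)
        mask = np.zeros(sal.values.shape[0], dtype=bool)
        for ev in subj.events:
            mask[ev.start:ev.start + ev.length] = True
        hits += sal.values[mask].mean() > sal.values[~mask].mean()
    return hits / len(patients)


def ica_recovery_min_corr(seed: int) -> float:
    """Minimum matched |r| between known independent sources and components
    recovered from their noiseless linear mixture."""
    rng = np.random.default_rng(subseed(seed, 9))
    T, C, R = 400, 3, 10
    sources = np.column_stack([
        np.sign(np.sin(np.arange(T) * 0.7)),
        rng.uniform(-1, 1, T),
        np.sin(np.arange(T) * 0.13),
    ])
    mixed = sources @ rng.standard_normal((C, R))
    ts = RoiTimeSeries(mixed, [f"r{i}" for i in range(R)], 2.0)
    ica = fit_ica_components(ts, n_components=C, seed=subseed(seed, 10))
    corr = np.abs(np.corrcoef(sources.T, ica.values.T)[:C, C:])
    matched, used = [], set()
    for i in np.argsort(-corr.max(axis=1)):
        j = max((j for j in range(C) if j not in used), key=lambda j: corr[i, j])
        used.add(j)
        matched.append(corr[i, j])
    return float(min(matched))


def bootstrap_coverage_rate(seed: int, n_replications: int = 200,
                            n_subjects: int = 50, p_true: float = 0.7,
                            n_resamples: int = 1000) -> float:
    """Coverage of the 95% percentile bootstrap CI for the accuracy of a
    Bernoulli(p_true) classifier over seeded replications."""
    rng = np.random.default_rng(subseed(seed, 11))
    covered = 0
    for rep in range(n_replications):
        outcomes = (rng.random(n_subjects) < p_true).astype(float)
        lo, hi = bootstrap_ci(outcomes, np.mean, n_resamples=n_resamples,
                              seed=subseed(seed, 12, rep))
        covered += lo <= p_true <= hi
    return covered / n_replications
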