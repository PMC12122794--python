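"""Seeded two-class synthetic resting-state cohorts with ground-truth
transient coupling events.

Each region's baseline signal is a lag-1 autoregressive (AR(1)) process scaled
to unit marginal variance — the cheapest process with BOLD-like temporal
smoothness. Patients additionally carry brief "events": within each event
window a single white latent signal is mixed into a fixed subset of regions
with weight ``delta`` and the sum renormalized to unit variance, so the
expected within-window correlation between two affected regions is exactly
delta^2 / (1 + delta^2). With ``delta = 0`` the two classes are exchangeable
in distribution. Event onsets are jittered per subject (default +/- 10 time
points) so that a classifier must use temporal attention rather than a fixed
position.

Cohort shapes default to a small two-class resting-state study: tens of
subjects per class, T around 130-230 time points, 48 regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .features import AtlasLabelImage, RoiTimeSeries, zscore_normalize

__all__ = [
    "CONTROL", "PATIENT", "SynthConfig", "SynthSubject", "SynthCohort",
    "EventAnnotation", "generate_subject", "generate_cohort",
    "make_fixture_atlas", "write_synthetic_nifti",
]

CONTROL, PATIENT = 0, 1
LABEL_NAMES = {CONTROL: "control", PATIENT: "patient"}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults mirror a small two-class cohort with
    transient coupling in a "striatum-like" region subset."""

    n_per_class: int = 12
    T: int = 132
    R: int = 48
    tr_seconds: float = 2.0
    ar_coef: float = 0.4
    delta: float = 0.8
    event_windows: tuple[tuple[int, int], ...] = ((30, 30), (85, 30))
    affected_rois: tuple[int, ...] = (5, 6, 7, 8)
    event_jitter: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 2:
            raise ValueError(
                f"n_per_class must be >= 2 (cross-validation impossible), got {self.n_per_class}")
        if self.T < 8:
            raise ValueError(f"T must be >= 8, got {self.T}")
        if self.R < 2:
            raise ValueError(f"R must be >= 2, got {self.R}")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError(f"ar_coef must lie in [0, 1), got {self.ar_coef}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if not self.event_windows:
            raise ValueError("at least one event window is required "
                             "(patients must carry >= 1 event)")
        for start, length in self.event_windows:
            if length < 2 or start < 0 or start + length > self.T:
                raise ValueError(
                    f"event window ({start}, {length}) must lie inside [0, {self.T})")
        for r in self.affected_rois:
            if not 0 <= r < self.R:
                raise ValueError(f"affected ROI {r} outside [0, {self.R})")
        if len(self.affected_rois) < 2:
            raise ValueError("need at least 2 affected ROIs to create coupling")


@dataclass(frozen=True)
class EventAnnotation:
    start: int
    length: int
    rois: tuple[int, ...]

    @property
    def window(self) -> tuple[int, int]:
        return self.start, self.start + self.length


@dataclass
class SynthSubject:
    subject_id: str
    label: int
    roi: RoiTimeSeries
    events: tuple[EventAnnotation, ...]


@dataclass
class SynthCohort:
    subjects: list[SynthSubject]
    config: SynthConfig

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects])

    def by_label(self, label: int) -> list[SynthSubject]:
        return [s for s in self.subjects if s.label == label]


def _ar1(rng: np.random.Generator, T: int, R: int, phi: float) -> np.ndarray:
    """AR(1) noise with unit marginal variance, stationary start."""
    innov_sd = np.sqrt(1.0 - phi**2)
    x = np.empty((T, R))
    x[0] = rng.standard_normal(R)
    eps = rng.standard_normal((T - 1, R)) * innov_sd
    for t in range(1, T):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def generate_subject(cfg: SynthConfig, label: int,
                     rng: np.random.Generator
                     ) -> tuple[RoiTimeSeries, tuple[EventAnnotation, ...]]:
    """One subject's T x R series plus its ground-truth event annotations.

    Patients receive every configured event (with jittered onset); controls
    receive none. The series is z-scored per region before returning.
    """
    cfg.validate()
    if label not in (CONTROL, PATIENT):
        raise ValueError(f"label must be {CONTROL} (control) or {PATIENT} (patient)")
    x = _ar1(rng, cfg.T, cfg.R, cfg.ar_coef)
    events: list[EventAnnotation] = []
    if label == PATIENT:
        rois = np.array(cfg.affected_rois)
        norm = np.sqrt(1.0 + cfg.delta**2)
        for start, length in cfg.event_windows:
            jitter = int(rng.integers(-cfg.event_jitter, cfg.event_jitter + 1)) \
                if cfg.event_jitter else 0
            s = int(np.clip(start + jitter, 0, cfg.T - length))
            latent = rng.standard_normal(length)
            x[s:s + length, rois] = (x[s:s + length, rois]
                                     + cfg.delta * latent[:, None]) / norm
            events.append(EventAnnotation(s, length, tuple(cfg.affected_rois)))
    names = _region_names(cfg.R, cfg.affected_rois)
    ts = RoiTimeSeries(x, names, cfg.tr_seconds, normalized=False)
    return zscore_normalize(ts), tuple(events)


def _region_names(R: int, affected: tuple[int, ...]) -> list[str]:
    return [f"striatum-like-{r:02d}" if r in affected else f"ctx-region-{r:02d}"
            for r in range(R)]


def generate_cohort(cfg: SynthConfig) -> SynthCohort:
    """Balanced two-class cohort; per-subject RNG streams are derived from
    (cfg.seed, subject index) so generation is reproducible and independent of
    call order."""
    cfg.validate()
    subjects: list[SynthSubject] = []
    for idx in range(2 * cfg.n_per_class):
        label = CONTROL if idx < cfg.n_per_class else PATIENT
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(idx,)))
        ts, events = generate_subject(cfg, label, rng)
        short = LABEL_NAMES[label][:3]
        subjects.append(SynthSubject(f"sub-{short}-{idx:03d}", label, ts, events))
    return SynthCohort(subjects, cfg)


def make_fixture_atlas(R: int, voxels_per_region: int = 2,
                       affected: tuple[int, ...] = (5, 6, 7, 8)) -> AtlasLabelImage:
    """Tiny block atlas: region r occupies ``voxels_per_region`` voxels of a
    (R, voxels_per_region, 1) grid; names mark the coupled subset."""
    labels = np.zeros((R, voxels_per_region, 1), dtype=np.int32)
    for r in range(R):
        labels[r, :, 0] = r + 1
    return AtlasLabelImage(labels, _region_names(R, tuple(a for a in affected if a < R)))


def write_synthetic_nifti(cohort: SynthCohort, atlas: AtlasLabelImage,
                          out_dir: str | Path, voxel_noise: float = 0.0,
                          seed: int = 0) -> dict:
    """One 4D NIfTI per subject; every voxel of region r carries that region's
    series (plus optional white voxel noise). With zero noise, parcellation of
    these files recovers the input series exactly.

    Returns (and writes) a cohort manifest with files, labels and ground truth.
    """
    import nibabel as nib

    cfg = cohort.config
    present = set(np.unique(atlas.labels)) - {0}
    missing = [r for r in range(1, cfg.R + 1) if r not in present]
    if missing:
        raise ValueError(f"atlas is missing labels: {missing}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries = []
    for subj in cohort.subjects:
        T = subj.roi.n_timepoints
        data = np.zeros(atlas.labels.shape + (T,), dtype=np.float64)
        for r in range(1, cfg.R + 1):
            mask = atlas.labels == r
            data[mask, :] = subj.roi.values[:, r - 1]
        if voxel_noise > 0:
            data = data + rng.normal(0, voxel_noise, data.shape)
        fname = f"{subj.subject_id}_bold.nii.gz"
        img = nib.Nifti1Image(data, affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, cfg.tr_seconds))
        nib.save(img, out_dir / fname)
        entries.append({
            "subject_id": subj.subject_id,
            "label": subj.label,
            "label_name": LABEL_NAMES[subj.label],
            "file": fname,
            "events": [{"start": e.start, "length": e.length, "rois": list(e.rois)}
                       for e in subj.events],
        })
    manifest = {"config": asdict(cfg), "subjects": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
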