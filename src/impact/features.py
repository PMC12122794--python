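"""Feature extraction: atlas parcellation, temporal filtering, motion QC,
per-subject ICA, and sliding-window dynamic functional connectivity (dFC).

The three streams produced here — ROI time series (mean BOLD per atlas region,
z-scored), ICA component time series, and Fisher-z dFC vectors — are the
inputs of the multimodal classifier. Conventions fixed by this module:

* z-scoring uses the population standard deviation (divide by n); constant
  columns become all-zero rather than NaN.
* Pearson correlation uses the sample standard deviation (n-1); the two cancel
  in the correlation itself but the choice matters for oracles.
* Fisher's z is atanh after clamping |r| to 1 - 1e-7, so dFC vectors are
  always finite.
* dFC flattening takes the strict upper triangle in row-major (i < j) order.
* Only full windows are used; a trailing partial window is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt
from sklearn.decomposition import FastICA

__all__ = [
    "BoldVolumeSeries", "AtlasLabelImage", "RoiTimeSeries", "IcaTimeSeries",
    "DfcSequence", "SubjectFeatures",
    "discard_initial_volumes", "highpass_filter", "frame_displacement_qc",
    "extract_roi_timeseries", "zscore_normalize", "fit_ica_components",
    "sliding_windows", "window_correlation", "fisher_z", "flatten_dfc",
    "unflatten_dfc", "compute_dfc", "harmonize_roi_count",
    "build_subject_features",
]

FISHER_CLAMP = 1.0 - 1e-7


# --------------------------------------------------------------------- types

@dataclass
class BoldVolumeSeries:
    """4D BOLD data, shape (x, y, z, t)."""

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        if self.data.ndim != 4 or self.data.shape[3] < 1:
            raise ValueError(f"expected 4D (x,y,z,t) data, got shape {self.data.shape}")


@dataclass
class AtlasLabelImage:
    """3D integer label image (0 = background) with an ordered region-name table."""

    labels: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if len(set(self.names)) != len(self.names):
            raise ValueError("region names must be unique")

    @property
    def n_regions(self) -> int:
        return len(self.names)


@dataclass
class RoiTimeSeries:
    """T x R matrix of regional mean BOLD signals."""

    values: np.ndarray
    region_names: list[str]
    tr_seconds: float
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ROI time series must be a T x R matrix")
        if self.values.shape[1] != len(self.region_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.region_names)} names")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class IcaTimeSeries:
    """T x C independent-component time series, unit variance per component."""

    values: np.ndarray
    mixing: np.ndarray          # R x C: column c maps component c back to ROI space
    mean: np.ndarray            # per-ROI mean removed before unmixing

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


@dataclass
class DfcSequence:
    """N_w x R(R-1)/2 matrix of Fisher-z connectivity vectors."""

    vectors: np.ndarray
    window_starts: list[int]
    window_width: int
    stride: int
    n_regions: int

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]


@dataclass
class SubjectFeatures:
    subject_id: str
    roi: RoiTimeSeries
    ica: IcaTimeSeries
    dfc: DfcSequence
    label: int | None = None


# ---------------------------------------------------------------- operations

def discard_initial_volumes(vol: BoldVolumeSeries, k: int = 5) -> BoldVolumeSeries:
    """Drop the first ``k`` frames (scanner stabilization)."""
    t = vol.data.shape[3]
    if t <= k:
        raise ValueError(f"cannot discard {k} volumes from a series of length {t}")
    return replace(vol, data=vol.data[..., k:])


def highpass_filter(ts: RoiTimeSeries, cutoff_seconds: float = 100.0) -> RoiTimeSeries:
    """Zero-phase Butterworth high-pass (order 2) removing drifts slower than the cutoff."""
    if ts.tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if ts.n_timepoints < 8:
        raise ValueError("need at least 8 time points to filter")
    if cutoff_seconds <= 2.0 * ts.tr_seconds:
        raise ValueError(
            f"cutoff {cutoff_seconds}s is below the resolvable band (2*TR = {2 * ts.tr_seconds}s)")
    fs = 1.0 / ts.tr_seconds
    sos = butter(2, 1.0 / cutoff_seconds, btype="highpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, ts.values, axis=0)
    filtered = filtered - filtered.mean(axis=0, keepdims=True)
    return replace(ts, values=filtered, normalized=False)


def frame_displacement_qc(motion_params: np.ndarray, threshold_mm: float = 0.5
                          ) -> tuple[float, bool]:
    """Mean framewise displacement (Power convention) and a keep/exclude flag.

    ``motion_params`` is T x 6: three translations in mm then three rotations
    in radians; rotations are converted to arc length on a 50 mm sphere.
    """
    motion_params = np.asarray(motion_params, dtype=np.float64)
    if motion_params.ndim != 2 or motion_params.shape[1] != 6:
        raise ValueError(f"motion parameters must be T x 6, got {motion_params.shape}")
    if motion_params.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    d = np.abs(np.diff(motion_params, axis=0))
    fd = d[:, :3].sum(axis=1) + 50.0 * d[:, 3:].sum(axis=1)
    mean_fd = float(fd.mean())
    return mean_fd, mean_fd <= threshold_mm


def extract_roi_timeseries(vol: BoldVolumeSeries, atlas: AtlasLabelImage) -> RoiTimeSeries:
    """Mean BOLD signal per atlas region: column r is the voxel average over V_r."""
    if vol.data.shape[:3] != atlas.labels.shape:
        raise ValueError(
            f"volume grid {vol.data.shape[:3]} does not match atlas grid {atlas.labels.shape}")
    T = vol.data.shape[3]
    R = atlas.n_regions
    out = np.empty((T, R))
    flat = vol.data.reshape(-1, T)
    lab = atlas.labels.ravel()
    empty = []
    for r in range(1, R + 1):
        mask = lab == r
        if not mask.any():
            empty.append(r)
            continue
        out[:, r - 1] = flat[mask].mean(axis=0)
    if empty:
        raise ValueError(f"atlas regions with no voxels: {empty}")
    return RoiTimeSeries(out, list(atlas.names), vol.tr_seconds, normalized=False)


def zscore_normalize(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Per-column (x - mean) / population std; constant columns become zeros."""
    if ts.n_timepoints < 2:
        raise ValueError("need at least 2 time points to z-score")
    x = ts.values
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)          # population (divide by n)
    centered = x - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 1e-12, centered / np.where(sd > 1e-12, sd, 1.0), 0.0)
    return replace(ts, values=z, normalized=True)


def fit_ica_components(ts: RoiTimeSeries, n_components: int = 5,
                       seed: int = 0) -> IcaTimeSeries:
    """Per-subject temporal ICA of the ROI matrix into C component time series.

    Components have unit (population) variance and a fixed sign convention:
    the largest-magnitude entry of each mixing column is positive.
    """
    T, R = ts.values.shape
    if n_components >= R or n_components >= T:
        raise ValueError(
            f"n_components={n_components} must be smaller than both T={T} and R={R}")
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=2000, tol=1e-7)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on degenerate fixtures
        sources = ica.fit_transform(ts.values)
    mixing = ica.mixing_.copy()
    sd = sources.std(axis=0)
    sd[sd == 0] = 1.0
    sources = sources / sd
    mixing = mixing * sd
    for c in range(n_components):
        j = int(np.argmax(np.abs(mixing[:, c])))
        if mixing[j, c] < 0:
            mixing[:, c] *= -1.0
            sources[:, c] *= -1.0
    return IcaTimeSeries(values=sources, mixing=mixing, mean=ica.mean_.copy())


def sliding_windows(T: int, W: int = 50, stride: int = 25) -> list[tuple[int, int]]:
    """Half-open full windows (start, start+W); count = floor((T-W)/stride) + 1."""
    if W < 2:
        raise ValueError("window width must be at least 2")
    if stride < 1:
        raise ValueError("stride must be at least 1")
    if T < W:
        raise ValueError(f"series length {T} shorter than window width {W}")
    starts = range(0, T - W + 1, stride)
    return [(s, s + W) for s in starts]


def window_correlation(ts: RoiTimeSeries, window: tuple[int, int]) -> np.ndarray:
    """Pearson correlation matrix of all region pairs within one window.

    Zero-variance columns yield zero off-diagonal entries; the diagonal is 1.
    """
    start, end = window
    if end - start < 3:
        raise ValueError("window must contain at least 3 time points")
    x = ts.values[start:end]
    n = x.shape[0]
    centered = x - x.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0, ddof=1)
    cov = centered.T @ centered / (n - 1)
    valid = sd > 1e-12
    denom = np.outer(np.where(valid, sd, 1.0), np.where(valid, sd, 1.0))
    corr = cov / denom
    corr[~valid, :] = 0.0
    corr[:, ~valid] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def fisher_z(r):
    """Variance-stabilizing atanh transform, clamped so |r| = 1 stays finite."""
    arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("correlation values must satisfy |r| <= 1")
    clamped = np.clip(arr, -FISHER_CLAMP, FISHER_CLAMP)
    out = np.arctanh(clamped)
    return float(out) if np.isscalar(r) else out


def flatten_dfc(z_matrices: list[np.ndarray], window_starts: list[int],
                window_width: int, stride: int) -> DfcSequence:
    """Stack the strict upper triangle (i < j, row-major) of each Fisher-z matrix."""
    if not z_matrices:
        raise ValueError("no windows to flatten")
    R = z_matrices[0].shape[0]
    iu = np.triu_indices(R, k=1)
    rows = []
    for Z in z_matrices:
        if Z.shape != (R, R):
            raise ValueError("all matrices must share the same R x R shape")
        if np.max(np.abs(Z - Z.T)) > 1e-9:
            raise ValueError("connectivity matrix is not symmetric")
        rows.append(Z[iu])
    return DfcSequence(np.array(rows), list(window_starts), window_width, stride, R)


def unflatten_dfc(vector: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of the upper-triangle flattening, with a zero diagonal."""
    Z = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    Z[iu] = vector
    return Z + Z.T


def compute_dfc(ts: RoiTimeSeries, W: int = 50, stride: int = 25) -> DfcSequence:
    """Sliding-window Pearson correlation -> Fisher z -> flattened sequence."""
    windows = sliding_windows(ts.n_timepoints, W, stride)
    z_mats = [fisher_z(window_correlation(ts, w)) for w in windows]
    return flatten_dfc(z_mats, [w[0] for w in windows], W, stride)


def harmonize_roi_count(features: SubjectFeatures, n_keep: int = 45) -> SubjectFeatures:
    """Truncate to the first ``n_keep`` regions and recompute dFC; ICA untouched."""
    R = features.roi.n_regions
    if n_keep < 2:
        raise ValueError("must keep at least 2 regions")
    if n_keep > R:
        raise ValueError(f"n_keep={n_keep} exceeds region count {R}")
    if n_keep == R:
        return features
    roi = replace(features.roi, values=features.roi.values[:, :n_keep],
                  region_names=features.roi.region_names[:n_keep])
    dfc = compute_dfc(roi, features.dfc.window_width, features.dfc.stride)
    return replace(features, roi=roi, dfc=dfc)


def build_subject_features(source: BoldVolumeSeries | RoiTimeSeries,
                           atlas: AtlasLabelImage | None = None,
                           subject_id: str | None = None,
                           label: int | None = None,
                           discard_k: int = 5,
                           highpass_seconds: float | None = None,
                           n_ica: int = 5,
                           window_width: int = 50,
                           stride: int = 25,
                           seed: int = 0) -> SubjectFeatures:
    """Compose the full per-subject pipeline into the three feature streams.

    Accepts either a 4D volume (atlas required; the first ``discard_k`` frames
    are dropped before parcellation) or a ready ROI matrix (parcellation
    skipped). Everything is computed from this subject's data alone, so
    cross-validation cannot leak information between subjects.
    """
    if isinstance(source, BoldVolumeSeries):
        if atlas is None:
            raise ValueError("volume input requires an atlas")
        vol = discard_initial_volumes(source, discard_k) if discard_k else source
        roi = extract_roi_timeseries(vol, atlas)
        subject_id = subject_id or source.subject_id
    else:
        roi = source
    if highpass_seconds is not None:
        roi = highpass_filter(roi, highpass_seconds)
    if not roi.normalized:
        roi = zscore_normalize(roi)
    ica = fit_ica_components(roi, n_components=n_ica, seed=seed)
    dfc = compute_dfc(roi, W=window_width, stride=stride)
    return SubjectFeatures(subject_id=subject_id or "", roi=roi, ica=ica,
                           dfc=dfc, label=label)
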