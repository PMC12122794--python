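"""Gradient-based interpretability: GradCAM saliency over time x region,
attention-weight statistics, and group-level importance aggregations (region
ranking, lobe summaries, connectivity-edge importance).

GradCAM is adapted to temporal transformer features: the target layer is the
last transformer layer of the ROI encoder (states T x h). Channel weights are
the temporal mean of the target-class logit's gradient at that layer; the
class-activation profile ReLU(sum_c w_c A[t, c] rho[r, c]) is routed back to
regions through the ROI input-projection magnitudes rho (each channel's
|W_e| column normalized over regions), then max-normalized per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import SubjectFeatures
from .model import ImpactModel
from .training import stack_streams

__all__ = [
    "SaliencyMap", "AttentionStats", "gradcam_saliency", "attention_stats",
    "rank_roi_importance", "temporal_importance_profile", "edge_importance",
    "lobe_importance", "load_lobe_map",
]


@dataclass
class SaliencyMap:
    """Per-subject nonnegative T x R importance, max-normalized to [0, 1]."""

    values: np.ndarray
    subject_id: str
    predicted_class: int
    all_zero: bool = False          # warning flag: the gradient vanished

    def __post_init__(self):
        if np.any(self.values < 0) or np.any(self.values > 1.0 + 1e-12):
            raise ValueError("saliency values must lie in [0, 1]")


@dataclass
class AttentionStats:
    mean: float
    std: float
    sparsity: float                 # fraction of entries < 1/(10 * row length)


def _roi_cam(result, model) -> np.ndarray | None:
    """GradCAM at the last ROI-encoder layer, routed to regions through the
    ROI input-projection magnitudes."""
    activations = result.encoders["roi"].states      # (1, T, h), in the graph
    grad = activations.grad
    if grad is None or not np.any(grad):
        return None
    A = activations.data[0]                          # (T, h)
    w = grad[0].mean(axis=0)                         # channel weights, (h,)
    We = np.abs(model.encoders["roi"].embed.weight.data)   # (R, h)
    col = We.sum(axis=0, keepdims=True)
    rho = We / np.where(col > 0, col, 1.0)           # per-channel region shares
    return np.maximum((w * A) @ rho.T, 0.0)          # (T, R)


def _conn_cam(conn_input: "Tensor", subject: SubjectFeatures
              ) -> np.ndarray | None:
    """Connectivity GradCAM: gradient-selected pair importance times the
    rectified instantaneous co-fluctuation of each pair.

    Transient coupling changes the correlation structure, not the amplitude,
    of the region signals, so it is invisible to an activation map on the
    ROI encoder. The gradient of the class score with respect to the dFC
    input says *which region pairs* the model relies on; the edge time
    series x_i(t)·x_j(t) of those pairs says *when* they co-fluctuate. Their
    product is the time-resolved activation map for the connectivity stream.
    """
    grad = conn_input.grad
    if grad is None or not np.any(grad):
        return None
    # pairs whose increased coupling pushes the score toward the target
    # class; gradients of small-sample models are diffuse, so the weights
    # are sharpened (normalized, 4th power) to concentrate on the pairs
    # that drive the decision
    pair_w = np.maximum(grad[0].mean(axis=0), 0.0)   # (P,)
    peak = pair_w.max()
    if peak <= 0:
        return None
    pair_w = (pair_w / peak) ** 4
    T = subject.roi.n_timepoints
    R = subject.roi.n_regions
    x = subject.roi.values                           # (T, R), z-scored
    iu, ju = np.triu_indices(R, k=1)
    edges = np.maximum(x[:, iu] * x[:, ju], 0.0)     # (T, P) co-fluctuation
    # light temporal smoothing stabilizes the per-time-point product noise
    from scipy.ndimage import uniform_filter1d
    edges = np.maximum(uniform_filter1d(edges, size=5, axis=0, mode="nearest"),
                       0.0)
    weighted = edges * pair_w[None, :]
    cam = np.zeros((T, R))
    np.add.at(cam.T, iu, weighted.T)
    np.add.at(cam.T, ju, weighted.T)
    return cam


def gradcam_saliency(model: ImpactModel, subject: SubjectFeatures,
                     target_class: int | None = None) -> SaliencyMap:
    """GradCAM importance of each (time point, region) for the target class.

    Gradients of the class-contrast logit (z_target − z_other) are taken at
    the last layer of the ROI encoder and, when the dFC stream is enabled, of
    the connectivity encoder; the two maps are combined with the model's own
    fusion gate weights and max-normalized. ``target_class`` defaults to the
    model's predicted class.
    """
    from .nn import Tensor

    if model.training:
        raise ValueError("model must be in eval mode for saliency")
    streams = stack_streams([subject], model.cfg.modalities)
    conn_input = None
    if "conn" in model.cfg.modalities:
        conn_input = Tensor(streams["conn"], requires_grad=True)
        streams["conn"] = conn_input
    result = model(streams)
    pred = int(np.argmax(result.output.probabilities[0]))
    target = pred if target_class is None else int(target_class)

    model.zero_grad()
    if result.logits.shape[-1] == 2:
        score = result.logits[0, target] - result.logits[0, 1 - target]
    else:
        score = result.logits[0, target]
    score.backward()

    gates = dict(zip(result.fusion.gate_order, result.fusion.gates.data[0]))
    T, R = subject.roi.n_timepoints, subject.roi.n_regions
    combined = np.zeros((T, R))
    for name, cam_fn in (("roi", lambda: _roi_cam(result, model)),
                         ("conn", lambda: _conn_cam(conn_input, subject))):
        if name not in model.cfg.modalities:
            continue
        cam = cam_fn()
        if cam is None or cam.max() <= 0:
            continue
        combined += float(gates[name]) * cam / cam.max()
    peak = combined.max()
    if peak <= 0:
        return SaliencyMap(np.zeros((T, R)), subject.subject_id, pred,
                           all_zero=True)
    return SaliencyMap(np.clip(combined / peak, 0.0, 1.0),
                       subject.subject_id, pred)


def attention_stats(attention_maps: list[np.ndarray]) -> AttentionStats:
    """Mean/std over every attention entry of all layers, heads and subjects,
    plus a sparsity factor: the fraction of entries below 1/(10 * row length)
    (a tenth of the uniform weight)."""
    if not attention_maps:
        raise ValueError("need at least one attention map")
    flat = []
    sparse = 0
    total = 0
    for m in attention_maps:
        m = np.asarray(m)
        row_len = m.shape[-1]
        sparse += int((m < 1.0 / (10.0 * row_len)).sum())
        total += m.size
        flat.append(m.ravel())
    allw = np.concatenate(flat)
    return AttentionStats(float(allw.mean()), float(allw.std()),
                          float(sparse / total))


def rank_roi_importance(maps: list[SaliencyMap], region_names: list[str],
                        group: str = "", k: int = 10) -> pd.DataFrame:
    """Region score = mean over subjects of the temporal-mean saliency.

    Returns the full table sorted descending with a ``top_k`` flag.
    """
    if not maps:
        raise ValueError("need at least one saliency map")
    R = maps[0].values.shape[1]
    if k > R:
        import warnings
        warnings.warn(f"k={k} exceeds region count {R}; clipping")
        k = R
    scores = np.mean([m.values.mean(axis=0) for m in maps], axis=0)
    table = pd.DataFrame({"region": region_names, "score": scores,
                          "group": group})
    table = table.sort_values("score", ascending=False,
                              kind="mergesort").reset_index(drop=True)
    table["top_k"] = table.index < k
    return table


def temporal_importance_profile(maps: list[SaliencyMap],
                                top_regions: list[int] | None = None
                                ) -> dict[str, np.ndarray]:
    """Mean saliency per time point (over subjects and regions); optionally
    per-region profiles for selected regions."""
    if not maps:
        raise ValueError("need at least one saliency map")
    T = maps[0].values.shape[0]
    if any(m.values.shape[0] != T for m in maps):
        raise ValueError("saliency maps have mixed lengths; profiles not alignable")
    stacked = np.stack([m.values for m in maps])        # (S, T, R)
    out = {"mean": stacked.mean(axis=(0, 2))}
    if top_regions is not None:
        for r in top_regions:
            out[f"region_{r}"] = stacked[:, :, r].mean(axis=0)
    return out


def edge_importance(model: ImpactModel, features: list[SubjectFeatures],
                    labels: np.ndarray | None = None,
                    target_class: int = 1) -> pd.DataFrame:
    """Mean absolute gradient of the target logit with respect to each
    region-pair dFC input, averaged over windows and subjects.

    With ``labels`` given, adds per-group means and their difference
    (patient - control).
    """
    if "conn" not in model.cfg.modalities:
        raise ValueError("dFC stream is disabled in this model")
    from .nn import Tensor

    per_subject = []
    for f in features:
        streams = stack_streams([f], model.cfg.modalities)
        conn = Tensor(streams["conn"], requires_grad=True)
        streams["conn"] = conn
        result = model(streams)
        model.zero_grad()
        result.logits[0, target_class].backward()
        per_subject.append(np.abs(conn.grad[0]).mean(axis=0))   # (P,)
    per_subject = np.stack(per_subject)

    R = features[0].dfc.n_regions
    names = features[0].roi.region_names
    iu = np.triu_indices(R, k=1)
    table = pd.DataFrame({
        "region_i": [names[i] for i in iu[0]],
        "region_j": [names[j] for j in iu[1]],
        "score": per_subject.mean(axis=0),
    })
    if labels is not None:
        labels = np.asarray(labels)
        table["score_patient"] = per_subject[labels == 1].mean(axis=0)
        table["score_control"] = per_subject[labels == 0].mean(axis=0)
        table["group_difference"] = table["score_patient"] - table["score_control"]
    return table.sort_values("score", ascending=False,
                             kind="mergesort").reset_index(drop=True)


def lobe_importance(table: pd.DataFrame, lobe_map: dict[str, str]) -> pd.DataFrame:
    """Lobe score = mean of member-region scores, normalized to sum 1."""
    missing = [r for r in table["region"] if r not in lobe_map]
    if missing:
        raise ValueError(f"regions missing from the lobe map: {missing}")
    lobes = table["region"].map(lobe_map)
    grouped = table.groupby(lobes)["score"].mean()
    total = grouped.sum()
    if total > 0:
        grouped = grouped / total
    out = grouped.rename_axis("lobe").reset_index(name="score")
    return out.sort_values("score", ascending=False,
                           kind="mergesort").reset_index(drop=True)


def load_lobe_map(path=None) -> dict[str, str]:
    """Region -> lobe lookup; defaults to the packaged table for the 48
    cortical regions of the Harvard-Oxford atlas."""
    if path is None:
        from importlib.resources import files
        path = files("impact.data").joinpath("harvard_oxford_lobes.tsv")
        text = path.read_text()
    else:
        text = open(path).read()
    out = {}
    for line in text.strip().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        region, lobe = line.rstrip("\n").split("\t")
        if region == "region" and lobe == "lobe":
            continue
        out[region] = lobe
    return out
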