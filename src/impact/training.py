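"""Subject-level training and evaluation: weighted cross-entropy with an L1
penalty on the fusion gate weights, AdamW + one-cycle learning rates with
gradient clipping and early stopping, leave-one-out cross-validation, metric
reports with bootstrap confidence intervals, and the statistical
model-comparison stack (Mann-Whitney U, Cliff's delta, Benjamini-Hochberg).

Early stopping needs a validation signal: each fold carves a stratified inner
validation split (default 20% of the training subjects) and restores the
parameters with the best inner-validation loss before scoring the held-out
subject. Feature extraction is strictly per subject, so no statistic is ever
pooled across the train/test boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import (balanced_accuracy_score, f1_score, matthews_corrcoef)
from sklearn.model_selection import StratifiedKFold

from .features import SubjectFeatures
from .model import ForwardResult, ImpactModel, ModelConfig
from .nn import AdamW, OneCycleLR, Tensor, clip_grad_norm
from .stats import auc_rank, benjamini_hochberg, bootstrap_ci, cliffs_delta, \
    mann_whitney_u

__all__ = [
    "TrainConfig", "ALTERNATE_RECIPE", "FoldResult", "MetricReport",
    "ComparisonResult", "ABLATION_SUBSETS", "class_weights", "training_loss",
    "make_loocv_splits", "stack_streams", "train_model", "train_fold",
    "run_loocv", "compute_metrics", "bootstrap_distribution", "compare_models",
    "run_ablation", "impact_factory",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe. Defaults follow the consolidated parameter table
    (max_lr 1e-3, weight decay 1e-4, 200 epochs, clip 1.0); an alternate
    recipe with the more conservative settings that appear alongside it
    (1e-4 / 5e-4 / 150 epochs / clip 0.1) ships as ``ALTERNATE_RECIPE``."""

    batch_size: int = 16
    max_lr: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 200
    patience: int = 25
    grad_clip: float = 1.0
    div_factor: float = 25.0
    final_div_factor: float = 1000.0
    pct_start: float = 0.3
    l1_coef: float = 1e-5
    inner_val_fraction: float = 0.2
    n_ensemble: int = 1          # models per fold; predictions are averaged
    early_stopping: bool = True  # False: full one-cycle budget, no inner split
    mixup_alpha: float = 0.0     # >0: Beta(alpha, alpha) mixup augmentation
    input_noise: float = 0.0     # sd of Gaussian noise added to training inputs
    seed: int = 0

    def __post_init__(self):
        for name in ("batch_size", "max_lr", "weight_decay", "epochs", "patience",
                     "grad_clip", "div_factor", "final_div_factor", "inner_val_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.pct_start < 1.0:
            raise ValueError("pct_start must lie in (0, 1)")
        if self.patience > self.epochs:
            raise ValueError("patience cannot exceed the epoch budget")
        if self.l1_coef < 0:
            raise ValueError("l1_coef must be >= 0")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")


ALTERNATE_RECIPE = TrainConfig(max_lr=1e-4, weight_decay=5e-4, epochs=150,
                               patience=25, grad_clip=0.1)

ABLATION_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("ica",), ("roi", "ica"), ("roi",), ("roi", "conn"), ("ica", "conn"), ("conn",),
)


@dataclass
class FoldResult:
    subject_id: str
    y_true: int
    p1: float                    # predicted probability of class 1 (patient)
    epochs_run: int
    best_val_loss: float


@dataclass
class MetricReport:
    auc: float
    accuracy: float
    f1: float
    balanced_accuracy: float
    mcc: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_resamples: int = 0


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    u_statistic: float
    p_value: float
    p_adjusted: float
    reject: bool
    delta: float
    delta_ci: tuple[float, float]


# ------------------------------------------------------------------- pieces

def class_weights(labels: np.ndarray) -> np.ndarray:
    """Per-class weights proportional to 1/n_c, normalized to mean 1."""
    labels = np.asarray(labels)
    counts = np.array([(labels == c).sum() for c in (0, 1)], dtype=np.float64)
    if np.any(counts == 0):
        raise ValueError("both classes must be present to compute class weights")
    w = 1.0 / counts
    return w / w.mean()


def training_loss(logits: Tensor, labels: np.ndarray, weights: np.ndarray,
                  l1_coef: float = 0.0, gate_params: list[Tensor] | None = None
                  ) -> Tensor:
    """Weighted cross-entropy (weighted mean of per-sample NLL) plus
    ``l1_coef`` times the L1 norm of the fusion gate weights."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    logp = logits.log_softmax(axis=-1)
    nll = -logp[np.arange(n), labels]
    w = np.asarray(weights)[labels]
    loss = (nll * Tensor(w)).sum() * (1.0 / float(w.sum()))
    if l1_coef > 0 and gate_params:
        l1 = None
        for p in gate_params:
            term = p.abs().sum()
            l1 = term if l1 is None else l1 + term
        loss = loss + l1 * l1_coef
    return loss


def make_loocv_splits(subject_ids: list[str]) -> list[tuple[list[str], str]]:
    """One fold per subject; all of a subject's streams stay on one side."""
    if len(set(subject_ids)) != len(subject_ids):
        dupes = sorted({s for s in subject_ids if subject_ids.count(s) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    if len(subject_ids) < 3:
        raise ValueError("need at least 3 subjects for leave-one-out CV")
    return [([t for t in subject_ids if t != s], s) for s in subject_ids]


def stack_streams(features: list[SubjectFeatures],
                  modalities: tuple[str, ...] = ("roi", "ica", "conn")
                  ) -> dict[str, np.ndarray]:
    """Stack per-subject streams into batched model inputs.

    Inputs are z-scored per subject: ROI and ICA streams already are by
    construction; the Fisher-z connectivity vectors are standardized here
    (per subject, over the whole matrix) so all three streams enter the
    encoders on a comparable scale.
    """
    out = {}
    if "roi" in modalities:
        out["roi"] = np.stack([f.roi.values for f in features])
    if "ica" in modalities:
        out["ica"] = np.stack([f.ica.values for f in features])
    if "conn" in modalities:
        mats = []
        for f in features:
            v = f.dfc.vectors
            sd = v.std()
            mats.append((v - v.mean()) / (sd if sd > 1e-12 else 1.0))
        out["conn"] = np.stack(mats)
    return out


def _logits(model, streams: dict[str, np.ndarray]) -> Tensor:
    res = model(streams)
    return res.logits if isinstance(res, ForwardResult) else res


def _slice(streams: dict[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {m: a[idx] for m, a in streams.items()}


def _stratified_inner_split(labels: np.ndarray, fraction: float,
                            rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        members = rng.permutation(members)
        n_val = max(1, int(round(fraction * members.size)))
        val_idx.extend(members[:n_val])
        train_idx.extend(members[n_val:])
    train_idx = np.sort(np.array(train_idx))
    val_idx = np.sort(np.array(val_idx))
    for c in (0, 1):
        if (labels[train_idx] == c).sum() < 2:
            raise ValueError(
                "fewer than 2 training subjects per class after the inner "
                "validation split; use a smaller inner_val_fraction")
    return train_idx, val_idx


# ---------------------------------------------------------------- main loops

def train_model(model, streams: dict[str, np.ndarray], labels: np.ndarray,
                cfg: TrainConfig, rng: np.random.Generator,
                weights: np.ndarray | None = None) -> tuple[int, float]:
    """Train ``model`` in place with an inner early-stopping split.

    Returns (epochs run, best inner-validation loss); the parameters with the
    best inner-validation loss are restored before returning.

    ``weights`` are the cross-entropy class weights. When not given they are
    computed from ``labels``. Cross-validation harnesses pass cohort-level
    weights instead: computed per fold, the weight vector covaries with the
    held-out subject's label (the training set is always one subject short in
    that class), which systematically shifts predictions toward the held-out
    class and biases LOOCV metrics even under the null.
    """
    labels = np.asarray(labels)
    dtype = model.parameters()[0].data.dtype
    if dtype != np.float64:
        streams = {m: a.astype(dtype) for m, a in streams.items()}
    if cfg.early_stopping:
        tr_idx, val_idx = _stratified_inner_split(labels, cfg.inner_val_fraction,
                                                  rng)
    else:
        # fixed one-cycle budget on all training subjects: with very small
        # cohorts the inner-validation loss is too noisy to stop on
        tr_idx = np.arange(labels.size)
        val_idx = np.array([], dtype=int)
    if weights is None:
        weights = class_weights(labels[tr_idx])
    train_streams, val_streams = _slice(streams, tr_idx), _slice(streams, val_idx)
    y_tr, y_val = labels[tr_idx], labels[val_idx]

    gate_params = (model.gate_weight_tensors()
                   if hasattr(model, "gate_weight_tensors") else None)
    pretext = getattr(model, "pretext_train", None)
    if pretext is not None:
        pretext(train_streams, cfg, rng)

    params = model.parameters()
    opt = AdamW(params, weight_decay=cfg.weight_decay)
    steps_per_epoch = math.ceil(tr_idx.size / cfg.batch_size)
    sched = OneCycleLR(opt, cfg.max_lr, total_steps=cfg.epochs * steps_per_epoch,
                       pct_start=cfg.pct_start, div_factor=cfg.div_factor,
                       final_div_factor=cfg.final_div_factor)

    best_loss = np.inf
    best_state = model.state_dict()
    bad_epochs = 0
    epochs_run = 0
    last_train_loss = np.inf
    for epoch in range(cfg.epochs):
        epochs_run = epoch + 1
        model.train()
        order = rng.permutation(tr_idx.size)
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            xb = _slice(train_streams, batch)
            yb = y_tr[batch]
            if cfg.input_noise > 0:
                xb = {m: a + rng.normal(0, cfg.input_noise, a.shape).astype(a.dtype)
                      for m, a in xb.items()}
            if cfg.mixup_alpha > 0 and batch.size > 1:
                lam = float(rng.beta(cfg.mixup_alpha, cfg.mixup_alpha))
                perm = rng.permutation(batch.size)
                xb = {m: lam * a + (1.0 - lam) * a[perm] for m, a in xb.items()}
                logits = _logits(model, xb)
                loss = (training_loss(logits, yb, weights, cfg.l1_coef,
                                      gate_params) * lam
                        + training_loss(logits, yb[perm], weights,
                                        cfg.l1_coef, gate_params) * (1.0 - lam))
            else:
                logits = _logits(model, xb)
                loss = training_loss(logits, yb, weights,
                                     cfg.l1_coef, gate_params)
            model.zero_grad()
            loss.backward()
            clip_grad_norm(params, cfg.grad_clip)
            opt.step()
            sched.step()
            last_train_loss = float(loss.item())
        if not cfg.early_stopping:
            continue
        model.eval()
        val_logits = _logits(model, val_streams)
        val_loss = float(training_loss(val_logits, y_val, weights).item())
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    if cfg.early_stopping:
        model.load_state_dict(best_state)
    else:
        best_loss = last_train_loss
    model.eval()
    return epochs_run, float(best_loss)


def train_fold(model_factory, train_features: list[SubjectFeatures],
               test_feature: SubjectFeatures, cfg: TrainConfig,
               fold_index: int = 0,
               weights: np.ndarray | None = None) -> FoldResult:
    """Train on ``train_features`` and score the held-out subject.

    With ``cfg.n_ensemble > 1``, several independently seeded models are
    trained per fold and their predicted probabilities averaged.
    ``weights`` should be cohort-level class weights (see ``train_model``);
    by default they are computed over train + test labels of this fold.
    """
    from .model import softmax_probabilities

    labels = np.array([f.label for f in train_features])
    if weights is None:
        weights = class_weights(np.append(labels, test_feature.label))
    p1s, epochs, best_vals = [], [], []
    modalities = None
    for member in range(cfg.n_ensemble):
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(fold_index, member)))
        model = model_factory(int(rng.integers(0, 2**31 - 1)))
        if modalities is None:
            modalities = getattr(getattr(model, "cfg", None), "modalities",
                                 ("roi", "ica", "conn"))
            streams = stack_streams(train_features, modalities)
            test_streams = stack_streams([test_feature], modalities)
        epochs_run, best_val = train_model(model, streams, labels, cfg, rng,
                                           weights=weights)
        logits = _logits(model, test_streams)
        p1s.append(float(softmax_probabilities(logits.data)[0, 1]))
        epochs.append(epochs_run)
        best_vals.append(best_val)
    return FoldResult(test_feature.subject_id, int(test_feature.label),
                      float(np.mean(p1s)), int(np.max(epochs)),
                      float(np.min(best_vals)))


def run_loocv(model_factory, features: list[SubjectFeatures],
              cfg: TrainConfig) -> list[FoldResult]:
    """Leave-one-out cross-validation: each subject is scored by a model that
    never saw any of its streams."""
    by_id = {f.subject_id: f for f in features}
    splits = make_loocv_splits([f.subject_id for f in features])
    cohort_weights = class_weights(np.array([f.label for f in features]))
    results = []
    for k, (train_ids, test_id) in enumerate(splits):
        results.append(train_fold(model_factory, [by_id[s] for s in train_ids],
                                  by_id[test_id], cfg, fold_index=k,
                                  weights=cohort_weights))
    return results


def impact_factory(model_cfg: ModelConfig):
    """Factory producing a fresh IMPACT model per fold (seed injected)."""
    def make(seed: int) -> ImpactModel:
        return ImpactModel(replace(model_cfg, seed=seed))
    return make


# ------------------------------------------------------------------- metrics

def compute_metrics(folds: list[FoldResult], n_resamples: int = 0,
                    seed: int = 0) -> MetricReport:
    """Point metrics (AUC by rank formulation, threshold-0.5 accuracy, F1,
    balanced accuracy, MCC) with optional subject-level bootstrap CIs."""
    y = np.array([f.y_true for f in folds])
    p = np.array([f.p1 for f in folds])
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined: both classes must be present")
    pred = (p > 0.5).astype(int)
    report = MetricReport(
        auc=auc_rank(y, p),
        accuracy=float((pred == y).mean()),
        f1=float(f1_score(y, pred, zero_division=0)),
        balanced_accuracy=float(balanced_accuracy_score(y, pred)),
        mcc=float(matthews_corrcoef(y, pred)),
    )
    if n_resamples > 0:
        stats = {
            "auc": lambda yy, pp: auc_rank(yy, pp),
            "accuracy": lambda yy, pp: float(((pp > 0.5).astype(int) == yy).mean()),
            "f1": lambda yy, pp: float(f1_score(yy, (pp > 0.5).astype(int),
                                                zero_division=0)),
            "balanced_accuracy": lambda yy, pp: float(
                balanced_accuracy_score(yy, (pp > 0.5).astype(int))),
            "mcc": lambda yy, pp: float(matthews_corrcoef(yy, (pp > 0.5).astype(int))),
        }
        for name, fn in stats.items():
            report.ci[name] = bootstrap_ci((y, p), fn, n_resamples=n_resamples,
                                           seed=seed)
        report.n_resamples = n_resamples
    return report


def bootstrap_distribution(folds: list[FoldResult], n_resamples: int,
                           seed: int) -> np.ndarray:
    """Bootstrap distribution of the AUC under subject-level resampling."""
    y = np.array([f.y_true for f in folds])
    p = np.array([f.p1 for f in folds])
    rng = np.random.default_rng(seed)
    out = np.empty(n_resamples)
    got = 0
    while got < n_resamples:
        idx = rng.integers(0, y.size, size=y.size)
        if np.unique(y[idx]).size < 2:
            continue
        out[got] = auc_rank(y[idx], p[idx])
        got += 1
    return out


def compare_models(results: dict[str, list[FoldResult]], reference: str,
                   n_resamples: int = 10_000, seed: int = 0,
                   q: float = 0.05) -> list[ComparisonResult]:
    """Compare the reference model against every other model.

    Each model's per-subject predictions are bootstrapped into an AUC
    distribution (``n_resamples`` draws); Mann-Whitney U tests compare the
    reference distribution to each competitor's, Cliff's delta quantifies the
    effect size (with a percentile bootstrap CI over the two distributions),
    and p-values are Benjamini-Hochberg adjusted across the comparisons.
    """
    if reference not in results:
        raise ValueError(f"unknown reference model '{reference}'")
    dists = {name: bootstrap_distribution(folds, n_resamples, seed=seed + i)
             for i, (name, folds) in enumerate(sorted(results.items()))}
    ref = dists[reference]
    rows: list[ComparisonResult] = []
    rng = np.random.default_rng(seed)
    for name in sorted(results):
        if name == reference:
            continue
        other = dists[name]
        u, p = mann_whitney_u(ref, other)
        delta = cliffs_delta(ref, other)
        resampled = np.empty(200)
        for b in range(200):
            ia = rng.integers(0, ref.size, size=ref.size)
            ib = rng.integers(0, other.size, size=other.size)
            resampled[b] = cliffs_delta(ref[ia], other[ib])
        lo, hi = np.quantile(resampled, [0.025, 0.975])
        rows.append(ComparisonResult(reference, name, u, p, np.nan, False,
                                     delta, (float(lo), float(hi))))
    adjusted, flags = benjamini_hochberg([r.p_value for r in rows], q=q)
    for row, adj, flag in zip(rows, adjusted, flags):
        row.p_adjusted = float(adj)
        row.reject = bool(flag)
    return rows


# ------------------------------------------------------------------ ablation

def run_ablation(features: list[SubjectFeatures], model_cfg: ModelConfig,
                 cfg: TrainConfig,
                 subsets: tuple[tuple[str, ...], ...] = ABLATION_SUBSETS,
                 n_splits: int = 5) -> pd.DataFrame:
    """Train modality-subset variants under stratified k-fold CV.

    Absent modalities are removed from the fusion (the gate softmax runs over
    the remaining streams; cross attention only engages when both ROI and ICA
    are present). Returns one row per configuration with fold-wise
    mean +/- sd of AUC, accuracy and F1.
    """
    labels = np.array([f.label for f in features])
    rows = []
    for si, subset in enumerate(subsets):
        if not subset:
            raise ValueError("modality subset must be non-empty")
        sub_cfg = replace(model_cfg, modalities=tuple(subset))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=cfg.seed)
        fold_metrics = []
        for k, (tr, te) in enumerate(skf.split(np.zeros(len(features)), labels)):
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed, spawn_key=(si, k)))
            model = ImpactModel(replace(sub_cfg, seed=int(rng.integers(2**31 - 1))))
            streams = stack_streams([features[i] for i in tr], sub_cfg.modalities)
            train_model(model, streams, labels[tr], cfg, rng,
                        weights=class_weights(labels))
            test_streams = stack_streams([features[i] for i in te],
                                         sub_cfg.modalities)
            from .model import softmax_probabilities
            p1 = softmax_probabilities(_logits(model, test_streams).data)[:, 1]
            y_te = labels[te]
            pred = (p1 > 0.5).astype(int)
            fold_metrics.append({
                "auc": auc_rank(y_te, p1),
                "accuracy": float((pred == y_te).mean()),
                "f1": float(f1_score(y_te, pred, zero_division=0)),
            })
        fm = pd.DataFrame(fold_metrics)
        rows.append({
            "configuration": "+".join(subset),
            **{f"{m}_mean": fm[m].mean() for m in fm.columns},
            **{f"{m}_sd": fm[m].std(ddof=1) for m in fm.columns},
        })
    return pd.DataFrame(rows)
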