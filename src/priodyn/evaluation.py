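"""Cross-validated evaluation: decoding / self-prediction metrics, dimension
sweeps, the performance-frontier test, forecasting baselines and latent-state
standardization for visualization.

Decoding accuracy is the mean Pearson correlation (CC) between each behavior
dimension and its one-step-ahead prediction from past neural activity alone;
neural self-prediction is the analogous CC for the neural channels.  Folds are
contiguous segments of the recording, so test data is never interleaved with
training data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from .model import ModelSpec, Predictions
from .training import FitConfig, TimeSeriesPair, fit

__all__ = [
    "contiguous_kfold",
    "mean_cc",
    "multiclass_auc",
    "dimension_sweep",
    "select_dimension",
    "performance_frontier",
    "paired_signed_rank",
    "naive_forecast_baseline",
    "standardize_2d_latents",
    "DEFAULT_DIMS",
]

DEFAULT_DIMS = (1, 2, 4, 8, 16, 32, 64, 128)  # powers of 2 from 1 to 128


def contiguous_kfold(T: int, K: int):
    """K contiguous, disjoint, exhaustive (train, test) index arrays.

    Fold lengths differ by at most one; the remainder goes to the earliest
    folds.
    """
    if T < K:
        raise ValueError("need at least K samples")
    base, rem = divmod(T, K)
    folds = []
    start = 0
    for k in range(K):
        length = base + (1 if k < rem else 0)
        test = np.arange(start, start + length)
        train = np.concatenate([np.arange(0, start), np.arange(start + length, T)])
        folds.append((train, test))
        start += length
    return folds


def mean_cc(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson CC per dimension, averaged.

    Dimensions with constant *actual* values have undefined CC and are
    excluded with a warning; a constant *predicted* dimension carries no
    signal and scores 0.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("shape mismatch")
    if actual.ndim == 1:
        actual, predicted = actual[:, None], predicted[:, None]
    ccs = []
    for j in range(actual.shape[1]):
        a, p = actual[:, j], predicted[:, j]
        sa, sp = a.std(), p.std()
        if sa == 0:
            warnings.warn(f"dimension {j} is constant; excluded from mean CC")
            continue
        if sp == 0:
            ccs.append(0.0)
            continue
        ccs.append(float(np.corrcoef(a, p)[0, 1]))
    if not ccs:
        raise ValueError("no dimension with defined CC")
    return float(np.mean(ccs))


def multiclass_auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """One-vs-rest ROC AUC per class, macro-averaged.

    ``labels`` is (T,) integer classes (or (T, n_z); dimensions are averaged);
    ``probabilities`` is (T, n_c) or (T, n_z, n_c).  Classes absent from the
    labels are excluded with a warning.  1 is perfect, 0.5 is chance.
    """
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.ndim == 3:
        if labels.ndim != 2:
            raise ValueError("3-D probabilities require (T x n_z) labels")
        return float(
            np.mean(
                [
                    multiclass_auc(labels[:, j], probabilities[:, j])
                    for j in range(probabilities.shape[1])
                ]
            )
        )
    n_c = probabilities.shape[1]
    aucs = []
    for c in range(n_c):
        pos = labels == c
        if not pos.any():
            warnings.warn(f"class {c} absent from labels; excluded from AUC")
            continue
        if pos.all():
            warnings.warn(f"class {c} is the only label; AUC undefined, excluded")
            continue
        aucs.append(roc_auc_score(pos.astype(int), probabilities[:, c]))
    if not aucs:
        raise ValueError("no class with defined AUC")
    return float(np.mean(aucs))


def _evaluate(model, data: TimeSeriesPair):
    preds = model.decode(data.Y)
    if model.spec.behavior_mode == "categorical":
        dec = multiclass_auc(data.Z, preds.z_hat)
    else:
        dec = mean_cc(data.Z, preds.z_hat)
    sp = mean_cc(data.Y, preds.y_hat)
    return dec, sp


def dimension_sweep(
    data: TimeSeriesPair,
    spec_template: ModelSpec,
    cfg: FitConfig | None = None,
    dims=DEFAULT_DIMS,
    n_folds: int = 5,
    n1_cap: int = 16,
) -> pd.DataFrame:
    """Fit one model per (fold, total state dimension) and tabulate metrics.

    The behavior-prioritized dimension is ``n_1 = min(n1_cap, n_x)`` unless the
    template fixes its own rule via ``n1_cap``.  Returns tidy rows
    (fold, dim, split, metric, value) where split is train or test.
    """
    cfg = FitConfig() if cfg is None else cfg
    dims = sorted(dims)
    rows = []
    for fold, (tr, te) in enumerate(contiguous_kfold(data.T, n_folds)):
        train, test = data.slice(tr), data.slice(te)
        for dim in dims:
            spec = spec_template.replace(n_x=dim, n_1=min(n1_cap, dim))
            try:
                model = fit(train, spec, cfg.replace(seed=cfg.seed + fold))
            except (FloatingPointError, ValueError) as exc:
                warnings.warn(f"fit failed for fold {fold}, dim {dim}: {exc}")
                continue
            for split, part in (("train", train), ("test", test)):
                dec, sp = _evaluate(model, part)
                rows.append(dict(fold=fold, dim=dim, split=split, metric="decoding", value=dec))
                rows.append(dict(fold=fold, dim=dim, split=split, metric="selfpred", value=sp))
    return pd.DataFrame(rows)


def select_dimension(report: pd.DataFrame, rule: str = "decoding_peak") -> dict:
    """Per-fold state-dimension selection from *training-data* metric curves.

    ``decoding_peak``: smallest dimension attaining the training-decoding
    maximum.  ``joint_peak``: the larger of (smallest dimension at the
    training self-prediction peak, smallest dimension at the training decoding
    peak).
    """
    if rule not in ("decoding_peak", "joint_peak"):
        raise ValueError(f"unknown rule {rule!r}")
    train = report[report["split"] == "train"]
    if train.empty:
        raise ValueError("empty metric curves")
    out = {}
    for fold, grp in train.groupby("fold"):
        def smallest_at_peak(metric):
            curve = (
                grp[grp["metric"] == metric]
                .groupby("dim")["value"].mean().sort_index()
            )
            return int(curve.index[np.argmax(curve.values >= curve.max())])

        d_dec = smallest_at_peak("decoding")
        if rule == "decoding_peak":
            out[fold] = d_dec
        else:
            out[fold] = max(d_dec, smallest_at_peak("selfpred"))
    return out


def paired_signed_rank(a, b, side: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank p-value for paired samples.

    All-zero differences return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("unpaired samples")
    d = a - b
    if np.all(d == 0):
        return 1.0
    res = scipy.stats.wilcoxon(a, b, alternative=side, zero_method="wilcox")
    return float(res.pvalue)


def _significantly_better(a, b, alpha=0.05, min_rel=0.01) -> bool:
    """Significance: signed-rank P <= alpha AND >= 1% relative mean difference."""
    ma, mb = np.mean(a), np.mean(b)
    if not (ma - mb >= min_rel * abs(mb)):
        return False
    return paired_signed_rank(a, b, "greater") <= alpha


def performance_frontier(metric_samples: dict, alpha=0.05, min_rel=0.01) -> dict:
    """Best-performance-frontier membership for a group of models.

    ``metric_samples`` maps model name -> (decoding samples, self-prediction
    samples), paired across session-folds.  Model A is on the frontier if
    against every other model B it is significantly better in decoding, or
    significantly better in self-prediction, or not significantly different
    in both.  Significance requires both a one-sided signed-rank P <= alpha
    and at least ``min_rel`` relative difference of means.
    """
    names = list(metric_samples)
    if len(names) < 1:
        raise ValueError("need at least one model")
    lengths = {len(v[0]) for v in metric_samples.values()} | {
        len(v[1]) for v in metric_samples.values()
    }
    if len(lengths) != 1:
        raise ValueError("unpaired samples across models")
    on = {}
    for a in names:
        da, sa = metric_samples[a]
        ok = True
        for b in names:
            if a == b:
                continue
            db, sb = metric_samples[b]
            if _significantly_better(da, db, alpha, min_rel):
                continue
            if _significantly_better(sa, sb, alpha, min_rel):
                continue
            if _significantly_better(db, da, alpha, min_rel) or _significantly_better(
                sb, sa, alpha, min_rel
            ):
                ok = False
                break
        on[a] = ok
    return on


def naive_forecast_baseline(Y: np.ndarray, m: int) -> Predictions:
    """Model-free m-step prediction: hold the last observed value.

    The prediction for time k is ``Y[k - m]`` (earliest value for k < m);
    reflects only the smoothness of the series.
    """
    if m < 1:
        raise ValueError("horizon m must be >= 1")
    Y = np.asarray(Y, dtype=float)
    y_hat = np.empty_like(Y)
    y_hat[: m] = Y[0]
    y_hat[m:] = Y[:-m]
    return Predictions(y_hat=y_hat, z_hat=np.zeros((Y.shape[0], 0)), horizon=m)


def standardize_2d_latents(condition_trajs):
    """Standardize 2-D latent trajectories for across-fold averaging.

    ``condition_trajs`` is a sequence of (T_c x 2) mean state trajectories,
    one per behavioral condition.  All are z-scored with pooled statistics,
    rotated so the first condition's trajectory starts at polar angle 0, and
    reflected (second dimension negated) if the first condition's rotation
    direction is not counterclockwise.  The identical transform applies to
    every condition.
    """
    trajs = [np.asarray(t, dtype=float) for t in condition_trajs]
    if any(t.ndim != 2 or t.shape[1] != 2 for t in trajs):
        raise ValueError("trajectories must be (T x 2)")
    pooled = np.concatenate(trajs, axis=0)
    mean, std = pooled.mean(axis=0), pooled.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    trajs = [(t - mean) / std for t in trajs]
    p0 = trajs[0][0]
    theta = np.arctan2(p0[1], p0[0])
    c, s = np.cos(-theta), np.sin(-theta)
    Rot = np.array([[c, -s], [s, c]])
    trajs = [t @ Rot.T for t in trajs]
    # signed area of the first condition's trajectory: positive = counterclockwise
    t0 = trajs[0]
    area = 0.5 * np.sum(t0[:-1, 0] * t0[1:, 1] - t0[1:, 0] * t0[:-1, 1])
    if area < 0:
        trajs = [t * np.array([1.0, -1.0]) for t in trajs]
    return trajs
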