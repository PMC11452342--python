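"""Four-step prioritized optimization of the two-section model.

Step 1 trains section 1 end-to-end (recursion, neural input and behavior
readout) to minimize the behavior prediction loss, so the first ``n_1`` latent
dimensions are learned with behavior priority.  Step 2 fits the section-1
neural readout on the frozen extracted states.  Step 3 trains section 2 to
predict the neural residual left by section 1, receiving both the neural
observation and the updated section-1 state as inputs.  Step 4 (used when
``n_1 = 0``, or on request) fits a joint behavior readout from both state
blocks.  Each step is independent of later steps; none is revisited.

Losses are negative log-likelihoods: sum of squared errors for continuous
(Gaussian) series and categorical cross-entropy for discrete behavior, in both
cases restricted to time steps where behavior is observed (intermittent
sampling).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("priodyn.training")

from ._rnn import RNNSection
from .maps import Adam, LinearMap, MLPMap, ParamMap
from .model import DPADModel, ModelSpec, _Scaler, build_model, softmax_probabilities

__all__ = [
    "TimeSeriesPair",
    "FitConfig",
    "loss_gaussian",
    "loss_categorical",
    "fit",
    "fit_step1",
    "fit_step2",
    "fit_step3",
    "fit_step4",
    "estimate_noise_covariances",
]

PROB_CLAMP = 1e-7  # floor for categorical probabilities inside the NLL


@dataclass
class TimeSeriesPair:
    """Aligned neural series ``Y`` (T x n_y) and behavior ``Z``.

    ``Z`` is (T x n_z) continuous or (T x n_z) integer class labels.  ``mask``
    flags the time steps at which behavior was observed (all true when fully
    sampled).  ``dt`` is the sampling interval in seconds.
    """

    Y: np.ndarray
    Z: np.ndarray
    mask: np.ndarray | None = None
    dt: float = 0.05

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.Z = np.asarray(self.Z)
        if self.Y.ndim != 2 or self.Z.ndim != 2:
            raise ValueError("Y and Z must be 2-D (time x channels)")
        if self.Y.shape[0] != self.Z.shape[0]:
            raise ValueError("Y and Z must have equal length")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("Y contains non-finite values")
        if self.mask is None:
            self.mask = np.ones(self.Y.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.Y.shape[0],):
            raise ValueError("mask must be (T,)")
        if not np.all(np.isfinite(np.asarray(self.Z, dtype=float)[self.mask])):
            raise ValueError("Z must be finite wherever mask is true")

    @property
    def T(self) -> int:
        return self.Y.shape[0]

    def slice(self, idx) -> "TimeSeriesPair":
        return TimeSeriesPair(self.Y[idx], self.Z[idx], self.mask[idx], self.dt)


@dataclass
class FitConfig:
    """Optimization settings shared by all four steps.

    ``max_epochs``/``patience`` implement the convergence rule: stop when the
    training objective fails to improve for ``patience`` consecutive epochs.
    Continuous recordings are cut into ``sequence_length`` chunks (state reset
    to zero at chunk starts) for truncated backpropagation, trained with Adam
    in minibatches of ``batch_size`` sequences.
    """

    max_epochs: int = 2500
    patience: int = 3
    learning_rate: float = 0.003
    batch_size: int = 32
    sequence_length: int = 128
    seed: int = 0
    scale_inputs: bool = True
    fit_unified_cy: bool = False
    clip_norm: float = 10.0  # global gradient-norm clip (recurrent steps)
    regularization: float = 0.0  # L2 weight; config hook, unused by default

    def replace(self, **kw) -> "FitConfig":
        import dataclasses

        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def loss_gaussian(actual: np.ndarray, predicted: np.ndarray, mask=None) -> float:
    """Sum over observed samples of the squared two-norm prediction error."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("shape mismatch")
    if mask is None:
        mask = np.ones(actual.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask excludes all samples (empty objective)")
    err = actual[mask] - predicted[mask]
    return float(np.sum(err * err))


def loss_categorical(labels: np.ndarray, probabilities: np.ndarray, mask=None) -> float:
    """Summed negative log probability of the true class over observed steps.

    ``labels`` is (T x n_z) integer classes; ``probabilities`` is
    (T x n_z x n_c), normalized over the class axis.  Probabilities are
    clamped at ``PROB_CLAMP`` to avoid log 0.
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    T, n_z, n_c = probabilities.shape
    if labels.shape != (T, n_z):
        raise ValueError("labels must be (T x n_z)")
    if mask is None:
        mask = np.ones(T, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask excludes all samples (empty objective)")
    p = probabilities[mask]
    lab = labels[mask].astype(int)
    picked = np.take_along_axis(p, lab[:, :, None], axis=2)[:, :, 0]
    return float(-np.log(np.maximum(picked, PROB_CLAMP)).sum())


# ---------------------------------------------------------------------------
# internal trainers
# ---------------------------------------------------------------------------

def _chop(T: int, L: int):
    """Split 0..T-1 into consecutive chunks of length L (last may be short)."""
    starts = list(range(0, T, L))
    return [(s, min(s + L, T)) for s in starts]


def _readout_loss_grad(readout, X_flat, targets, weights, mode, n_z, n_c):
    """Loss (mean over observed elements) and dL/d(readout input states)."""
    out, cache = readout.forward(X_flat)
    if mode == "gaussian":
        err = (out - targets) * weights[:, None]
        denom = max(weights.sum() * targets.shape[1], 1.0)
        loss = float(np.sum(err * err) / denom)
        g_out = 2.0 * err / denom
    else:  # categorical cross-entropy on logits
        N = X_flat.shape[0]
        P = softmax_probabilities(out, n_z, n_c)
        lab = targets.astype(int)
        onehot = np.zeros_like(P)
        idx0 = np.repeat(np.arange(N), n_z)
        idx1 = np.tile(np.arange(n_z), N)
        onehot[idx0, idx1, lab.ravel()] = 1.0
        denom = max(weights.sum() * n_z, 1.0)
        picked = np.take_along_axis(P, lab[:, :, None], axis=2)[:, :, 0]
        loss = float(
            -(np.log(np.maximum(picked, PROB_CLAMP)) * weights[:, None]).sum() / denom
        )
        g_logits = (P - onehot) * weights[:, None, None] / denom
        g_out = g_logits.reshape(N, n_z * n_c)
    g_X = readout.vjp(cache, g_out)
    return loss, g_X


def _train_recurrent(
    section: RNNSection,
    readout: ParamMap,
    U: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    cfg: FitConfig,
    mode: str,
    n_z: int = 0,
    n_c: int = 0,
    rng: np.random.Generator | None = None,
    x0: np.ndarray | None = None,
    step_name: str = "step",
):
    """Train a recurrent section end-to-end with truncated BPTT + Adam.

    ``U`` (T x u_dim) drives the state; the readout of the exposed state at
    time t predicts ``targets[t]`` with per-step loss weight ``weights[t]``.
    Early stopping: strict no-improvement for ``cfg.patience`` epochs; the
    best-epoch weights are restored.  When ``x0`` is given it is trained as
    the shared initial carry of every sequence.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    T = U.shape[0]
    chunks = _chop(T, cfg.sequence_length)
    params = [*section.params, *readout.params]
    if x0 is not None:
        params = [*params, x0]
        x0_grad = np.zeros_like(x0)
    opt = Adam(params, lr=cfg.learning_rate)
    best_loss = np.inf
    best_weights = None
    stall = 0
    n = section.n

    # group equal-length chunks so each minibatch is a dense (B, L, .) batch
    full = [c for c in chunks if c[1] - c[0] == cfg.sequence_length]
    tail = [c for c in chunks if c[1] - c[0] != cfg.sequence_length]

    def run_batch(batch_chunks, train=True):
        L = batch_chunks[0][1] - batch_chunks[0][0]
        B = len(batch_chunks)
        Ub = np.stack([U[s:e] for s, e in batch_chunks])
        Tb = np.stack([targets[s:e] for s, e in batch_chunks])
        Wb = np.stack([weights[s:e] for s, e in batch_chunks])
        carry = section.init_carry(B)
        if x0 is not None:
            carry = carry + x0[None, :]
        X = np.empty((B, L, n))
        caches = []
        for t in range(L):
            X[:, t] = section.exposed(carry)
            if t < L - 1:
                carry, cache = section.step(carry, Ub[:, t])
                caches.append(cache)
        X_flat = X.reshape(B * L, n)
        W_flat = Wb.reshape(B * L)
        if mode == "gaussian":
            T_flat = Tb.reshape(B * L, -1)
        else:
            T_flat = Tb.reshape(B * L, n_z)
        loss, g_X = _readout_loss_grad(readout, X_flat, T_flat, W_flat, mode, n_z, n_c)
        if not np.isfinite(loss):
            raise FloatingPointError("training loss diverged (non-finite)")
        if not train:
            return loss
        GX = g_X.reshape(B, L, n)
        g = np.zeros((B, section.carry_dim))
        g[:, :n] = GX[:, L - 1]
        for t in range(L - 2, -1, -1):
            g = section.step_vjp(caches[t], g)
            g[:, :n] += GX[:, t]
        if x0 is not None:
            x0_grad[...] += g.sum(axis=0)  # dL/d(initial carry), shared
        return loss

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(full))
        batches = [
            [full[i] for i in order[b : b + cfg.batch_size]]
            for b in range(0, len(full), cfg.batch_size)
        ]
        if tail:
            batches.append(tail)
        if not batches:
            raise ValueError("no training sequences")
        epoch_loss = 0.0
        total_w = 0.0
        for batch in batches:
            section.zero_grad()
            readout.zero_grad()
            if x0 is not None:
                x0_grad[...] = 0.0
            loss = run_batch(batch)
            grads = [*section.grads, *readout.grads]
            if x0 is not None:
                grads = [*grads, x0_grad]
            if cfg.regularization > 0.0:
                grads = [g + 2.0 * cfg.regularization * p for g, p in zip(grads, params)]
            if cfg.clip_norm > 0.0:
                norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
                if norm > cfg.clip_norm:
                    grads = [g * (cfg.clip_norm / norm) for g in grads]
            opt.step(grads)
            w = sum(weights[s:e].sum() for s, e in batch)
            epoch_loss += loss * max(w, 1.0)
            total_w += max(w, 1.0)
        epoch_loss /= max(total_w, 1.0)
        logger.debug("%s epoch %d: loss %.6g", step_name, epoch + 1, epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_weights = [p.copy() for p in params]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    if best_weights is not None:
        for p, w in zip(params, best_weights):
            p[...] = w
    return best_loss


def _fit_static(
    readout: ParamMap,
    X: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    cfg: FitConfig,
    mode: str,
    n_z: int = 0,
    n_c: int = 0,
):
    """Fit a static readout map on frozen states.

    Linear Gaussian readouts are solved exactly by least squares (the unique
    minimizer of the same sum-of-squares objective); anything else is trained
    with Adam under the same early-stopping rule as the recurrent steps.
    """
    obs = weights > 0
    if not obs.any():
        raise ValueError("mask excludes all samples (empty objective)")
    if isinstance(readout, LinearMap) and mode == "gaussian" and not readout.has_bias:
        W, *_ = np.linalg.lstsq(X[obs], targets[obs], rcond=None)
        readout.W[...] = W.T
        err = X[obs] @ W - targets[obs]
        return float(np.sum(err * err) / max(obs.sum() * targets.shape[1], 1))
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(readout.params, lr=cfg.learning_rate)
    best_loss, best_weights, stall = np.inf, None, 0
    N = X.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(N)
        epoch_loss, total_w = 0.0, 0.0
        bs = max(cfg.batch_size * cfg.sequence_length, 256)
        for b in range(0, N, bs):
            idx = order[b : b + bs]
            readout.zero_grad()
            loss, _ = _readout_loss_grad(
                readout, X[idx], targets[idx], weights[idx], mode, n_z, n_c
            )
            if not np.isfinite(loss):
                raise FloatingPointError("readout training loss diverged")
            opt.step(readout.grads)
            w = max(weights[idx].sum(), 1.0)
            epoch_loss += loss * w
            total_w += w
        epoch_loss /= total_w
        if epoch_loss < best_loss:
            best_loss, best_weights, stall = epoch_loss, readout.get_weights(), 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    if best_weights is not None:
        readout.set_weights(best_weights)
    return best_loss


# ---------------------------------------------------------------------------
# the four optimization steps
# ---------------------------------------------------------------------------

def _behavior_targets_weights(model: DPADModel, data: TimeSeriesPair):
    spec = model.spec
    w = data.mask.astype(float)
    if spec.behavior_mode == "categorical":
        Z = np.where(data.mask[:, None], data.Z, 0).astype(int)
        return Z, w
    Zs = model.z_scaler.transform(np.where(data.mask[:, None], data.Z, 0.0))
    return Zs, w


def fit_step1(model: DPADModel, data: TimeSeriesPair, cfg: FitConfig) -> np.ndarray:
    """Train section 1 end-to-end on the behavior loss; return states x1.

    Returns the filtered section-1 states on the training data, including the
    one-step-ahead state (T+1 rows).
    """
    spec = model.spec
    if spec.n_1 < 1:
        raise ValueError("step 1 requires n_1 >= 1")
    Ys = model.y_scaler.transform(data.Y)
    targets, w = _behavior_targets_weights(model, data)
    mode = "categorical" if spec.behavior_mode == "categorical" else "gaussian"
    _train_recurrent(
        model.section1,
        model.Cz1,
        Ys,
        targets,
        w,
        cfg,
        mode,
        n_z=spec.n_z,
        n_c=spec.n_c or 0,
        rng=np.random.default_rng(cfg.seed),
        x0=model.x0_1 if spec.learn_initial_state else None,
        step_name="step1",
    )
    return model.section1.run(Ys, model.x0_1[None, :])


def fit_step2(model: DPADModel, x1: np.ndarray, Y: np.ndarray, cfg: FitConfig) -> None:
    """Fit the section-1 neural readout C_y^(1) on frozen states x1."""
    Ys = model.y_scaler.transform(Y)
    if x1.shape[0] == Ys.shape[0] + 1:
        x1 = x1[:-1]
    _fit_static(model.Cy1, x1, Ys, np.ones(Ys.shape[0]), cfg, "gaussian")


def fit_step3(model: DPADModel, data: TimeSeriesPair, x1: np.ndarray, cfg: FitConfig) -> np.ndarray:
    """Train section 2 on the aggregate neural loss; return states x2.

    The section-2 input is ``[y_k, x1_{k+1}]`` (just ``y_k`` when n_1 = 0) and
    its target is the neural residual ``y_k - C_y^(1)(x1_k)``.
    """
    spec = model.spec
    if spec.n_2 < 1:
        raise ValueError("step 3 requires n_2 >= 1")
    Ys = model.y_scaler.transform(data.Y)
    T = Ys.shape[0]
    if spec.n_1 > 0:
        if x1.shape[0] != T + 1:
            raise ValueError("x1 must include the one-step-ahead state (T+1 rows)")
        U2 = np.concatenate([Ys, x1[1:]], axis=1)
        resid = Ys - model.Cy1(x1[:T])
    else:
        U2 = Ys
        resid = Ys
    _train_recurrent(
        model.section2,
        model.Cy2,
        U2,
        resid,
        np.ones(T),
        cfg,
        "gaussian",
        rng=np.random.default_rng(cfg.seed + 2),
        x0=model.x0_2 if spec.learn_initial_state else None,
        step_name="step3",
    )
    return model.section2.run(U2, model.x0_2[None, :])


def fit_step4(
    model: DPADModel,
    x1: np.ndarray,
    x2: np.ndarray,
    data: TimeSeriesPair,
    cfg: FitConfig,
) -> None:
    """Fit a unified behavior readout C_z(x1, x2) replacing the per-section
    readouts; optionally also a unified neural readout C_y."""
    from .model import _make_readout

    spec = model.spec
    T = data.T
    X = np.concatenate([x1[:T], x2[:T]], axis=1)
    model.unified_Cz = _make_readout(spec, "Cz", X.shape[1], spec.cz_out_dim)
    targets, w = _behavior_targets_weights(model, data)
    mode = "categorical" if spec.behavior_mode == "categorical" else "gaussian"
    _fit_static(model.unified_Cz, X, targets, w, cfg, mode, spec.n_z, spec.n_c or 0)
    if cfg.fit_unified_cy:
        model.unified_Cy = _make_readout(spec, "Cy", X.shape[1], spec.n_y)
        Ys = model.y_scaler.transform(data.Y)
        _fit_static(model.unified_Cy, X, Ys, np.ones(T), cfg, "gaussian")


def estimate_noise_covariances(model: DPADModel, data: TimeSeriesPair):
    """Sample covariances of the one-step-ahead residuals e_k and eps_k."""
    preds = model.decode(data.Y)
    e = data.Y - preds.y_hat
    T = data.T
    if T <= model.spec.n_y:
        warnings.warn("fewer samples than neural dimensions: Sigma_e is rank deficient")
    Sigma_e = (e - e.mean(0)).T @ (e - e.mean(0)) / max(T - 1, 1)
    if model.spec.behavior_mode == "continuous":
        obs = data.mask
        eps = (data.Z[obs] - preds.z_hat[obs]).astype(float)
        n_obs = obs.sum()
        if n_obs <= model.spec.n_z:
            warnings.warn("fewer samples than behavior dimensions: Sigma_eps is rank deficient")
        eps = eps - eps.mean(0)
        Sigma_eps = eps.T @ eps / max(n_obs - 1, 1)
    else:
        Sigma_eps = np.zeros((model.spec.n_z, model.spec.n_z))
    model.Sigma_e = Sigma_e
    model.Sigma_eps = Sigma_eps
    return Sigma_e, Sigma_eps


def fit(data: TimeSeriesPair, spec: ModelSpec, cfg: FitConfig | None = None) -> DPADModel:
    """Run the four-step prioritized optimization and return the fitted model.

    Steps 1-2 run when ``n_1 > 0``; steps 3-4 when ``n_1 < n_x``.  When
    ``0 < n_1 < n_x`` step 4 is skipped and behavior is predicted from the
    section-1 states alone.  Finishes by estimating the residual covariances.
    """
    cfg = FitConfig() if cfg is None else cfg
    spec = spec.replace()  # validate / normalize settings
    if data.Y.shape[1] != spec.n_y:
        raise ValueError("data/spec neural dimension mismatch")
    if data.Z.shape[1] != spec.n_z:
        raise ValueError("data/spec behavior dimension mismatch")
    model = build_model(spec, seed=np.random.default_rng(cfg.seed))
    if cfg.scale_inputs:
        model.y_scaler = _Scaler.fit(data.Y)
        if spec.behavior_mode == "continuous":
            model.z_scaler = _Scaler.fit(np.asarray(data.Z, dtype=float), data.mask)
    x1 = np.zeros((data.T + 1, 0))
    if spec.n_1 > 0:
        logger.info("step 1: training section 1 (n_1=%d) on behavior loss", spec.n_1)
        x1 = fit_step1(model, data, cfg)
        logger.info("step 2: fitting section-1 neural readout")
        fit_step2(model, x1, data.Y, cfg)
    if spec.n_2 > 0:
        logger.info("step 3: training section 2 (n_2=%d) on residual neural loss", spec.n_2)
        x2 = fit_step3(model, data, x1, cfg)
        if spec.n_1 == 0:
            logger.info("step 4: fitting joint behavior readout")
            fit_step4(model, x1, x2, data, cfg)
    estimate_noise_covariances(model, data)
    return model
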