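"""Two-section recurrent state-space model in predictor form.

The model jointly describes neural activity ``y_k`` and behavior ``z_k``
through latent states split into two blocks: ``x^(1)`` carries the
behaviorally relevant neural dynamics and ``x^(2)`` the remaining neural
dynamics.  Each section updates as ``x' = A'(x) + K(u)`` (or variants, see
:mod:`priodyn._rnn`), where section 1 consumes the neural observation and
section 2 additionally receives the updated section-1 state.  Readouts map
states to one-step-ahead predictions of neural activity and behavior.  Because
the state update consumes the observed output directly (predictor form),
filtering is causal and requires no inference step at test time.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from ._rnn import RNNSection
from .maps import LinearMap, MLPMap, ParamMap

PARAM_NAMES = ("A", "K", "Cy", "Cz")

__all__ = [
    "NonlinearitySetting",
    "ModelSpec",
    "LatentTrajectory",
    "Predictions",
    "DPADModel",
    "build_model",
    "step_state",
    "filter_states",
    "predict",
    "forecast",
    "softmax_probabilities",
]


@dataclass(frozen=True)
class NonlinearitySetting:
    """How one model parameter (A', K, C_y or C_z) is realized.

    ``form`` is one of ``linear``, ``feedforward`` (ReLU MLP) or ``lstm``
    (recursion only).  ``hidden_layers``/``hidden_units`` apply to the
    feedforward form only.
    """

    form: str = "linear"
    hidden_layers: int = 1
    hidden_units: int = 64

    def __post_init__(self):
        if self.form not in ("linear", "feedforward", "lstm"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "feedforward":
            if self.hidden_layers not in (1, 2):
                raise ValueError("feedforward maps use 1 or 2 hidden layers")
            if self.hidden_units < 1:
                raise ValueError("hidden_units must be positive")


def _default_settings():
    return {name: NonlinearitySetting() for name in PARAM_NAMES}


@dataclass
class ModelSpec:
    """Dimensions and per-parameter nonlinearity settings of a model.

    ``n_1`` of the ``n_x`` latent dimensions are learned with behavior
    priority (section 1); the remaining ``n_2 = n_x - n_1`` form section 2.
    The same nonlinearity setting for a parameter applies to both sections.
    """

    n_y: int
    n_z: int
    n_x: int
    n_1: int
    settings: dict = field(default_factory=_default_settings)
    behavior_mode: str = "continuous"
    n_c: int | None = None
    learn_initial_state: bool = False

    def __post_init__(self):
        if not (0 <= self.n_1 <= self.n_x):
            raise ValueError("need 0 <= n_1 <= n_x")
        if self.n_x < 1 or self.n_y < 1 or self.n_z < 1:
            raise ValueError("dimensions must be positive")
        if self.behavior_mode not in ("continuous", "categorical"):
            raise ValueError(f"unknown behavior_mode {self.behavior_mode!r}")
        if self.behavior_mode == "categorical" and (self.n_c is None or self.n_c < 2):
            raise ValueError("categorical behavior requires n_c >= 2")
        full = _default_settings()
        full.update(self.settings)
        self.settings = full
        for name, s in self.settings.items():
            if not isinstance(s, NonlinearitySetting):
                raise TypeError(f"setting for {name!r} must be a NonlinearitySetting")
            if s.form == "lstm" and name != "A":
                raise ValueError("lstm form is allowed only for the recursion A'")

    @property
    def n_2(self) -> int:
        return self.n_x - self.n_1

    @property
    def cz_out_dim(self) -> int:
        if self.behavior_mode == "categorical":
            return self.n_z * self.n_c
        return self.n_z

    def replace(self, **kw) -> "ModelSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class LatentTrajectory:
    """Filtered latent states: ``x1`` is (T x n_1), ``x2`` is (T x n_2)."""

    x1: np.ndarray
    x2: np.ndarray

    @property
    def T(self) -> int:
        return max(self.x1.shape[0], self.x2.shape[0])

    def concat(self) -> np.ndarray:
        parts = [x for x in (self.x1, self.x2) if x.shape[1] > 0]
        if not parts:
            return np.zeros((self.T, 0))
        return np.concatenate(parts, axis=1)


@dataclass
class Predictions:
    """One-step (or m-step) ahead predictions.

    ``z_hat`` is (T x n_z) for continuous behavior or (T x n_z x n_c) class
    probabilities for categorical behavior.
    """

    y_hat: np.ndarray
    z_hat: np.ndarray
    horizon: int = 1


class _Scaler:
    """Per-channel z-scoring fit on training data, identity by default."""

    def __init__(self, mean=None, std=None):
        self.mean = mean
        self.std = std

    @classmethod
    def fit(cls, X: np.ndarray, mask: np.ndarray | None = None) -> "_Scaler":
        sel = X if mask is None else X[mask]
        mean = sel.mean(axis=0)
        std = sel.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(mean, std)

    def transform(self, X):
        if self.mean is None:
            return np.asarray(X, dtype=float)
        return (X - self.mean) / self.std

    def inverse(self, X):
        if self.mean is None:
            return X
        return X * self.std + self.mean


def softmax_probabilities(logits: np.ndarray, n_z: int, n_c: int) -> np.ndarray:
    """Softmax over the class axis of reshaped (T x n_z x n_c) logits."""
    L = logits.reshape(logits.shape[0], n_z, n_c)
    L = L - L.max(axis=-1, keepdims=True)
    E = np.exp(L)
    return E / E.sum(axis=-1, keepdims=True)


class DPADModel:
    """A (possibly untrained) two-section model with readouts and noise stats.

    Attributes
    ----------
    section1, section2 : RNNSection or None
        Recurrent sections; section 2 is absent when ``n_1 = n_x`` and
        section 1 is absent when ``n_1 = 0``.
    Cy1, Cy2, Cz1 : ParamMap or None
        Per-section readouts.  ``unified_Cz``/``unified_Cy`` (step 4) replace
        the per-section behavior/neural readouts when present.
    Sigma_e, Sigma_eps : (n_y x n_y), (n_z x n_z) residual covariances.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.spec = spec
        s = spec.settings

        def readout(in_dim, out_dim):
            if s["Cy"].form == "linear":
                return LinearMap(in_dim, out_dim, rng=rng)
            return MLPMap(in_dim, out_dim, s["Cy"].hidden_layers, s["Cy"].hidden_units, rng=rng)

        def z_readout(in_dim):
            out_dim = spec.cz_out_dim
            if s["Cz"].form == "linear":
                return LinearMap(in_dim, out_dim, rng=rng)
            return MLPMap(in_dim, out_dim, s["Cz"].hidden_layers, s["Cz"].hidden_units, rng=rng)

        self.section1 = None
        self.section2 = None
        self.Cy1 = self.Cy2 = self.Cz1 = None
        self.unified_Cz: ParamMap | None = None
        self.unified_Cy: ParamMap | None = None
        if spec.n_1 > 0:
            self.section1 = RNNSection(spec.n_1, spec.n_y, s["A"], s["K"], rng)
            self.Cz1 = z_readout(spec.n_1)
            self.Cy1 = readout(spec.n_1, spec.n_y)
        if spec.n_2 > 0:
            u_dim = spec.n_y + (spec.n_1 if spec.n_1 > 0 else 0)
            self.section2 = RNNSection(spec.n_2, u_dim, s["A"], s["K"], rng)
            self.Cy2 = readout(spec.n_2, spec.n_y)
        self.Sigma_e = np.zeros((spec.n_y, spec.n_y))
        self.Sigma_eps = np.zeros((spec.n_z, spec.n_z))
        self.y_scaler = _Scaler()
        self.z_scaler = _Scaler()
        self.x0_1 = np.zeros(self.section1.carry_dim) if self.section1 else np.zeros(0)
        self.x0_2 = np.zeros(self.section2.carry_dim) if self.section2 else np.zeros(0)

    # -- filtering ---------------------------------------------------------
    def filter_states(self, Y: np.ndarray, return_next=False):
        """Causally extract latent states from neural activity alone.

        The state at index k is a function of ``Y[0..k-1]`` only.  With
        ``return_next`` the one-step-ahead states at index T are appended.
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != self.spec.n_y:
            raise ValueError(f"Y must be (T x {self.spec.n_y})")
        if not np.all(np.isfinite(Y)):
            raise ValueError("Y contains non-finite values")
        T = Y.shape[0]
        Ys = self.y_scaler.transform(Y)
        if self.section1 is not None:
            X1 = self.section1.run(Ys, self.x0_1[None, :])
        else:
            X1 = np.zeros((T + 1, 0))
        if self.section2 is not None:
            U2 = np.concatenate([Ys, X1[1:, :]], axis=1) if self.spec.n_1 > 0 else Ys
            X2 = self.section2.run(U2, self.x0_2[None, :])
        else:
            X2 = np.zeros((T + 1, 0))
        if return_next:
            return LatentTrajectory(X1, X2)
        return LatentTrajectory(X1[:T], X2[:T])

    # -- readout -----------------------------------------------------------
    def _y_from_states(self, x1, x2):
        if self.unified_Cy is not None:
            return self.unified_Cy(np.concatenate([x1, x2], axis=1))
        out = np.zeros((max(x1.shape[0], x2.shape[0]), self.spec.n_y))
        if self.Cy1 is not None and x1.shape[1] > 0:
            out = out + self.Cy1(x1)
        if self.Cy2 is not None and x2.shape[1] > 0:
            out = out + self.Cy2(x2)
        return out

    def _z_logits_from_states(self, x1, x2):
        if self.unified_Cz is not None:
            return self.unified_Cz(np.concatenate([x1, x2], axis=1))
        if self.Cz1 is None:
            raise ValueError("model has no behavior readout (run step 4 for n_1 = 0)")
        return self.Cz1(x1)

    def predict(self, traj: LatentTrajectory, horizon: int = 1) -> Predictions:
        """Readouts applied to filtered states; behavior may be categorical."""
        x1, x2 = traj.x1, traj.x2
        y_hat = self.y_scaler.inverse(self._y_from_states(x1, x2))
        logits = self._z_logits_from_states(x1, x2)
        if self.spec.behavior_mode == "categorical":
            if self.spec.n_c is None:
                raise ValueError("categorical behavior requires n_c")
            z_hat = softmax_probabilities(logits, self.spec.n_z, self.spec.n_c)
        else:
            z_hat = self.z_scaler.inverse(logits)
        return Predictions(y_hat=y_hat, z_hat=z_hat, horizon=horizon)

    def decode(self, Y: np.ndarray) -> Predictions:
        """One-step-ahead prediction of behavior and neural activity from Y."""
        return self.predict(self.filter_states(Y))

    # -- forecasting -------------------------------------------------------
    def forecast(self, Y: np.ndarray, m: int) -> Predictions:
        """m-step-ahead prediction by feeding predicted neural activity back.

        For m > 1, the model's one-step neural prediction replaces the
        observation in the state update, repeated m - 1 times.
        """
        if m < 1:
            raise ValueError("horizon m must be >= 1")
        if m == 1:
            return self.predict(self.filter_states(Y), horizon=1)
        Y = np.asarray(Y, dtype=float)
        T = Y.shape[0]
        Ys = self.y_scaler.transform(Y)
        # collect carries over time (treat time as a batch for feedback steps)
        c1 = np.zeros((T, self.section1.carry_dim)) if self.section1 else np.zeros((T, 0))
        c2 = np.zeros((T, self.section2.carry_dim)) if self.section2 else np.zeros((T, 0))
        carry1 = self.x0_1[None, :].copy() if self.section1 else np.zeros((1, 0))
        carry2 = self.x0_2[None, :].copy() if self.section2 else np.zeros((1, 0))
        for t in range(T):
            if self.section1:
                c1[t] = carry1[0]
            if self.section2:
                c2[t] = carry2[0]
            if self.section1:
                carry1, _ = self.section1.step(carry1, Ys[t : t + 1])
            if self.section2:
                u2 = Ys[t : t + 1]
                if self.spec.n_1 > 0:
                    u2 = np.concatenate([u2, self.section1.exposed(carry1)], axis=1)
                carry2, _ = self.section2.step(carry2, u2)
        y_out = np.empty((T, self.spec.n_y))
        z_shape = (T, self.spec.n_z, self.spec.n_c) if self.spec.behavior_mode == "categorical" else (T, self.spec.n_z)
        z_out = np.empty(z_shape)

        def read(c1_, c2_):
            x1 = self.section1.exposed(c1_) if self.section1 else np.zeros((c2_.shape[0], 0))
            x2 = self.section2.exposed(c2_) if self.section2 else np.zeros((c1_.shape[0], 0))
            yh = self._y_from_states(x1, x2)
            logit = self._z_logits_from_states(x1, x2)
            return yh, logit

        def store(idx, yh, logit):
            y_out[idx] = self.y_scaler.inverse(yh)
            if self.spec.behavior_mode == "categorical":
                z_out[idx] = softmax_probabilities(
                    np.atleast_2d(logit), self.spec.n_z, self.spec.n_c
                )
            else:
                z_out[idx] = self.z_scaler.inverse(logit)

        # index 0 can only ever be predicted from the initial state
        yh0, l0 = read(c1[:1], c2[:1])
        store(0, yh0[0], l0[0])
        for j in range(2, m + 1):
            # feedback step j-1: advance every carry using its own prediction
            yh, _ = read(c1, c2)
            if self.section1:
                c1, _ = self.section1.step(c1, yh)
            if self.section2:
                u2 = yh
                if self.spec.n_1 > 0:
                    u2 = np.concatenate([u2, self.section1.exposed(c1)], axis=1)
                c2, _ = self.section2.step(c2, u2)
            # element 0 now holds the state at time j-1 given no observations:
            # times k < m-1 get their largest feasible horizon
            yh0, l0 = read(c1[:1], c2[:1])
            store(j - 1, yh0[0], l0[0])
        yh, logits = read(c1[: T - m + 1], c2[: T - m + 1])
        y_out[m - 1 :] = self.y_scaler.inverse(yh)
        if self.spec.behavior_mode == "categorical":
            z_out[m - 1 :] = softmax_probabilities(logits, self.spec.n_z, self.spec.n_c)
        else:
            z_out[m - 1 :] = self.z_scaler.inverse(logits)
        return Predictions(y_hat=y_out, z_hat=z_out, horizon=m)

    # -- serialization -----------------------------------------------------
    def _components(self):
        comps = {}
        if self.section1 is not None:
            comps["section1"] = self.section1
        if self.section2 is not None:
            comps["section2"] = self.section2
        for name in ("Cy1", "Cy2", "Cz1", "unified_Cz", "unified_Cy"):
            obj = getattr(self, name)
            if obj is not None:
                comps[name] = obj
        return comps

    def save(self, path) -> None:
        """Write spec, every weight and the noise statistics to an HDF5 file."""
        spec = self.spec
        with h5py.File(path, "w") as f:
            g = f.create_group("spec")
            for k in ("n_y", "n_z", "n_x", "n_1"):
                g.attrs[k] = getattr(spec, k)
            g.attrs["behavior_mode"] = spec.behavior_mode
            g.attrs["n_c"] = -1 if spec.n_c is None else spec.n_c
            g.attrs["learn_initial_state"] = spec.learn_initial_state
            gs = g.create_group("settings")
            for name, s in spec.settings.items():
                gg = gs.create_group(name)
                gg.attrs["form"] = s.form
                gg.attrs["hidden_layers"] = s.hidden_layers
                gg.attrs["hidden_units"] = s.hidden_units
            gw = f.create_group("weights")
            for cname, comp in self._components().items():
                gc = gw.create_group(cname)
                weights = comp.get_weights() if hasattr(comp, "get_weights") else comp.params
                for i, w in enumerate(weights):
                    gc.create_dataset(str(i), data=w)
            f.create_dataset("Sigma_e", data=self.Sigma_e)
            f.create_dataset("Sigma_eps", data=self.Sigma_eps)
            f.create_dataset("x0_1", data=self.x0_1)
            f.create_dataset("x0_2", data=self.x0_2)
            gn = f.create_group("scalers")
            for nm, sc in (("y", self.y_scaler), ("z", self.z_scaler)):
                gg = gn.create_group(nm)
                gg.attrs["identity"] = sc.mean is None
                if sc.mean is not None:
                    gg.create_dataset("mean", data=sc.mean)
                    gg.create_dataset("std", data=sc.std)

    @classmethod
    def load(cls, path) -> "DPADModel":
        with h5py.File(path, "r") as f:
            g = f["spec"]
            settings = {}
            for name in g["settings"]:
                gg = g["settings"][name]
                settings[name] = NonlinearitySetting(
                    form=gg.attrs["form"],
                    hidden_layers=int(gg.attrs["hidden_layers"]),
                    hidden_units=int(gg.attrs["hidden_units"]),
                )
            n_c = int(g.attrs["n_c"])
            spec = ModelSpec(
                n_y=int(g.attrs["n_y"]),
                n_z=int(g.attrs["n_z"]),
                n_x=int(g.attrs["n_x"]),
                n_1=int(g.attrs["n_1"]),
                settings=settings,
                behavior_mode=str(g.attrs["behavior_mode"]),
                n_c=None if n_c < 0 else n_c,
                learn_initial_state=bool(g.attrs["learn_initial_state"]),
            )
            model = build_model(spec, seed=0)
            gw = f["weights"]
            # step-4 unified readouts must exist before loading their weights
            if "unified_Cz" in gw:
                model.unified_Cz = _make_readout(spec, "Cz", spec.n_x, spec.cz_out_dim)
            if "unified_Cy" in gw:
                model.unified_Cy = _make_readout(spec, "Cy", spec.n_x, spec.n_y)
            for cname, comp in model._components().items():
                gc = gw[cname]
                weights = [gc[str(i)][...] for i in range(len(gc))]
                comp.set_weights(weights)
            model.Sigma_e = f["Sigma_e"][...]
            model.Sigma_eps = f["Sigma_eps"][...]
            model.x0_1 = f["x0_1"][...]
            model.x0_2 = f["x0_2"][...]
            for nm, attr in (("y", "y_scaler"), ("z", "z_scaler")):
                gg = f["scalers"][nm]
                if not gg.attrs["identity"]:
                    setattr(model, attr, _Scaler(gg["mean"][...], gg["std"][...]))
        return model


def _make_readout(spec: ModelSpec, which: str, in_dim: int, out_dim: int) -> ParamMap:
    s = spec.settings[which]
    rng = np.random.default_rng(0)
    if s.form == "linear":
        return LinearMap(in_dim, out_dim, rng=rng)
    return MLPMap(in_dim, out_dim, s.hidden_layers, s.hidden_units, rng=rng)


def build_model(spec: ModelSpec, seed: int | np.random.Generator = 0) -> DPADModel:
    """Construct an untrained model with randomly initialized parameter maps."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return DPADModel(spec, rng)


def step_state(model: DPADModel, x1, x2, y):
    """One state update.  ``x1``/``x2`` are carries (equal to the latent state
    except for LSTM recursion, where they include the internal cell state).
    Section 1 is updated first and independently of section 2; section 2
    additionally receives the updated section-1 state."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite neural sample")
    ys = model.y_scaler.transform(y)
    x1 = np.atleast_2d(np.asarray(x1, dtype=float)) if model.section1 else np.zeros((1, 0))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float)) if model.section2 else np.zeros((1, 0))
    x1n = x1
    if model.section1 is not None:
        x1n, _ = model.section1.step(x1, ys)
    x2n = x2
    if model.section2 is not None:
        u2 = ys
        if model.spec.n_1 > 0:
            u2 = np.concatenate([ys, model.section1.exposed(x1n)], axis=1)
        x2n, _ = model.section2.step(x2, u2)
    return x1n[0], x2n[0]


def filter_states(model: DPADModel, Y: np.ndarray) -> LatentTrajectory:
    return model.filter_states(Y)


def predict(model: DPADModel, traj: LatentTrajectory) -> Predictions:
    return model.predict(traj)


def forecast(model: DPADModel, Y: np.ndarray, m: int) -> Predictions:
    return model.forecast(Y, m)
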