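"""Flexible-nonlinearity architecture search.

Enumerates the candidate nonlinearity settings (each of recursion A', neural
input K, neural readout C_y and behavior readout C_z independently linear or
nonlinear; nonlinear parameters share one of four feed-forward shapes; plus an
LSTM-recursion family), scores each candidate by twofold inner
cross-validation on the training data only, and selects one by either a
decoding-focused or a self-prediction-focused criterion with a 1-s.e.m.
tolerance band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import _evaluate, contiguous_kfold
from .model import ModelSpec, NonlinearitySetting
from .training import FitConfig, TimeSeriesPair, fit

__all__ = [
    "Candidate",
    "enumerate_architectures",
    "inner_cv_score",
    "select_architecture",
    "run_search",
]

PARAMS = ("A", "K", "Cy", "Cz")
SHAPES = ((1, 64), (1, 128), (2, 64), (2, 128))  # (hidden layers, units)


@dataclass(frozen=True)
class Candidate:
    """One architecture: per-parameter nonlinearity settings."""

    settings: tuple  # tuple of (name, NonlinearitySetting) pairs, fixed order

    def as_dict(self) -> dict:
        return dict(self.settings)

    @property
    def n_nonlinear(self) -> int:
        return sum(1 for _, s in self.settings if s.form != "linear")

    @property
    def has_lstm(self) -> bool:
        return any(s.form == "lstm" for _, s in self.settings)

    @property
    def is_linear(self) -> bool:
        return all(s.form == "linear" for _, s in self.settings)

    def label(self) -> str:
        parts = []
        for name, s in self.settings:
            if s.form == "linear":
                continue
            if s.form == "lstm":
                parts.append(f"{name}:lstm")
            else:
                parts.append(f"{name}:ff{s.hidden_layers}x{s.hidden_units}")
        return "+".join(parts) if parts else "linear"


def enumerate_architectures() -> list[Candidate]:
    """The full 90-candidate grid.

    61 non-LSTM members: every subset of the 4 parameters nonlinear (15
    nonempty subsets x 4 shared feed-forward shapes) plus the single fully
    linear model.  29 LSTM members: recursion as LSTM with every subset of the
    remaining 3 parameters nonlinear (7 nonempty subsets x 4 shapes) plus the
    all-others-linear case.
    """
    linear = NonlinearitySetting("linear")
    candidates = [Candidate(tuple((p, linear) for p in PARAMS))]

    def build(nonlinear_set, shape, recursion_lstm=False):
        layers, units = shape
        ff = NonlinearitySetting("feedforward", layers, units)
        settings = []
        for p in PARAMS:
            if recursion_lstm and p == "A":
                settings.append((p, NonlinearitySetting("lstm")))
            elif p in nonlinear_set:
                settings.append((p, ff))
            else:
                settings.append((p, linear))
        return Candidate(tuple(settings))

    # non-LSTM family: 15 nonempty subsets x 4 shapes
    for mask in range(1, 16):
        subset = {p for i, p in enumerate(PARAMS) if mask >> i & 1}
        for shape in SHAPES:
            candidates.append(build(subset, shape))
    # LSTM-recursion family: all-linear-others (1) + 7 nonempty subsets x 4
    candidates.append(build(set(), SHAPES[0], recursion_lstm=True))
    others = tuple(p for p in PARAMS if p != "A")
    for mask in range(1, 8):
        subset = {p for i, p in enumerate(others) if mask >> i & 1}
        for shape in SHAPES:
            candidates.append(build(subset, shape, recursion_lstm=True))
    return candidates


def inner_cv_score(
    data_train: TimeSeriesPair,
    candidate: Candidate,
    spec_template: ModelSpec,
    cfg: FitConfig | None = None,
    n_inner_folds: int = 2,
):
    """Twofold inner cross-validation of one candidate on training data only.

    Returns (decoding mean, self-prediction mean, decoding s.e.m.,
    self-prediction s.e.m.) across the inner folds, or None if the candidate
    failed to train (recorded with a warning).
    """
    cfg = FitConfig() if cfg is None else cfg
    spec = spec_template.replace(settings=candidate.as_dict())
    decs, sps = [], []
    try:
        for k, (tr, te) in enumerate(contiguous_kfold(data_train.T, n_inner_folds)):
            model = fit(data_train.slice(tr), spec, cfg.replace(seed=cfg.seed + 17 * k))
            dec, sp = _evaluate(model, data_train.slice(te))
            decs.append(dec)
            sps.append(sp)
    except (FloatingPointError, ValueError) as exc:
        warnings.warn(f"candidate {candidate.label()} failed to train: {exc}")
        return None
    decs, sps = np.array(decs), np.array(sps)
    n = len(decs)
    # s.e.m. = sample std / sqrt(n); for n = 2 this equals |difference| / 2
    sem = lambda v: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(decs.mean()), float(sps.mean()), sem(decs), sem(sps)


def select_architecture(scores: pd.DataFrame, criterion: str = "decoding_focused"):
    """Pick one candidate from an inner-CV score table.

    ``decoding_focused``: among candidates within 1 s.e.m. of the best
    decoding, maximize self-prediction; ``self_prediction_focused`` mirrors
    the rule.  Ties on the maximized metric break toward parsimony: fewer
    nonlinear parameters, then fewer hidden units, then fewer layers, then
    candidate index.
    """
    if criterion not in ("decoding_focused", "self_prediction_focused"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if scores.empty:
        raise ValueError("empty score set")
    primary, secondary = ("decoding", "selfpred")
    if criterion == "self_prediction_focused":
        primary, secondary = secondary, primary
    best = scores[primary].max()
    band = scores[scores[primary] >= best - scores.loc[scores[primary].idxmax(), f"{primary}_sem"]]
    top = band[band[secondary] == band[secondary].max()]
    if len(top) > 1:
        order = top.sort_values(
            ["n_nonlinear", "hidden_units", "hidden_layers", "index"]
        )
        return int(order.iloc[0]["index"])
    return int(top.iloc[0]["index"])


def run_search(
    data_train: TimeSeriesPair,
    spec_template: ModelSpec,
    cfg: FitConfig | None = None,
    criterion: str = "decoding_focused",
    max_candidates: int | None = None,
):
    """Score the grid (optionally capped for smoke tests) and select.

    Returns (selected Candidate, tidy score DataFrame with a ``selected``
    flag).  Candidates are independent jobs; results are merged in candidate
    index order so the outcome is order-deterministic.
    """
    grid = enumerate_architectures()
    if max_candidates is not None:
        grid = grid[:max_candidates]
    rows = []
    for i, cand in enumerate(grid):
        out = inner_cv_score(data_train, cand, spec_template, cfg)
        if out is None:
            continue
        dec, sp, dsem, ssem = out
        shapes = [s for _, s in cand.settings if s.form == "feedforward"]
        rows.append(
            dict(
                index=i,
                label=cand.label(),
                n_nonlinear=cand.n_nonlinear,
                hidden_layers=shapes[0].hidden_layers if shapes else 0,
                hidden_units=shapes[0].hidden_units if shapes else 0,
                decoding=dec,
                selfpred=sp,
                decoding_sem=dsem,
                selfpred_sem=ssem,
            )
        )
    scores = pd.DataFrame(rows)
    chosen = select_architecture(scores, criterion)
    scores["selected"] = scores["index"] == chosen
    return grid[chosen], scores
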