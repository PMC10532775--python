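"""Learning-curve-penalized ensemble regression for log10 solubility.

Each regressor family in a registry is hyperparameter-tuned by minimizing a
custom loss that rewards both accuracy and generalizability:

    loss = val_MAE(full training set)
           + alpha * mean over LCA points of max(0, val_metric - train_metric)

where the learning-curve analysis (LCA) runs k-fold cross-validation at
increasing fractions of the training data (a cheap two-point 50%/100% curve
inside the tuning loop; a dense 20-point curve for the final candidates).
Tuned candidates are then ranked by the area under their dense train and
validation RMS learning curves, and the joint-low-AUC cluster becomes the
ensemble.  Ensemble predictions are the unweighted mean of the member
predictions after discarding non-negative values — log10 of a mole fraction
must be negative — and a row where every member violates the constraint is
flagged as failed rather than given a number.

The tuner ships two samplers: 'random', and 'tpe_like', a compact
tree-structured-Parzen-estimator-style sampler that models good and bad
trial densities per hyperparameter and proposes the candidate with the best
good/bad density ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingRegressor,
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, NuSVR
from sklearn.tree import ExtraTreeRegressor

from .consonance import mape_log10

KEY_COLUMNS = ("solvent_id", "solvent_fraction", "T")
TARGET_COLUMN = "log10x"

__all__ = [
    "LearningCurve",
    "ModelSpec",
    "TunedModel",
    "EnsembleModel",
    "split_data",
    "learning_curve",
    "auc_of_curve",
    "custom_loss",
    "RandomSampler",
    "TPESampler",
    "tune",
    "select_ensemble",
    "ensemble_predict",
    "evaluate",
    "default_registry",
    "feature_columns",
    "train_ensemble",
]


# ---------------------------------------------------------------------------
# data splitting

def split_data(
    table: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Seeded train/test/validation row split, stratified by solvent.

    Rows of each solvent are permuted and allocated to the three subsets by
    largest-remainder apportionment of the requested fractions, so no subset
    lacks a solvent (every solvent contributes at least its share).  The
    partition is disjoint, exhaustive, and reproducible under the seed.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be three positive numbers, got {fractions}")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for _, group in table.groupby("solvent_id", sort=True):
        idx = group.index.to_numpy()
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        quotas = np.array([f * n for f in fractions])
        counts = np.floor(quotas).astype(int)
        for j in np.argsort(-(quotas - counts))[: n - counts.sum()]:
            counts[j] += 1
        start = 0
        for j, c in enumerate(counts):
            parts[j].extend(idx[start : start + c])
            start += c
    if any(len(p) == 0 for p in parts):
        raise ValueError(
            f"a subset would be empty with fractions {fractions} on {len(table)} rows"
        )
    return tuple(table.loc[sorted(p)].copy() for p in parts)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# learning curves and the custom loss

@dataclass(frozen=True)
class LearningCurve:
    """Train/validation error versus fraction of training data used."""

    fractions: tuple[float, ...]
    train_metric: tuple[float, ...]
    val_metric: tuple[float, ...]
    metric_name: str  # "MAE" or "RMS"
    cv_folds: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions)
        if len(f) != len(self.train_metric) or len(f) != len(self.val_metric):
            raise ValueError("fractions and metrics must have equal lengths")
        if np.any(np.diff(f) <= 0):
            raise ValueError("fractions must be strictly increasing")
        if f.min() < 0.5 - 1e-9 or f.max() > 1.0 + 1e-9:
            raise ValueError("fractions must lie within [0.5, 1.0]")
        if self.metric_name not in ("MAE", "RMS"):
            raise ValueError(f"unknown metric {self.metric_name!r}")


def _metric(name: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if name == "MAE":
        return float(mean_absolute_error(y_true, y_pred))
    return float(np.sqrt(mean_squared_error(y_true, y_pred)))


def learning_curve(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    fractions: Sequence[float] = (0.5, 1.0),
    cv_folds: int = 5,
    seed: int = 0,
    metric: str = "MAE",
) -> LearningCurve:
    """Cross-validated learning curve over nested subsamples of the data.

    For each fraction f a seeded subsample of round(f*n) rows (nested across
    fractions) is scored by ``cv_folds``-fold cross-validation; the mean
    training-fold and validation-fold errors are recorded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    tr, va = [], []
    for f in fractions:
        n_sub = int(round(f * len(y)))
        if n_sub < cv_folds:
            raise ValueError(
                f"subsample of {n_sub} rows at fraction {f} is smaller than "
                f"{cv_folds} folds"
            )
        sub = order[:n_sub]
        Xs, ys = X[sub], y[sub]
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
        t_scores, v_scores = [], []
        for itr, iva in kf.split(Xs):
            est = clone(estimator)
            with warnings.catch_warnings():
                # small-subsample fits inside the curve may stop at max_iter;
                # that is part of the configuration being scored
                warnings.simplefilter("ignore")
                est.fit(Xs[itr], ys[itr])
            t_scores.append(_metric(metric, ys[itr], est.predict(Xs[itr])))
            v_scores.append(_metric(metric, ys[iva], est.predict(Xs[iva])))
        tr.append(float(np.mean(t_scores)))
        va.append(float(np.mean(v_scores)))
    return LearningCurve(
        fractions=tuple(float(f) for f in fractions),
        train_metric=tuple(tr),
        val_metric=tuple(va),
        metric_name=metric,
        cv_folds=cv_folds,
    )


def auc_of_curve(curve: LearningCurve, which: str = "val") -> float:
    """Trapezoidal area under metric-vs-fraction, normalized by the span.

    The normalization makes a flat curve's AUC equal its constant value, so
    AUCs are on the metric's own scale.
    """
    if which not in ("train", "val"):
        raise ValueError(f"which must be 'train' or 'val', got {which!r}")
    if len(curve.fractions) < 2:
        raise ValueError("AUC needs at least two curve points")
    x = np.asarray(curve.fractions)
    yv = np.asarray(curve.train_metric if which == "train" else curve.val_metric)
    return float(np.trapezoid(yv, x) / (x[-1] - x[0]))


def custom_loss(curve: LearningCurve, alpha: float = 1.0) -> float:
    """Accuracy plus generalization-gap penalty from the learning curve.

    loss = validation MAE at the full training size
         + alpha * mean_i max(0, val_i - train_i).

    The hinge keeps models that validate better than they train (negative gap)
    from being rewarded for it; alpha=0 reduces to plain validation MAE.
    """
    if curve.metric_name != "MAE":
        raise ValueError("custom loss is defined on MAE learning curves")
    full = [i for i, f in enumerate(curve.fractions) if math.isclose(f, 1.0)]
    if not full:
        raise ValueError("curve lacks the full-data (fraction = 1.0) point")
    val_full = curve.val_metric[full[0]]
    gaps = np.maximum(
        0.0, np.asarray(curve.val_metric) - np.asarray(curve.train_metric)
    )
    return float(val_full + alpha * gaps.mean())


# ---------------------------------------------------------------------------
# hyperparameter samplers

ParamSpace = dict[str, tuple]  # name -> ("float"|"logfloat", lo, hi) | ("int", lo, hi) | ("cat", options)


def _sample_random(space: ParamSpace, rng: np.random.Generator) -> dict:
    params = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "float":
            params[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "logfloat":
            params[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "int":
            params[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "cat":
            params[name] = spec[1][rng.integers(len(spec[1]))]
        else:
            raise ValueError(f"unknown parameter kind {kind!r}")
    return params


class RandomSampler:
    """Uniform random search over the declared space."""

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)

    def suggest(self, space: ParamSpace, history: list[tuple[dict, float]]) -> dict:
        return _sample_random(space, self.rng)


class TPESampler:
    """Tree-structured-Parzen-estimator-style sampler.

    After ``n_startup`` random trials the history is split at the ``gamma``
    loss quantile into good and bad sets.  Candidates are drawn by perturbing
    good configurations (Gaussian kernels in the, possibly log-, transformed
    coordinate; frequency-weighted draws for categoricals) and the candidate
    maximizing the summed log density ratio good/bad is proposed — the
    expected-improvement proxy of TPE.
    """

    def __init__(
        self,
        seed: int = 0,
        n_startup: int = 15,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ):
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    @staticmethod
    def _fwd(spec: tuple, v):
        return math.log(v) if spec[0] == "logfloat" else float(v)

    @staticmethod
    def _kde_logpdf(v: float, pts: np.ndarray, lo: float, hi: float) -> float:
        bw = max(1.06 * pts.std() * len(pts) ** -0.2, 0.05 * (hi - lo), 1e-12)
        z = (v - pts) / bw
        dens = np.exp(-0.5 * z**2).sum() / (len(pts) * bw * math.sqrt(2 * math.pi))
        return math.log(dens + 1e-300)

    def suggest(self, space: ParamSpace, history: list[tuple[dict, float]]) -> dict:
        ok = [(p, l) for p, l in history if math.isfinite(l)]
        if len(ok) < self.n_startup:
            return _sample_random(space, self.rng)
        losses = np.array([l for _, l in ok])
        n_good = max(2, int(math.ceil(self.gamma * len(ok))))
        order = np.argsort(losses, kind="stable")
        good = [ok[i][0] for i in order[:n_good]]
        bad = [ok[i][0] for i in order[n_good:]] or good
        best_score, best = -np.inf, None
        for _ in range(self.n_candidates):
            base = good[self.rng.integers(len(good))]
            cand, score = {}, 0.0
            for name, spec in space.items():
                kind = spec[0]
                if kind == "cat":
                    opts = list(spec[1])
                    counts = np.array(
                        [1.0 + sum(g[name] == o for g in good) for o in opts]
                    )
                    v = opts[self.rng.choice(len(opts), p=counts / counts.sum())]
                    p_good = counts[opts.index(v)] / counts.sum()
                    bcounts = np.array(
                        [1.0 + sum(b[name] == o for b in bad) for o in opts]
                    )
                    p_bad = bcounts[opts.index(v)] / bcounts.sum()
                    score += math.log(p_good / p_bad)
                    cand[name] = v
                    continue
                lo, hi = (
                    (math.log(spec[1]), math.log(spec[2]))
                    if kind == "logfloat"
                    else (float(spec[1]), float(spec[2]))
                )
                gpts = np.array([self._fwd(spec, g[name]) for g in good])
                bpts = np.array([self._fwd(spec, b[name]) for b in bad])
                bw = max(1.06 * gpts.std() * len(gpts) ** -0.2, 0.05 * (hi - lo))
                v = float(
                    np.clip(self._fwd(spec, base[name]) + self.rng.normal(0, bw), lo, hi)
                )
                score += self._kde_logpdf(v, gpts, lo, hi) - self._kde_logpdf(
                    v, bpts, lo, hi
                )
                if kind == "logfloat":
                    cand[name] = float(math.exp(v))
                elif kind == "int":
                    cand[name] = int(round(v))
                else:
                    cand[name] = v
            if score > best_score:
                best_score, best = score, cand
        assert best is not None
        return best


# ---------------------------------------------------------------------------
# model registry

@dataclass(frozen=True)
class ModelSpec:
    """A tunable regressor family: id, estimator factory, and search space."""

    algorithm_id: str
    factory: Callable[[dict, int], Pipeline]
    space: ParamSpace


def _pipe(est) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def default_registry() -> list[ModelSpec]:
    """The nine ensemble-member families plus a linear (ridge) baseline.

    Support vector (NuSVR, SVR), a small multilayer perceptron, two gradient
    boosting variants, random forest, bagging, k-nearest neighbors, a single
    extremely randomized tree, and ridge regression.  Search spaces are
    bounded and desk-scale; extend by appending further ModelSpecs.
    """
    return [
        ModelSpec(
            "nusvr",
            lambda p, s: _pipe(NuSVR(C=p["C"], nu=p["nu"], gamma=p["gamma"])),
            {
                "C": ("logfloat", 1e-2, 1e3),
                "nu": ("float", 0.05, 0.95),
                "gamma": ("logfloat", 1e-3, 1e1),
            },
        ),
        ModelSpec(
            "svr",
            lambda p, s: _pipe(SVR(C=p["C"], epsilon=p["epsilon"], gamma=p["gamma"])),
            {
                "C": ("logfloat", 1e-2, 1e3),
                "epsilon": ("logfloat", 1e-3, 1.0),
                "gamma": ("logfloat", 1e-3, 1e1),
            },
        ),
        ModelSpec(
            "mlp",
            lambda p, s: _pipe(
                MLPRegressor(
                    hidden_layer_sizes=(p["hidden"],),
                    alpha=p["alpha"],
                    learning_rate_init=p["lr"],
                    max_iter=250,
                    tol=1e-3,
                    random_state=s,
                )
            ),
            {
                "hidden": ("int", 8, 48),
                "alpha": ("logfloat", 1e-6, 1e-1),
                "lr": ("logfloat", 1e-4, 1e-1),
            },
        ),
        ModelSpec(
            "gradient_boosting",
            lambda p, s: _pipe(
                GradientBoostingRegressor(
                    n_estimators=p["n_estimators"],
                    learning_rate=p["learning_rate"],
                    max_depth=p["max_depth"],
                    subsample=p["subsample"],
                    random_state=s,
                )
            ),
            {
                "n_estimators": ("int", 40, 150),
                "learning_rate": ("logfloat", 0.01, 0.3),
                "max_depth": ("int", 1, 4),
                "subsample": ("float", 0.5, 1.0),
            },
        ),
        ModelSpec(
            "hist_gradient_boosting",
            lambda p, s: _pipe(
                HistGradientBoostingRegressor(
                    max_iter=p["max_iter"],
                    learning_rate=p["learning_rate"],
                    max_depth=p["max_depth"],
                    l2_regularization=p["l2"],
                    min_samples_leaf=p["min_samples_leaf"],
                    random_state=s,
                )
            ),
            {
                "max_iter": ("int", 30, 100),
                "learning_rate": ("logfloat", 0.02, 0.3),
                "max_depth": ("int", 2, 8),
                "l2": ("logfloat", 1e-8, 1e1),
                "min_samples_leaf": ("int", 2, 10),
            },
        ),
        ModelSpec(
            "random_forest",
            lambda p, s: _pipe(
                RandomForestRegressor(
                    n_estimators=p["n_estimators"],
                    max_depth=p["max_depth"],
                    min_samples_leaf=p["min_samples_leaf"],
                    max_features=p["max_features"],
                    random_state=s,
                )
            ),
            {
                "n_estimators": ("int", 20, 100),
                "max_depth": ("int", 2, 12),
                "min_samples_leaf": ("int", 1, 8),
                "max_features": ("float", 0.3, 1.0),
            },
        ),
        ModelSpec(
            "bagging",
            lambda p, s: _pipe(
                BaggingRegressor(
                    n_estimators=p["n_estimators"],
                    max_samples=p["max_samples"],
                    max_features=p["max_features"],
                    random_state=s,
                )
            ),
            {
                "n_estimators": ("int", 10, 40),
                "max_samples": ("float", 0.5, 1.0),
                "max_features": ("float", 0.5, 1.0),
            },
        ),
        ModelSpec(
            "knn",
            lambda p, s: _pipe(
                KNeighborsRegressor(
                    n_neighbors=p["n_neighbors"], weights=p["weights"], p=p["p"]
                )
            ),
            {
                "n_neighbors": ("int", 1, 15),
                "weights": ("cat", ("uniform", "distance")),
                "p": ("cat", (1, 2)),
            },
        ),
        ModelSpec(
            "extra_tree",
            lambda p, s: _pipe(
                ExtraTreeRegressor(
                    max_depth=p["max_depth"],
                    min_samples_leaf=p["min_samples_leaf"],
                    min_samples_split=p["min_samples_split"],
                    random_state=s,
                )
            ),
            {
                "max_depth": ("int", 2, 16),
                "min_samples_leaf": ("int", 1, 8),
                "min_samples_split": ("int", 2, 8),
            },
        ),
        ModelSpec(
            "ridge",
            lambda p, s: _pipe(Ridge(alpha=p["alpha"])),
            {"alpha": ("logfloat", 1e-6, 1e3)},
        ),
    ]


# ---------------------------------------------------------------------------
# tuning, selection, prediction

@dataclass
class TunedModel:
    """Best configuration of one regressor family."""

    algorithm_id: str
    hyperparameters: dict
    custom_loss: float
    lca: LearningCurve
    spec: ModelSpec
    seed: int
    dense_lca: LearningCurve | None = None
    fitted: Pipeline | None = None

    def make_estimator(self) -> Pipeline:
        return self.spec.factory(self.hyperparameters, self.seed)


def tune(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_trials: int = 200,
    sampler: str = "tpe_like",
    seed: int = 0,
    alpha: float = 1.0,
    cv_folds: int = 5,
    lca_fractions: Sequence[float] = (0.5, 1.0),
) -> TunedModel:
    """Minimize the custom loss over the family's search space.

    Each trial scores a sampled configuration with a (cheap, two-point by
    default) cross-validated learning curve; the cv partition is held fixed
    across trials so configurations compete on identical folds.  Deterministic
    under a fixed seed.  Failed trials are recorded; if every trial fails, the
    per-trial diagnostics are propagated.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if sampler == "tpe_like":
        smp = TPESampler(seed=seed)
    elif sampler == "random":
        smp = RandomSampler(seed=seed)
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    history: list[tuple[dict, float]] = []
    failures: list[tuple[dict, str]] = []
    best: TunedModel | None = None
    for _ in range(n_trials):
        params = smp.suggest(spec.space, history)
        try:
            est = spec.factory(params, seed)
            curve = learning_curve(
                est, X, y, lca_fractions, cv_folds=cv_folds, seed=seed, metric="MAE"
            )
            loss = custom_loss(curve, alpha=alpha)
        except Exception as exc:  # a bad configuration, not a fatal error
            failures.append((params, repr(exc)))
            history.append((params, math.inf))
            continue
        history.append((params, loss))
        if best is None or loss < best.custom_loss:
            best = TunedModel(
                algorithm_id=spec.algorithm_id,
                hyperparameters=params,
                custom_loss=loss,
                lca=curve,
                spec=spec,
                seed=seed,
            )
    if best is None:
        raise RuntimeError(
            f"all {n_trials} trials failed for {spec.algorithm_id!r}: {failures[:5]}"
        )
    return best


@dataclass
class EnsembleModel:
    """Selected members with their learning-curve AUCs and the averaging rule."""

    members: list[TunedModel]
    auc_train: dict[str, float]
    auc_val: dict[str, float]
    selection_rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")


def select_ensemble(candidates: Sequence[TunedModel], k: int = 9) -> EnsembleModel:
    """Pick the joint-low-AUC cluster of k candidates.

    Candidates are ranked separately by the AUC of their dense train and
    validation learning curves; the selection key is the worse (max) of the
    two ranks, so a member must sit low on *both* curves — the formalization
    of the visually distinct low-AUC cluster.  Ties break by summed AUC, then
    algorithm id.
    """
    candidates = list(candidates)
    if len(candidates) < k:
        raise ValueError(f"need >= {k} candidates, got {len(candidates)}")
    if any(c.dense_lca is None for c in candidates):
        missing = [c.algorithm_id for c in candidates if c.dense_lca is None]
        raise ValueError(f"candidates lack a dense learning curve: {missing}")
    a_tr = {c.algorithm_id: auc_of_curve(c.dense_lca, "train") for c in candidates}
    a_va = {c.algorithm_id: auc_of_curve(c.dense_lca, "val") for c in candidates}

    def _ranks(values: dict[str, float]) -> dict[str, int]:
        order = sorted(values, key=lambda a: (values[a], a))
        return {a: i for i, a in enumerate(order)}

    r_tr, r_va = _ranks(a_tr), _ranks(a_va)
    key = lambda c: (
        max(r_tr[c.algorithm_id], r_va[c.algorithm_id]),
        a_tr[c.algorithm_id] + a_va[c.algorithm_id],
        c.algorithm_id,
    )
    members = sorted(candidates, key=key)[:k]
    return EnsembleModel(
        members=members,
        auc_train={c.algorithm_id: a_tr[c.algorithm_id] for c in members},
        auc_val={c.algorithm_id: a_va[c.algorithm_id] for c in members},
        selection_rule={"k": k, "rule": "max of train/val AUC ranks"},
    )


def ensemble_predict(ensemble: EnsembleModel, X: np.ndarray) -> pd.DataFrame:
    """Negative-only unweighted averaging of member predictions.

    log10 of a mole fraction is necessarily negative, so member predictions
    >= 0 are discarded before averaging; a row where every member predicts
    >= 0 is flagged failed (log10x_pred = NaN) rather than given a value.
    """
    fitted = [m for m in ensemble.members if m.fitted is not None]
    if len(fitted) != len(ensemble.members):
        raise ValueError("all ensemble members must be fitted before prediction")
    X = np.asarray(X, dtype=float)
    preds = np.column_stack([m.fitted.predict(X) for m in fitted])
    neg = preds < 0
    n_used = neg.sum(axis=1)
    with np.errstate(invalid="ignore"):
        avg = np.where(
            n_used > 0,
            np.where(neg, preds, 0.0).sum(axis=1) / np.maximum(n_used, 1),
            np.nan,
        )
    return pd.DataFrame(
        {
            "log10x_pred": avg,
            "n_members_used": n_used,
            "failed": n_used == 0,
        }
    )


def evaluate(pred: Sequence[float], obs: Sequence[float]) -> dict[str, float]:
    """MAE, RMSE, R^2 and decadal-log MAPE of predictions against observations."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.size < 2:
        raise ValueError("need equal-length vectors with at least 2 points")
    return {
        "MAE": float(mean_absolute_error(o, p)),
        "RMSE": float(np.sqrt(mean_squared_error(o, p))),
        "R2": float(r2_score(o, p)),
        "MAPE_log10": mape_log10(p, o),
    }


# ---------------------------------------------------------------------------
# orchestration

def feature_columns(table: pd.DataFrame) -> list[str]:
    """Descriptor columns used as features: everything but row keys and target."""
    drop = {"solvent_id", TARGET_COLUMN}
    return [c for c in table.columns if c not in drop]


def train_ensemble(
    table: pd.DataFrame,
    n_trials: int = 200,
    k: int = 9,
    seed: int = 0,
    alpha: float = 1.0,
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    cv_folds: int = 5,
    sampler: str = "tpe_like",
    registry: Sequence[ModelSpec] | None = None,
    dense_points: int = 20,
    features: Sequence[str] | None = None,
) -> tuple[EnsembleModel, dict]:
    """Full training pass: split, tune every family, dense LCA, select, fit.

    Returns the fitted ensemble and a report with per-member tuning results
    and ensemble metrics on the held-out test and validation subsets.
    """
    registry = list(registry) if registry is not None else default_registry()
    train, test, val = split_data(table, split_fractions, seed)
    cols = list(features) if features is not None else feature_columns(table)
    Xtr, ytr = train[cols].to_numpy(float), train[TARGET_COLUMN].to_numpy(float)

    candidates: list[TunedModel] = []
    for i, spec in enumerate(registry):
        tuned = tune(
            spec,
            Xtr,
            ytr,
            n_trials=n_trials,
            sampler=sampler,
            seed=seed + 1000 * (i + 1),
            alpha=alpha,
            cv_folds=cv_folds,
        )
        dense_fracs = np.linspace(0.5, 1.0, dense_points)
        tuned.dense_lca = learning_curve(
            tuned.make_estimator(),
            Xtr,
            ytr,
            dense_fracs,
            cv_folds=cv_folds,
            seed=tuned.seed,
            metric="RMS",
        )
        candidates.append(tuned)

    ensemble = select_ensemble(candidates, k=min(k, len(candidates)))
    for m in ensemble.members:
        m.fitted = m.make_estimator().fit(Xtr, ytr)

    report: dict = {
        "features": cols,
        "candidates": {
            c.algorithm_id: {
                "custom_loss": c.custom_loss,
                "hyperparameters": c.hyperparameters,
                "auc_train": auc_of_curve(c.dense_lca, "train"),
                "auc_val": auc_of_curve(c.dense_lca, "val"),
            }
            for c in candidates
        },
        "members": [m.algorithm_id for m in ensemble.members],
    }
    for name, subset in (("test", test), ("validation", val)):
        out = ensemble_predict(ensemble, subset[cols].to_numpy(float))
        mask = ~out["failed"].to_numpy()
        report[name] = {
            "n": int(len(subset)),
            "n_failed": int((~mask).sum()),
            **(
                evaluate(
                    out["log10x_pred"].to_numpy()[mask],
                    subset[TARGET_COLUMN].to_numpy(float)[mask],
                )
                if mask.sum() >= 2
                else {}
            ),
        }
    return ensemble, report
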