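"""Reference-solvent (consonance) solubility screening.

Dapsone's fusion thermodynamics cannot be measured (the commercial polymorph
converts below its melting point), so direct solid-liquid-equilibrium (SLE)
solubility computation is impossible.  The workaround: back-calculate the
Gibbs free energy of fusion from the *experimental* solubility in a reference
solvent, then carry it to every other solvent.

The thermodynamic engine that supplies the chemical-potential gap between the
pure subcooled liquid and the solute in solution (COSMO-RS in practice) is
abstracted as a :class:`ThermoBackend`.  At saturation

    R*T*ln x  =  mu_gap(solvent, T, x) - dG_fus(T)

so a reference solvent with known x gives dG_fus(T), and the same relation
solved for x predicts every other solvent.  Because backend errors are similar
for chemically similar solvents, predictions are accurate within a solvent
class and poor across classes; the target-by-reference MAPE matrix exposes
that block structure, hierarchical clustering recovers the classes, and an
exhaustive search picks the minimal reference set ("consonance solvents").
A solvent matching no class (acetone in the dapsone study) is excluded from
the reference pool as a singleton.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .curation import ConsensusTable

# Gas constant in kcal/(mol*K)
R_KCAL = 1.98720e-3

MAX_EXHAUSTIVE_SOLVENTS = 20

__all__ = [
    "R_KCAL",
    "ThermoBackend",
    "TableBackend",
    "FusionEstimate",
    "ReferenceMatrix",
    "ConsonanceResult",
    "estimate_fusion",
    "estimate_fusion_profile",
    "predict_solubility",
    "mape_log10",
    "build_reference_matrix",
    "discover_classes",
    "select_reference_set",
    "consonance_screen",
    "predict_with_references",
]


@runtime_checkable
class ThermoBackend(Protocol):
    """Pluggable supplier of the solute's chemical-potential gap.

    ``mu_gap(solute_id, solvent_id, T, x)`` returns, in kcal/mol, the chemical
    potential of the pure subcooled-liquid solute minus its chemical potential
    in solution at mole fraction ``x``.  Backends with
    ``composition_dependent = False`` must ignore ``x`` (it may be None).
    """

    composition_dependent: bool

    def mu_gap(self, solute_id: str, solvent_id: str, T: float, x: float | None) -> float: ...


@dataclass
class TableBackend:
    """Composition-independent backend read from a table of mu_gap values.

    The table holds columns (solute_id, solvent_id, T, mu_gap_kcal_mol), e.g.
    exported from a COSMO-RS run; values are interpolated linearly in T inside
    the tabulated range.
    """

    table: pd.DataFrame
    composition_dependent: bool = False

    REQUIRED = ("solute_id", "solvent_id", "T", "mu_gap_kcal_mol")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"backend table missing columns: {missing}")

    @classmethod
    def from_csv(cls, path) -> "TableBackend":
        return cls(pd.read_csv(path))

    def mu_gap(self, solute_id: str, solvent_id: str, T: float, x: float | None = None) -> float:
        sub = self.table[
            (self.table["solute_id"] == solute_id)
            & (self.table["solvent_id"] == solvent_id)
        ].sort_values("T")
        if sub.empty:
            raise KeyError(f"no mu_gap entries for ({solute_id}, {solvent_id})")
        Ts = sub["T"].to_numpy(float)
        if not (Ts.min() - 1e-9 <= T <= Ts.max() + 1e-9):
            raise ValueError(
                f"T={T} K outside tabulated range [{Ts.min()}, {Ts.max()}] K "
                f"for ({solute_id}, {solvent_id})"
            )
        return float(np.interp(T, Ts, sub["mu_gap_kcal_mol"].to_numpy(float)))


@dataclass(frozen=True)
class FusionEstimate:
    """Per-temperature Gibbs free energy of fusion anchored to one reference solvent."""

    solute_id: str
    reference_solvent: str
    values: Mapping[float, float]  # T [K] -> dG_fus [kcal/mol]

    def at(self, T: float) -> float:
        for t, v in self.values.items():
            if math.isclose(t, T, rel_tol=0.0, abs_tol=1e-9):
                return v
        raise KeyError(f"dG_fus not estimated at T={T} K (have {sorted(self.values)})")


def estimate_fusion(
    backend: ThermoBackend,
    solute_id: str,
    reference: str,
    x_exp: float,
    T: float,
) -> FusionEstimate:
    """Back-calculate dG_fus at one temperature from a reference solubility.

    dG_fus(T) = mu_gap(reference, T, x_exp) - R*T*ln(x_exp).  In the ideal-melt
    limit (x_exp -> 1 with a vanishing mu_gap) the fusion cost goes to zero.
    """
    if not 0.0 < x_exp < 1.0:
        raise ValueError(f"x_exp must lie in (0, 1), got {x_exp}")
    g = backend.mu_gap(solute_id, reference, T, x_exp) - R_KCAL * T * math.log(x_exp)
    return FusionEstimate(solute_id, reference, {float(T): float(g)})


def estimate_fusion_profile(
    backend: ThermoBackend,
    solute_id: str,
    reference: str,
    x_profile: Mapping[float, float],
) -> FusionEstimate:
    """dG_fus estimated independently at each temperature of a reference profile.

    No parametric dG_fus(T) form is imposed; each temperature is anchored to
    the experimental point measured there.
    """
    values: dict[float, float] = {}
    for T, x in sorted(x_profile.items()):
        values[float(T)] = estimate_fusion(backend, solute_id, reference, x, T).values[float(T)]
    return FusionEstimate(solute_id, reference, values)


def predict_solubility(
    backend: ThermoBackend,
    fusion: FusionEstimate,
    target: str,
    T: float,
    max_iter: int = 200,
    tol: float = 1e-13,
) -> float:
    """Solve the SLE condition ln x = (mu_gap(target, T, x) - dG_fus(T)) / (R*T).

    For a composition-independent backend this is a single closed-form
    evaluation; otherwise a damped fixed-point iteration on ln x is used.
    Predictions at or above x = 1 are clipped to 1 - 1e-12 with a warning
    (the backend claims the solute is miscible beyond the mole-fraction scale).
    """
    dgfus = fusion.at(T)
    rt = R_KCAL * T

    def _lnx_from(x: float | None) -> float:
        return (backend.mu_gap(fusion.solute_id, target, T, x) - dgfus) / rt

    if not backend.composition_dependent:
        lnx = _lnx_from(None)
    else:
        lnx = _lnx_from(1e-3)
        for _ in range(max_iter):
            new = _lnx_from(float(np.exp(min(lnx, 0.0))))
            if abs(new - lnx) < tol:
                lnx = new
                break
            lnx = 0.5 * (lnx + new)  # damping stabilizes stiff backends
        else:
            raise RuntimeError(
                f"SLE fixed-point failed to converge for target {target!r} at T={T} K"
            )
    x = math.exp(lnx)
    if x >= 1.0:
        warnings.warn(
            f"predicted x={x:.3g} >= 1 for {target!r} at T={T} K; clipped",
            stacklevel=2,
        )
        x = 1.0 - 1e-12
    return x


def mape_log10(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Mean absolute percentage error on the decadal-log solubility scale.

    100 * mean(|(log10 x_pred - log10 x_obs) / log10 x_obs|).  Because log10 x
    of a mole fraction is negative, the denominator enters through its
    absolute value; an observation with log10 x = 0 (x = 1) is rejected.
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("pred and obs must be equal-length, non-empty")
    if np.any(o == 0.0):
        raise ValueError("MAPE undefined for an observation with log10 x = 0")
    return float(100.0 * np.mean(np.abs((p - o) / o)))


@dataclass
class ReferenceMatrix:
    """Target-by-reference error matrix underlying the consonance heat map.

    ``mape`` holds the decadal-log MAPE of predicting each target (row) from
    each reference (column); the diagonal is exactly zero by self-consistency.
    ``signed_mean_error`` holds mean (log10 x_calc - log10 x_exp); its sign
    pattern is what distinguishes solvent classes.
    """

    mape: pd.DataFrame
    signed_mean_error: pd.DataFrame

    @property
    def solvents(self) -> list[str]:
        return list(self.mape.index)

    def off_diagonal_min(self, solvent: str) -> tuple[float, float]:
        """Min off-diagonal MAPE of ``solvent`` as target (row) and as reference (col)."""
        row = self.mape.loc[solvent].drop(solvent)
        col = self.mape[solvent].drop(solvent)
        return float(row.min()), float(col.min())

    def to_tsv(self, path) -> None:
        self.mape.to_csv(path, sep="\t")


def build_reference_matrix(
    backend: ThermoBackend,
    experimental: ConsensusTable,
    solvents: Sequence[str] | None = None,
) -> ReferenceMatrix:
    """All-pairs consonance predictions over the neat-solvent consensus data.

    For each reference r: estimate dG_fus(T) from r's profile; for each target
    t: predict x at every temperature of t's profile and score the decadal-log
    MAPE.  A failed pair is recorded as NaN rather than aborting the screen.
    """
    if solvents is None:
        solvents = sorted(
            {s for (s, f) in experimental.systems() if math.isclose(f, 1.0)}
        )
    solvents = list(solvents)
    profiles = {s: experimental.x_profile(s, 1.0) for s in solvents}
    n = len(solvents)
    mape = np.full((n, n), np.nan)
    signed = np.full((n, n), np.nan)
    for j, ref in enumerate(solvents):
        try:
            fusion = estimate_fusion_profile(
                backend, experimental.solute_id, ref, profiles[ref]
            )
        except Exception:
            continue
        for i, tgt in enumerate(solvents):
            if tgt == ref:
                # self-consistency: re-predicting the reference returns its
                # experimental values exactly
                mape[i, j] = 0.0
                signed[i, j] = 0.0
                continue
            try:
                preds, obs = [], []
                for T, x_obs in sorted(profiles[tgt].items()):
                    x_pred = predict_solubility(backend, fusion, tgt, T)
                    preds.append(math.log10(x_pred))
                    obs.append(math.log10(x_obs))
                mape[i, j] = mape_log10(preds, obs)
                signed[i, j] = float(np.mean(np.asarray(preds) - np.asarray(obs)))
            except Exception:
                pass  # recorded as missing
    return ReferenceMatrix(
        mape=pd.DataFrame(mape, index=solvents, columns=solvents),
        signed_mean_error=pd.DataFrame(signed, index=solvents, columns=solvents),
    )


def discover_classes(matrix: ReferenceMatrix, k: int) -> dict[str, int]:
    """Group solvents by the sign/magnitude profile of their prediction errors.

    Average-linkage hierarchical clustering (Euclidean) of the rows of the
    signed-mean-error matrix, cut at k clusters.  Solvents are processed in
    lexicographic id order so ties break deterministically; cluster labels are
    renumbered 0..k-1 by first appearance in that order.
    """
    solvents = sorted(matrix.solvents)
    if not 1 <= k <= len(solvents):
        raise ValueError(f"k must lie in [1, {len(solvents)}], got {k}")
    X = matrix.signed_mean_error.loc[solvents, solvents].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("signed-error matrix has missing entries; cannot cluster")
    if k == len(solvents):
        return {s: i for i, s in enumerate(solvents)}
    Z = linkage(X, method="average", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for s, lab in zip(solvents, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel)
        out[s] = relabel[lab]
    return out


@dataclass
class ConsonanceResult:
    """Outcome of the reference-solvent screen."""

    classes: tuple[tuple[str, ...], ...]  # partition of the non-excluded solvents
    reference_set: tuple[str, ...]
    excluded: tuple[str, ...]
    overall_mape: float
    assignment: dict[str, str] = field(default_factory=dict)  # target -> reference


def select_reference_set(
    matrix: ReferenceMatrix,
    k: int,
    exclusion_threshold: float = 30.0,
) -> ConsonanceResult:
    """Exhaustively pick the k-solvent reference set minimizing mean assigned MAPE.

    A solvent whose minimum off-diagonal MAPE exceeds ``exclusion_threshold``
    both as a target and as a reference matches no class (the acetone case) and
    is excluded from the pool first.  Every k-subset of the remaining solvents
    is then scored by assigning each remaining solvent to its best reference in
    the subset; the enumeration is exact (and guarded to <= 20 solvents).  Ties
    go to the lexicographically smallest reference tuple.
    """
    all_solvents = sorted(matrix.solvents)
    excluded = []
    for s in all_solvents:
        as_target, as_ref = matrix.off_diagonal_min(s)
        if as_target > exclusion_threshold and as_ref > exclusion_threshold:
            excluded.append(s)
    pool = [s for s in all_solvents if s not in excluded]
    if not pool:
        raise ValueError("all solvents excluded by the threshold")
    if k > len(pool):
        raise ValueError(f"k={k} exceeds the {len(pool)} non-excluded solvents")
    if len(pool) > MAX_EXHAUSTIVE_SOLVENTS:
        raise ValueError(
            f"exhaustive enumeration guarded to <= {MAX_EXHAUSTIVE_SOLVENTS} solvents"
        )
    mape = matrix.mape.loc[pool, pool]
    best: tuple[float, tuple[str, ...]] | None = None
    for subset in itertools.combinations(pool, k):  # lexicographic order
        assigned = mape[list(subset)].min(axis=1)
        score = float(assigned.mean())
        if best is None or score < best[0] - 1e-12:
            best = (score, subset)
    assert best is not None
    score, subset = best
    assignment = {
        t: mape.loc[t, list(subset)].idxmin() for t in pool
    }
    groups: dict[str, list[str]] = {r: [] for r in subset}
    for t, r in assignment.items():
        groups[r].append(t)
    classes = tuple(tuple(sorted(g)) for r, g in sorted(groups.items()) if g)
    return ConsonanceResult(
        classes=classes,
        reference_set=subset,
        excluded=tuple(excluded),
        overall_mape=score,
        assignment=assignment,
    )


def consonance_screen(
    backend: ThermoBackend,
    experimental: ConsensusTable,
    k: int = 3,
    exclusion_threshold: float = 30.0,
) -> tuple[ReferenceMatrix, dict[str, int], ConsonanceResult]:
    """Full screen: error matrix, class discovery, and reference-set selection."""
    matrix = build_reference_matrix(backend, experimental)
    classes = discover_classes(matrix, min(k, len(matrix.solvents)))
    result = select_reference_set(matrix, k, exclusion_threshold)
    return matrix, classes, result


def predict_with_references(
    backend: ThermoBackend,
    experimental: ConsensusTable,
    result: ConsonanceResult,
    mode: str = "best",
) -> pd.DataFrame:
    """Predict every non-excluded solvent from the selected reference set.

    ``mode='best'`` (default) uses each target's assigned reference;
    ``mode='average'`` averages the dG_fus estimates of all references before
    predicting.  Returns rows (solvent_id, T, log10x_pred, log10x_obs).
    """
    if mode not in ("best", "average"):
        raise ValueError(f"mode must be 'best' or 'average', got {mode!r}")
    profiles = {
        s: experimental.x_profile(s, 1.0)
        for s in set(result.assignment) | set(result.reference_set)
    }
    fusions = {
        r: estimate_fusion_profile(backend, experimental.solute_id, r, profiles[r])
        for r in result.reference_set
    }
    rows = []
    for target, ref in sorted(result.assignment.items()):
        for T, x_obs in sorted(profiles[target].items()):
            if mode == "best":
                x_pred = predict_solubility(backend, fusions[ref], target, T)
            else:
                preds = [
                    predict_solubility(backend, f, target, T)
                    for f in fusions.values()
                ]
                x_pred = float(np.exp(np.mean(np.log(preds))))
            rows.append(
                {
                    "solvent_id": target,
                    "T": T,
                    "log10x_pred": math.log10(x_pred),
                    "log10x_obs": math.log10(x_obs),
                }
            )
    return pd.DataFrame(rows)
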