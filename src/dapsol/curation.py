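"""Curation of solubility-temperature profiles via the three-parameter van't Hoff model.

Multi-source mole-fraction solubility data are standardized by fitting

    ln x = A + B/T + C/T**2

per (solute, solvent, composition) system.  The quadratic term in 1/T allows a
temperature-dependent dissolution enthalpy.  The model is linear in (A, B, C),
so the RMSD-minimizing parameters are the ordinary least-squares solution in
the basis (1, 1/T, 1/T**2); no iterative optimizer is needed.  Consensus
log10-solubility values are the back-calculated fit values at the experimental
temperatures — these, not the raw data, feed the downstream screening and
regression stages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LN10 = math.log(10.0)

__all__ = [
    "SolubilityRecord",
    "VantHoffFit",
    "ConsensusTable",
    "fit_vanthoff",
    "backcalc",
    "build_consensus",
    "mole_fraction_from_molarity",
    "solubility_ratio",
]


@dataclass(frozen=True)
class SolubilityRecord:
    """One saturation observation: mole-fraction solubility of a solute at one T.

    ``solvent_fraction`` is 1 for neat solvents; for binary mixtures it is the
    mole/volume fraction of the first solvent named in ``solvent_id``.
    """

    solute_id: str
    solvent_id: str
    T: float
    x: float
    solvent_fraction: float = 1.0
    s: float | None = None  # molar concentration, mol/dm^3
    sd_x: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"temperature must be positive, got T={self.T}")
        if not 0.0 < self.x < 1.0:
            raise ValueError(f"mole fraction must lie in (0, 1), got x={self.x}")
        if not 0.0 <= self.solvent_fraction <= 1.0:
            raise ValueError(
                f"solvent_fraction must lie in [0, 1], got {self.solvent_fraction}"
            )
        if self.sd_x is not None and self.sd_x < 0:
            raise ValueError(f"sd_x must be non-negative, got {self.sd_x}")


@dataclass(frozen=True)
class VantHoffFit:
    """Parameters of ln x = A + B/T + C/T^2 with fit diagnostics.

    A is dimensionless, B in K, C in K^2.  Back-calculation outside
    [T_min, T_max] is extrapolation and is flagged with a warning.
    """

    A: float
    B: float
    C: float
    rmsd_lnx: float
    n_points: int
    T_min: float
    T_max: float

    def ln_x(self, T: float | np.ndarray) -> float | np.ndarray:
        T = np.asarray(T, dtype=float)
        out = self.A + self.B / T + self.C / T**2
        return float(out) if out.ndim == 0 else out


def _design_matrix(T: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(T), 1.0 / T, 1.0 / T**2])


def fit_vanthoff(records: Sequence[SolubilityRecord]) -> VantHoffFit:
    """Least-squares fit of the three-parameter van't Hoff model to one profile.

    Requires at least three distinct temperatures from a single
    (solute, solvent, composition) system.  Minimizing the RMSD of ln x
    residuals is an ordinary linear least-squares problem, solved exactly.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to fit")
    keys = {(r.solute_id, r.solvent_id, r.solvent_fraction) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records mix systems: {sorted(keys)}")
    T = np.array([r.T for r in records], dtype=float)
    if len(np.unique(T)) < 3:
        raise ValueError(
            f"need >= 3 distinct temperatures, got {len(np.unique(T))}"
        )
    y = np.log([r.x for r in records])
    X = _design_matrix(T)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return VantHoffFit(
        A=float(beta[0]),
        B=float(beta[1]),
        C=float(beta[2]),
        rmsd_lnx=float(np.sqrt(np.mean(resid**2))),
        n_points=len(records),
        T_min=float(T.min()),
        T_max=float(T.max()),
    )


def backcalc(fit: VantHoffFit, T: float, warn_extrapolation: bool = True) -> float:
    """Back-calculated log10 mole-fraction solubility at temperature T."""
    if not T > 0:
        raise ValueError(f"temperature must be positive, got T={T}")
    if warn_extrapolation and not (fit.T_min <= T <= fit.T_max):
        warnings.warn(
            f"T={T} K outside fitted range [{fit.T_min}, {fit.T_max}] K; "
            "back-calculation is an extrapolation",
            stacklevel=2,
        )
    return fit.ln_x(T) / LN10


@dataclass
class ConsensusTable:
    """Consensus log10 solubility per (solvent, composition, T).

    Every consensus value is the back-calculated pooled-fit value at an
    experimental temperature, never a raw datum.  ``per_source_rmsd`` reports,
    per system and source, the RMSD of that source's ln x values against the
    pooled fit — the inconsistency diagnostic.
    """

    solute_id: str
    table: pd.DataFrame  # solvent_id, solvent_fraction, T, log10x_consensus, n_sources, rmsd
    fits: dict[tuple[str, float], VantHoffFit] = field(default_factory=dict)
    per_source_rmsd: dict[tuple[str, float, str], float] = field(default_factory=dict)

    def systems(self) -> list[tuple[str, float]]:
        return sorted(self.fits.keys())

    def x_profile(self, solvent_id: str, solvent_fraction: float = 1.0) -> dict[float, float]:
        """Consensus mole fractions keyed by temperature for one system."""
        sub = self.table[
            (self.table["solvent_id"] == solvent_id)
            & (np.isclose(self.table["solvent_fraction"], solvent_fraction))
        ]
        if sub.empty:
            raise KeyError(f"no consensus values for ({solvent_id}, {solvent_fraction})")
        return {
            float(t): float(10.0**v)
            for t, v in zip(sub["T"], sub["log10x_consensus"])
        }


def build_consensus(
    record_groups: Mapping[str, Sequence[SolubilityRecord]],
) -> ConsensusTable:
    """Pool sources per system, fit once, back-calculate at all experimental T.

    Sources are pooled (no down-weighting); disagreement between sources shows
    up as an elevated per-source RMSD against the pooled fit.
    """
    tagged: list[SolubilityRecord] = []
    for source, recs in record_groups.items():
        for r in recs:
            tagged.append(r if r.source == source else
                          SolubilityRecord(r.solute_id, r.solvent_id, r.T, r.x,
                                           r.solvent_fraction, r.s, r.sd_x, source))
    if not tagged:
        raise ValueError("no records supplied")
    solutes = {r.solute_id for r in tagged}
    if len(solutes) > 1:
        raise ValueError(f"records mix solutes: {sorted(solutes)}")

    fits: dict[tuple[str, float], VantHoffFit] = {}
    per_source: dict[tuple[str, float, str], float] = {}
    rows = []
    systems: dict[tuple[str, float], list[SolubilityRecord]] = {}
    for r in tagged:
        systems.setdefault((r.solvent_id, r.solvent_fraction), []).append(r)

    for (solvent, frac), recs in sorted(systems.items()):
        fit = fit_vanthoff(recs)
        fits[(solvent, frac)] = fit
        by_source: dict[str, list[SolubilityRecord]] = {}
        for r in recs:
            by_source.setdefault(r.source, []).append(r)
        for src, srecs in by_source.items():
            res = np.log([r.x for r in srecs]) - fit.ln_x(np.array([r.T for r in srecs]))
            per_source[(solvent, frac, src)] = float(np.sqrt(np.mean(res**2)))
        for T in sorted({r.T for r in recs}):
            rows.append(
                {
                    "solvent_id": solvent,
                    "solvent_fraction": frac,
                    "T": T,
                    "log10x_consensus": backcalc(fit, T),
                    "n_sources": len(by_source),
                    "rmsd": fit.rmsd_lnx,
                }
            )
    table = pd.DataFrame(rows)
    return ConsensusTable(
        solute_id=next(iter(solutes)),
        table=table,
        fits=fits,
        per_source_rmsd=per_source,
    )


def mole_fraction_from_molarity(
    s: float, rho: float, M_solute: float, M_solvent: float
) -> float:
    """Convert molar concentration to mole fraction via the solution density.

    Parameters
    ----------
    s : molar concentration of the solute, mol/dm^3.
    rho : density of the saturated solution, g/cm^3.
    M_solute, M_solvent : molar masses, g/mol.

    The solvent mass in one litre is 1000*rho - s*M_solute grams; the mole
    fraction follows from the mole balance.
    """
    if min(s, rho, M_solute, M_solvent) < 0 or rho <= 0 or M_solute <= 0 or M_solvent <= 0:
        raise ValueError("all inputs must be positive (s may be zero)")
    solvent_mass = 1000.0 * rho - s * M_solute
    if solvent_mass <= 0:
        raise ValueError(
            f"non-positive solvent mass ({solvent_mass:.3g} g/L): "
            "density inconsistent with the stated concentration"
        )
    n_solvent = solvent_mass / M_solvent
    return s / (s + n_solvent)


def solubility_ratio(
    records: Iterable[SolubilityRecord],
    solvent_id: str,
    T_hi: float,
    T_lo: float,
) -> float:
    """Mole-fraction solubility ratio x(T_hi)/x(T_lo) for one solvent, to 1 decimal.

    For dapsone this summarizes the temperature sensitivity of each solvent:
    between 298.15 K and 313.15 K the ratio is largest for NMP (10.6) and
    smallest for DMSO (2.4).
    """

    def _x_at(T: float) -> float:
        xs = [r.x for r in records if r.solvent_id == solvent_id and math.isclose(r.T, T)]
        if not xs:
            raise ValueError(f"no record for solvent {solvent_id!r} at T={T} K")
        return float(np.mean(xs))

    records = list(records)
    return round(_x_at(T_hi) / _x_at(T_lo), 1)
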