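"""Seeded synthetic data with the statistical structure of the dapsone study.

The real inputs to the pipeline are (i) solubility-temperature profiles, (ii)
a COSMO-RS-style thermodynamic backend, and (iii) a table of solute-solvent
affinity descriptors.  Only the five newly measured neat-solvent profiles are
printed in full; the literature profiles, the backend output and the
descriptor appendix are not.  This module generates all three with planted
ground truth so every downstream stage can be validated by parameter
recovery:

* solubility profiles follow a planted three-parameter van't Hoff law with
  multiplicative (log-scale) replicate noise;
* solvents fall into three chemistry classes (proton-donating,
  proton-accepting, non-hydrogen-bonding polar) plus an optional singleton
  (the acetone role); the mock backend's error is a shared per-class bias plus
  a per-solvent offset frozen at construction — a fixed level-of-theory bias,
  not per-call noise — which is exactly the structure the consonance screen
  must discover;
* descriptors are linear in log10 solubility with noise calibrated to a target
  population R-squared (0.7 for the dimerization affinity, matching the
  reported solute self-association correlation).

Every generator is bit-identical under a fixed seed, and the planted
parameters travel with the data in a :class:`SyntheticTruth` sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .curation import SolubilityRecord
from .consonance import R_KCAL

CLASS_LABELS = ("proton_donating", "proton_accepting", "nonHB_polar")
SINGLETON = "singleton"

#: Default descriptor links: (slope [kcal/mol per log10 unit], intercept
#: [kcal/mol], population R^2 of the link).  The dimerization affinity is tied
#: to log-solubility at R^2 = 0.7 (weaker self-association in better
#: solvents, hence positive slope); solvation free energies track solubility
#: most closely, the enthalpy/entropy split of the solute-solvent affinity
#: least.
DEFAULT_DESCRIPTOR_LINKS: dict[str, tuple[float, float, float]] = {
    "dG_dimer": (0.8, -12.0, 0.70),
    "dG_solute_solvent": (-1.2, -10.0, 0.80),
    "dH_solute_solvent": (-1.0, -15.0, 0.75),
    "minus_TdS_solute_solvent": (0.5, 4.0, 0.75),
    "dG_solv_monomer": (-1.36, -8.0, 0.90),
    "dG_solv_dimer": (-2.0, -18.0, 0.90),
    "dG_solv_pair": (-1.6, -14.0, 0.90),
}

__all__ = [
    "CLASS_LABELS",
    "SINGLETON",
    "DEFAULT_DESCRIPTOR_LINKS",
    "SolventSpec",
    "SyntheticTruth",
    "MockBackend",
    "default_fusion_truth",
    "gen_solvent_space",
    "gen_truth",
    "gen_solubility_profiles",
    "gen_descriptor_table",
    "gen_mock_backend",
    "gen_binary_mixture_profiles",
]


@dataclass(frozen=True)
class SolventSpec:
    """A synthetic solvent: identity, chemistry class, and backend error model."""

    solvent_id: str
    class_label: str
    class_bias: float  # kcal/mol, shared systematic backend error of the class
    within_class_sd: float  # kcal/mol, sd of the frozen per-solvent offset

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS + (SINGLETON,):
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.within_class_sd < 0:
            raise ValueError("within_class_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted parameters stored alongside every generated dataset.

    ``vanthoff`` maps solvent_id -> (A, B [K], C [K^2]); ``descriptor_links``
    maps column name -> (slope, intercept, r2); ``noise_sd`` is the replicate
    noise on ln x.  Regeneration with the same seed is bit-identical.
    """

    vanthoff: dict[str, tuple[float, float, float]]
    descriptor_links: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_LINKS)
    )
    noise_sd: float = 0.02
    seed: int = 0

    def ln_x(self, solvent_id: str, T: float | np.ndarray) -> float | np.ndarray:
        A, B, C = self.vanthoff[solvent_id]
        T = np.asarray(T, dtype=float)
        out = A + B / T + C / T**2
        return float(out) if out.ndim == 0 else out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            vanthoff={k: tuple(v) for k, v in d["vanthoff"].items()},
            descriptor_links={k: tuple(v) for k, v in d["descriptor_links"].items()},
            noise_sd=d["noise_sd"],
            seed=d["seed"],
        )


def gen_solvent_space(
    n_per_class: int,
    class_biases: Sequence[float] = (-1.0, 0.0, 1.0),
    seed: int = 0,
    within_class_sd: float = 0.05,
    singleton_bias: float | None = None,
) -> list[SolventSpec]:
    """Build a 3-class solvent space, optionally plus an acetone-like singleton.

    ``class_biases`` gives one backend bias (kcal/mol) per chemistry class; a
    ``singleton_bias`` far from every class bias plants a solvent that matches
    no class and should be excluded by the consonance screen.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    if len(class_biases) != len(CLASS_LABELS):
        raise ValueError(
            f"need one bias per class ({len(CLASS_LABELS)}), got {len(class_biases)}"
        )
    prefixes = {"proton_donating": "don", "proton_accepting": "acc", "nonHB_polar": "pol"}
    specs = [
        SolventSpec(f"{prefixes[label]}{i:02d}", label, float(bias), within_class_sd)
        for label, bias in zip(CLASS_LABELS, class_biases)
        for i in range(n_per_class)
    ]
    if singleton_bias is not None:
        specs.append(SolventSpec("singleton00", SINGLETON, float(singleton_bias), 0.0))
    return specs


def gen_truth(
    solvents: Sequence[SolventSpec],
    seed: int = 0,
    lnx_range: tuple[float, float] = (-11.5, -4.6),
    enthalpy_range_kJ: tuple[float, float] = (15.0, 55.0),
    curvature_range: tuple[float, float] = (-4e5, 4e5),
    noise_sd: float = 0.02,
) -> SyntheticTruth:
    """Plant one van't Hoff triple per solvent in a drug-like solubility regime.

    ln x at 298.15 K is drawn uniformly in ``lnx_range`` (x ~ 1e-5 .. 1e-2, the
    dapsone regime), the dissolution enthalpy in ``enthalpy_range_kJ`` (kJ/mol,
    endothermic as observed for dapsone in all measured solvents) fixes the
    B coefficient, and a modest curvature C allows a temperature-dependent
    enthalpy.  The triple is then A = ln x0 - B/T0 - C/T0^2.
    """
    rng = np.random.default_rng(seed)
    T0 = 298.15
    R_KJ = 8.31446e-3  # kJ/(mol*K)
    triples: dict[str, tuple[float, float, float]] = {}
    for spec in sorted(solvents, key=lambda s: s.solvent_id):
        lnx0 = rng.uniform(*lnx_range)
        dH = rng.uniform(*enthalpy_range_kJ)
        C = rng.uniform(*curvature_range)
        # d(ln x)/d(1/T) = -dH/R at T0 => B = -dH/R - 2*C/T0
        B = -dH / R_KJ - 2.0 * C / T0
        A = lnx0 - B / T0 - C / T0**2
        triples[spec.solvent_id] = (float(A), float(B), float(C))
    return SyntheticTruth(vanthoff=triples, noise_sd=noise_sd, seed=seed)


def gen_solubility_profiles(
    solvents: Sequence[SolventSpec],
    T_grid: Sequence[float],
    truth: SyntheticTruth,
    noise_sd: float | None = None,
    seed: int = 0,
    solute_id: str = "DAP",
) -> list[SolubilityRecord]:
    """Sample ln x = A + B/T + C/T^2 + Normal(0, noise_sd) on a temperature grid.

    Noise is applied on ln x (multiplicative on x), matching the log-scale
    replicate scatter of shake-flask measurements.  A planted triple implying
    x >= 1 anywhere on the grid is rejected with a diagnostic.
    """
    T_grid = [float(t) for t in T_grid]
    if any(t <= 0 for t in T_grid):
        raise ValueError("all temperatures must be positive")
    if noise_sd is None:
        noise_sd = truth.noise_sd
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[SolubilityRecord] = []
    for spec in sorted(solvents, key=lambda s: s.solvent_id):
        if spec.solvent_id not in truth.vanthoff:
            raise KeyError(f"truth holds no van't Hoff triple for {spec.solvent_id!r}")
        for T in T_grid:
            lnx = float(truth.ln_x(spec.solvent_id, T)) + (
                rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            )
            x = math.exp(lnx)
            if x >= 1.0:
                raise ValueError(
                    f"planted parameters for {spec.solvent_id!r} give x={x:.3g} >= 1 "
                    f"at T={T} K; inconsistent with the mole-fraction scale"
                )
            records.append(
                SolubilityRecord(
                    solute_id=solute_id,
                    solvent_id=spec.solvent_id,
                    T=T,
                    x=x,
                    source="synthetic",
                )
            )
    return records


def descriptor_noise_sd(slope: float, var_log10x: float, r2: float) -> float:
    """Noise sd making the population R^2 of d = slope*log10x + eps equal r2.

    From R^2 = slope^2 Var(y) / (slope^2 Var(y) + sd^2):
    sd^2 = slope^2 * Var(y) * (1 - R^2) / R^2.
    """
    if not 0.0 < r2 < 1.0:
        raise ValueError(f"target R^2 must lie in (0, 1), got {r2}")
    return abs(slope) * math.sqrt(var_log10x * (1.0 - r2) / r2)


def gen_descriptor_table(
    records: Sequence[SolubilityRecord],
    truth: SyntheticTruth,
    target_r2: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Build an affinity-descriptor table linearly linked to log10 solubility.

    Each descriptor column is d = slope*log10(x) + intercept + eps with eps
    i.i.d. Normal and sd chosen so the planted population R^2 of the link
    equals the link's r2 (all overridden by ``target_r2`` when given).
    Temperature and solvent fraction are carried as exact columns.  Row keys
    are (solvent_id, solvent_fraction, T); the target column is log10x.
    """
    if target_r2 is not None and not 0.0 < target_r2 < 1.0:
        raise ValueError(f"target_r2 must lie in (0, 1), got {target_r2}")
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    rng = np.random.default_rng(seed)
    y = np.array([math.log10(r.x) for r in records])
    var_y = float(np.var(y))
    rows = {
        "solvent_id": [r.solvent_id for r in records],
        "solvent_fraction": [r.solvent_fraction for r in records],
        "T": [r.T for r in records],
    }
    for name, (slope, intercept, r2) in truth.descriptor_links.items():
        r2_eff = target_r2 if target_r2 is not None else r2
        sd = descriptor_noise_sd(slope, var_y, r2_eff) if var_y > 0 else 0.0
        rows[name] = slope * y + intercept + rng.normal(0.0, sd, size=len(y))
    rows["log10x"] = y
    return pd.DataFrame(rows)


def default_fusion_truth(T: float) -> float:
    """Planted Gibbs free energy of fusion, kcal/mol.

    dG_fus(T) = dH_fus * (1 - T/T_m) with dH_fus = 7 kcal/mol and T_m = 450 K,
    a dapsone-like melting regime; positive below the melting point.
    """
    return 7.0 * (1.0 - T / 450.0)


@dataclass
class MockBackend:
    """Composition-independent backend with planted class-structured errors.

    mu_gap = [exact value implied by the planted solubility and fusion truth]
    + class bias + a per-solvent offset drawn once at construction.  With all
    biases and offsets zero, consonance prediction from any reference
    reproduces the planted solubility exactly.
    """

    truth: SyntheticTruth
    fusion_truth: Callable[[float], float]
    offsets: dict[str, float]  # per-solvent: class_bias + frozen random offset
    composition_dependent: bool = False

    def mu_gap(self, solute_id: str, solvent_id: str, T: float, x: float | None = None) -> float:
        lnx_true = float(self.truth.ln_x(solvent_id, T))
        exact = self.fusion_truth(T) + R_KCAL * T * lnx_true
        return exact + self.offsets[solvent_id]


def gen_mock_backend(
    solvents: Sequence[SolventSpec],
    truth: SyntheticTruth,
    fusion_truth: Callable[[float], float] = default_fusion_truth,
    seed: int = 0,
) -> MockBackend:
    """Freeze per-solvent backend errors and wrap the planted thermodynamics."""
    rng = np.random.default_rng(seed)
    offsets: dict[str, float] = {}
    for spec in sorted(solvents, key=lambda s: s.solvent_id):
        jitter = rng.normal(0.0, spec.within_class_sd) if spec.within_class_sd > 0 else 0.0
        offsets[spec.solvent_id] = spec.class_bias + jitter
    return MockBackend(truth=truth, fusion_truth=fusion_truth, offsets=offsets)


def gen_binary_mixture_profiles(
    solvent_a: SolventSpec,
    solvent_b: SolventSpec,
    fractions: Sequence[float],
    T_grid: Sequence[float],
    truth: SyntheticTruth,
    seed: int = 0,
    excess_term: float = 0.0,
    noise_sd: float | None = None,
    solute_id: str = "DAP",
) -> list[SolubilityRecord]:
    """Binary-mixture profiles interpolating the neat-solvent models.

    ln x(f) = f*ln x_a + (1-f)*ln x_b + f*(1-f)*excess_term + noise, a
    one-parameter symmetric (Margules-like) excess on the log scale; endpoints
    reproduce the neat solvents exactly when noiseless.  ``fractions`` must be
    sorted and within [0, 1].
    """
    fr = [float(f) for f in fractions]
    if any(not 0.0 <= f <= 1.0 for f in fr):
        raise ValueError("fractions must lie in [0, 1]")
    if fr != sorted(fr):
        raise ValueError("fractions must be sorted ascending")
    if noise_sd is None:
        noise_sd = truth.noise_sd
    rng = np.random.default_rng(seed)
    mix_id = f"{solvent_a.solvent_id}+{solvent_b.solvent_id}"
    records: list[SolubilityRecord] = []
    for f in fr:
        for T in (float(t) for t in T_grid):
            lnx = (
                f * float(truth.ln_x(solvent_a.solvent_id, T))
                + (1.0 - f) * float(truth.ln_x(solvent_b.solvent_id, T))
                + f * (1.0 - f) * excess_term
            )
            if noise_sd > 0:
                lnx += rng.normal(0.0, noise_sd)
            if lnx >= 0.0:
                raise ValueError(
                    f"mixture x >= 1 at f={f}, T={T} K; excess term inconsistent "
                    "with the mole-fraction scale"
                )
            records.append(
                SolubilityRecord(
                    solute_id=solute_id,
                    solvent_id=mix_id,
                    T=T,
                    x=math.exp(lnx),
                    solvent_fraction=f,
                    source="synthetic",
                )
            )
    return records
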