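"""Conformer-resolved pair energetics and affinity descriptors.

Solute-solute and solute-solvent affinities are quantified by the Gibbs free
energy of the pair-formation reaction X + Y -> XY (a homodimer when X = Y).
A cluster's conformer list is first pruned — conformers more than a relative
energy window (2.5 kcal/mol by default) above the minimum are discarded, and
near-duplicates (similar energy *and* similar geometry after optimal rigid
superposition) are removed — then per-conformer quantities are averaged with
Boltzmann population weights.  The resulting reaction energies, their
enthalpic/entropic split, and solvation free energies form the descriptor
table consumed by the regression stage; the squared Pearson correlation of a
descriptor with log10 solubility is the module's link diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .consonance import R_KCAL

DEFAULT_ENERGY_WINDOW = 2.5  # kcal/mol, relative-energy retention window
DEFAULT_RMSD_THRESHOLD = 0.5  # Angstrom, dedup geometry threshold (repo default)
DEFAULT_ENERGY_TOL = 0.1  # kcal/mol, dedup energy threshold (repo default)

__all__ = [
    "Conformer",
    "ClusterPair",
    "energy_window_filter",
    "kabsch_rmsd",
    "dedup_clusters",
    "boltzmann_weights",
    "weighted_correction",
    "reaction_gibbs",
    "affinity_solubility_r2",
    "read_xyz_conformers",
]


@dataclass(frozen=True)
class Conformer:
    """One conformer of a molecular cluster.

    ``energy`` is in kcal/mol; relative energies are acceptable everywhere
    because both the retention window and the Boltzmann weights are invariant
    to a uniform shift.  ``corrections`` may carry per-conformer energy
    corrections keyed 'cor' (electron correlation), 'zpe', 'bsse'.
    """

    id: str
    energy: float
    elements: tuple[str, ...] | None = None
    coords: tuple[tuple[float, float, float], ...] | None = None
    corrections: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise ValueError(f"conformer {self.id!r} has non-finite energy")
        if (self.elements is None) != (self.coords is None):
            raise ValueError("elements and coords must be given together")
        if self.coords is not None:
            if len(self.coords) < 1:
                raise ValueError("coordinates must contain at least one atom")
            if len(self.elements) != len(self.coords):
                raise ValueError("elements and coords length mismatch")

    @property
    def xyz(self) -> np.ndarray:
        if self.coords is None:
            raise ValueError(f"conformer {self.id!r} carries no coordinates")
        return np.asarray(self.coords, dtype=float)


def energy_window_filter(
    conformers: Sequence[Conformer], window: float = DEFAULT_ENERGY_WINDOW
) -> list[Conformer]:
    """Keep conformers within ``window`` kcal/mol of the lowest energy.

    Order is preserved; the filter is idempotent and monotone in the window.
    """
    conformers = list(conformers)
    if not conformers:
        raise ValueError("empty conformer list")
    e_min = min(c.energy for c in conformers)
    return [c for c in conformers if c.energy - e_min <= window]


def _as_coords(a: "Conformer | np.ndarray") -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(a, Conformer):
        return a.xyz, a.elements
    return np.asarray(a, dtype=float), None


def kabsch_rmsd(a, b) -> float:
    """Minimal RMSD between two structures over proper rigid motions.

    Both arguments may be :class:`Conformer` objects (element sequences must
    match) or plain (n, 3) arrays.  The optimal rotation is found by the
    Kabsch algorithm; improper rotations (reflections) are excluded, matching
    standard cluster-overlap practice.
    """
    pa, ea = _as_coords(a)
    pb, eb = _as_coords(b)
    if pa.shape != pb.shape or pa.ndim != 2 or pa.shape[1] != 3:
        raise ValueError(f"coordinate shape mismatch: {pa.shape} vs {pb.shape}")
    if ea is not None and eb is not None and ea != eb:
        raise ValueError("element sequences differ")
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    H = pa.T @ pb
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = pa @ R.T - pb
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def dedup_clusters(
    conformers: Sequence[Conformer],
    rmsd_threshold: float = DEFAULT_RMSD_THRESHOLD,
    energy_tol: float = DEFAULT_ENERGY_TOL,
) -> list[Conformer]:
    """Drop near-duplicate conformers (close in both energy and geometry).

    Greedy scan in ascending energy order (ties broken by id, so the result is
    independent of input ordering): a conformer is discarded when some already
    retained conformer lies within both ``energy_tol`` and ``rmsd_threshold``.
    """
    conformers = list(conformers)
    if any(c.coords is None for c in conformers):
        missing = [c.id for c in conformers if c.coords is None]
        raise ValueError(f"conformers without coordinates: {missing}")
    kept: list[Conformer] = []
    for c in sorted(conformers, key=lambda c: (c.energy, c.id)):
        duplicate = any(
            abs(c.energy - k.energy) <= energy_tol
            and kabsch_rmsd(c, k) <= rmsd_threshold
            for k in kept
        )
        if not duplicate:
            kept.append(c)
    return kept


def boltzmann_weights(energies: Sequence[float], T: float) -> np.ndarray:
    """Population fractions w_i ∝ exp(-(E_i - E_min)/(R*T)); sums to one.

    Shift-invariant, so relative energies are fine.
    """
    if len(energies) == 0:
        raise ValueError("empty energy list")
    if not T > 0:
        raise ValueError(f"temperature must be positive, got T={T}")
    e = np.asarray(energies, dtype=float)
    w = np.exp(-(e - e.min()) / (R_KCAL * T))
    return w / w.sum()


def weighted_correction(
    conformers: Sequence[Conformer], T: float, which: str
) -> float:
    """Boltzmann-weighted mean of a per-conformer energy correction.

    ``which`` is one of 'cor', 'zpe', 'bsse'; every conformer must carry it.
    """
    if which not in ("cor", "zpe", "bsse"):
        raise ValueError(f"unknown correction {which!r}")
    missing = [c.id for c in conformers if which not in c.corrections]
    if missing:
        raise ValueError(f"conformers missing {which!r} correction: {missing}")
    w = boltzmann_weights([c.energy for c in conformers], T)
    vals = np.array([c.corrections[which] for c in conformers], dtype=float)
    return float(w @ vals)


def reaction_gibbs(g_xy: float, g_x: float, g_y: float) -> float:
    """Gibbs free energy of pair formation X + Y -> XY: dG_r = G_XY - G_X - G_Y."""
    if not all(map(math.isfinite, (g_xy, g_x, g_y))):
        raise ValueError("non-finite Gibbs energy input")
    return g_xy - g_x - g_y


@dataclass
class ClusterPair:
    """A homo- or heteromolecular pair with its averaged energetics.

    ``dG_r_a`` is the activity-based (composition-independent) reaction Gibbs
    energy and ``dG_r_x`` the mole-fraction-based one; they differ by
    R*T*ln(activity-coefficient product).  When both the enthalpic and
    entropic contributions are present they must recompose the Gibbs energy.
    """

    species_x: str
    species_y: str
    conformers: list[Conformer]
    T: float
    dG_r_a: float | None = None
    dG_r_x: float | None = None
    dH_r: float | None = None
    minus_TdS_r: float | None = None
    ln_gamma_product: float | None = None

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("temperature must be positive")
        if (
            self.dG_r_a is not None
            and self.dG_r_x is not None
            and self.ln_gamma_product is not None
        ):
            expected = self.dG_r_a + R_KCAL * self.T * self.ln_gamma_product
            if abs(self.dG_r_x - expected) > 1e-6:
                raise ValueError(
                    f"dG_r_x={self.dG_r_x} inconsistent with dG_r_a and the "
                    f"activity-coefficient product (expected {expected})"
                )
        dg = self.dG_r_a if self.dG_r_a is not None else self.dG_r_x
        if dg is not None and self.dH_r is not None and self.minus_TdS_r is not None:
            if abs(self.dH_r + self.minus_TdS_r - dg) > 1e-6:
                raise ValueError(
                    "enthalpic + entropic contributions do not recompose dG_r"
                )

    @property
    def is_homodimer(self) -> bool:
        return self.species_x == self.species_y

    def weighted(self, which: str) -> float:
        """Boltzmann-weighted correction (cor/zpe/bsse) over this pair's conformers."""
        return weighted_correction(self.conformers, self.T, which)


def affinity_solubility_r2(
    descriptor: Sequence[float], log10x: Sequence[float]
) -> float:
    """Squared Pearson correlation between a descriptor and log10 solubility.

    The dapsone self-association affinity correlates with solubility at
    R^2 ~ 0.7 across solvents; this diagnostic reproduces that check for any
    descriptor column.
    """
    d = np.asarray(descriptor, dtype=float)
    y = np.asarray(log10x, dtype=float)
    if d.shape != y.shape or d.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.var(d) == 0.0 or np.var(y) == 0.0:
        raise ValueError("zero variance in descriptor or target")
    r = np.corrcoef(d, y)[0, 1]
    return float(r * r)


def read_xyz_conformers(path, energies: Mapping[str, float] | None = None) -> list[Conformer]:
    """Read a multi-structure XYZ file into conformers.

    Each block is: atom count line, comment line (used as the conformer id;
    a trailing ``energy=<value>`` token is parsed when present), then one
    ``element x y z`` line per atom.  ``energies`` overrides/provides energies
    keyed by conformer id.
    """
    conformers: list[Conformer] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1].strip()
        cid, energy = comment, math.nan
        for tok in comment.split():
            if tok.startswith("energy="):
                energy = float(tok.split("=", 1)[1])
                cid = comment.replace(tok, "").strip() or cid
        elements, coords = [], []
        for ln in lines[i + 2 : i + 2 + n]:
            parts = ln.split()
            elements.append(parts[0])
            coords.append((float(parts[1]), float(parts[2]), float(parts[3])))
        if energies is not None and cid in energies:
            energy = float(energies[cid])
        if not math.isfinite(energy):
            raise ValueError(f"no energy available for conformer {cid!r}")
        conformers.append(
            Conformer(id=cid, energy=energy, elements=tuple(elements), coords=tuple(coords))
        )
        i += 2 + n
    return conformers
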