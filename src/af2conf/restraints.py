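"""Confidence-weighted adaptive (top-out) restraints against a reference model.

When a working model is rebuilt against experimental data with a predicted
reference, each restrained atom pair gets a flat-bottomed, top-out distance
potential with four parameters: kappa (overall strength), wellHalfWidth
(range over which the restoring force grows roughly linearly), tolerance
(width of the zero-force flat bottom around the target) and fallOff (rate at
which the potential tapers at large deviation, letting the model escape
where the data disagree).  wellHalfWidth, tolerance and fallOff all increase
with the reference distance; kappa, tolerance and fallOff are additionally
adjusted by the pLDDT of the lowest-confidence atom of the pair, and any
restraint whose pair includes an atom with pLDDT < 50 is disabled outright.

Energy model (deviation x = max(0, |r − target| − tolerance), well width c):

    E(x) = kappa · (1 − exp(−x² / (2 c² (1 + fallOff·x/c))))

E is quadratic in x near 0 (harmonic well), the force dE/dx peaks near
x ≈ c and decays toward zero as x → ∞ for fallOff > 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import AF2Model

__all__ = [
    "DistanceRestraint",
    "TorsionRestraint",
    "RestraintConfig",
    "make_distance_restraints",
    "adaptive_energy",
    "dihedral",
    "make_torsion_restraints",
]

AtomRef = tuple[str, int, str]  # (chain, residue number, atom name)


@dataclass(frozen=True)
class RestraintConfig:
    """Coefficients of the distance-restraint parameterization.

    All three distance-dependent parameters scale linearly with the reference
    distance d₀ relative to ``d_ref_scale``; the defaults give a 0.4 Å well
    half-width, 0.1 Å tolerance and fallOff 2 for a typical 4 Å Cα–Cα pair.
    """

    kappa_base: float = 10.0     # energy units
    w0: float = 0.3              # Å   — wellHalfWidth at d₀ = d_ref_scale
    t0: float = 0.075            # Å   — tolerance at d₀ = d_ref_scale
    f0: float = 2.0              #     — fallOff at d₀ = d_ref_scale
    d_ref_scale: float = 3.0     # Å


@dataclass
class DistanceRestraint:
    atom_a: AtomRef
    atom_b: AtomRef
    target_distance: float
    kappa: float
    well_half_width: float
    tolerance: float
    fall_off: float
    enabled: bool
    min_plddt: float

    def __post_init__(self) -> None:
        if self.target_distance <= 0:
            raise ValueError("target_distance must be > 0")
        if self.kappa < 0 or self.well_half_width <= 0 or self.tolerance < 0:
            raise ValueError("invalid restraint parameters")
        if self.enabled != (self.min_plddt >= 50.0):
            raise ValueError("enabled flag inconsistent with min_plddt")


@dataclass
class TorsionRestraint:
    atoms: tuple[AtomRef, AtomRef, AtomRef, AtomRef]
    name: str                # phi | psi | chi1 ...
    target_angle: float      # degrees, (−180, 180]
    strength: float
    enabled: bool

    def __post_init__(self) -> None:
        if len(set(self.atoms)) != 4:
            raise ValueError("torsion needs four distinct atoms")
        if not -180.0 < self.target_angle <= 180.0:
            raise ValueError("target angle must lie in (−180, 180]")


def _pair_map(model: AF2Model) -> dict[tuple[str, int], int]:
    return {(model.chain_ids[i], int(model.numbers[i])): i for i in range(len(model))}


def make_distance_restraints(working: AF2Model, reference: AF2Model,
                             distance_cutoff: float = 8.0,
                             plddt_weighting: bool = True,
                             min_separation: int = 3,
                             config: RestraintConfig = RestraintConfig(),
                             ) -> list[DistanceRestraint]:
    """Cα–Cα distance restraints of the working model against the reference.

    Residues are mapped by (chain, residue number).  A pair is restrained
    when its Cα distance is within ``distance_cutoff`` in either model
    (symmetric selection) and the sequence separation is at least
    ``min_separation``.  The target is always the reference distance d₀;
    wellHalfWidth, tolerance and fallOff scale linearly with d₀.  With
    pLDDT weighting on, p = the pair's minimum reference pLDDT:
    kappa ×= clip((p−50)/50, 0, 1); tolerance and fallOff ×= 1+(100−p)/50;
    pairs with p < 50 are disabled (kappa 0).
    """
    if distance_cutoff <= 0:
        raise ValueError("distance_cutoff must be > 0")
    ref_map = _pair_map(reference)
    shared = [(i, ref_map[key]) for i, key in
              (((w, (working.chain_ids[w], int(working.numbers[w])))
                for w in range(len(working))))
              if key in ref_map]
    if not shared:
        raise ValueError("working and reference share no mappable residues")
    w_idx = np.array([s[0] for s in shared])
    r_idx = np.array([s[1] for s in shared])
    restraints: list[DistanceRestraint] = []
    cfg = config
    for a in range(len(shared)):
        for b in range(a + 1, len(shared)):
            wa, wb = w_idx[a], w_idx[b]
            ra, rb = r_idx[a], r_idx[b]
            if working.chain_ids[wa] == working.chain_ids[wb] and \
                    abs(int(working.numbers[wa]) - int(working.numbers[wb])) < min_separation:
                continue
            d_ref = float(np.linalg.norm(reference.ca[ra] - reference.ca[rb]))
            d_work = float(np.linalg.norm(working.ca[wa] - working.ca[wb]))
            if min(d_ref, d_work) > distance_cutoff or d_ref <= 0:
                continue
            scale = d_ref / cfg.d_ref_scale
            whw = cfg.w0 * scale
            tol = cfg.t0 * scale
            foff = cfg.f0 * scale
            p = float(min(reference.plddt[ra], reference.plddt[rb]))
            kappa = cfg.kappa_base
            if plddt_weighting:
                kappa *= min(max((p - 50.0) / 50.0, 0.0), 1.0)
                conf = 1.0 + (100.0 - p) / 50.0
                tol *= conf
                foff *= conf
            enabled = p >= 50.0
            if not enabled:
                kappa = 0.0
            restraints.append(DistanceRestraint(
                atom_a=(working.chain_ids[wa], int(working.numbers[wa]), "CA"),
                atom_b=(working.chain_ids[wb], int(working.numbers[wb]), "CA"),
                target_distance=d_ref,
                kappa=kappa,
                well_half_width=whw,
                tolerance=tol,
                fall_off=foff,
                enabled=enabled,
                min_plddt=p,
            ))
    return restraints


def adaptive_energy(restraint: DistanceRestraint, r: float) -> tuple[float, float]:
    """Energy and force magnitude of a top-out restraint at distance r.

    Inside the flat bottom (|r − target| ≤ tolerance) both are exactly zero;
    beyond it the well is harmonic near the target, the force peaks near one
    well half-width of deviation and tapers toward zero at large deviation
    for fallOff > 0.  Disabled restraints contribute (0, 0).
    """
    if r <= 0:
        raise ValueError("distance must be > 0")
    if not restraint.enabled or restraint.kappa == 0:
        return 0.0, 0.0
    x = max(0.0, abs(r - restraint.target_distance) - restraint.tolerance)
    if x == 0.0:
        return 0.0, 0.0
    c = restraint.well_half_width
    f = restraint.fall_off
    denom = 1.0 + f * x / c
    g = x * x / (2.0 * c * c * denom)
    expg = math.exp(-g)
    energy = restraint.kappa * (1.0 - expg)
    dg = x * (2.0 + f * x / c) / (2.0 * c * c * denom * denom)
    force = restraint.kappa * expg * dg
    return energy, force


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees) of four points; NaN when degenerate
    (collinear triples give zero-length plane normals)."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return float("nan")
    b1u = b1 / np.linalg.norm(b1)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, b1u), n2)
    return float(np.degrees(np.arctan2(y, x)))


_CHI1_ATOMS = {
    "R": "CG", "N": "CG", "D": "CG", "C": "SG", "Q": "CG", "E": "CG",
    "H": "CG", "I": "CG1", "L": "CG", "K": "CG", "M": "CG", "F": "CG",
    "P": "CG", "S": "OG", "T": "OG1", "W": "CG", "Y": "CG", "V": "CG1",
}


def make_torsion_restraints(working: AF2Model, reference: AF2Model,
                            strength: float = 1.0) -> list[TorsionRestraint]:
    """Restrain φ/ψ (and χ1 where side-chain atoms exist) to the reference.

    Torsions are measured on the reference model; residues mapped by
    (chain, residue number).  Residues with reference pLDDT < 50 yield
    disabled restraints (no graded weighting of torsions).  Degenerate
    (collinear) torsions are skipped with a warning.
    """
    if not reference.has_atoms:
        raise ValueError("reference model has no atom records for torsions")
    atom_of = []
    for rec in reference.atoms:
        atom_of.append({a.name: np.asarray(a.coord) for a in rec})
    ref_map = _pair_map(reference)
    work_keys = {(working.chain_ids[i], int(working.numbers[i])) for i in range(len(working))}
    restraints: list[TorsionRestraint] = []

    def add(name: str, quads: list[tuple[int, str]], key_res: int) -> None:
        coords = []
        refs: list[AtomRef] = []
        for ri, aname in quads:
            if aname not in atom_of[ri]:
                warnings.warn(f"missing atom {aname} in residue {ri}: {name} skipped")
                return
            coords.append(atom_of[ri][aname])
            refs.append((reference.chain_ids[ri], int(reference.numbers[ri]), aname))
        ang = dihedral(*coords)
        if math.isnan(ang):
            warnings.warn(f"degenerate geometry: {name} torsion undefined, skipped")
            return
        if ang <= -180.0:
            ang += 360.0
        restraints.append(TorsionRestraint(
            atoms=tuple(refs), name=name, target_angle=ang,
            strength=strength, enabled=bool(reference.plddt[key_res] >= 50.0)))

    for cid in reference.chains:
        idx = [int(i) for i in reference.chain_index(cid)]
        for pos, ri in enumerate(idx):
            key = (reference.chain_ids[ri], int(reference.numbers[ri]))
            if key not in work_keys:
                continue
            if pos > 0:
                add("phi", [(idx[pos - 1], "C"), (ri, "N"), (ri, "CA"), (ri, "C")], ri)
            if pos < len(idx) - 1:
                add("psi", [(ri, "N"), (ri, "CA"), (ri, "C"), (idx[pos + 1], "N")], ri)
            chi_end = _CHI1_ATOMS.get(reference.aa[ri])
            if chi_end is not None and chi_end in atom_of[ri] and "CB" in atom_of[ri]:
                add("chi1", [(ri, "N"), (ri, "CA"), (ri, "CB"), (ri, chi_end)], ri)
    return restraints
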