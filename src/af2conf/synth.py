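"""Synthetic AlphaFold-like inputs with planted ground truth.

Every downstream stage (segmentation, disorder scoring, shape-mers, PAE
domain clustering, oligomer-state calls, pocket overlap) is testable against
these generators without downloading real models.  The generators are pure
functions of their spec and seed: the same arguments always reproduce the
same output bit for bit.

What is emulated — and what is not
----------------------------------
Cα traces are built from ideal secondary-structure geometry (helix: 1.5 Å
rise, 2.3 Å radius, 100°/residue; strand: near-extended 3.8 Å steps with an
alternating pleat) and disordered blocks as 3.8 Å-step self-avoiding random
walks; pLDDT profiles are drawn per segment (optionally with AR(1)
autocorrelation) so that low confidence co-occurs with the disordered
blocks, mirroring the empirical association between low pLDDT and intrinsic
disorder.  PAE matrices are block-structured with Gaussian noise.  No side
chains, no energetics, no realistic loop closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import AF2Model, Atom, DisorderAnnotation, MSA, PAEMatrix
from .oligomer import OligomerScan
from .pockets import PocketPrediction

__all__ = [
    "SegmentSpec",
    "ModelSpec",
    "PAESpec",
    "synth_model",
    "synth_pae",
    "synth_oligomer_scan",
    "synth_msa",
    "synth_binding_site",
    "synth_backbone",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

CLASH_RADIUS = 2.5  # Å, Cα–Cα self-avoidance
STEP = 3.8          # Å, trans Cα–Cα virtual bond
MAX_RETRIES = 1000


@dataclass(frozen=True)
class SegmentSpec:
    kind: str  # helix | strand | coil
    length: int
    plddt_mean: float
    plddt_sd: float
    disordered: bool

    def __post_init__(self) -> None:
        if self.kind not in {"helix", "strand", "coil"}:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if not 0 <= self.plddt_mean <= 100:
            raise ValueError("plddt_mean must lie in [0, 100]")
        if self.plddt_sd < 0:
            raise ValueError("plddt_sd must be >= 0")


@dataclass(frozen=True)
class ModelSpec:
    segments: tuple[SegmentSpec, ...]
    seed: int = 0
    plddt_rho: float = 0.0  # AR(1) autocorrelation of the pLDDT noise

    @classmethod
    def from_tuples(cls, segs, seed: int = 0, plddt_rho: float = 0.0) -> "ModelSpec":
        return cls(tuple(SegmentSpec(*s) for s in segs), seed, plddt_rho)


@dataclass(frozen=True)
class PAESpec:
    block_sizes: tuple[int, ...]
    intra_mean: float
    inter_mean: float
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be >= 1")
        if self.intra_mean < 0 or self.inter_mean < 0 or self.noise_sd < 0:
            raise ValueError("PAE means and noise must be >= 0")
        if not self.intra_mean < self.inter_mean:
            raise ValueError("intra_mean must be < inter_mean")


def _helix_template(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _strand_template(n: int) -> np.ndarray:
    # step chosen so consecutive Cα–Cα = 3.8 Å with a ±0.5 Å pleat
    dx = math.sqrt(STEP**2 - 1.0)
    i = np.arange(n)
    return np.column_stack([dx * i, 0.5 * (-1.0) ** i, np.zeros(n)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _clashes(coords: np.ndarray, placed: list[np.ndarray], skip_last: int) -> bool:
    """True if any new point comes within CLASH_RADIUS of a non-adjacent old one."""
    if not placed:
        return False
    old = np.asarray(placed)
    if skip_last:
        old = old[:-skip_last]
    if old.size == 0:
        return False
    d = np.linalg.norm(coords[:, None, :] - old[None, :, :], axis=-1)
    return bool(np.any(d < CLASH_RADIUS))


def _append_segment(placed: list[np.ndarray], seg: SegmentSpec,
                    rng: np.random.Generator) -> None:
    if seg.kind == "coil":
        for _ in range(seg.length):
            for attempt in range(MAX_RETRIES):
                if not placed:
                    placed.append(np.zeros(3))
                    break
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = placed[-1] + STEP * u
                if not _clashes(cand[None, :], placed, skip_last=1):
                    placed.append(cand)
                    break
            else:
                raise RuntimeError(
                    "self-avoiding walk failed after bounded retries; "
                    "use a shorter coil or a different seed (larger box)"
                )
        return
    template = _helix_template(seg.length) if seg.kind == "helix" else _strand_template(seg.length)
    template = template - template[0]
    for attempt in range(MAX_RETRIES):
        rot = _random_rotation(rng)
        coords = template @ rot.T
        if placed:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords = coords + placed[-1] + STEP * u
        if not _clashes(coords, placed, skip_last=1):
            # also require the new segment not to clash with itself beyond design
            placed.extend(coords)
            return
    raise RuntimeError(
        f"could not place {seg.kind} segment without clashes after "
        f"{MAX_RETRIES} retries; use a different seed (larger box)"
    )


def synth_model(spec: ModelSpec, name: str | None = None) -> tuple[AF2Model, DisorderAnnotation]:
    """Generate a Cα-trace model plus its ground-truth disorder labels.

    Helix and strand segments use ideal secondary-structure geometry; coil
    segments are self-avoiding random walks.  Consecutive Cα–Cα distances lie
    in [3.5, 4.1] Å throughout.  pLDDT is Normal(mean, sd) per segment,
    clipped to [0, 100], optionally AR(1)-correlated along the chain.
    """
    rng = np.random.default_rng(spec.seed)
    placed: list[np.ndarray] = []
    labels: list[int] = []
    means: list[float] = []
    sds: list[float] = []
    for seg in spec.segments:
        _append_segment(placed, seg, rng)
        labels.extend([int(seg.disordered)] * seg.length)
        means.extend([seg.plddt_mean] * seg.length)
        sds.extend([seg.plddt_sd] * seg.length)
    n = len(placed)
    noise = np.empty(n)
    eps = rng.normal(size=n)
    rho = spec.plddt_rho
    noise[0] = eps[0]
    for i in range(1, n):
        noise[i] = rho * noise[i - 1] + math.sqrt(1 - rho**2) * eps[i]
    plddt = np.clip(np.asarray(means) + np.asarray(sds) * noise, 0.0, 100.0)
    model_name = name or f"synth-{spec.seed}"
    model = AF2Model(
        chain_ids=["A"] * n,
        numbers=np.arange(1, n + 1),
        aa=[AA20[i] for i in rng.integers(0, 20, size=n)],
        ca=np.asarray(placed),
        plddt=plddt,
        name=model_name,
    )
    annot = DisorderAnnotation.from_array(model_name, model, labels)
    return model, annot


def synth_pae(spec: PAESpec) -> PAEMatrix:
    """Block-structured PAE: low expected error inside planted rigid blocks,
    high across them, with Gaussian noise clipped at 0 and the diagonal set
    to intra_mean/2."""
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.block_sizes)
    block_of = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    same = block_of[:, None] == block_of[None, :]
    mean = np.where(same, spec.intra_mean, spec.inter_mean)
    values = mean + (rng.normal(size=(n, n)) * spec.noise_sd if spec.noise_sd > 0 else 0.0)
    values = np.clip(values, 0.0, None)
    np.fill_diagonal(values, spec.intra_mean / 2.0)
    return PAEMatrix(values)


def synth_oligomer_scan(true_state: int, n_states: int = 4, n_models: int = 5,
                        gap: float = 0.2, noise_sd: float = 0.05,
                        seed: int = 0, base: float = 0.85) -> OligomerScan:
    """Planted homo-oligomer state scan: per state s the per-model pTM scores
    are Normal(base − gap·|s − true_state|, noise_sd) clipped to [0, 1]."""
    if not 1 <= true_state <= n_states:
        raise ValueError("true_state must lie in 1..n_states")
    if gap <= 0:
        raise ValueError("gap must be > 0")
    rng = np.random.default_rng(seed)
    scores = {}
    for s in range(1, n_states + 1):
        mu = base - gap * abs(s - true_state)
        draws = np.full(n_models, mu)
        if noise_sd > 0:
            draws = draws + rng.normal(size=n_models) * noise_sd
        scores[s] = [float(v) for v in np.clip(draws, 0.0, 1.0)]
    return OligomerScan(scores=scores, annotated_state=true_state)


def synth_msa(n_rows: int, length: int, mutation_rate: float, seed: int = 0) -> MSA:
    """Toy MSA: a random query plus copies with i.i.d. per-column substitutions."""
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    query = "".join(AA20[i] for i in rng.integers(0, 20, size=length))
    rows = [("query", query)]
    for r in range(1, n_rows):
        seq = list(query)
        hits = rng.random(length) < mutation_rate
        for j in np.flatnonzero(hits):
            seq[j] = AA20[rng.integers(0, 20)]
        rows.append((f"hom{r}", "".join(seq)))
    return MSA(rows)


def synth_binding_site(model: AF2Model, n_site: int, n_decoys: int,
                       seed: int = 0, jitter: float = 0.3,
                       decoy_min_dist: float = 15.0) -> tuple[set[int], list[PocketPrediction]]:
    """Plant a known binding site plus decoy pockets on a model.

    The site core is a spatially contiguous residue set grown from a random
    seed residue by 3D proximity; the "true" pocket places points at the core
    residues' Cα plus jitter, and the known site is defined as the residues
    that pocket maps to (so the planted truth is consistent with the
    pocket→residue contact mapping used downstream).  Decoys are centred on
    residues at least ``decoy_min_dist`` Å from every site residue.
    Returns (site residue indices, pockets); pockets[0] is the true pocket.
    """
    import warnings

    from .pockets import pocket_residues

    if n_site > len(model):
        raise ValueError("n_site exceeds model length")
    rng = np.random.default_rng(seed)
    seed_idx = int(rng.integers(0, len(model)))
    d = np.linalg.norm(model.ca - model.ca[seed_idx], axis=1)
    core = np.sort(np.argsort(d)[:n_site])
    core_ca = model.ca[core]
    true_pocket = PocketPrediction(
        id="true",
        points=core_ca + rng.normal(scale=jitter, size=core_ca.shape),
        score=1.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        site = set(pocket_residues(true_pocket, model))
    pockets = [true_pocket]
    site_ca = model.ca[sorted(site)]
    dist_to_site = np.min(
        np.linalg.norm(model.ca[:, None, :] - site_ca[None, :, :], axis=-1), axis=1
    )
    candidates = np.flatnonzero(dist_to_site >= decoy_min_dist)
    if len(candidates) < n_decoys:
        raise ValueError(
            f"model too small to place {n_decoys} decoys >= {decoy_min_dist} Å "
            "from the site"
        )
    chosen = rng.choice(candidates, size=n_decoys, replace=False)
    for k, c in enumerate(chosen):
        pockets.append(PocketPrediction(
            id=f"decoy{k}",
            points=model.ca[c] + rng.normal(scale=jitter, size=(5, 3)),
            score=float(rng.random() * 0.5),
        ))
    return site, pockets


# --- backbone builder (N, CA, C) from torsions --------------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D given A, B, C."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        -bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def synth_backbone(phi: list[float], psi: list[float], omega: float = 180.0,
                   plddt: float = 90.0, name: str = "backbone") -> AF2Model:
    """Build an all-backbone (N, CA, C) poly-alanine chain from φ/ψ torsions.

    ``phi[0]`` and ``psi[-1]`` are undefined for a chain and ignored.  Useful
    as a geometry oracle: torsions measured on the result reproduce the
    inputs to within numerical precision.
    """
    n = len(phi)
    if len(psi) != n or n < 2:
        raise ValueError("phi and psi must have equal length >= 2")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(_ANG_N_CA_C)
    C = [CA[0] + np.array([-_BOND_CA_C * math.cos(ang), _BOND_CA_C * math.sin(ang), 0.0])]
    for i in range(1, n):
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], _BOND_C_N, _ANG_CA_C_N, psi[i - 1]))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i], _BOND_N_CA, _ANG_C_N_CA, omega))
        C.append(_place_atom(C[i - 1], N[i], CA[i], _BOND_CA_C, _ANG_N_CA_C, phi[i]))
    atoms = [
        [Atom("N", "N", tuple(N[i]), 1.0, plddt),
         Atom("CA", "C", tuple(CA[i]), 1.0, plddt),
         Atom("C", "C", tuple(C[i]), 1.0, plddt)]
        for i in range(n)
    ]
    return AF2Model(
        chain_ids=["A"] * n,
        numbers=np.arange(1, n + 1),
        aa=["A"] * n,
        ca=np.asarray(CA),
        plddt=np.full(n, plddt),
        atoms=atoms,
        name=name,
    )
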