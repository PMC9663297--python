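"""Core domain types for confidence-aware analysis of predicted structures.

The central container is :class:`AF2Model`, a light residue-level view of an
AlphaFold2-style model: one record per residue carrying the chain id, the
author residue number, the one-letter amino-acid code, the Cα coordinate and
the per-residue pLDDT confidence (0–100, stored in the B-factor column of
AlphaFold coordinate files).  Full-atom records are optional and only needed
by the SASA and torsion-restraint operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "AF2Model",
    "PAEMatrix",
    "MSA",
    "DisorderAnnotation",
]


@dataclass(frozen=True)
class Atom:
    """A single atom record attached to a residue."""

    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0


@dataclass
class AF2Model:
    """Residue-level view of a predicted (or experimental) protein model.

    Parameters
    ----------
    chain_ids
        Per-residue chain identifier (length L).
    numbers
        Author residue numbers, strictly increasing within each chain.
    aa
        One-letter amino-acid codes (length L).
    ca
        (L, 3) array of Cα coordinates in Å.
    plddt
        Per-residue confidence in [0, 100].
    atoms
        Optional per-residue atom lists (full-atom models).
    name
        Free-form identifier, used in reports and TSV output.
    """

    chain_ids: list[str]
    numbers: np.ndarray
    aa: list[str]
    ca: np.ndarray
    plddt: np.ndarray
    atoms: list[list[Atom]] | None = None
    name: str = "model"

    def __post_init__(self) -> None:
        self.numbers = np.asarray(self.numbers, dtype=int)
        self.ca = np.asarray(self.ca, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.chain_ids)
        if n < 1:
            raise ValueError("model must contain at least one residue")
        if not (len(self.aa) == n == len(self.numbers) == len(self.plddt)):
            raise ValueError("per-residue arrays have inconsistent lengths")
        if self.ca.shape != (n, 3):
            raise ValueError(f"ca must be ({n}, 3), got {self.ca.shape}")
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValueError("pLDDT values must lie in [0, 100]")
        if self.atoms is not None and len(self.atoms) != n:
            raise ValueError("atoms list length must equal residue count")
        for cid in self.chains:
            nums = self.numbers[self.chain_index(cid)]
            if np.any(np.diff(nums) <= 0):
                raise ValueError(
                    f"residue numbers not strictly increasing in chain {cid!r}"
                )

    def __len__(self) -> int:
        return len(self.chain_ids)

    @property
    def chains(self) -> list[str]:
        """Chain ids in file order."""
        seen: dict[str, None] = {}
        for cid in self.chain_ids:
            seen.setdefault(cid, None)
        return list(seen)

    def chain_index(self, chain_id: str) -> np.ndarray:
        """0-based residue indices belonging to *chain_id* (file order)."""
        return np.flatnonzero(np.asarray(self.chain_ids) == chain_id)

    @property
    def has_atoms(self) -> bool:
        return self.atoms is not None

    def subset(self, indices: Sequence[int] | np.ndarray, name: str | None = None) -> "AF2Model":
        """New model restricted to the given residue indices (kept sorted)."""
        idx = np.sort(np.asarray(indices, dtype=int))
        if idx.size == 0:
            raise ValueError("cannot build an empty model subset")
        return AF2Model(
            chain_ids=[self.chain_ids[i] for i in idx],
            numbers=self.numbers[idx],
            aa=[self.aa[i] for i in idx],
            ca=self.ca[idx],
            plddt=self.plddt[idx],
            atoms=None if self.atoms is None else [self.atoms[i] for i in idx],
            name=name or self.name,
        )

    def with_plddt(self, plddt: np.ndarray) -> "AF2Model":
        return replace(self, plddt=np.asarray(plddt, dtype=float))


@dataclass
class PAEMatrix:
    """Predicted-aligned-error matrix in Å.

    ``values[i, j]`` is the expected positional error of residue *i* when the
    predicted and true structures are superposed on residue *j*; the matrix is
    in general asymmetric.  ``residue_index`` maps rows/columns to the 0-based
    residue indices of an attached :class:`AF2Model` (identity by default).
    """

    values: np.ndarray
    residue_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"PAE matrix must be square, got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("PAE entries must be non-negative")
        if self.residue_index is None:
            self.residue_index = np.arange(self.values.shape[0])
        else:
            self.residue_index = np.asarray(self.residue_index, dtype=int)
            if self.residue_index.shape[0] != self.values.shape[0]:
                raise ValueError("residue_index length must match matrix size")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.values, self.values.T))


@dataclass
class MSA:
    """A rectangular multiple sequence alignment; the first row is the query."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA must contain at least one row")
        w = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != w:
                raise ValueError(f"ragged MSA: row {rid!r} has width {len(seq)} != {w}")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def query(self) -> str:
        return self.rows[0][1]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.rows)


@dataclass
class DisorderAnnotation:
    """Per-residue binary order/disorder labels (1 = disordered)."""

    protein_id: str
    labels: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for num, lab in self.labels.items():
            if lab not in (0, 1):
                raise ValueError(f"label for residue {num} must be 0 or 1, got {lab}")

    def aligned_to(self, model: AF2Model) -> np.ndarray:
        """Label vector aligned to the model's residues (−1 where unannotated)."""
        return np.array([self.labels.get(int(n), -1) for n in model.numbers])

    @classmethod
    def from_array(cls, protein_id: str, model: AF2Model, labels: Sequence[int]) -> "DisorderAnnotation":
        if len(labels) != len(model):
            raise ValueError("label array length must equal model length")
        return cls(protein_id, {int(n): int(l) for n, l in zip(model.numbers, labels)})
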