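"""Homo-oligomer state-scan bookkeeping and MSA construction.

A state scan runs structure prediction for each candidate copy number
(typically 1–4 for monomers/dimers, 1–5 for trimers/tetramers) with several
model parameter sets, and calls the oligomeric state from the per-state pTM
scores.  Robustness is obtained by aggregating with the *worst* score per
state before taking the argmax.  A scan counts as a success when the called
state matches the annotation, or when the state one above the annotated one
scores substantially lower (default margin 0.1) — a local peak at the truth.

For paired-chain (heterodimer) prediction with a single-chain pipeline, the
two chains are merged into one with a large residue-number gap (default 200)
so the predictor treats them as one chain with an implied long linker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MSA

__all__ = [
    "OligomerScan",
    "expand_msa_homooligomer",
    "renumber_heterodimer",
    "predict_state",
    "scan_success",
]


@dataclass
class OligomerScan:
    """Per-copy-number pTM scores, optionally with the annotated true state."""

    scores: dict[int, list[float]]
    annotated_state: int | None = None

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError("scan must contain at least one state")
        for s, vals in self.scores.items():
            if not vals:
                raise ValueError(f"state {s} has no scores")
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"pTM scores for state {s} must lie in [0, 1]")

    @property
    def states(self) -> list[int]:
        return sorted(self.scores)


def expand_msa_homooligomer(msa: MSA, copies: int) -> MSA:
    """Build the N-copy alignment: copy, pad with gaps, concatenate.

    Each input row appears once per block, carrying its aligned sequence in
    that block's columns and gaps everywhere else; a final query row repeats
    the query sequence across every block so the target sequence covers all
    copies.  Output width = copies × input width.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    w = msa.width
    gaps = "-" * w
    rows: list[tuple[str, str]] = []
    for j in range(copies):
        for rid, seq in msa:
            rows.append((f"{rid}_copy{j + 1}", gaps * j + seq + gaps * (copies - 1 - j)))
    rows.append(("query_full", msa.query * copies))
    return MSA(rows)


def renumber_heterodimer(len_a: int, len_b: int, gap: int = 200) -> dict[tuple[str, int], int]:
    """Residue-number mapping merging chains A and B into one long chain.

    Chain A keeps numbers 1..len_a; chain B is shifted to start at
    len_a + gap + 1, leaving a ``gap``-residue hole so the merged numbering
    implies a long break between the chains.  The mapping is invertible.
    """
    if len_a < 1 or len_b < 1:
        raise ValueError("chain lengths must be >= 1")
    if gap < 1:
        raise ValueError("gap must be >= 1")
    mapping = {("A", i): i for i in range(1, len_a + 1)}
    mapping.update({("B", i): len_a + gap + i for i in range(1, len_b + 1)})
    return mapping


def predict_state(scan: OligomerScan, aggregate: str = "min") -> tuple[int, dict[int, float]]:
    """Call the oligomeric state from a scan.

    Per state the model scores are aggregated (default: worst-of-models
    minimum); the predicted state is the aggregate argmax, ties broken
    toward the smaller copy number.
    Returns (predicted state, per-state aggregate table).
    """
    agg_fn = {"min": min, "mean": lambda v: sum(v) / len(v)}.get(aggregate)
    if agg_fn is None:
        raise ValueError(f"unknown aggregate {aggregate!r} (expected 'min' or 'mean')")
    table = {s: float(agg_fn(scan.scores[s])) for s in scan.states}
    best = max(table.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return best, table


def scan_success(scan: OligomerScan, margin: float = 0.1, aggregate: str = "min") -> bool:
    """Success rule for a state scan against its annotation.

    True when the scan's peak matches the annotated state, or when the next
    oligomer state (annotated + 1) scores at least ``margin`` below the
    annotated state's aggregate — the annotated state is then still a clear
    local peak even if not the global one.
    """
    if scan.annotated_state is None:
        raise ValueError("scan has no annotated state")
    if scan.annotated_state not in scan.scores:
        raise ValueError("annotated state is not among the scanned states")
    predicted, table = predict_state(scan, aggregate=aggregate)
    if predicted == scan.annotated_state:
        return True
    nxt = scan.annotated_state + 1
    return nxt in table and table[scan.annotated_state] - table[nxt] >= margin
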