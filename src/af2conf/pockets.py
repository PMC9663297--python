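"""Pocket-to-residue mapping, pocket confidence and overlap metrics.

Pocket *detection* is delegated to external tools (AutoSite-style point
clouds are consumed, not produced).  This module maps a predicted pocket's
points to the residues they contact, scores the pocket's reliability by the
mean pLDDT of those residues (high quality iff mean > 90), computes
residue-level F-score and Matthews correlation against a known site, and
applies the enzyme-candidate filter (mean pLDDT ≥ 70, 100–500 residues,
ranked by top pocket score).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .model import AF2Model

__all__ = [
    "PocketPrediction",
    "read_pockets",
    "pocket_residues",
    "pocket_confidence",
    "overlap_metrics",
    "enzyme_candidate_filter",
]


@dataclass
class PocketPrediction:
    """A predicted pocket as a point cloud with a detector ranking score."""

    id: str
    points: np.ndarray
    score: float = 0.0
    residues: set[int] | None = None   # filled by pocket_residues
    mean_plddt: float | None = None    # filled by pocket_confidence

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ValueError("pocket needs >= 1 three-dimensional point")


def read_pockets(path: str | Path) -> list[PocketPrediction]:
    """Read pocket point clouds from an AutoSite-style PDB file (fill points
    as pseudo-atoms, one pocket per file) or a TSV with columns
    pocket_id, x, y, z, score."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".pdb", ".pdbqt"}:
        pts = []
        for line in text.splitlines():
            if line.startswith(("ATOM", "HETATM")):
                pts.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        if not pts:
            raise ValueError(f"{path}: no fill points found")
        return [PocketPrediction(id=path.stem, points=np.asarray(pts))]
    groups: dict[str, list[list[float]]] = {}
    scores: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("pocket_id"):
            continue
        pid, x, y, z, *rest = line.split("\t")
        groups.setdefault(pid, []).append([float(x), float(y), float(z)])
        if rest:
            scores[pid] = float(rest[0])
    if not groups:
        raise ValueError(f"{path}: no pocket points found")
    return [PocketPrediction(id=pid, points=np.asarray(pts), score=scores.get(pid, 0.0))
            for pid, pts in groups.items()]


def pocket_residues(pocket: PocketPrediction, model: AF2Model,
                    contact_cutoff: float = 4.5) -> set[int]:
    """Residues (0-based indices) with any atom within ``contact_cutoff`` Å of
    any pocket point.  Cα-only models fall back to an enlarged 8 Å cutoff
    (flagged with a warning) since side-chain atoms are absent."""
    if pocket.points.shape[0] < 1:
        raise ValueError("empty pocket")
    if model.has_atoms:
        coords = []
        owner = []
        for i, rec in enumerate(model.atoms):
            for a in rec:
                coords.append(a.coord)
                owner.append(i)
        coords = np.asarray(coords)
        owner = np.asarray(owner)
        cutoff = contact_cutoff
    else:
        warnings.warn("Cα-only model: using enlarged 8 Å pocket contact cutoff")
        coords = model.ca
        owner = np.arange(len(model))
        cutoff = max(contact_cutoff, 8.0)
    tree = cKDTree(coords)
    hit = tree.query_ball_point(pocket.points, r=cutoff)
    res = {int(owner[j]) for lst in hit for j in lst}
    pocket.residues = res
    return res


def pocket_confidence(pocket: PocketPrediction, model: AF2Model) -> tuple[float, str]:
    """Mean pLDDT over pocket-associated residues; quality is 'high' iff the
    mean is strictly above 90, else 'low'."""
    if pocket.residues is None:
        pocket_residues(pocket, model)
    if not pocket.residues:
        raise ValueError(f"pocket {pocket.id!r} has no associated residues")
    mean = float(np.mean(model.plddt[sorted(pocket.residues)]))
    pocket.mean_plddt = mean
    return mean, ("high" if mean > 90.0 else "low")


def overlap_metrics(predicted: set[int], known: set[int], n_total: int) -> tuple[float, float]:
    """Residue-level F-score and Matthews correlation coefficient.

    TP/FP/FN/TN are counted over ``n_total`` residues; a zero denominator
    makes the corresponding metric 0.
    """
    union = predicted | known
    if n_total < len(union):
        raise ValueError("n_total smaller than |predicted ∪ known|")
    tp = len(predicted & known)
    fp = len(predicted - known)
    fn = len(known - predicted)
    tn = n_total - len(union)
    f = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return float(f), float(mcc)


def enzyme_candidate_filter(models: list[AF2Model], pocket_scores: list[float],
                            min_plddt: float = 70.0,
                            min_len: int = 100, max_len: int = 500,
                            min_pocket_plddt: float | None = None,
                            pocket_plddts: list[float] | None = None,
                            ) -> list[tuple[int, AF2Model, float]]:
    """Rank enzyme-candidate models by top pocket score.

    Keeps models with mean pLDDT ≥ ``min_plddt`` and length within
    [min_len, max_len], ranked descending by their top pocket score.  When
    ``min_pocket_plddt`` and per-model pocket mean-pLDDT values are given,
    models whose top pocket is low-confidence are additionally dropped.
    Returns (original index, model, score) triples.
    """
    if len(pocket_scores) != len(models):
        raise ValueError("need one top-pocket score per model")
    kept = []
    for i, (m, s) in enumerate(zip(models, pocket_scores)):
        if not (min_len <= len(m) <= max_len):
            continue
        if float(np.mean(m.plddt)) < min_plddt:
            continue
        if min_pocket_plddt is not None and pocket_plddts is not None:
            if pocket_plddts[i] < min_pocket_plddt:
                continue
        kept.append((i, m, float(s)))
    kept.sort(key=lambda t: -t[2])
    return kept
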