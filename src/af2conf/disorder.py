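"""Per-residue disorder inference from predicted-structure metrics.

Residues in intrinsically disordered regions tend to receive low pLDDT and
high solvent exposure in predicted models.  Four per-residue scores are
provided, all oriented so that higher means more disordered: ``plddt``
(1 − pLDDT/100), ``rsa`` (relative solvent-accessible surface area), and
their 20-residue moving-average variants ``plddt_20`` / ``rsa_20``.
Evaluation against binary order/disorder annotations uses per-residue ROC
curves and the rank-statistic AUC.

Relative SASA divides each residue's absolute SASA by its maximum exposure
in an extended Gly-Gly-X-Gly-Gly context, so values near 1 mean fully
exposed (slight excess over 1 is possible for unusual conformations).
"""

from __future__ import annotations

import warnings

import numpy as np

from .model import AF2Model

__all__ = [
    "MAX_SASA",
    "relative_sasa",
    "window_smooth",
    "disorder_score",
    "roc_auc",
]

# Maximum solvent exposure (Å²) of residue X in an extended Gly-X-Gly context
# (theoretical values of Tien et al. 2013); used to normalize absolute SASA.
MAX_SASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

_PROBE = 1.4        # Å, water probe
_N_POINTS = 960     # sphere points for the Shrake–Rupley calculation
_CA_RADIUS = 3.0    # Å, coarse whole-residue sphere for Cα-only models


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _ca_sphere_exposure(model: AF2Model) -> np.ndarray:
    """Coarse per-residue exposure for Cα-only models: the fraction of a
    residue-sized probe-extended sphere not occluded by neighboring residue
    spheres.  Normalized so an isolated residue scores exactly 1."""
    from scipy.spatial import cKDTree

    pts = _fibonacci_sphere(_N_POINTS)
    r_ext = _CA_RADIUS + _PROBE
    ca = model.ca
    n = len(model)
    tree = cKDTree(ca)
    exposure = np.empty(n)
    for i in range(n):
        nbrs = [j for j in tree.query_ball_point(ca[i], 2 * r_ext) if j != i]
        if not nbrs:
            exposure[i] = 1.0
            continue
        surface = ca[i] + r_ext * pts
        d = np.linalg.norm(surface[:, None, :] - ca[nbrs][None, :, :], axis=-1)
        exposure[i] = np.mean(np.all(d >= r_ext, axis=1))
    return exposure


def relative_sasa(model: AF2Model) -> np.ndarray:
    """Per-residue relative SASA.

    Full-atom models: Shrake–Rupley SASA (1.4 Å probe, 960 sphere points)
    summed per residue, divided by the residue type's maximum exposure
    (``MAX_SASA``).  Cα-only models fall back to a coarse sphere-exposure
    estimate (flagged with a warning): the unoccluded fraction of a
    residue-sized sphere, already normalized to [0, 1].
    """
    if not model.has_atoms:
        warnings.warn("Cα-only model: using coarse sphere-exposure SASA fallback")
        return _ca_sphere_exposure(model)
    import biotite.structure as struc

    n_atoms = sum(len(rec) for rec in model.atoms)
    arr = struc.AtomArray(n_atoms)
    k = 0
    for i, rec in enumerate(model.atoms):
        for a in rec:
            arr.coord[k] = a.coord
            arr.atom_name[k] = a.name
            arr.element[k] = a.element.upper()
            arr.res_id[k] = int(model.numbers[i])
            arr.res_name[k] = "UNK"
            arr.chain_id[k] = model.chain_ids[i]
            k += 1
    per_atom = struc.sasa(arr, probe_radius=_PROBE, point_number=_N_POINTS,
                          vdw_radii="Single")
    rsa = np.empty(len(model))
    k = 0
    for i, rec in enumerate(model.atoms):
        abs_sasa = float(np.nansum(per_atom[k:k + len(rec)]))
        k += len(rec)
        aa = model.aa[i]
        if aa not in MAX_SASA:
            warnings.warn(f"unknown residue type {aa!r}: using alanine max-SASA")
            aa = "A"
        rsa[i] = abs_sasa / MAX_SASA[aa]
    return rsa


def window_smooth(values, window: int = 20) -> np.ndarray:
    """Centered moving average with symmetric shrinkage at the termini.

    At position i the averaging radius is min(window // 2, i, n−1−i), so the
    window stays centered and shrinks symmetrically at the chain ends;
    window = 1 is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    n = values.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        r = min(half, i, n - 1 - i)
        out[i] = values[i - r:i + r + 1].mean()
    return out


def disorder_score(model: AF2Model, metric: str = "plddt_20",
                   window: int = 20) -> np.ndarray:
    """Per-residue disorder score for one of the four metrics.

    ``plddt``: 1 − pLDDT/100; ``rsa``: relative SASA; the ``_20`` variants
    apply a 20-residue moving average per chain before orientation.  Higher
    always means more disordered.
    """
    options = {"plddt", "plddt_20", "rsa", "rsa_20"}
    if metric not in options:
        raise ValueError(f"unknown metric {metric!r}; options: {sorted(options)}")
    base = model.plddt / 100.0 if metric.startswith("plddt") else relative_sasa(model)
    if metric.endswith("_20"):
        smoothed = base.copy()
        for cid in model.chains:
            idx = model.chain_index(cid)
            smoothed[idx] = window_smooth(base[idx], window=window)
        base = smoothed
    return 1.0 - base if metric.startswith("plddt") else base


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-residue ROC curve and AUC (rank statistic; ties count ½).

    ``labels`` are binary (1 = disordered = positive class); ``scores`` are
    oriented so higher means more disordered.  Requires both classes.
    """
    from sklearn.metrics import roc_auc_score, roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain at least one positive and one negative")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(roc_auc_score(labels, scores))
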