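"""Readers and writers for model coordinates, PAE matrices and alignments.

AlphaFold-style coordinate files store the per-residue pLDDT confidence in
the B-factor column; the reader takes it from each residue's Cα atom.  PAE
matrices are accepted in both public AlphaFold-DB JSON dialects and
normalized to a single :class:`~af2conf.model.PAEMatrix` type.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import gemmi
import numpy as np

from .model import AF2Model, Atom, MSA, PAEMatrix

logger = logging.getLogger(__name__)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def read_model(path: str | Path, format: str = "auto") -> AF2Model:
    """Read a PDB or mmCIF model into an :class:`AF2Model`.

    pLDDT is taken from the Cα B-factor of each residue.  Residues without a
    Cα atom are skipped with a warning.  B-factors outside [0, 100] are
    accepted but flagged (the file may be a real experimental structure whose
    B column holds thermal factors, not confidences).
    """
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r} (expected pdb, mmcif or auto)")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {format}: {exc}") from exc

    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    if len(st) > 1:
        warnings.warn(f"{path}: multi-model file, using first model only")
    st.setup_entities()
    model = st[0]

    chain_ids: list[str] = []
    numbers: list[int] = []
    aa: list[str] = []
    ca: list[list[float]] = []
    plddt: list[float] = []
    atoms: list[list[Atom]] = []
    flagged = False
    for chain in model:
        for res in chain:
            ca_atom = None
            res_atoms: list[Atom] = []
            seen_names: set[str] = set()
            for at in res:
                if at.name in seen_names:  # keep first altloc only
                    continue
                seen_names.add(at.name)
                res_atoms.append(
                    Atom(at.name, at.element.name,
                         (at.pos.x, at.pos.y, at.pos.z), at.occ, at.b_iso)
                )
                if at.name == "CA" and at.element.name != "Ca" and ca_atom is None:
                    ca_atom = at
            if ca_atom is None:
                logger.warning("%s: residue %s %s/%d has no CA atom, skipped",
                               path.name, res.name, chain.name, res.seqid.num)
                continue
            b = float(ca_atom.b_iso)
            if not 0.0 <= b <= 100.0:
                flagged = True
            chain_ids.append(chain.name)
            numbers.append(res.seqid.num)
            aa.append(_THREE_TO_ONE.get(res.name, "X"))
            ca.append([ca_atom.pos.x, ca_atom.pos.y, ca_atom.pos.z])
            plddt.append(min(max(b, 0.0), 100.0))
            atoms.append(res_atoms)
    if not chain_ids:
        raise ValueError(f"{path}: no residues with CA atoms")
    if flagged:
        warnings.warn(
            f"{path.name}: B-factors outside [0, 100] — file may be an "
            "experimental structure, not an AlphaFold confidence-tagged model"
        )
    return AF2Model(chain_ids, np.array(numbers), aa, np.array(ca),
                    np.array(plddt), atoms=atoms, name=path.stem)


def write_model(model: AF2Model, path: str | Path, format: str = "pdb",
                b_override: float | None = None) -> Path:
    """Write a model as a standard PDB file.

    With ``b_override`` every atom's B column is replaced by a constant —
    the convention used when preparing molecular-replacement search models,
    where a flat B of 50 replaces the confidence values.
    """
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    path = Path(path)
    if np.any(model.numbers > 9999):
        raise ValueError(
            "residue number exceeds 9999: PDB cannot represent it; "
            "renumber the chain (mmCIF output is not supported)"
        )
    st = gemmi.Structure()
    st.name = model.name
    md = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for i in range(len(model)):
        cid = model.chain_ids[i]
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(model.aa[i], "UNK")
        res.seqid = gemmi.SeqId(int(model.numbers[i]), " ")
        rec = model.atoms[i] if model.atoms is not None else None
        if rec is None:
            rec = [Atom("CA", "C", tuple(model.ca[i]), 1.0, float(model.plddt[i]))]
        for a in rec:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coord)
            at.occ = a.occupancy
            at.b_iso = b_override if b_override is not None else a.b_factor
            res.add_atom(at)
        chain_map[cid].add_residue(res)
    for chain in chain_map.values():
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))
    return path


def read_pae(path: str | Path) -> PAEMatrix:
    """Read an AlphaFold-DB-style PAE JSON file (either public dialect).

    The nested dialect stores the full ``predicted_aligned_error`` matrix;
    the flat dialect lists ``residue1``/``residue2``/``distance`` triples
    (1-based indices).  Both are normalized to the same L×L matrix in Å.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):
        if not data:
            raise ValueError(f"{path}: empty PAE JSON")
        data = data[0]
    if "predicted_aligned_error" in data:
        mat = np.asarray(data["predicted_aligned_error"], dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError(f"{path}: predicted_aligned_error is not square: {mat.shape}")
    elif {"residue1", "residue2", "distance"} <= set(data):
        r1 = np.asarray(data["residue1"], dtype=int)
        r2 = np.asarray(data["residue2"], dtype=int)
        d = np.asarray(data["distance"], dtype=float)
        if not (len(r1) == len(r2) == len(d)):
            raise ValueError(f"{path}: residue1/residue2/distance lengths differ")
        n = int(max(r1.max(), r2.max()))
        mat = np.full((n, n), np.nan)
        mat[r1 - 1, r2 - 1] = d
        if np.isnan(mat).any():
            missing = np.argwhere(np.isnan(mat))[:10] + 1
            raise ValueError(
                f"{path}: incomplete PAE matrix, missing pairs (1-based) "
                f"{[tuple(p) for p in missing]}"
            )
    else:
        raise ValueError(
            f"{path}: unrecognized PAE JSON dialect "
            "(expected 'predicted_aligned_error' or 'residue1/residue2/distance')"
        )
    if np.any(mat < 0):
        raise ValueError(f"{path}: negative PAE entries")
    return PAEMatrix(mat)


def write_pae(pae: PAEMatrix, path: str | Path) -> Path:
    """Write a PAE matrix in the nested AlphaFold-DB JSON dialect."""
    path = Path(path)
    payload = {
        "predicted_aligned_error": [[float(v) for v in row] for row in pae.values],
        "max_predicted_aligned_error": float(pae.values.max()),
    }
    path.write_text(json.dumps(payload))
    return path


def read_msa(path: str | Path, format: str = "auto") -> MSA:
    """Read an A3M or aligned-FASTA file into an :class:`MSA` (query first).

    In A3M, lowercase letters are insertion states relative to the query and
    are removed to obtain the rectangular query-aligned form.
    """
    path = Path(path)
    if format == "auto":
        format = "a3m" if path.suffix.lower() == ".a3m" else "fasta"
    text = path.read_text()
    rows: list[tuple[str, str]] = []
    rid: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if rid is not None:
                rows.append((rid, "".join(chunks)))
            rid = line[1:].split()[0] or f"seq{len(rows)}"
            chunks = []
        elif rid is not None:
            chunks.append(line)
    if rid is not None:
        rows.append((rid, "".join(chunks)))
    if not rows:
        raise ValueError(f"{path}: empty alignment file")
    if format == "a3m":
        rows = [(rid, "".join(c for c in seq if not c.islower())) for rid, seq in rows]
    width = len(rows[0][1])
    for rid, seq in rows:
        if len(seq) != width:
            raise ValueError(
                f"{path}: row {rid!r} has width {len(seq)} != {width} "
                "after a3m normalization"
            )
    return MSA(rows)


def write_msa(msa: MSA, path: str | Path) -> Path:
    """Write an MSA as aligned FASTA (also valid A3M)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in msa:
            fh.write(f">{rid}\n{seq}\n")
    return path
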