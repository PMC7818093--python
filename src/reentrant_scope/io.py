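"""Readers and writers for the external formats the pipeline touches.

All readers normalise residue indices to 1-based on read and raise
:class:`~reentrant_scope.types.FormatError` on malformed input.  Writers
are exact inverses where a round trip is meaningful (contact maps round
trip with scores preserved to 6 decimals).
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1
from lxml import etree

from .types import (
    Contact,
    ContactMap,
    FormatError,
    Region,
    RegionAnnotation,
    ResidueRecord,
    Sequence,
    SSProfile,
    StructureModel,
    TopologyProfile,
)

PathLike = Union[str, Path]

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_casp_rr",
    "write_casp_rr",
    "read_ss2",
    "write_ss2",
    "read_topcons",
    "write_topcons",
    "read_pdb_model",
    "write_pdb_model",
    "read_pdbtm_regions",
    "read_z_matrix",
    "write_report_json",
    "write_report_csv",
    "PDBTM_CODE_MAP",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> list[Sequence]:
    """Read all records of a FASTA file, order preserved."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return [Sequence(rec.id, str(rec.seq).upper()) for rec in records]


def write_fasta(path: PathLike, sequences: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for k in range(0, seq.L, 60):
                fh.write(seq.residues[k : k + 60] + "\n")


# ---------------------------------------------------------------------------
# CASP RR contact lists

def read_casp_rr(path: PathLike, L: int) -> ContactMap:
    """Read a CASP-RR contact list (lines ``i j d1 d2 score``).

    The distance columns are read but ignored; only ``(i, j, score)`` is
    retained.  Pairs are canonicalised to ``i < j`` and duplicates keep
    the maximum score.  Header lines (``PFRMAT``, ``TARGET``, ``MODEL``,
    a bare sequence line, ``END``) are skipped.
    """
    if L < 1:
        raise FormatError(f"chain length must be positive, got {L}")
    contacts: list[Contact] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.split()[0] in {"PFRMAT", "TARGET", "AUTHOR",
                                               "METHOD", "MODEL", "REMARK", "END"}:
                continue
            parts = line.split()
            if len(parts) < 5:
                if parts[0].isalpha():  # bare sequence line in full RR dialect
                    continue
                raise FormatError(f"{path}:{lineno}: expected 'i j d1 d2 score'")
            try:
                i, j = int(parts[0]), int(parts[1])
                score = float(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not (1 <= i <= L and 1 <= j <= L):
                raise FormatError(
                    f"{path}:{lineno}: residue index outside [1, {L}]"
                )
            if not (0.0 <= score <= 1.0):
                raise FormatError(f"{path}:{lineno}: score {score} outside [0, 1]")
            contacts.append(Contact(i, j, score))
    return ContactMap(L, contacts)


def write_casp_rr(path: PathLike, cmap: ContactMap,
                  sequence: Optional[Sequence] = None) -> None:
    """Write a contact map as a minimal CASP-RR file (scores to 6 decimals)."""
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        if sequence is not None:
            fh.write(sequence.residues + "\n")
        for c in sorted(cmap.contacts, key=lambda c: (-c.score, c.i, c.j)):
            fh.write(f"{c.i} {c.j} 0 8 {c.score:.6f}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# PSIPRED ss2 (vertical format)

_SS2_ORDER = "CHE"  # ss2 column order: coil, helix, strand


def read_ss2(path: PathLike) -> SSProfile:
    """Read a PSIPRED ss2 (VFORMAT) file into an :class:`SSProfile`.

    ss2 lists per residue: index, amino acid, state, then P(coil),
    P(helix), P(strand).  Confidences are re-ordered to the package's
    (H, E, C) convention.
    """
    states: list[str] = []
    conf: list[tuple[float, float, float]] = []
    expected = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 ss2 columns")
            try:
                idx = int(parts[0])
                pc, ph, pe = (float(x) for x in parts[3:6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if idx != expected:
                raise FormatError(
                    f"{path}:{lineno}: residue index {idx}, expected {expected}"
                )
            expected += 1
            states.append(parts[2])
            conf.append((ph, pe, pc))
    if not states:
        raise FormatError(f"{path}: empty ss2 file")
    return SSProfile("".join(states), np.array(conf))


def write_ss2(path: PathLike, ss: SSProfile, sequence: Sequence) -> None:
    if sequence.L != ss.L:
        raise FormatError("sequence and secondary-structure lengths differ")
    conf = ss.confidences
    if conf is None:
        onehot = {"H": (1.0, 0.0, 0.0), "E": (0.0, 1.0, 0.0), "C": (0.0, 0.0, 1.0)}
        conf = np.array([onehot[s] for s in ss.states])
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT\n\n")
        for k, (aa, state) in enumerate(zip(sequence.residues, ss.states)):
            ph, pe, pc = conf[k]
            fh.write(f"{k + 1:4d} {aa} {state}  {pc:6.3f} {ph:6.3f} {pe:6.3f}\n")


# ---------------------------------------------------------------------------
# TOPCONS-style topology strings

def read_topcons(path: PathLike) -> TopologyProfile:
    """Read a per-residue topology string (characters in ``{i, o, M, S}``).

    Accepts a bare string split over lines, optionally preceded by ``#``
    comments or a single FASTA-style ``>`` header (the layout of a saved
    TOPCONS per-method block).
    """
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith(">"):
                continue
            chunks.append(line)
    if not chunks:
        raise FormatError(f"{path}: no topology string found")
    return TopologyProfile("".join(chunks))


def write_topcons(path: PathLike, topo: TopologyProfile,
                  header: str = "topology") -> None:
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for k in range(0, topo.L, 60):
            fh.write(topo.labels[k : k + 60] + "\n")


# ---------------------------------------------------------------------------
# PDB coordinate models (ATOM records only)

def read_pdb_model(path: PathLike, chain: Optional[str] = None) -> StructureModel:
    """Read Cα/Cβ coordinates of one chain from a PDB file.

    Only the first model is considered.  ``chain`` selects a chain id;
    by default the first chain is used.  Residues lacking a Cα are
    skipped with a warning.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no models in PDB file")
    model = st[0]
    if chain is None:
        gchain = model[0]
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise FormatError(f"{path}: chain {chain!r} not found")
    residues: list[ResidueRecord] = []
    for res in gchain:
        ca = res.find_atom("CA", "*")
        if ca is None:
            warnings.warn(f"{path}: residue {res.seqid.num} has no CA; skipped")
            continue
        cb = res.find_atom("CB", "*")
        aa = protein_letters_3to1.get(res.name.capitalize(), "X")
        residues.append(
            ResidueRecord(
                index=res.seqid.num,
                aa=aa,
                ca=(ca.pos.x, ca.pos.y, ca.pos.z),
                cb=(cb.pos.x, cb.pos.y, cb.pos.z) if cb is not None else None,
            )
        )
    if not residues:
        raise FormatError(f"{path}: no usable residues")
    return StructureModel(residues, id=str(path))


def write_pdb_model(path: PathLike, model: StructureModel,
                    chain: str = "A") -> None:
    """Write a reduced (Cα/Cβ) model as a single-chain PDB file."""
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")
    gchain = gemmi.Chain(chain)
    for r in model.residues:
        res = gemmi.Residue()
        res.name = protein_letters_1to3.get(r.aa, "Unk").upper()
        res.seqid = gemmi.SeqId(r.index, " ")
        for name, element, pos in (("CA", "C", r.ca), ("CB", "C", r.cb)):
            if pos is None:
                continue
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        gchain.add_residue(res)
    gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# PDBTM-style XML region annotations

#: Default mapping from PDBTM region type codes to the package vocabulary.
#: The code used for membrane re-entrant loops is configurable because the
#: XML dialect's choice is not fixed across database versions.
PDBTM_CODE_MAP: dict[str, str] = {
    "H": "tm_helix",
    "L": "reentrant",
    "1": "side1",
    "2": "side2",
    "F": "interfacial",
}


def read_pdbtm_regions(path: PathLike,
                       code_map: Optional[Mapping[str, str]] = None,
                       ) -> list[RegionAnnotation]:
    """Read PDBTM-style XML region annotations, one entry per chain.

    Only the region list and chain ids are parsed; coordinates come from
    the companion PDB file.  Region type codes are mapped through
    ``code_map`` (default :data:`PDBTM_CODE_MAP`); unknown codes are
    preserved verbatim with a warning.
    """
    mapping = dict(PDBTM_CODE_MAP if code_map is None else code_map)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()

    def _local(tag: str) -> str:
        return etree.QName(tag).localname if "}" in tag else tag

    annotations: list[RegionAnnotation] = []
    for chain_el in root.iter():
        if _local(chain_el.tag) != "CHAIN":
            continue
        chain_id = chain_el.get("CHAINID") or chain_el.get("chainid") or "?"
        regions: list[Region] = []
        for reg_el in chain_el:
            if _local(reg_el.tag) != "REGION":
                continue
            try:
                start = int(reg_el.get("seq_beg"))
                end = int(reg_el.get("seq_end"))
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: chain {chain_id}: REGION lacks integer "
                    f"seq_beg/seq_end"
                ) from exc
            code = reg_el.get("type") or "?"
            if code not in mapping:
                warnings.warn(
                    f"{path}: chain {chain_id}: unknown region code {code!r} "
                    f"preserved verbatim"
                )
            regions.append(Region(start, end, mapping.get(code, code)))
        annotations.append(RegionAnnotation(chain_id, regions))
    if not annotations:
        raise FormatError(f"{path}: no CHAIN elements found")
    return annotations


# ---------------------------------------------------------------------------
# Z-score matrices and result reports

def read_z_matrix(path: PathLike) -> tuple[list[str], np.ndarray]:
    """Read a square labelled Z-score matrix from CSV (ids in header + col 0)."""
    df = pd.read_csv(path, index_col=0)
    ids = [str(x) for x in df.index]
    if ids != [str(c) for c in df.columns]:
        raise FormatError(f"{path}: row and column labels differ")
    return ids, df.to_numpy(dtype=float)


def write_report_json(path: PathLike, report: Mapping) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (frozenset, set)):
            return sorted(obj)
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def write_report_csv(path: PathLike, rows: Iterable[Mapping],
                     fieldnames: Optional[list[str]] = None) -> None:
    rows = list(rows)
    if fieldnames is None:
        fieldnames = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
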