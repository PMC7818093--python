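"""Re-entrant-loop segment library: extraction, redundancy removal, clustering.

A library entry is a re-entrant loop as annotated in a PDBTM-style
region file, extended by the 30 residues preceding it (the adjacent TM
helix that packs against the loop).  Redundancy is removed greedily at a
40% global-alignment sequence-identity threshold, and entries are
grouped from a supplied all-against-all structural-similarity Z-score
matrix by connected components at a fixed cut-off (default Z >= 4.5).
The structural aligner itself is out of scope; this module consumes its
Z matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence as TSequence

import networkx as nx
import numpy as np
from Bio import Align

from .types import (
    InputError,
    ParameterError,
    RegionAnnotation,
    ResidueRecord,
    Sequence,
    StructureModel,
)

__all__ = [
    "LibraryEntry",
    "extract_entries",
    "sequence_identity",
    "nonredundant",
    "SimilarityGraph",
    "cluster",
]

PAD = 30              # residues preceding the loop included in each entry
ID_THRESHOLD = 0.40   # redundancy-removal identity threshold
Z_CUT = 4.5           # structural-similarity clustering threshold


@dataclass
class LibraryEntry:
    """One library segment: a re-entrant loop plus its preceding residues."""

    source_id: str
    loop: tuple[int, int]
    extended: tuple[int, int]
    sequence: str
    coords: Optional[StructureModel] = None
    complete: bool = True   # False when coordinates are missing in the interval

    @property
    def id(self) -> str:
        return f"{self.source_id}:{self.extended[0]}-{self.extended[1]}"


def extract_entries(annotations: Iterable[RegionAnnotation],
                    models: Mapping[str, StructureModel],
                    pad: int = PAD,
                    region_code: str = "reentrant") -> list[LibraryEntry]:
    """One entry per annotated re-entrant region, with the preceding pad.

    The extended interval ``[loop_start - pad, loop_end]`` is clipped at
    residue 1.  Entries whose extended interval lacks coordinates in the
    model are flagged ``complete=False`` rather than dropped.  An
    annotation naming a chain absent from ``models`` is an error.
    """
    entries: list[LibraryEntry] = []
    for ann in annotations:
        if ann.chain not in models:
            raise InputError(f"no coordinates supplied for chain {ann.chain!r}")
        model = models[ann.chain]
        by_index = {r.index: r for r in model.residues}
        for region in ann.of_code(region_code):
            start = max(1, region.start - pad)
            end = region.end
            residues = [by_index[k] for k in range(start, end + 1)
                        if k in by_index]
            complete = len(residues) == end - start + 1
            seq = "".join(r.aa for r in residues)
            entries.append(
                LibraryEntry(
                    source_id=ann.chain,
                    loop=(region.start, region.end),
                    extended=(start, end),
                    sequence=seq,
                    coords=StructureModel(residues, id=ann.chain)
                    if residues else None,
                    complete=complete,
                )
            )
    return entries


def _aligner() -> Align.PairwiseAligner:
    # Identity-oriented global alignment; gap costs are documented constants.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    return aligner


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matched positions / alignment length."""
    if not a or not b:
        return 0.0
    alignment = _aligner().align(a, b)[0]
    counts = alignment.counts()
    length = alignment.length
    return counts.identities / length if length else 0.0


def nonredundant(entries: TSequence[LibraryEntry],
                 id_threshold: float = ID_THRESHOLD) -> list[LibraryEntry]:
    """Greedy redundancy removal in input order.

    An entry is kept iff its identity to every already-kept entry is
    below the threshold.  Order-dependent by design; deterministic for a
    fixed input order.
    """
    if not entries:
        raise ParameterError("no entries to filter")
    kept: list[LibraryEntry] = []
    for entry in entries:
        if all(sequence_identity(entry.sequence, k.sequence) < id_threshold
               for k in kept):
            kept.append(entry)
    return kept


@dataclass
class SimilarityGraph:
    """Entries under a thresholded structural-similarity graph."""

    ids: list[str]
    z: np.ndarray
    z_cut: float
    components: list[list[str]] = field(default_factory=list)

    def membership(self) -> dict[str, int]:
        return {eid: k for k, comp in enumerate(self.components) for eid in comp}


def cluster(ids: TSequence[str], z: np.ndarray,
            z_cut: float = Z_CUT, atol: float = 1e-6) -> SimilarityGraph:
    """Connected components of the graph with edges Z >= z_cut.

    The diagonal is ignored; the matrix must be symmetric within
    ``atol``.  Components are reported largest first (ties by smallest
    member id); singletons are allowed.  Raising ``z_cut`` only ever
    splits components, never merges them.
    """
    z = np.asarray(z, dtype=float)
    n = len(ids)
    if z.shape != (n, n):
        raise InputError(f"Z matrix shape {z.shape} does not match {n} ids")
    if not np.allclose(z, z.T, atol=atol):
        raise InputError(f"Z matrix asymmetric beyond {atol}")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for a in range(n):
        for b in range(a + 1, n):
            if z[a, b] >= z_cut:
                graph.add_edge(ids[a], ids[b])
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return SimilarityGraph(ids=list(ids), z=z, z_cut=z_cut, components=comps)
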