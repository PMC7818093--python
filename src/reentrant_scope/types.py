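"""Shared domain types for contact-map analysis of helical membrane proteins.

Conventions used throughout the package:

* residue indices are 1-based;
* intervals are closed, ``[start, end]`` inclusive on both ends;
* a contact is an unordered residue pair stored canonically as ``i < j``
  with a confidence score in ``[0, 1]``.

These match the conventions of the upstream prediction servers whose output
files the package consumes (contact predictors emitting CASP-RR lists,
TOPCONS topology strings, PSIPRED ss2 profiles, PDB coordinate models).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence as TSequence

import numpy as np

__all__ = [
    "FormatError",
    "ParameterError",
    "InputError",
    "AMINO_ACIDS",
    "Sequence",
    "Contact",
    "ContactMap",
    "TopologyProfile",
    "SSProfile",
    "ResidueRecord",
    "StructureModel",
    "Region",
    "RegionAnnotation",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Codes accepted in sequences: the 20 standard residues plus the unknown code X.
VALID_RESIDUES = AMINO_ACIDS | frozenset("X")


class FormatError(ValueError):
    """An input file does not conform to its declared format."""


class ParameterError(ValueError):
    """A caller-supplied parameter is outside its admissible range."""


class InputError(ValueError):
    """Inputs are individually well-formed but mutually inconsistent."""


@dataclass(frozen=True)
class Sequence:
    """A protein chain: an identifier and a string of one-letter codes."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = sorted(set(self.residues) - VALID_RESIDUES)
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid residue character(s) {''.join(bad)!r}"
            )
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")

    @property
    def L(self) -> int:
        """Chain length (number of residues)."""
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


class Contact(NamedTuple):
    """A scored residue-pair prediction, canonically ordered ``i < j``."""

    i: int
    j: int
    score: float


@dataclass
class ContactMap:
    """Scored residue-pair predictions over a chain of length ``L``.

    Invariants enforced on construction: ``1 <= i < j <= L`` for every
    entry, pairs unique, scores in ``[0, 1]``.  Input pairs given as
    ``(j, i)`` are canonicalised; duplicate pairs keep the maximum score.
    """

    L: int
    contacts: list[Contact] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ParameterError(f"chain length must be positive, got {self.L}")
        best: dict[tuple[int, int], float] = {}
        for c in self.contacts:
            i, j, score = int(c[0]), int(c[1]), float(c[2])
            if i > j:
                i, j = j, i
            if i == j:
                raise FormatError(f"self-contact ({i},{j}) is not allowed")
            if not (1 <= i and j <= self.L):
                raise FormatError(
                    f"contact ({i},{j}) outside residue range [1, {self.L}]"
                )
            if not (0.0 <= score <= 1.0):
                raise FormatError(f"contact ({i},{j}): score {score} outside [0, 1]")
            key = (i, j)
            if key not in best or score > best[key]:
                best[key] = score
        self.contacts = [Contact(i, j, s) for (i, j), s in sorted(best.items())]

    def __len__(self) -> int:
        return len(self.contacts)

    def pair_set(self) -> frozenset[tuple[int, int]]:
        """The unordered contact pairs, scores discarded."""
        return frozenset((c.i, c.j) for c in self.contacts)

    def scores(self) -> np.ndarray:
        return np.array([c.score for c in self.contacts], dtype=float)


#: Per-residue membrane-topology codes: inside, outside, membrane, signal.
TOPOLOGY_CODES = frozenset("ioMS")


@dataclass(frozen=True)
class TopologyProfile:
    """Per-residue membrane topology labels over ``{i, o, M, S}``.

    ``segments`` lists the maximal constant-label runs as closed intervals
    ``(start, end, label)``; they tile ``1..L`` without gaps or overlaps.
    """

    labels: str

    def __post_init__(self) -> None:
        bad = sorted(set(self.labels) - TOPOLOGY_CODES)
        if bad:
            raise FormatError(f"invalid topology code(s) {''.join(bad)!r}")
        if not self.labels:
            raise FormatError("empty topology string")

    @property
    def L(self) -> int:
        return len(self.labels)

    @property
    def segments(self) -> list[tuple[int, int, str]]:
        segs: list[tuple[int, int, str]] = []
        start = 1
        for pos in range(2, self.L + 2):
            if pos > self.L or self.labels[pos - 1] != self.labels[start - 1]:
                segs.append((start, pos - 1, self.labels[start - 1]))
                start = pos
        return segs

    def membrane_segments(self) -> list[tuple[int, int]]:
        """Closed intervals of the M-labelled (membrane-embedded) runs."""
        return [(a, b) for a, b, lab in self.segments if lab == "M"]


SS_STATES = frozenset("HEC")


@dataclass(frozen=True)
class SSProfile:
    """Per-residue secondary-structure states over ``{H, E, C}``.

    ``confidences`` is an optional ``(L, 3)`` array of state probabilities
    in ``(H, E, C)`` column order; each row must sum to 1 within 0.01.
    """

    states: str
    confidences: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        bad = sorted(set(self.states) - SS_STATES)
        if bad:
            raise FormatError(f"invalid secondary-structure state(s) {''.join(bad)!r}")
        if self.confidences is not None:
            conf = np.asarray(self.confidences, dtype=float)
            if conf.shape != (len(self.states), 3):
                raise FormatError(
                    f"confidence array shape {conf.shape} does not match "
                    f"L={len(self.states)}"
                )
            sums = conf.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 0.01):
                k = int(np.argmax(np.abs(sums - 1.0)))
                raise FormatError(
                    f"confidence triple at residue {k + 1} sums to {sums[k]:.3f}"
                )
            object.__setattr__(self, "confidences", conf)

    @property
    def L(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of a 3D model: index, amino acid, Cα and optional Cβ."""

    index: int
    aa: str
    ca: tuple[float, float, float]
    cb: Optional[tuple[float, float, float]] = None


@dataclass
class StructureModel:
    """A single-chain 3D model reduced to Cα/Cβ coordinates.

    Residue indices must be strictly increasing and all coordinates finite.
    Glycine has no Cβ; contact evaluation falls back to Cα for such
    residues (the standard convention where Cβ is undefined).
    """

    residues: list[ResidueRecord]
    id: str = "model"

    def __post_init__(self) -> None:
        prev = 0
        for r in self.residues:
            if r.index <= prev:
                raise FormatError(
                    f"residue indices must be strictly increasing (saw {r.index} "
                    f"after {prev})"
                )
            prev = r.index
            for coord in (r.ca, r.cb):
                if coord is not None and not all(math.isfinite(x) for x in coord):
                    raise FormatError(f"non-finite coordinate at residue {r.index}")

    @property
    def L(self) -> int:
        return self.residues[-1].index if self.residues else 0

    def sequence(self, id: Optional[str] = None) -> Sequence:
        return Sequence(id or self.id, "".join(r.aa for r in self.residues))

    def contact_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(indices, coordinates) used for contact evaluation: Cβ, Cα for Gly."""
        idx = np.array([r.index for r in self.residues], dtype=int)
        xyz = np.array(
            [r.cb if r.cb is not None else r.ca for r in self.residues], dtype=float
        )
        return idx, xyz


class Region(NamedTuple):
    """An annotated chain region: closed interval plus a region code."""

    start: int
    end: int
    code: str


#: Canonical region vocabulary used by the loop-library stage.
REGION_CODES = (
    "tm_helix",      # membrane-spanning alpha helix
    "reentrant",     # membrane re-entrant loop
    "side1",         # aqueous side 1
    "side2",         # aqueous side 2
    "interfacial",   # helix lying in the membrane interface
)


@dataclass
class RegionAnnotation:
    """Membrane-region annotations for one chain (PDBTM-style)."""

    chain: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        spans = sorted((r.start, r.end) for r in self.regions)
        for (s, e) in spans:
            if s > e:
                raise FormatError(f"chain {self.chain}: region start {s} > end {e}")
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise FormatError(f"chain {self.chain}: overlapping regions")

    def of_code(self, code: str) -> list[Region]:
        return [r for r in self.regions if r.code == code]
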