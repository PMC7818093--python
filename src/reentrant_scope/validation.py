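"""Model validation by satisfaction of predicted contacts.

A 3D model is scored by the fraction of the top-L predicted contacts
(L = chain length) that are realised in the model under the package-wide
contact definition: Cβ–Cβ distance ≤ 8 Å (Cα for glycine) at sequence
separation ≥ 5.  High satisfaction is the hallmark of a model consistent
with the evolutionary covariance signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .types import Contact, ContactMap, InputError, ParameterError, StructureModel

__all__ = [
    "D_CUT",
    "S_MIN",
    "model_contacts",
    "PrecisionReport",
    "topL_precision",
]

D_CUT = 8.0   # Å, Cβ–Cβ contact threshold
S_MIN = 5     # minimum sequence separation |i - j|


def model_contacts(model: StructureModel, d_cut: float = D_CUT,
                   s_min: int = S_MIN) -> ContactMap:
    """All residue pairs of the model in contact, score 1.0.

    Uses Cβ coordinates with a Cα fallback for residues lacking one
    (glycine).  Residues missing coordinates are excluded with a warning.
    """
    if len(model.residues) < 2:
        raise InputError("model must have at least 2 residues")
    if d_cut <= 0:
        raise ParameterError("distance cut-off must be positive")
    idx, xyz = model.contact_coords()
    dist = cdist(xyz, xyz)
    contacts = [
        Contact(int(idx[a]), int(idx[b]), 1.0)
        for a in range(len(idx))
        for b in range(a + 1, len(idx))
        if abs(int(idx[b]) - int(idx[a])) >= s_min and dist[a, b] <= d_cut
    ]
    return ContactMap(model.L, contacts)


@dataclass
class PrecisionReport:
    """Outcome of checking predicted contacts against a model."""

    n_considered: int
    n_satisfied: int
    fraction: float
    d_cut: float
    s_min: int
    matched: list[tuple[int, int]] = field(default_factory=list)
    mismatched: list[tuple[int, int]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_considered": self.n_considered,
            "n_satisfied": self.n_satisfied,
            "fraction": self.fraction,
            "d_cut": self.d_cut,
            "s_min": self.s_min,
            "matched": sorted(self.matched),
            "mismatched": sorted(self.mismatched),
        }


def topL_precision(pred: ContactMap, model: StructureModel,
                   n: int | None = None, d_cut: float = D_CUT,
                   s_min: int = S_MIN) -> PrecisionReport:
    """Fraction of the top-n predicted contacts satisfied by the model.

    ``n`` defaults to L, the chain length.  Deterministic: ties in the
    top-n selection break on (smaller i, then smaller j).
    """
    from .density import select_top  # shared top-n selection rule

    if pred.L != model.L:
        raise InputError(
            f"predicted map length {pred.L} != model length {model.L}"
        )
    n = pred.L if n is None else n
    top = select_top(pred, n)
    realised = model_contacts(model, d_cut=d_cut, s_min=s_min).pair_set()
    matched = [(c.i, c.j) for c in top.contacts if (c.i, c.j) in realised]
    mismatched = [(c.i, c.j) for c in top.contacts if (c.i, c.j) not in realised]
    n_considered = len(top)
    fraction = len(matched) / n_considered if n_considered else 0.0
    return PrecisionReport(
        n_considered=n_considered,
        n_satisfied=len(matched),
        fraction=fraction,
        d_cut=d_cut,
        s_min=s_min,
        matched=matched,
        mismatched=mismatched,
    )
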