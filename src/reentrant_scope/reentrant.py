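"""Detection of candidate re-entrant helices.

A re-entrant loop (helix-turn-helix entering and leaving the membrane on
the same side) is commonly mispredicted by topology servers as a single
TM helix.  Its tell-tale combination of evidence is:

* a predicted membrane segment whose secondary structure carries one
  short internal coil break near the segment mid-point (the turn), with
  helical limbs on both sides; and
* a contact-map packing signature against an adjacent full TM helix —
  the limb nearer the partner packs antiparallel (negative rank
  correlation of contacting index pairs) and the far limb parallel.

Candidates are geometric first (the broken-TM rule is deterministic) and
are then scored by the packing correlations.  The rule cannot by itself
distinguish a genuine re-entrant loop from a strongly kinked TM helix;
results are therefore always reported as candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import spearmanr

from .density import select_top
from .types import ContactMap, InputError, ParameterError, SSProfile, TopologyProfile

__all__ = [
    "ReentrantCandidate",
    "find_broken_tm",
    "packing_orientation",
    "score_reentrant",
    "detect_reentrants",
]

MIN_BREAK = 2    # shortest coil break accepted (observed turn lengths: 2)
MAX_BREAK = 8    # longest coil break accepted (observed: 6; headroom to 8)
MIN_LIMB = 4     # helical limbs flanking the break must be at least this long
W_GEOM = 0.4     # weight of the geometric (broken-TM) evidence
W_PACK = 0.6     # weight of the packing-correlation evidence


@dataclass
class ReentrantCandidate:
    """A TM-predicted segment with an internal coil break, plus packing evidence.

    All intervals are closed 1-based ``(start, end)`` pairs.  ``rho1`` /
    ``rho2`` are the Spearman correlations of the contacting index pairs
    between the partner helix and limb1 / limb2; they are ``None`` when
    fewer than 3 supporting contacts exist.
    """

    segment: tuple[int, int]
    brk: tuple[int, int]
    limb1: tuple[int, int]
    limb2: tuple[int, int]
    partner: Optional[tuple[int, int]] = None
    rho1: Optional[float] = None
    rho2: Optional[float] = None
    n1: int = 0
    n2: int = 0
    score: Optional[float] = None
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "segment": list(self.segment),
            "break": list(self.brk),
            "limb1": list(self.limb1),
            "limb2": list(self.limb2),
            "partner": list(self.partner) if self.partner else None,
            "rho1": self.rho1,
            "rho2": self.rho2,
            "n1": self.n1,
            "n2": self.n2,
            "score": self.score,
            "notes": list(self.notes),
        }


def _runs(states: str) -> list[tuple[int, int, str]]:
    """Maximal constant-state runs of a string as (start, end, state), 1-based."""
    out = []
    start = 0
    for k in range(1, len(states) + 1):
        if k == len(states) or states[k] != states[start]:
            out.append((start + 1, k, states[start]))
            start = k
    return out


def find_broken_tm(topology: TopologyProfile, ss: SSProfile,
                   min_break: int = MIN_BREAK, max_break: int = MAX_BREAK,
                   min_limb: int = MIN_LIMB) -> list[ReentrantCandidate]:
    """Geometric re-entrant candidates from topology + secondary structure.

    For each membrane (M) segment of the topology, a candidate is
    reported iff the secondary-structure states inside it contain exactly
    one maximal coil run, of length in ``[min_break, max_break]``, flanked
    on both sides by helical runs of at least ``min_limb`` residues, with
    the run's centre inside the middle 50% of the segment.
    """
    if topology.L != ss.L:
        raise InputError(
            f"topology length {topology.L} != secondary-structure length {ss.L}"
        )
    candidates: list[ReentrantCandidate] = []
    for (a, b) in topology.membrane_segments():
        states = ss.states[a - 1 : b]
        coil_runs = [(s, e) for (s, e, st) in _runs(states) if st == "C"]
        if len(coil_runs) != 1:
            continue
        s, e = coil_runs[0]
        if not (min_break <= e - s + 1 <= max_break):
            continue
        if s - 1 < min_limb or len(states) - e < min_limb:
            continue
        if any(st == "E" for st in states):
            continue  # strand inside a putative re-entrant helix: reject
        seg_len = b - a + 1
        centre = (s + e) / 2.0
        if not (0.25 * seg_len <= centre <= 0.75 * seg_len):
            continue
        candidates.append(
            ReentrantCandidate(
                segment=(a, b),
                brk=(a + s - 1, a + e - 1),
                limb1=(a, a + s - 2),
                limb2=(a + e, b),
            )
        )
    return candidates


def packing_orientation(cmap: ContactMap, segA: tuple[int, int],
                        segB: tuple[int, int],
                        n_top: Optional[int] = None,
                        ) -> tuple[Optional[float], int]:
    """Packing orientation of two disjoint segments from top-n contacts.

    Returns ``(rho, n)``: the Spearman rank correlation of the contacting
    index pairs (segA coordinate against segB coordinate) and the number
    of supporting contacts.  ``rho`` is ``None`` when n < 3 (or when the
    correlation is degenerate).  Antiparallel packing gives rho near -1,
    parallel packing near +1.  ``n_top`` defaults to L, the package-wide
    top-L selection convention.
    """
    a1, a2 = segA
    b1, b2 = segB
    if max(a1, b1) <= min(a2, b2):
        raise ParameterError(f"segments {segA} and {segB} overlap")
    n_top = cmap.L if n_top is None else n_top
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        top = select_top(cmap, min(n_top, max(1, len(cmap))))
    xs: list[int] = []
    ys: list[int] = []
    for c in top.contacts:
        if a1 <= c.i <= a2 and b1 <= c.j <= b2:
            xs.append(c.i)
            ys.append(c.j)
        elif b1 <= c.i <= b2 and a1 <= c.j <= a2:
            xs.append(c.j)
            ys.append(c.i)
    n = len(xs)
    if n < 3:
        return None, n
    rho = spearmanr(xs, ys).statistic
    if not np.isfinite(rho):
        return None, n
    return float(rho), n


def score_reentrant(candidate: ReentrantCandidate, cmap: ContactMap,
                    flanking: list[tuple[int, int]],
                    n_top: Optional[int] = None,
                    w_geom: float = W_GEOM,
                    w_pack: float = W_PACK) -> ReentrantCandidate:
    """Attach partner-helix packing evidence and a composite score.

    The partner is the flanking TM segment with the most supporting
    contacts (n1 + n2).  The limb expected antiparallel to the partner is
    the sequence-adjacent one: limb1 for a preceding partner, limb2 for a
    following one.  Composite score = w_geom + w_pack * max(0,
    (-rho_anti + rho_para) / 2), with undefined correlations contributing
    zero.  Without any flanking TM segment, the packing component is 0
    and a note is recorded.
    """
    best = None
    for seg in flanking:
        rho1, n1 = packing_orientation(cmap, candidate.limb1, seg, n_top)
        rho2, n2 = packing_orientation(cmap, candidate.limb2, seg, n_top)
        if best is None or n1 + n2 > best[3] + best[4]:
            best = (seg, rho1, rho2, n1, n2)
    if best is None:
        candidate.notes.append("no flanking TM segment; packing component 0")
        candidate.score = w_geom
        return candidate
    seg, rho1, rho2, n1, n2 = best
    candidate.partner = seg
    candidate.rho1, candidate.rho2 = rho1, rho2
    candidate.n1, candidate.n2 = n1, n2
    if seg[1] < candidate.segment[0]:
        rho_anti, rho_para = rho1, rho2
    else:
        rho_anti, rho_para = rho2, rho1
    anti = -(rho_anti if rho_anti is not None else 0.0)
    para = rho_para if rho_para is not None else 0.0
    candidate.score = w_geom + w_pack * max(0.0, (anti + para) / 2.0)
    return candidate


def detect_reentrants(cmap: ContactMap, topology: TopologyProfile,
                      ss: SSProfile,
                      min_break: int = MIN_BREAK, max_break: int = MAX_BREAK,
                      min_limb: int = MIN_LIMB,
                      n_top: Optional[int] = None,
                      w_geom: float = W_GEOM,
                      w_pack: float = W_PACK) -> list[ReentrantCandidate]:
    """Full re-entrant detection: broken-TM rule, then packing score.

    Membrane segments without a qualifying break serve as candidate
    partner helices.  Returns candidates ranked by score (ties by
    segment start).
    """
    candidates = find_broken_tm(topology, ss, min_break, max_break, min_limb)
    cand_segments = {c.segment for c in candidates}
    flanking = [seg for seg in topology.membrane_segments()
                if seg not in cand_segments]
    scored = [
        score_reentrant(c, cmap, flanking, n_top, w_geom, w_pack)
        for c in candidates
    ]
    scored.sort(key=lambda c: (-(c.score or 0.0), c.segment[0]))
    return scored
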