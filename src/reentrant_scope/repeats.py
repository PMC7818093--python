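"""Internal tandem-repeat detection from intra-half contact submaps.

An internal structural repeat leaves a fingerprint in a predicted
contact map even when all sequence similarity between the units has been
erased by divergence: splitting the chain at the inter-unit boundary
yields two intra-unit submaps with near-identical patterns.  The
statistic here is the Jaccard overlap of the two binarised submaps,
maximised over a small index offset (tolerating indel drift between the
units), with significance from a permutation null that redraws each
half's contacts at random while preserving the multiset of sequence
separations |i - j| (the dominant nuisance structure of contact maps).

Repeats are compared in direct orientation only: a contact map is
invariant under rigid 3D inversion, so an inverted-topology repeat still
produces matching intra-unit maps; the membrane orientation of the units
is inferred downstream from topology and re-entrant geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence as TSequence

import numpy as np

from .density import select_top
from .types import Contact, ContactMap, ParameterError

__all__ = [
    "split_map",
    "repeat_score",
    "RepeatHit",
    "detect_repeat",
    "separation_preserving_draw",
]

DELTA_MAX = 10        # offsets tried between the half-maps
TOP_FACTOR = 1.5      # binarise each half at top 1.5 * (half length)


def split_map(cmap: ContactMap, b: int) -> tuple[ContactMap, ContactMap, int]:
    """Split a map at residue b into two re-indexed intra-half submaps.

    The first submap holds contacts with j <= b (indices kept 1..b); the
    second holds contacts with i > b, re-indexed to 1..(L-b).  Cross-half
    contacts are discarded; their count is returned as the third value.
    """
    if not (1 < b < cmap.L):
        raise ParameterError(f"split must satisfy 1 < b < L={cmap.L}, got {b}")
    first: list[Contact] = []
    second: list[Contact] = []
    n_cross = 0
    for c in cmap.contacts:
        if c.j <= b:
            first.append(c)
        elif c.i > b:
            second.append(Contact(c.i - b, c.j - b, c.score))
        else:
            n_cross += 1
    return ContactMap(b, first), ContactMap(cmap.L - b, second), n_cross


def _score_sets(a_pairs: set, b_pairs: set, LA: int, LB: int,
                delta: int) -> float:
    """Jaccard of shifted pair sets over the window valid in both maps."""
    lo = max(1, 1 + delta)
    hi = min(LB, LA + delta)
    a = {
        (i + delta, j + delta)
        for (i, j) in a_pairs
        if lo <= i + delta and j + delta <= hi
    }
    b = {(i, j) for (i, j) in b_pairs if lo <= i and j <= hi}
    n_union = len(a | b)
    return len(a & b) / n_union if n_union else 0.0


def repeat_score(A: ContactMap, B: ContactMap, delta: int = 0) -> float:
    """Jaccard overlap of two binarised submaps at index offset ``delta``.

    A's pairs are shifted by +delta and compared with B's over the index
    window valid in both maps; an empty union scores 0.  Symmetric:
    ``repeat_score(A, B, d) == repeat_score(B, A, -d)``.
    """
    return _score_sets(set(A.pair_set()), set(B.pair_set()), A.L, B.L, delta)


@dataclass(frozen=True)
class RepeatHit:
    """Best internal-repeat split with its significance.

    The pairs ``(split, delta)`` with equal ``split + delta`` describe
    the same inter-unit alignment (half-A position p matches global
    position ``split + delta + p``), so ``period = split + delta`` is the
    canonical tandem boundary: for a two-unit repeat it estimates the
    first unit's length.
    """

    split: int
    delta: int
    score: float
    p_value: float
    n_permutations: int
    orientation: str = "direct"
    n_cross_discarded: int = 0

    @property
    def period(self) -> int:
        return self.split + self.delta

    def as_dict(self) -> dict:
        return {
            "split": self.split,
            "delta": self.delta,
            "period": self.period,
            "orientation": self.orientation,
            "score": self.score,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "n_cross_discarded": self.n_cross_discarded,
        }


def separation_preserving_draw(pairs: Iterable[tuple[int, int]], L: int,
                               rng: np.random.Generator) -> set[tuple[int, int]]:
    """Random contact set with exactly the |i-j| multiset of ``pairs``.

    For each separation s the i positions are sampled without
    replacement from 1..L-s, so the draw is a valid unique-pair map with
    the observed separation multiset preserved exactly.
    """
    by_sep: dict[int, int] = {}
    for (i, j) in pairs:
        by_sep[j - i] = by_sep.get(j - i, 0) + 1
    out: set[tuple[int, int]] = set()
    for s, count in sorted(by_sep.items()):
        slots = L - s
        if count > slots:
            raise ParameterError(
                f"cannot place {count} pairs of separation {s} on a chain "
                f"of length {L}"
            )
        picks = rng.choice(slots, size=count, replace=False) + 1
        out.update((int(i), int(i + s)) for i in picks)
    return out


def _binarised_halves(cmap: ContactMap, b: int, top_factor: float,
                      ) -> tuple[frozenset, frozenset, int, int, int]:
    A, B, n_cross = split_map(cmap, b)
    nA = max(1, int(round(top_factor * A.L)))
    nB = max(1, int(round(top_factor * B.L)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fewer contacts than requested is fine
        a = select_top(A, nA).pair_set() if len(A) else frozenset()
        b_pairs = select_top(B, nB).pair_set() if len(B) else frozenset()
    return a, b_pairs, A.L, B.L, n_cross


def _best_over_offsets(a_pairs: set, b_pairs: set, LA: int, LB: int,
                       delta_max: int) -> tuple[float, int]:
    best, best_d = -1.0, 0
    # Offsets ordered by |d| so score ties resolve to the smallest shift.
    for d in sorted(range(-delta_max, delta_max + 1), key=lambda d: (abs(d), d)):
        s = _score_sets(a_pairs, b_pairs, LA, LB, d)
        if s > best:
            best, best_d = s, d
    return best, best_d


def detect_repeat(cmap: ContactMap,
                  splits: Optional[TSequence[int]] = None,
                  scan: Optional[tuple[int, int]] = None,
                  n_perm: int = 199,
                  seed: int = 0,
                  delta_max: int = DELTA_MAX,
                  top_factor: float = TOP_FACTOR) -> RepeatHit:
    """Best tandem-repeat split over candidate split points.

    ``splits`` supplies candidate split residues (typically contact-density
    minima); alternatively ``scan=(lo, hi)`` scans every split in a closed
    range.  The statistic is the maximum over splits and offsets |delta|
    <= delta_max of the Jaccard overlap of the binarised half-maps; its
    p-value comes from ``n_perm`` separation-preserving permutations of
    both halves (the same maximisation applied to each draw):
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 19:
        raise ParameterError(
            f"n_perm={n_perm} gives too coarse a p-value grid; need >= 19"
        )
    if splits is None and scan is None:
        raise ParameterError("supply candidate splits or a scan range")
    if splits is None:
        lo, hi = scan
        splits = list(range(max(2, lo), min(cmap.L - 1, hi) + 1))
    splits = [int(b) for b in splits if 1 < int(b) < cmap.L]
    if not splits:
        raise ParameterError("no valid split points in (1, L)")

    halves = {b: _binarised_halves(cmap, b, top_factor) for b in splits}

    observed, best_b, best_d = -1.0, splits[0], 0
    for b in splits:
        a, bb, LA, LB, _ = halves[b]
        s, d = _best_over_offsets(set(a), set(bb), LA, LB, delta_max)
        if s > observed:
            observed, best_b, best_d = s, b, d

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        null_stat = -1.0
        for b in splits:
            a, bb, LA, LB, _ = halves[b]
            ra = separation_preserving_draw(a, LA, rng)
            rb = separation_preserving_draw(bb, LB, rng)
            s, _d = _best_over_offsets(ra, rb, LA, LB, delta_max)
            null_stat = max(null_stat, s)
        if null_stat >= observed:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)

    return RepeatHit(
        split=best_b,
        delta=best_d,
        score=observed,
        p_value=p,
        n_permutations=n_perm,
        n_cross_discarded=halves[best_b][4],
    )
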