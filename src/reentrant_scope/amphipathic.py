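"""Eisenberg hydrophobic moments and amphipathic-helix windows.

The hydrophobic moment of a window of N residues placed on an ideal
helical wheel (100 degrees per residue) is

    uH = (1/N) * sqrt( (sum_n H_n sin(d*n))^2 + (sum_n H_n cos(d*n))^2 )

with H_n the per-residue hydrophobicity on the Fauchere-Pliska (1983)
scale, n = 0..N-1 and d = 100 degrees.  A helix with segregated
hydrophobic and polar faces has a large uH; a uniformly hydrophobic TM
core has a small one.  The default analysis window is the 15 residues
immediately preceding a putative re-entrant loop, where surface
amphipathic helices sit in this fold family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from functools import lru_cache
from typing import Iterable, Optional

from .types import InputError, ParameterError, Sequence

__all__ = [
    "load_scale",
    "hydrophobic_moment",
    "moment_direction",
    "AmphipathicWindow",
    "window_stats",
    "windows_before_reentrants",
    "scan",
    "wheel_coordinates",
    "DELTA_DEG",
    "DEFAULT_WINDOW",
]

DELTA_DEG = 100.0     # helical wheel rotation per residue
DEFAULT_WINDOW = 15   # residues preceding a re-entrant loop


@lru_cache(maxsize=None)
def load_scale(name: str = "fauchere_pliska") -> dict[str, float]:
    """Load a packaged per-residue hydrophobicity table."""
    text = resources.files("reentrant_scope.data").joinpath(f"{name}.tsv").read_text()
    scale: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        scale[aa] = float(value)
    return scale


def _moment_components(window: str, scale: Optional[dict[str, float]],
                       delta_deg: float) -> tuple[float, float]:
    if not window:
        raise InputError("empty window")
    table = load_scale() if scale is None else scale
    s = c = 0.0
    for n, aa in enumerate(window):
        if aa not in table:
            raise InputError(f"residue {aa!r} absent from hydrophobicity scale")
        theta = math.radians(delta_deg * n)
        h = table[aa]
        s += h * math.sin(theta)
        c += h * math.cos(theta)
    return s, c


def hydrophobic_moment(window: str, scale: Optional[dict[str, float]] = None,
                       delta_deg: float = DELTA_DEG) -> float:
    """Normalised hydrophobic moment uH of a residue window."""
    s, c = _moment_components(window, scale, delta_deg)
    return math.hypot(s, c) / len(window)


def moment_direction(window: str, scale: Optional[dict[str, float]] = None,
                     delta_deg: float = DELTA_DEG) -> float:
    """Direction of the moment in the wheel frame, degrees in [0, 360).

    Residue 0 of the window sits at wheel angle 0.
    """
    s, c = _moment_components(window, scale, delta_deg)
    return math.degrees(math.atan2(s, c)) % 360.0


def mean_hydrophobicity(window: str,
                        scale: Optional[dict[str, float]] = None) -> float:
    table = load_scale() if scale is None else scale
    try:
        return sum(table[aa] for aa in window) / len(window)
    except KeyError as exc:
        raise InputError(f"residue {exc.args[0]!r} absent from scale") from exc


@dataclass(frozen=True)
class AmphipathicWindow:
    """A scored helical-wheel window, closed interval [start, end]."""

    start: int
    end: int
    mean_h: float
    mu_h: float
    angle_deg: float

    @property
    def N(self) -> int:
        return self.end - self.start + 1


def window_stats(seq: Sequence, start: int, end: int,
                 scale: Optional[dict[str, float]] = None) -> AmphipathicWindow:
    """Score the closed window ``[start, end]`` of ``seq``."""
    if not (1 <= start <= end <= seq.L):
        raise ParameterError(f"window [{start}, {end}] outside chain 1..{seq.L}")
    window = seq.residues[start - 1 : end]
    return AmphipathicWindow(
        start=start,
        end=end,
        mean_h=mean_hydrophobicity(window, scale),
        mu_h=hydrophobic_moment(window, scale),
        angle_deg=moment_direction(window, scale),
    )


def windows_before_reentrants(seq: Sequence, candidates: Iterable,
                              w: int = DEFAULT_WINDOW,
                              scale: Optional[dict[str, float]] = None,
                              ) -> list[AmphipathicWindow]:
    """One window of ``w`` residues immediately preceding each candidate.

    For a candidate whose first limb starts at residue ``b``, the window
    is ``[b - w, b - 1]``.  Candidates too close to the N terminus are
    skipped with a warning.
    """
    import warnings

    out: list[AmphipathicWindow] = []
    for cand in candidates:
        limb_start = cand.limb1[0] if hasattr(cand, "limb1") else int(cand)
        if limb_start - w < 1:
            warnings.warn(
                f"candidate at residue {limb_start}: preceding {w}-residue "
                f"window would start before residue 1; skipped"
            )
            continue
        out.append(window_stats(seq, limb_start - w, limb_start - 1, scale))
    return out


def scan(seq: Sequence, w: int = DEFAULT_WINDOW, step: int = 1,
         scale: Optional[dict[str, float]] = None) -> list[AmphipathicWindow]:
    """Score every length-``w`` window of the chain (stride ``step``)."""
    if w < 3:
        raise ParameterError(f"window length must be >= 3, got {w}")
    if w > seq.L:
        raise ParameterError(f"window length {w} exceeds chain length {seq.L}")
    return [
        window_stats(seq, start, start + w - 1, scale)
        for start in range(1, seq.L - w + 2, step)
    ]


def wheel_coordinates(window: str, delta_deg: float = DELTA_DEG,
                      ) -> list[tuple[str, float, float]]:
    """(residue, wheel angle deg, radius) triples for external plotting."""
    return [(aa, (delta_deg * n) % 360.0, 1.0) for n, aa in enumerate(window)]
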