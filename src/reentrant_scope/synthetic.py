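"""Idealised helical membrane proteins with planted, known ground truth.

The generator builds toy α-helical membrane proteins from an ordered list
of architectural elements (TM helices, re-entrant hairpins, amphipathic
surface helices, loops), lays them out as packed vertical helices in a
30 Å membrane slab, and derives every per-residue track the analysis
pipeline consumes: sequence, TOPCONS-style topology labels, PSIPRED-style
secondary structure, ideal Cα/Cβ coordinates, the exact geometric contact
map, and a noise-corrupted "predicted" contact map.

Design choices (documented in the methods note):

* ideal α-helix geometry — 1.5 Å rise and 100° turn per residue, Cα at
  2.3 Å and Cβ at 3.3 Å from the axis;
* membrane slab |z| ≤ 15 Å; re-entrant hairpins descend roughly half the
  slab depth and return to the same side;
* helix axes are placed on a row of slots 9.4 Å apart, so sequential
  neighbours pack and produce the canonical antiparallel contact stripes;
* topology labels emulate a TopCons-style *prediction*: a re-entrant
  hairpin is labelled as a single membrane (M) segment and flips the
  predicted side, exactly the failure mode the analysis exploits;
* sequences are drawn from hydrophobicity classes (not evolutionary
  models): TM cores are uniformly hydrophobic (low hydrophobic moment),
  amphipathic helices alternate faces (high moment), loops are polar.

Everything is deterministic for a fixed :class:`SyntheticSpec` seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .types import (
    Contact,
    ContactMap,
    ParameterError,
    ResidueRecord,
    Sequence,
    SSProfile,
    StructureModel,
    TopologyProfile,
)

__all__ = [
    "Element",
    "SyntheticSpec",
    "TruthLabels",
    "SyntheticProtein",
    "build_protein",
    "corrupt_map",
    "write_fixture",
    "ideal_helix",
    "tm_bundle_spec",
    "deda_like_spec",
    "two_domain_spec",
    "tandem_repeat_spec",
]

# Geometry constants (Å / degrees).
RISE = 1.5            # axial rise per residue of an ideal alpha helix
TURN_DEG = 100.0      # wheel rotation per residue
CA_RADIUS = 2.3       # Calpha distance from the helix axis
CB_RADIUS = 3.3       # Cbeta distance from the helix axis
SLAB_HALF = 15.0      # membrane slab spans z in [-15, +15]
SLOT_DX = 9.4         # axis-to-axis spacing of packed helices
AMPHI_Y = -9.0        # lateral offset of surface helices off the slot row
AMPHI_Z = SLAB_HALF + 2.5

ELEMENT_KINDS = ("tm_helix", "reentrant_hairpin", "amphipathic_helix",
                 "loop", "domain_linker")

# Residue alphabets per hydrophobicity class.
_TM_CORE = "ILVFA"
_HAIRPIN_POLAR = "STN"
_AMPHI_PHOBIC = "LFIM"
_AMPHI_POLAR = "SQEKNR"
_LOOP = "GSNPD"
_TURN = "GNS"


@dataclass(frozen=True)
class Element:
    """One architectural element of a synthetic membrane protein.

    ``spacing`` is the axis-to-axis distance (Å) to the next packed
    helix and ``z_shift`` an axial offset of the helix in the membrane;
    both default to the regular lattice and exist so that constructs can
    carry the geometric irregularity of natural bundles (interfaces of
    different tightness, helices of different register).
    """

    kind: str
    length: int
    turn: int = 2                     # coil turn length; hairpins only
    spacing: Optional[float] = None   # Å to the next vertical element
    z_shift: float = 0.0              # axial offset, Å
    tilt_deg: float = 0.0             # axis tilt from the membrane normal

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise ParameterError(f"unknown element kind {self.kind!r}")
        if self.length < 3:
            raise ParameterError(f"{self.kind}: element length must be >= 3")
        if self.spacing is not None and self.spacing <= 6.0:
            raise ParameterError("helix spacing below 6 Å is a clash")
        if self.kind == "reentrant_hairpin":
            if not (2 <= self.turn <= self.length - 8):
                raise ParameterError(
                    "reentrant_hairpin needs a turn of >= 2 residues and "
                    "helical limbs of >= 4 residues each"
                )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic protein.

    ``repeat`` optionally names an inclusive element-index range to
    duplicate; the copy is appended after the original list and, when the
    unit crosses the membrane an odd number of times, lands with inverted
    membrane orientation — the pseudo-2-fold inverted repeat geometry of
    dual-topology transporter folds.
    """

    elements: tuple[Element, ...]
    repeat: Optional[tuple[int, int]] = None
    p_tp: float = 1.0       # true-positive retention rate of the noisy map
    n_fp: int = 0           # count of injected false-positive contacts
    seed: int = 0
    mu_amphi_min: float = 0.35   # planted amphipathic helices exceed this
    mu_tm_max: float = 0.25      # TM cores stay below this moment

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_tp <= 1.0):
            raise ParameterError(f"p_tp must be in [0, 1], got {self.p_tp}")
        if self.n_fp < 0:
            raise ParameterError("n_fp must be >= 0")
        if self.repeat is not None:
            lo, hi = self.repeat
            if not (0 <= lo <= hi < len(self.elements)):
                raise ParameterError(f"repeat range {self.repeat} out of bounds")


@dataclass
class TruthLabels:
    """Planted ground truth carried alongside every synthetic protein."""

    boundaries: list[int] = field(default_factory=list)       # first residue of each C-side domain
    repeat_units: list[tuple[int, int]] = field(default_factory=list)
    repeat_orientation: Optional[str] = None                  # "inverted" | "direct"
    reentrant: list[tuple[int, int]] = field(default_factory=list)
    turns: list[tuple[int, int]] = field(default_factory=list)
    amphipathic: list[tuple[int, int]] = field(default_factory=list)
    tm_helices: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SyntheticProtein:
    """A planted-truth bundle: model, tracks, maps and labels."""

    model: StructureModel
    sequence: Sequence
    topology: TopologyProfile
    ss: SSProfile
    true_map: ContactMap
    noisy_map: ContactMap
    truth: TruthLabels

    @property
    def L(self) -> int:
        return self.sequence.L


# ---------------------------------------------------------------------------
# geometry primitives

def ideal_helix(start: np.ndarray, axis: np.ndarray, n: int,
                phase_deg: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Cα and Cβ coordinates of an ideal α-helix.

    ``start`` is the axis position of residue 0 and ``axis`` the unit
    direction of the rise.  Returns two ``(n, 3)`` arrays.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    # Orthonormal frame perpendicular to the axis.
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    t = np.arange(n)
    theta = np.radians(phase_deg + TURN_DEG * t)[:, None]
    radial = np.cos(theta) * u + np.sin(theta) * v
    centre = np.asarray(start, float) + RISE * t[:, None] * axis
    return centre + CA_RADIUS * radial, centre + CB_RADIUS * radial


def _loop_coords(p: np.ndarray, q: np.ndarray, n: int,
                 bulge: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """n coil residues interpolated between anchors with an outward bulge."""
    t = (np.arange(1, n + 1) / (n + 1))[:, None]
    ca = p + t * (q - p) + np.sin(np.pi * t) * bulge
    cb = ca + np.array([0.0, 1.0, 0.8])
    return ca, cb


# ---------------------------------------------------------------------------
# sequence design

def _moment(window: str) -> float:
    # Local import: amphipathicity owns the scale; synthetic only patterns it.
    from .amphipathic import hydrophobic_moment
    return hydrophobic_moment(window)


def _tm_sequence(n: int, rng: np.random.Generator, mu_max: float) -> str:
    best, best_mu = None, np.inf
    for _ in range(100):
        seq = "".join(rng.choice(list(_TM_CORE), size=n))
        mu = _moment(seq)
        if mu < best_mu:
            best, best_mu = seq, mu
        if mu < mu_max:
            return seq
    return best  # pragma: no cover - pattern almost always passes quickly


def _amphipathic_sequence(n: int, rng: np.random.Generator, face_deg: float,
                          mu_min: float) -> str:
    """Residues segregated into a hydrophobic face centred on ``face_deg``."""
    out = []
    for k in range(n):
        theta = math.radians(TURN_DEG * k - face_deg)
        if math.cos(theta) > 0.0:
            out.append(rng.choice(list(_AMPHI_PHOBIC)))
        else:
            out.append(rng.choice(list(_AMPHI_POLAR)))
    seq = "".join(out)
    if _moment(seq) < mu_min:  # pragma: no cover - faces always segregate
        raise RuntimeError("amphipathic patterning failed to reach threshold")
    return seq


def _hairpin_sequence(limb1: int, turn: int, limb2: int,
                      rng: np.random.Generator) -> str:
    def limb(n: int) -> str:
        return "".join(
            rng.choice(list(_HAIRPIN_POLAR)) if rng.random() < 0.25
            else rng.choice(list(_TM_CORE))
            for _ in range(n)
        )

    turn_seq = ("GP" + "".join(rng.choice(list(_TURN), size=max(0, turn - 2))))[:turn]
    return limb(limb1) + turn_seq + limb(limb2)


# ---------------------------------------------------------------------------
# the builder

def build_protein(spec: SyntheticSpec) -> SyntheticProtein:
    """Realise a :class:`SyntheticSpec` as a full planted-truth bundle.

    Deterministic for a fixed spec (including its seed).  Raises a
    :class:`ParameterError` when the element list yields fewer than 30
    residues.
    """
    elements = list(spec.elements)
    repeat_elem_ranges: list[tuple[int, int]] = []
    if spec.repeat is not None:
        lo, hi = spec.repeat
        repeat_elem_ranges.append((lo, hi))
        repeat_elem_ranges.append((len(elements), len(elements) + hi - lo))
        elements = elements + elements[lo : hi + 1]

    total = sum(e.length for e in elements)
    if total < 30:
        raise ParameterError(
            f"element list yields only {total} residues; need at least 30"
        )

    rng = np.random.default_rng(spec.seed)
    truth = TruthLabels()

    # --- pass 1: layout. Assign each element its coordinates (loops deferred).
    side = -1            # geometric side the chain is currently on (-1 = inside)
    pred_side = "i"      # side label a topology predictor would assign
    x = 0.0              # axis position of the next packed helix, Å
    y_off = 0.0
    ca_parts: list[Optional[np.ndarray]] = []
    cb_parts: list[Optional[np.ndarray]] = []
    seq_parts: list[str] = []
    topo_parts: list[str] = []
    ss_parts: list[str] = []
    loop_slots: list[tuple[int, np.ndarray]] = []   # (part index, bulge vector)
    elem_spans: list[tuple[int, int]] = []
    elem_x: list[float] = []        # cursor x at each element's start
    pos = 1

    for ei, el in enumerate(elements):
        n = el.length
        elem_spans.append((pos, pos + n - 1))
        elem_x.append(x)
        if el.kind == "tm_helix":
            z0 = side * (SLAB_HALF + (RISE * (n - 1) - 2 * SLAB_HALF) / 2) \
                + el.z_shift
            tilt = math.radians(el.tilt_deg)
            axis = np.array([math.sin(tilt), 0.0, -side * math.cos(tilt)])
            # Centre the tilted helix on the slot in x.
            x_start = x - math.sin(tilt) * RISE * (n - 1) / 2
            start = np.array([x_start, y_off, z0])
            ca, cb = ideal_helix(start, axis, n)
            ca_parts.append(ca)
            cb_parts.append(cb)
            seq_parts.append(_tm_sequence(n, rng, spec.mu_tm_max))
            topo_parts.append("M" * n)
            ss_parts.append("H" * n)
            truth.tm_helices.append((pos, pos + n - 1))
            x += el.spacing if el.spacing is not None else SLOT_DX
            side = -side
            pred_side = "o" if pred_side == "i" else "i"
        elif el.kind == "reentrant_hairpin":
            limb1 = (n - el.turn) // 2
            limb2 = n - el.turn - limb1
            z_surface = side * SLAB_HALF
            z_deep1 = z_surface - side * RISE * (limb1 - 1)
            x1 = x
            x2 = x + SLOT_DX
            ca1, cb1 = ideal_helix(np.array([x1, y_off, z_surface]),
                                   np.array([0, 0, -side]), limb1)
            z_deep2 = z_surface - side * RISE * (limb2 - 1)
            ca2, cb2 = ideal_helix(np.array([x2, y_off, z_deep2]),
                                   np.array([0, 0, side]), limb2,
                                   phase_deg=180.0)
            tip1 = ca1[-1]
            tip2 = ca2[0]
            tca, tcb = _loop_coords(tip1, tip2, el.turn,
                                    np.array([0.0, 0.0, -side * 2.0]))
            ca_parts.append(np.vstack([ca1, tca, ca2]))
            cb_parts.append(np.vstack([cb1, tcb, cb2]))
            seq_parts.append(_hairpin_sequence(limb1, el.turn, limb2, rng))
            topo_parts.append("M" * n)
            ss_parts.append("H" * limb1 + "C" * el.turn + "H" * limb2)
            truth.reentrant.append((pos, pos + n - 1))
            truth.turns.append((pos + limb1, pos + limb1 + el.turn - 1))
            x += 2.0 * SLOT_DX
            pred_side = "o" if pred_side == "i" else "i"  # predictor mislabel
        elif el.kind == "amphipathic_helix":
            start = np.array([x, y_off + AMPHI_Y, side * AMPHI_Z])
            ca, cb = ideal_helix(start, np.array([1.0, 0, 0]), n)
            ca_parts.append(ca)
            cb_parts.append(cb)
            # Hydrophobic face toward the membrane: the helix frame for a
            # +x axis has u = +y, v = (axis x u) = -z... orient by side.
            face = 90.0 if side > 0 else 270.0
            seq_parts.append(
                _amphipathic_sequence(n, rng, face, spec.mu_amphi_min)
            )
            topo_parts.append(pred_side * n)
            ss_parts.append("H" * n)
            truth.amphipathic.append((pos, pos + n - 1))
        else:  # loop / domain_linker — coordinates resolved in pass 2
            ca_parts.append(None)
            cb_parts.append(None)
            bulge = np.array([0.0, 0.0, side * 4.0])
            loop_slots.append((ei, bulge))
            seq_parts.append("".join(rng.choice(list(_LOOP), size=n)))
            topo_parts.append(pred_side * n)
            ss_parts.append("C" * n)
            if el.kind == "domain_linker":
                # The planted boundary is the linker; its midpoint is the
                # single-residue representative recorded as truth.
                truth.boundaries.append(pos + n // 2)
                x += SLOT_DX
                y_off += 34.0
        pos += n

    # --- duplicated units: an inverted-topology repeat is the proper
    # 180-degree rotation (about the in-membrane x axis) of its template,
    # exactly the pseudo-2-fold relation of dual-topology folds, so the
    # intra-unit contact maps match.  Direct (even-crossing) units already
    # emerge as translated copies of the template and need no overwrite.
    duplicated: set[int] = set()
    if spec.repeat is not None:
        (src_lo, src_hi), (dst_lo, dst_hi) = repeat_elem_ranges
        crossings = sum(
            1 for el in elements[src_lo : src_hi + 1] if el.kind == "tm_helix"
        )
        if crossings % 2:
            dx = elem_x[dst_lo] - elem_x[src_lo]

            def _flip(arr: np.ndarray) -> np.ndarray:
                out = arr.copy()
                out[:, 0] += dx
                out[:, 1] = -out[:, 1]
                out[:, 2] = -out[:, 2]
                return out

            for src, dst in zip(range(src_lo, src_hi + 1),
                                range(dst_lo, dst_hi + 1)):
                duplicated.add(dst)

    # --- pass 2: fill loop coordinates between their neighbours' anchors.
    # Loops inside a rotated duplicate are filled from their template after
    # the structured elements have been overwritten.
    if duplicated:
        for src, dst in zip(range(src_lo, src_hi + 1),
                            range(dst_lo, dst_hi + 1)):
            if ca_parts[src] is not None:
                ca_parts[dst] = _flip(ca_parts[src])
                cb_parts[dst] = _flip(cb_parts[src])
    for ei, bulge in loop_slots:
        if ei in duplicated and elements[ei].kind in ("loop", "domain_linker"):
            continue  # filled from the template below
        n = elements[ei].length
        prev = next(
            (ca_parts[k][-1] for k in range(ei - 1, -1, -1)
             if ca_parts[k] is not None), None)
        nxt = next(
            (ca_parts[k][0] for k in range(ei + 1, len(elements))
             if ca_parts[k] is not None), None)
        if prev is None and nxt is None:
            prev = np.zeros(3)
            nxt = np.array([3.5 * (n + 1), 0.0, 0.0])
        elif prev is None:
            prev = nxt - np.array([3.5 * (n + 1), 0.0, 0.0])
        elif nxt is None:
            nxt = prev + np.array([3.5 * (n + 1), 0.0, 0.0])
        ca_parts[ei], cb_parts[ei] = _loop_coords(prev, nxt, n, bulge)
    if duplicated:
        for src, dst in zip(range(src_lo, src_hi + 1),
                            range(dst_lo, dst_hi + 1)):
            if ca_parts[dst] is None:
                ca_parts[dst] = _flip(ca_parts[src])
                cb_parts[dst] = _flip(cb_parts[src])

    sequence = Sequence(f"synthetic_seed{spec.seed}", "".join(seq_parts))
    ca = np.vstack(ca_parts)
    cb = np.vstack(cb_parts)
    residues = [
        ResidueRecord(
            index=k + 1,
            aa=sequence.residues[k],
            ca=tuple(ca[k]),
            cb=None if sequence.residues[k] == "G" else tuple(cb[k]),
        )
        for k in range(sequence.L)
    ]
    model = StructureModel(residues, id=sequence.id)

    if repeat_elem_ranges:
        for lo, hi in repeat_elem_ranges:
            truth.repeat_units.append((elem_spans[lo][0], elem_spans[hi][1]))
        lo, hi = repeat_elem_ranges[0]
        crossings = sum(
            1 for el in elements[lo : hi + 1] if el.kind == "tm_helix"
        )
        truth.repeat_orientation = "inverted" if crossings % 2 else "direct"

    from .validation import model_contacts  # single contact definition package-wide

    true_map = model_contacts(model)
    noisy_map = corrupt_map(true_map, spec.p_tp, spec.n_fp, seed=spec.seed)

    return SyntheticProtein(
        model=model,
        sequence=sequence,
        topology=TopologyProfile("".join(topo_parts)),
        ss=SSProfile("".join(ss_parts),
                     np.array([{"H": (0.94, 0.03, 0.03),
                                "E": (0.03, 0.94, 0.03),
                                "C": (0.03, 0.03, 0.94)}[s]
                               for s in "".join(ss_parts)])),
        true_map=true_map,
        noisy_map=noisy_map,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# noise model

def corrupt_map(true: ContactMap, p_tp: float, n_fp: int,
                seed: int = 0) -> ContactMap:
    """Corrupt a ground-truth map into a plausible prediction.

    Each true contact is retained independently with probability ``p_tp``
    and given a high confidence (uniform in [0.5, 1]); ``n_fp`` distinct
    false positives with sequence separation >= 5 are injected with lower
    confidences (uniform in [0.1, 0.5)).  Deterministic per seed.
    """
    if not (0.0 <= p_tp <= 1.0):
        raise ParameterError(f"p_tp must be in [0, 1], got {p_tp}")
    if n_fp < 0:
        raise ParameterError("n_fp must be >= 0")
    L = true.L
    true_pairs = true.pair_set()
    eligible_total = max(0, (L - 5) * (L - 4) // 2)
    n_true_sep = sum(1 for (i, j) in true_pairs if j - i >= 5)
    if n_fp > eligible_total - n_true_sep:
        raise ParameterError(
            f"n_fp={n_fp} exceeds the {eligible_total - n_true_sep} "
            f"available non-true pairs with separation >= 5"
        )
    rng = np.random.default_rng(seed)
    contacts: list[Contact] = []
    keep = rng.random(len(true.contacts)) < p_tp
    hi_scores = rng.uniform(0.5, 1.0, size=len(true.contacts))
    for k, c in enumerate(true.contacts):
        if keep[k]:
            contacts.append(Contact(c.i, c.j, float(hi_scores[k])))
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_fp:
        i = int(rng.integers(1, L - 4))
        j = int(rng.integers(i + 5, L + 1))
        if (i, j) not in true_pairs and (i, j) not in chosen:
            chosen.add((i, j))
    lo_scores = rng.uniform(0.1, 0.5, size=len(chosen))
    for k, (i, j) in enumerate(sorted(chosen)):
        contacts.append(Contact(i, j, float(lo_scores[k])))
    return ContactMap(L, contacts)


# ---------------------------------------------------------------------------
# fixture export

def write_fixture(protein: SyntheticProtein, outdir: str | Path,
                  prefix: str = "synthetic") -> dict[str, Path]:
    """Write a full on-disk fixture (FASTA, RR, ss2, topology, PDB, truth).

    The CLI pipeline runs on these files exactly as it would on real
    predictor output.
    """
    from . import io as fio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prefix}.fasta",
        "rr": outdir / f"{prefix}.rr",
        "ss2": outdir / f"{prefix}.ss2",
        "topology": outdir / f"{prefix}.topo",
        "pdb": outdir / f"{prefix}.pdb",
        "truth": outdir / f"{prefix}.truth.json",
    }
    fio.write_fasta(paths["fasta"], [protein.sequence])
    fio.write_casp_rr(paths["rr"], protein.noisy_map, protein.sequence)
    fio.write_ss2(paths["ss2"], protein.ss, protein.sequence)
    fio.write_topcons(paths["topology"], protein.topology, protein.sequence.id)
    fio.write_pdb_model(paths["pdb"], protein.model)
    fio.write_report_json(paths["truth"], asdict(protein.truth))
    return paths


# ---------------------------------------------------------------------------
# canned study conditions

def tm_bundle_spec(n_tm: int = 4, seed: int = 0, p_tp: float = 1.0,
                   n_fp: int = 0) -> SyntheticSpec:
    """An irregular n-TM helical bundle with no hairpins — the negative control.

    Helix lengths, loop lengths, packing distances and axial registers
    vary (cycling through fixed patterns), as they do in natural
    non-repetitive bundles; a perfectly regular bundle would itself be a
    planted two-fold repeat and could not serve as a repeat-free control.
    """
    tm_lens = (22, 19, 25, 21, 24, 20)
    loop_lens = (4, 9, 6, 11, 5)
    spacings = (8.8, 10.2, 9.2, 10.0, 9.6)
    z_shifts = (0.0, 2.0, -3.0, 1.0, -1.5, 2.5)
    tilts = (14.0, -22.0, 6.0, -17.0, 20.0, -9.0)
    elements: list[Element] = []
    for k in range(n_tm):
        elements.append(
            Element("tm_helix", tm_lens[k % len(tm_lens)],
                    spacing=spacings[k % len(spacings)],
                    z_shift=z_shifts[k % len(z_shifts)],
                    tilt_deg=tilts[k % len(tilts)])
        )
        if k < n_tm - 1:
            elements.append(Element("loop", loop_lens[k % len(loop_lens)]))
    return SyntheticSpec(tuple(elements), p_tp=p_tp, n_fp=n_fp, seed=seed)


def deda_like_spec(seed: int = 0, p_tp: float = 0.85,
                   n_fp: Optional[int] = None,
                   turn: int = 2) -> SyntheticSpec:
    """Two inverted units of amphipathic helix + re-entrant hairpin + TM helix.

    Emulates the proposed dual-topology transporter-like architecture:
    each 64-residue unit carries a surface amphipathic helix, a
    helix-turn-helix hairpin re-entering from the same side, and a full
    TM helix; the second unit sits with inverted membrane orientation.
    """
    unit = (
        Element("amphipathic_helix", 15),
        Element("loop", 4),
        Element("reentrant_hairpin", 20, turn=turn),
        Element("loop", 4),
        Element("tm_helix", 21),
    )
    elements = unit + (Element("loop", 4),)
    n_fp_val = n_fp if n_fp is not None else 26  # ~0.2 L for L = 132
    return SyntheticSpec(elements, repeat=(0, len(unit) - 1),
                         p_tp=p_tp, n_fp=n_fp_val, seed=seed)


def two_domain_spec(seed: int = 0, p_tp: float = 0.8,
                    n_fp: Optional[int] = None) -> SyntheticSpec:
    """Two helical domains joined by a linker centred on residue 60.

    Mirrors the study condition of a ~170-residue protein splitting into
    a small N-domain and a larger C-domain around residue 60.
    """
    elements = (
        Element("loop", 6),
        Element("tm_helix", 21),
        Element("loop", 8),
        Element("tm_helix", 21),
        Element("domain_linker", 7),
        Element("tm_helix", 21),
        Element("loop", 5),
        Element("tm_helix", 21),
        Element("loop", 5),
        Element("tm_helix", 21),
        Element("loop", 5),
        Element("tm_helix", 21),
    )
    L = sum(e.length for e in elements)
    n_fp_val = n_fp if n_fp is not None else int(round(0.2 * L))
    return SyntheticSpec(elements, p_tp=p_tp, n_fp=n_fp_val, seed=seed)


def tandem_repeat_spec(seed: int = 0, p_tp: float = 0.85,
                       n_fp: int = 0) -> SyntheticSpec:
    """Two identical 60-residue two-TM units in tandem (split truth b = 60)."""
    unit = (
        Element("loop", 4),
        Element("tm_helix", 21),
        Element("loop", 6),
        Element("tm_helix", 21),
        Element("loop", 8),
    )
    return SyntheticSpec(unit, repeat=(0, len(unit) - 1),
                         p_tp=p_tp, n_fp=n_fp, seed=seed)
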