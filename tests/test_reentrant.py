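"""Re-entrant helix candidates: broken-TM rule and packing orientation."""

import numpy as np
import pytest

from reentrant_scope import reentrant, synthetic as syn
from reentrant_scope.types import (
    Contact,
    ContactMap,
    InputError,
    ParameterError,
    SSProfile,
    TopologyProfile,
)


def _profiles(L, m_segments, coil_runs):
    """Topology with given M segments; ss helical except the given coil runs."""
    topo = ["i"] * L
    for (a, b) in m_segments:
        for k in range(a - 1, b):
            topo[k] = "M"
    ss = ["H"] * L
    for (a, b) in coil_runs:
        for k in range(a - 1, b):
            ss[k] = "C"
    return TopologyProfile("".join(topo)), SSProfile("".join(ss))


class TestFindBrokenTM:
    def test_central_coil_break_reported(self):
        topo, ss = _profiles(60, [(20, 44)], [(31, 32)])
        (cand,) = reentrant.find_broken_tm(topo, ss)
        assert cand.segment == (20, 44)
        assert cand.brk == (31, 32)
        assert cand.limb1 == (20, 30)
        assert cand.limb2 == (33, 44)

    def test_fully_helical_segment_yields_nothing(self):
        topo, ss = _profiles(60, [(20, 44)], [])
        assert reentrant.find_broken_tm(topo, ss) == []

    def test_overlong_coil_rejected(self):
        topo, ss = _profiles(60, [(20, 44)], [(28, 37)])  # 10-residue coil
        assert reentrant.find_broken_tm(topo, ss) == []

    def test_off_centre_break_rejected(self):
        topo, ss = _profiles(60, [(20, 44)], [(24, 25)])  # in first quarter
        assert reentrant.find_broken_tm(topo, ss) == []

    def test_short_limb_rejected(self):
        topo, ss = _profiles(60, [(20, 34)], [(26, 27)])
        # limbs 6 and 7 pass at min_limb=4 but fail at min_limb=8
        assert reentrant.find_broken_tm(topo, ss, min_limb=8) == []
        assert len(reentrant.find_broken_tm(topo, ss)) == 1

    def test_two_coil_runs_rejected(self):
        topo, ss = _profiles(60, [(20, 44)], [(27, 28), (36, 37)])
        assert reentrant.find_broken_tm(topo, ss) == []

    def test_length_mismatch_rejected(self):
        topo = TopologyProfile("iiMMMMii")
        ss = SSProfile("HHHH")
        with pytest.raises(InputError, match="length"):
            reentrant.find_broken_tm(topo, ss)


class TestPackingOrientation:
    def test_antiparallel_contacts(self):
        cmap = ContactMap(60, [Contact(10, 40, 1.0), Contact(11, 39, 1.0),
                               Contact(12, 38, 1.0)])
        rho, n = reentrant.packing_orientation(cmap, (8, 14), (36, 42))
        assert (rho, n) == (-1.0, 3)

    def test_parallel_contacts(self):
        cmap = ContactMap(60, [Contact(10, 38, 1.0), Contact(11, 39, 1.0),
                               Contact(12, 40, 1.0)])
        rho, n = reentrant.packing_orientation(cmap, (8, 14), (36, 42))
        assert (rho, n) == (1.0, 3)

    def test_insufficient_support(self):
        cmap = ContactMap(60, [Contact(10, 40, 1.0), Contact(11, 39, 1.0)])
        rho, n = reentrant.packing_orientation(cmap, (8, 14), (36, 42))
        assert rho is None and n == 2

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(3)
        contacts = [Contact(int(i), int(i + 25 + rng.integers(0, 6)), 1.0)
                    for i in range(10, 20)]
        cmap = ContactMap(60, contacts)
        r1 = reentrant.packing_orientation(cmap, (10, 20), (35, 45))
        r2 = reentrant.packing_orientation(cmap, (35, 45), (10, 20))
        assert r1 == r2

    def test_overlapping_segments_rejected(self):
        cmap = ContactMap(60, [Contact(10, 40, 1.0)])
        with pytest.raises(ParameterError, match="overlap"):
            reentrant.packing_orientation(cmap, (8, 20), (15, 30))


class TestScoreReentrant:
    def test_perfect_packing_scores_one(self):
        # partner precedes: limb1 antiparallel (rho -1), limb2 parallel (+1)
        topo, ss = _profiles(80, [(10, 30), (40, 64)], [(51, 52)])
        contacts = (
            [Contact(20 + k, 50 - k, 1.0) for k in range(4)]       # limb1 anti
            + [Contact(24 + k, 56 + k, 1.0) for k in range(4)]     # limb2 para
        )
        cmap = ContactMap(80, contacts)
        (cand,) = reentrant.find_broken_tm(topo, ss)
        scored = reentrant.score_reentrant(cand, cmap, [(10, 30)])
        assert scored.partner == (10, 30)
        assert scored.rho1 == -1.0 and scored.rho2 == 1.0
        assert scored.score == pytest.approx(1.0)

    def test_no_flanking_segment_keeps_candidate_with_note(self):
        topo, ss = _profiles(60, [(20, 44)], [(31, 32)])
        cmap = ContactMap(60, [Contact(5, 50, 1.0)])
        (cand,) = reentrant.find_broken_tm(topo, ss)
        scored = reentrant.score_reentrant(cand, cmap, [])
        assert scored.score == pytest.approx(reentrant.W_GEOM)
        assert scored.notes


class TestOnSyntheticProteins:
    def test_planted_hairpins_recovered_and_ranked_first(self, deda):
        cands = reentrant.detect_reentrants(deda.noisy_map, deda.topology,
                                            deda.ss)
        assert {c.segment for c in cands} == set(deda.truth.reentrant)
        turns = dict(zip(deda.truth.reentrant, deda.truth.turns))
        for c in cands:
            t = turns[c.segment]
            assert not (c.brk[1] < t[0] or c.brk[0] > t[1])  # break overlaps turn
        assert cands[0].segment in set(deda.truth.reentrant)

    def test_hairpin_free_bundle_yields_no_candidates(self):
        # deterministic rule: clean secondary structure -> zero candidates
        for seed in range(5):
            p = syn.build_protein(syn.tm_bundle_spec(seed=seed))
            assert reentrant.detect_reentrants(p.noisy_map, p.topology,
                                               p.ss) == []
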