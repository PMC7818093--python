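"""The planted-truth generator: determinism, geometry, noise model."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from reentrant_scope import synthetic as syn
from reentrant_scope.synthetic import Element, SyntheticSpec
from reentrant_scope.types import ParameterError, ResidueRecord, StructureModel
from reentrant_scope.validation import model_contacts


class TestSpecValidation:
    def test_too_short_protein_rejected(self):
        with pytest.raises(ParameterError, match="30"):
            syn.build_protein(SyntheticSpec((Element("tm_helix", 21),)))

    def test_hairpin_needs_limbs(self):
        with pytest.raises(ParameterError, match="limb"):
            Element("reentrant_hairpin", 9, turn=3)

    def test_element_min_length(self):
        with pytest.raises(ParameterError):
            Element("loop", 2)


class TestDeterminism:
    def test_same_spec_same_seed_identical(self):
        spec = syn.deda_like_spec(seed=4)
        a = syn.build_protein(spec)
        b = syn.build_protein(spec)
        assert a.sequence == b.sequence
        assert a.topology == b.topology
        assert a.ss.states == b.ss.states
        assert a.true_map.contacts == b.true_map.contacts
        assert a.noisy_map.contacts == b.noisy_map.contacts
        for ra, rb in zip(a.model.residues, b.model.residues):
            assert ra == rb

    def test_different_seed_differs(self):
        a = syn.build_protein(syn.deda_like_spec(seed=1))
        b = syn.build_protein(syn.deda_like_spec(seed=2))
        assert a.sequence.residues != b.sequence.residues


class TestConsistency:
    def test_all_tracks_share_length(self, deda):
        L = deda.sequence.L
        assert deda.topology.L == L
        assert deda.ss.L == L
        assert deda.model.L == L
        assert deda.true_map.L == L

    def test_true_map_is_geometric_contact_set(self, deda):
        assert deda.true_map.contacts == model_contacts(deda.model).contacts

    def test_bundle_topology_alternates_sides(self, bundle):
        segs = bundle.topology.segments
        labels = [lab for _, _, lab in segs]
        # M segments (one per TM helix) interleaved with alternating sides
        assert sum(lab == "M" for lab in labels) == 4
        sides = [lab for lab in labels if lab in "io"]
        assert sides and all(x != y for x, y in zip(sides, sides[1:]))

    def test_repeat_truth_marks_inverted_units(self, deda):
        assert len(deda.truth.repeat_units) == 2
        assert deda.truth.repeat_orientation == "inverted"
        (a1, b1), (a2, b2) = deda.truth.repeat_units
        assert b1 - a1 == b2 - a2  # identical unit lengths

    def test_amphipathic_moments_respect_thresholds(self, deda):
        from reentrant_scope.amphipathic import hydrophobic_moment

        spec = syn.deda_like_spec(seed=11)
        for (a, b) in deda.truth.amphipathic:
            window = deda.sequence.residues[a - 1 : b]
            assert hydrophobic_moment(window) > spec.mu_amphi_min
        for (a, b) in deda.truth.tm_helices:
            window = deda.sequence.residues[a - 1 : b]
            assert hydrophobic_moment(window) < spec.mu_tm_max


class TestPackingGeometry:
    """Packed helix pairs leave the canonical stripe orientations."""

    @staticmethod
    def _two_helix_model(direction_b):
        ca1, cb1 = syn.ideal_helix(np.array([0, 0, 0]), np.array([0, 0, 1]), 20)
        start_b = np.array([9.4, 0, 28.5 if direction_b[2] < 0 else 0])
        ca2, cb2 = syn.ideal_helix(start_b, np.array(direction_b), 20)
        ca = np.vstack([ca1, ca2])
        cb = np.vstack([cb1, cb2])
        residues = [
            ResidueRecord(k + 1, "A", tuple(ca[k]), tuple(cb[k]))
            for k in range(40)
        ]
        return StructureModel(residues)

    @pytest.mark.parametrize(
        "direction,expected_sign",
        [((0, 0, -1), -1), ((0, 0, 1), 1)],
        ids=["antiparallel", "parallel"],
    )
    def test_inter_helix_contact_rank_correlation(self, direction, expected_sign):
        model = self._two_helix_model(direction)
        cmap = model_contacts(model)
        pairs = [(c.i, c.j) for c in cmap.contacts if c.i <= 20 < c.j]
        assert len(pairs) >= 5
        rho = spearmanr([p[0] for p in pairs], [p[1] for p in pairs]).statistic
        assert np.sign(rho) == expected_sign
        assert abs(rho) > 0.8


class TestCorruptMap:
    def test_identity_when_no_noise(self, deda):
        out = syn.corrupt_map(deda.true_map, p_tp=1.0, n_fp=0, seed=9)
        assert out.pair_set() == deda.true_map.pair_set()

    def test_annihilation(self, deda):
        out = syn.corrupt_map(deda.true_map, p_tp=0.0, n_fp=0, seed=9)
        assert len(out) == 0

    def test_retained_score_high_injected_low(self, deda):
        out = syn.corrupt_map(deda.true_map, p_tp=0.7, n_fp=30, seed=9)
        true_pairs = deda.true_map.pair_set()
        for c in out.contacts:
            if (c.i, c.j) in true_pairs:
                assert c.score >= 0.5
            else:
                assert c.score < 0.5
                assert c.j - c.i >= 5

    def test_too_many_false_positives_rejected(self, deda):
        with pytest.raises(ParameterError, match="available"):
            syn.corrupt_map(deda.true_map, p_tp=1.0, n_fp=10**7, seed=0)

    def test_retention_matches_binomial_expectation(self, deda):
        # mean retained over many seeds ~ Binomial(n_true, p_tp) expectation
        n_true = len(deda.true_map)
        p_tp = 0.8
        retained = [
            sum(1 for c in syn.corrupt_map(deda.true_map, p_tp, 0, seed=s).contacts)
            for s in range(300)
        ]
        expected = p_tp * n_true
        sd_of_mean = np.sqrt(n_true * p_tp * (1 - p_tp)) / np.sqrt(300)
        assert abs(np.mean(retained) - expected) < 5 * sd_of_mean

    def test_deterministic_per_seed(self, deda):
        a = syn.corrupt_map(deda.true_map, 0.8, 20, seed=3)
        b = syn.corrupt_map(deda.true_map, 0.8, 20, seed=3)
        assert a.contacts == b.contacts


class TestFixtureExport:
    def test_fixture_files_reload_consistently(self, tmp_path, deda):
        from reentrant_scope import io as fio

        paths = syn.write_fixture(deda, tmp_path)
        seq = fio.read_fasta(paths["fasta"])[0]
        assert seq.residues == deda.sequence.residues
        cmap = fio.read_casp_rr(paths["rr"], seq.L)
        assert cmap.pair_set() == deda.noisy_map.pair_set()
        assert fio.read_topcons(paths["topology"]).labels == deda.topology.labels
        assert fio.read_ss2(paths["ss2"]).states == deda.ss.states
        model = fio.read_pdb_model(paths["pdb"])
        assert model.L == deda.model.L
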