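import math

import numpy as np
import pytest

import motifgrammar as mg
from motifgrammar.errors import ConfigurationError, DataError, ParseError


class TestSimulateMotifs:
    def test_fixed_length_batch(self, rng):
        spec = mg.MotifSimSpec(n_motifs=8, len_min=10, len_max=10, alpha=1.0)
        ms = mg.simulate_motifs(spec, rng)
        assert ms.ids == [f"motif_{k}" for k in range(8)]
        for m in ms:
            assert m.length == 10
            np.testing.assert_allclose(m.matrix.sum(axis=1), 1.0, atol=1e-9)
            assert (m.matrix >= 0).all()

    def test_huge_alpha_gives_uniform_columns(self, rng):
        spec = mg.MotifSimSpec(n_motifs=3, len_min=5, len_max=5, alpha=1e6)
        ms = mg.simulate_motifs(spec, rng)
        for m in ms:
            assert np.abs(m.matrix - 0.25).max() < 0.01

    def test_length_distribution_uniform(self, rng):
        # binomial CI: each of the 5 lengths has p=1/5 over n=10000 draws
        spec = mg.MotifSimSpec(n_motifs=10_000, len_min=3, len_max=7, alpha=1.0)
        ms = mg.simulate_motifs(spec, rng)
        lengths = np.array([m.length for m in ms])
        se = math.sqrt(0.2 * 0.8 / 10_000)
        for L in range(3, 8):
            assert abs((lengths == L).mean() - 0.2) < 3 * se

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError, match="n_motifs"):
            mg.MotifSimSpec(n_motifs=0, len_min=3, len_max=5)
        with pytest.raises(ConfigurationError, match="len_min"):
            mg.MotifSimSpec(n_motifs=1, len_min=6, len_max=5)
        with pytest.raises(ConfigurationError, match="alpha"):
            mg.MotifSimSpec(n_motifs=1, len_min=3, len_max=5, alpha=0.0)


class TestInformationContent:
    @pytest.mark.parametrize(
        "column,expected_bits",
        [
            ([0.25, 0.25, 0.25, 0.25], 0.0),
            ([1.0, 0.0, 0.0, 0.0], 2.0),
            ([0.5, 0.5, 0.0, 0.0], 1.0),
        ],
    )
    def test_single_column(self, column, expected_bits):
        m = mg.Motif("m", np.array([column]))
        per, mean = mg.information_content(m)
        assert per.shape == (1,)
        assert per[0] == pytest.approx(expected_bits, abs=1e-12)
        assert mean == pytest.approx(expected_bits, abs=1e-12)

    def test_bounds(self, simulated_motifs):
        for m in simulated_motifs:
            per, mean = mg.information_content(m)
            assert (per >= 0).all() and (per <= 2 + 1e-12).all()
            assert 0 <= mean <= 2


class TestConcentrationControl:
    def test_expected_ic_monotone_decreasing_in_alpha(self):
        ics = [
            mg.expected_information_content(a, 4, n_columns=50_000)
            for a in (0.1, 0.5, 1.0, 5.0, 50.0)
        ]
        assert all(a > b for a, b in zip(ics, ics[1:]))

    def test_calibration_hits_midrange_target(self):
        target = 1.0
        alpha = mg.calibrate_concentration(target, 4, tol=0.02)
        achieved = mg.expected_information_content(alpha, 4)
        assert abs(achieved - target) <= 0.05

    def test_limits(self):
        assert mg.calibrate_concentration(1.95, 4, tol=0.02) < 0.1
        alpha_flat = mg.calibrate_concentration(0.02, 4, tol=0.01)
        assert alpha_flat > 10
        assert abs(mg.expected_information_content(alpha_flat, 4) - 0.02) <= 0.01
        with pytest.raises(ConfigurationError):
            mg.calibrate_concentration(2.5, 4)
        with pytest.raises(ConfigurationError):
            mg.calibrate_concentration(0.0, 4)


class TestMultimerize:
    def _set(self, one_hot_motifs):
        return one_hot_motifs

    def test_positive_gap_filled_with_background(self, one_hot_motifs):
        rule = mg.MultimerRule(["motif_0", "motif_1"], spacings=[2])
        m = mg.multimerize(one_hot_motifs, rule)
        assert m.length == 8
        np.testing.assert_allclose(m.matrix[3], 0.25)
        np.testing.assert_allclose(m.matrix[4], 0.25)
        np.testing.assert_allclose(m.matrix[:3], one_hot_motifs["motif_0"].matrix)
        np.testing.assert_allclose(m.matrix[5:], one_hot_motifs["motif_1"].matrix)

    def test_negative_spacing_degenerate_weight(self, one_hot_motifs):
        rule = mg.MultimerRule(["motif_0", "motif_1"], spacings=[-1],
                               weights=[1.0, 0.0])
        m = mg.multimerize(one_hot_motifs, rule)
        assert m.length == 5
        # overlap column (position 2) equals first motif's last column: G
        np.testing.assert_allclose(m.matrix[2], [0, 0, 1, 0])

    def test_negative_spacing_equal_weights(self):
        ms = mg.MotifSet(alphabet=mg.DNA)
        ms.add(mg.Motif("a", np.array([[1, 0, 0, 0]] * 2, dtype=float)))
        ms.add(mg.Motif("b", np.array([[0, 1, 0, 0]] * 2, dtype=float)))
        rule = mg.MultimerRule(["a", "b"], spacings=[-1], weights=[1.0, 1.0])
        m = mg.multimerize(ms, rule)
        np.testing.assert_allclose(m.matrix[1], [0.5, 0.5, 0, 0])

    def test_single_component_identity(self, one_hot_motifs):
        rule = mg.MultimerRule(["motif_2"], spacings=[])
        m = mg.multimerize(one_hot_motifs, rule)
        np.testing.assert_allclose(m.matrix, one_hot_motifs["motif_2"].matrix)
        assert m.source == "multimer"

    def test_unknown_component(self, one_hot_motifs):
        rule = mg.MultimerRule(["nope"], spacings=[])
        with pytest.raises(ConfigurationError, match="nope"):
            mg.multimerize(one_hot_motifs, rule)

    def test_invalid_rules(self):
        with pytest.raises(ConfigurationError):
            mg.MultimerRule(["a", "b"], spacings=[])  # wrong spacing count
        with pytest.raises(ConfigurationError):
            mg.MultimerRule(["a"], spacings=[], weights=[0.0])


class TestMotifIO:
    def test_meme_roundtrip_identity(self, simulated_motifs, tmp_path):
        path = tmp_path / "motifs.meme"
        mg.write_meme(simulated_motifs, path)
        back = mg.read_motifs(path, "meme")
        assert back.ids == simulated_motifs.ids
        for mid in back.ids:
            assert back[mid].length == simulated_motifs[mid].length
            np.testing.assert_allclose(
                back[mid].matrix, simulated_motifs[mid].matrix, atol=1e-6
            )

    def test_jaspar_counts_normalized(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0000.1 TEST\n"
            "A [ 10  0  5 ]\n"
            "C [  0 10  5 ]\n"
            "G [  0  0  5 ]\n"
            "T [  0  0  5 ]\n"
        )
        ms = mg.read_motifs(path, "jaspar")
        m = ms["MA0000.1"]
        np.testing.assert_allclose(m.matrix[0], [1, 0, 0, 0])
        np.testing.assert_allclose(m.matrix[2], [0.25, 0.25, 0.25, 0.25])
        assert m.source == "imported"

    def test_jaspar_zero_sum_column_is_error(self, tmp_path):
        path = tmp_path / "z.jaspar"
        path.write_text(
            ">MA0001.1 Z\nA [ 1 0 ]\nC [ 0 0 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        )
        with pytest.raises(DataError, match="zero-sum"):
            mg.read_motifs(path, "jaspar")

    def test_meme_missing_alphabet_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text(
            "MEME version 4\n\nMOTIF m\n"
            "letter-probability matrix: alength= 4 w= 1 nsites= 1 E= 0\n"
            "0.25 0.25 0.25 0.25\n"
        )
        with pytest.raises(ParseError):
            mg.read_motifs(path, "meme")

    def test_meme_logodds_softmax_fallback(self, tmp_path):
        path = tmp_path / "lo.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF lod_0\n"
            "log-odds matrix: alength= 4 w= 2 nsites= 20 E= 0\n"
            "2.0 -10.0 -10.0 -10.0\n"
            "0.0 0.0 0.0 0.0\n"
        )
        ms = mg.read_motifs(path, "meme")
        m = ms["lod_0"]
        assert m.matrix[0, 0] > 0.99
        np.testing.assert_allclose(m.matrix[1], 0.25)
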