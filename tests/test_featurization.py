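"""Descriptor-matrix assembly, normalization, and the displacement layout."""

import numpy as np
import pytest

from duplexml.descriptors import UnknownTermError
from duplexml.featurization import (
    DescriptorFeaturizer,
    FeaturizationError,
    MatrixScaler,
    build_dataset,
    build_matrix,
    displacement_input,
    normalize_temperature,
    unpaired_probability,
)
from duplexml.pools import SequenceSet


class TestBuildMatrix:
    def test_perfect_duplex_shape_and_padding(self, term_table, energy_table):
        m = build_matrix("(CGCG)", term_table, energy_table, width=10)
        assert m.values.shape == (3, 10)
        assert m.n_populated == 5  # 3 stacking + 2 initiating
        assert np.all(m.values[:, 5:] == 0.0)

    def test_natural_width_has_no_padding(self, term_table, energy_table):
        m = build_matrix("(CGCG)", term_table, energy_table)
        assert m.width == m.n_populated == 5
        assert np.all(m.values[0, :] > 0)  # Number row populated everywhere

    def test_normalized_entries_in_unit_interval(self, term_table, energy_table):
        m = build_matrix("CT(CGCG)A.AA(CGCG)", term_table, energy_table)
        assert np.all(m.values >= 0.0) and np.all(m.values <= 1.0)

    def test_entropy_row_zero_for_perfect_duplex(self, term_table, energy_table):
        m = build_matrix("(CGCG)", term_table, energy_table)
        assert np.all(m.values[2] == 0.0)

    def test_width_too_small_rejected(self, term_table, energy_table):
        with pytest.raises(FeaturizationError):
            build_matrix("(CGCG)", term_table, energy_table, width=3)

    def test_unknown_token_named(self, term_table, energy_table):
        broken = dict(term_table.ids)
        del broken["(CGC"]
        from duplexml.descriptors import TermTable

        small = TermTable(ids=broken, kinds=term_table.kinds)
        with pytest.raises(UnknownTermError, match=r"\(CGC"):
            build_matrix("(CGCG)", small, energy_table)

    def test_column_order_is_kind_major(self, term_table, energy_table):
        m = build_matrix("CT(CGCG)A", term_table, energy_table, normalize=False)
        kinds = [d.kind for d in m.descriptors]
        assert kinds == ["stacking"] * 3 + ["dangling"] * 3 + ["initiating"] * 2


class TestDataset:
    def test_common_width_is_longest_descriptor_list(self, term_table, energy_table):
        strings = ["(CGCG)", "CT(CGCG)A", "(AT)"]
        X = build_dataset(strings, term_table, energy_table)
        widths = [5, 8, 3]
        assert X.shape == (3, 3, max(widths))
        for mat, w in zip(X, widths):
            assert np.count_nonzero(mat[0]) == w

    def test_order_permutation_does_not_change_matrices(self, term_table, energy_table):
        strings = ["(CGCG)", "CT(CGCG)A", "(ATGC)T"]
        X = build_dataset(strings, term_table, energy_table)
        X_perm = build_dataset(strings[::-1], term_table, energy_table)
        assert np.array_equal(X, X_perm[::-1])


class TestTemperatureScaler:
    @pytest.mark.parametrize(
        "temp,expected", [(13, 0.0), (25, 1 / 3), (37, 2 / 3), (49, 1.0)]
    )
    def test_design_range_mapping(self, temp, expected):
        assert normalize_temperature(temp) == pytest.approx(expected)


class TestUnpairedProbability:
    def test_perfect_duplex_all_zero(self):
        assert np.all(unpaired_probability("(CGCG)") == 0.0)

    def test_unpaired_strand_all_one(self):
        assert np.all(unpaired_probability("TTAACC") == 1.0)

    def test_override_reproduced_verbatim(self):
        values = [0.1, 0.5, 0.9, 1.0]
        assert unpaired_probability("AAAA", override=values).tolist() == values

    def test_override_length_mismatch_rejected(self):
        with pytest.raises(FeaturizationError):
            unpaired_probability("AAAA", override=[0.5, 0.5])

    def test_override_out_of_range_rejected(self):
        with pytest.raises(FeaturizationError):
            unpaired_probability("AAAA", override=[0.5, 0.5, 2.0, 0.5])


class TestDisplacementInput:
    def test_two_matrix_five_row_layout(self, term_table, energy_table):
        seqset = SequenceSet(id=0, toehold="ACGTA", spacer1="TT", branch="GCATGCATGCAT")
        X = displacement_input(
            seqset.invading_string, seqset.product_string, 37.0, term_table, energy_table
        )
        assert X.ndim == 3 and X.shape[0] == 2 and X.shape[1] == 5
        inv, prod = X
        # invader is fully unpaired: probability row is 1 on populated columns
        pop = inv[0] > 0
        assert np.all(inv[3, pop] == 1.0)
        # temperature row constant and normalized on populated columns
        assert np.allclose(inv[4, pop], 2 / 3)
        pop2 = prod[0] > 0
        assert np.allclose(prod[4, pop2], 2 / 3)
        # product spacers unpaired, stacks paired: prob row is mixed
        assert prod[3, pop2].max() == 1.0 and prod[3, pop2].min() == 0.0


class TestFeaturizerEstimator:
    def test_fit_freezes_width(self, energy_table):
        f = DescriptorFeaturizer(energy_table=energy_table)
        strings = ["(CGCG)", "CT(CGCG)A"]
        X = f.fit(strings).transform(strings)
        assert X.shape == (2, 3, 8)
        assert f.transform(["(AT)"]).shape == (1, 3, 8)

    def test_get_params_round_trip(self, energy_table):
        f = DescriptorFeaturizer(energy_table=energy_table, both_strands=True)
        params = f.get_params()
        assert params["both_strands"] is True
        f2 = DescriptorFeaturizer(**params)
        assert f2.get_params()["both_strands"] is True


class TestMatrixScaler:
    def test_scales_to_unit_interval_preserving_padding(self, term_table, energy_table):
        X = build_dataset(
            ["(CGCG)", "CT(CGCG)A", "(ATGC)T"],
            term_table,
            energy_table,
            normalize=False,
        )
        scaler = MatrixScaler().fit(X)
        Y = scaler.transform(X)
        pad = X[:, 0, :] == 0
        assert np.all(Y[:, :, :][np.broadcast_to(pad[:, None, :], Y.shape)] == 0)
        assert Y.min() >= 0.0 and Y.max() <= 1.0

    def test_frozen_scaler_is_reproducible_on_same_batch(self, term_table, energy_table):
        X = build_dataset(["(CGCG)", "CT(CGCG)A"], term_table, energy_table, normalize=False)
        scaler = MatrixScaler().fit(X)
        assert np.array_equal(scaler.transform(X), scaler.transform(X))

    def test_constant_row_maps_to_zero(self):
        X = np.ones((2, 2, 3))
        Y = MatrixScaler().fit(X).transform(X)
        assert np.all(Y == 0.0)

    def test_json_round_trip(self, term_table, energy_table, tmp_path):
        X = build_dataset(["(CGCG)", "CT(CGCG)A"], term_table, energy_table, normalize=False)
        scaler = MatrixScaler().fit(X)
        path = tmp_path / "scaler.json"
        scaler.to_json(path)
        back = MatrixScaler.from_json(path)
        assert np.array_equal(back.transform(X), scaler.transform(X))
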