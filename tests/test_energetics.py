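"""Energy assembly, counterpoise correction, and the averaging rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duplexml.descriptors import canonicalize_stacking, enumerate_terms
from duplexml.energetics import (
    DANGLING_COMPONENTS,
    STACKING_COMPONENTS,
    EnergeticsError,
    EnergyTable,
    InteractionEnergySet,
    counterpoise_pair_energy,
    dangling_term_energy,
    double_paren_contributors,
    fill_double_paren_terms,
    generate_synthetic_energy_table,
    stacking_term_energy,
)

finite = st.floats(min_value=-100, max_value=100, allow_nan=False)


class TestCounterpoise:
    def test_dimer_minus_monomers(self):
        assert counterpoise_pair_energy(-10.0, -4.0, -4.0) == -2.0
        assert counterpoise_pair_energy(0.0, 0.0, 0.0) == 0.0

    @given(finite, finite, finite)
    @settings(max_examples=100, deadline=None)
    def test_matches_direct_formula(self, e_ab, e_a, e_b):
        assert counterpoise_pair_energy(e_ab, e_a, e_b) == e_ab - e_a - e_b

    def test_non_finite_rejected(self):
        with pytest.raises(EnergeticsError):
            counterpoise_pair_energy(float("nan"), 0.0, 0.0)


def _ies(kind, components, values):
    return InteractionEnergySet(
        kind=kind,
        components={name: [(v, 0.0, 0.0)] for name, v in zip(components, values)},
    )


class TestTermAssembly:
    def test_stacking_linearity(self):
        ie = _ies("stacking", STACKING_COMPONENTS, [-1.0] * 6)
        assert stacking_term_energy(ie) == pytest.approx(-6.0)
        ie0 = _ies("stacking", STACKING_COMPONENTS, [0.0] * 6)
        assert stacking_term_energy(ie0) == 0.0

    @given(st.lists(finite, min_size=6, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_stacking_matches_sum_oracle(self, values):
        ie = _ies("stacking", STACKING_COMPONENTS, values)
        assert stacking_term_energy(ie) == pytest.approx(sum(values))

    @given(st.lists(finite, min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None)
    def test_dangling_matches_sum_oracle(self, values):
        ie = _ies("dangling", DANGLING_COMPONENTS, values)
        assert dangling_term_energy(ie) == pytest.approx(sum(values))

    def test_missing_component_named_in_error(self):
        ie = _ies("stacking", STACKING_COMPONENTS[:5], [-1.0] * 5)
        with pytest.raises(EnergeticsError, match="2-4"):
            stacking_term_energy(ie)

    def test_conformations_are_averaged(self):
        ie = InteractionEnergySet(
            kind="stacking",
            components={
                name: [(-2.0, 0.0, 0.0), (-4.0, 0.0, 0.0)]
                for name in STACKING_COMPONENTS
            },
        )
        assert stacking_term_energy(ie) == pytest.approx(6 * -3.0)

    def test_counterpoise_applied_per_component(self):
        ie = InteractionEnergySet(
            kind="dangling",
            components={name: [(-10.0, -4.0, -4.0)] for name in DANGLING_COMPONENTS},
        )
        assert dangling_term_energy(ie) == pytest.approx(3 * -2.0)


class TestDoubleParenRule:
    def test_exactly_24_contributors_of_25_combinations(self):
        for core in ("CG", "AT", "GG"):
            contributors = double_paren_contributors(core)
            assert len(contributors) == 24
            assert "(" + core + ")" not in contributors
            assert len(set(contributors) | {"(" + core + ")"}) == 25

    def test_mean_of_constants_is_constant(self):
        energies = {t: -30.0 for t in enumerate_terms("stacking")}
        table = fill_double_paren_terms(EnergyTable(energies=energies))
        assert table.energy("(CG)") == pytest.approx(-30.0)

    def test_matches_mean_oracle_on_random_inputs(self):
        rng = np.random.default_rng(5)
        energies = {
            t: float(rng.uniform(-50, -20)) for t in enumerate_terms("stacking")
        }
        table = fill_double_paren_terms(EnergyTable(energies=energies))
        for core in ("AA", "CT", "GC"):
            expected = np.mean([energies[t] for t in double_paren_contributors(core)])
            assert table.energy("(" + core + ")") == pytest.approx(expected)

    def test_other_entries_unchanged(self):
        rng = np.random.default_rng(6)
        energies = {
            t: float(rng.uniform(-50, -20)) for t in enumerate_terms("stacking")
        }
        table = fill_double_paren_terms(EnergyTable(energies=dict(energies)))
        for t, v in energies.items():
            if not (t[0] == "(" and t[-1] == ")"):
                assert table.energy(t) == v

    def test_missing_contributor_rejected(self):
        energies = {t: -30.0 for t in enumerate_terms("stacking")}
        del energies["ACGA"]
        with pytest.raises(EnergeticsError):
            fill_double_paren_terms(EnergyTable(energies=energies))


class TestSyntheticTable:
    def test_stacking_range_and_coverage(self, energy_table):
        vals = energy_table.stacking_values()
        assert vals.size == 400
        assert vals.min() >= -52.174 and vals.max() <= -20.615
        total = sum(len(enumerate_terms(k)) for k in
                    ("stacking", "dangling", "looping", "initiating"))
        assert len(energy_table.energies) == total == 449

    def test_zero_energy_terms(self, energy_table):
        for t in enumerate_terms("looping") + enumerate_terms("initiating"):
            assert energy_table.energy(t) == 0.0
        for t in enumerate_terms("dangling"):
            if t.startswith("*"):
                assert energy_table.energy(t) == 0.0
            else:
                assert -15.0 <= energy_table.energy(t) <= -2.0

    def test_deterministic_in_seed(self):
        a = generate_synthetic_energy_table(seed=3)
        b = generate_synthetic_energy_table(seed=3)
        c = generate_synthetic_energy_table(seed=4)
        assert a.energies == b.energies
        assert a.energies != c.energies

    def test_reverse_complement_classes_share_energy(self, energy_table):
        for token in enumerate_terms("stacking"):
            canonical = canonicalize_stacking(token)
            assert energy_table.energy(token) == energy_table.energy(canonical)

    def test_scaling_linearity_of_assembly(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(-5, 0, size=6)
        ie = _ies("stacking", STACKING_COMPONENTS, values)
        ie_scaled = _ies("stacking", STACKING_COMPONENTS, 3.0 * values)
        assert stacking_term_energy(ie_scaled) == pytest.approx(
            3.0 * stacking_term_energy(ie)
        )

    def test_invalid_range_rejected(self):
        with pytest.raises(EnergeticsError):
            generate_synthetic_energy_table(seed=0, range_lo=-10, range_hi=-20)

    def test_tsv_round_trip_bit_exact(self, energy_table, tmp_path):
        path = tmp_path / "energies.tsv"
        energy_table.to_tsv(path)
        assert EnergyTable.from_tsv(path).energies == energy_table.energies
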