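import numpy as np
import pytest

import omgnet as og
from omgnet import ConfigurationError, PatientRecord, SchemaError


class TestCountRecords:
    def test_empty_record_list_gives_zero_counts(self, structure):
        tables = og.count_records([], structure)
        assert set(tables) == set(structure.names)
        for t in tables.values():
            assert t.n_used == 0
            assert (t.counts == 0).all()

    def test_per_table_complete_case_semantics(self, structure):
        # sex observed but omg missing: counts toward the sex table only
        r = PatientRecord({"sex": "male"})
        tables = og.count_records([r], structure)
        assert tables["sex"].n_used == 1
        assert tables["omg"].n_used == 0
        # omg observed without sex: informs no table conditioned on sex
        r2 = PatientRecord({"omg": "positive", "ice": "positive"})
        tables2 = og.count_records([r2], structure)
        assert tables2["omg"].n_used == 0
        assert tables2["ice"].n_used == 1

    def test_undeclared_state_names_the_record(self, structure):
        bad = PatientRecord({"sex": "m"})
        with pytest.raises(SchemaError, match="record 0"):
            og.count_records([bad], structure)
        with pytest.raises(SchemaError, match="unknown variable"):
            og.count_records([PatientRecord({"hair": "brown"})], structure)

    def test_training_counts_from_expansion(self, structure, records):
        tables = og.count_records(records, structure)
        # 31 disease-positive cases had the pharmacologic test: 2 neg, 29 pos
        row = structure.row_index("edrophonium", {"omg": "positive"})
        assert tables["edrophonium"].counts[row].tolist() == [2, 29]
        assert tables["ice"].n_used == 51
        assert tables["sex"].counts[0].tolist() == [41, 48]


class TestFit:
    def test_concentration_is_prior_plus_count_exactly(self, structure, fixture_counts, model):
        for name in structure.names:
            expected = fixture_counts.tables[name].counts + 1.0
            assert np.array_equal(model.concentrations[name], expected)

    def test_zero_counts_give_uniform_dirichlet(self, structure):
        model = og.fit(og.count_records([], structure), structure, prior_strength=1.0)
        for name in structure.names:
            assert (model.concentrations[name] == 1.0).all()

    def test_missing_table_is_configuration_error(self, structure, fixture_counts):
        partial = {k: v for k, v in fixture_counts.tables.items() if k != "ice"}
        with pytest.raises(ConfigurationError, match="ice"):
            og.fit(partial, structure)

    def test_save_load_round_trip(self, model, tmp_path):
        path = tmp_path / "model.yaml"
        model.save(path)
        assert og.FittedModel.load(path) == model


class TestCpdSummary:
    def test_symmetric_uniform_row(self, structure):
        model = og.fit(og.count_records([], structure), structure)
        s = model.cpd_summary("sex", {}, "male")
        assert s.median == pytest.approx(0.5, abs=1e-12)
        assert s.q025 == pytest.approx(0.025, abs=1e-9)
        assert s.q975 == pytest.approx(0.975, abs=1e-9)

    def test_pharmacologic_test_row(self, model):
        # concentrations (3, 30): median ~91.7%, 95% interval ~(79%, 98%)
        s = model.cpd_summary("edrophonium", {"omg": "positive"}, "positive")
        assert 100 * s.median == pytest.approx(91.7, abs=0.05)
        assert 100 * s.q025 == pytest.approx(79.2, abs=0.1)
        assert 100 * s.q975 == pytest.approx(98.0, abs=0.1)

    def test_three_state_root_marginal_is_beta(self, model):
        # age concentrations (26, 31, 35): first-bin marginal is Beta(26, 66)
        s = model.cpd_summary("age", {}, "18-50")
        assert 100 * s.median == pytest.approx(28.1, abs=0.05)

    def test_undeclared_state_raises(self, model):
        with pytest.raises(SchemaError):
            model.cpd_summary("edrophonium", {"omg": "positive"}, "maybe")
        with pytest.raises(SchemaError):
            model.cpd_summary("edrophonium", {"omg": "unsure"}, "positive")


class TestSampleParameters:
    def test_rows_are_probability_vectors(self, structure, model):
        draws = model.sample_parameters(n_samples=50, seed=4)
        for name in structure.names:
            arr = draws[name]
            assert arr.shape == (50, structure.n_rows(name),
                                 len(structure[name].states))
            assert (arr >= 0).all()
            np.testing.assert_allclose(arr.sum(axis=2), 1.0, atol=1e-12)

    def test_same_seed_bitwise_identical(self, model):
        a = model.sample_parameters(n_samples=10, seed=123)
        b = model.sample_parameters(n_samples=10, seed=123)
        assert all(np.array_equal(a[n], b[n]) for n in a)

    def test_monte_carlo_quantiles_converge_to_exact(self, structure, model):
        # empirical quantiles of 1e5 Dirichlet draws vs exact Beta quantiles
        draws = model.sample_parameters(n_samples=100_000, seed=8)
        row = structure.row_index("edrophonium", {"omg": "positive"})
        s_idx = structure.state_index("edrophonium", "positive")
        sampled = draws["edrophonium"][:, row, s_idx]
        exact = model.cpd_summary("edrophonium", {"omg": "positive"}, "positive")
        assert np.median(sampled) == pytest.approx(exact.median, abs=0.01)
        assert np.quantile(sampled, 0.025) == pytest.approx(exact.q025, abs=0.01)
        assert np.quantile(sampled, 0.975) == pytest.approx(exact.q975, abs=0.01)

    def test_uniform_row_has_symmetric_mean(self, structure):
        model = og.fit(og.count_records([], structure), structure)
        draws = model.sample_parameters(n_samples=20_000, seed=2)
        assert draws["sex"][:, 0, 0].mean() == pytest.approx(0.5, abs=0.01)
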