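import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import placlock as pl
from conftest import make_sheet


def bicor_oracle(x, y):
    """Independent direct-formula biweight midcorrelation (test-local)."""
    def transform(v):
        m = np.median(v)
        d = np.median(np.abs(v - m))
        u = (v - m) / (9 * d)
        a = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - m) * a
    xt, yt = transform(np.asarray(x, float)), transform(np.asarray(y, float))
    return float(np.sum(xt * yt)
                 / (np.sqrt(np.sum(xt**2)) * np.sqrt(np.sum(yt**2))))


class TestBicor:
    def test_perfect_linear_and_antisymmetry(self):
        x = np.arange(1.0, 11.0)
        assert pl.bicor(x, 2 * x + 1) == pytest.approx(1.0)
        assert pl.bicor(x, -x) == pytest.approx(-1.0)

    def test_agrees_with_direct_formula_oracle(self):
        rng = np.random.default_rng(100)
        for _ in range(100):
            x, y = rng.normal(size=(2, 20))
            assert pl.bicor(x, y) == pytest.approx(bicor_oracle(x, y),
                                                   abs=1e-12)

    def test_matrix_form_matches_scalar_form(self):
        rng = np.random.default_rng(101)
        x = rng.uniform(6, 42, 30)
        Y = rng.random((30, 15))
        out = pl.bicor_matrix(x, Y)
        for j in range(15):
            assert out[j] == pytest.approx(pl.bicor(x, Y[:, j]), abs=1e-12)

    def test_zero_mad_falls_back_to_pearson(self):
        # >50% ties makes the median absolute deviation zero
        x = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, 1.1, 0.9, 1.0, 2.0, 3.0])
        assert pl.bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_constant_vector_is_nan(self):
        assert np.isnan(pl.bicor([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]))

    def test_equals_pearson_when_weights_are_uniform(self):
        # every deviation from the median has the same magnitude, so all
        # biweights coincide and medians equal means: bicor == Pearson
        x = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
        y = np.array([-1.0, -1.0, 1.0, -1.0, 1.0, 1.0])
        assert pl.bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1],
                                               abs=1e-12)
        assert pl.bicor(x, y) == pytest.approx(1.0 / 3.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounded_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 12))
        r = pl.bicor(x, y)
        assert -1.0 <= r <= 1.0
        assert pl.bicor(y, x) == pytest.approx(r, abs=1e-12)


class TestStouffer:
    def test_single_stratum_identity(self):
        assert pl.stouffer_meta([3.3], [50]) == pytest.approx(3.3)

    def test_equal_strata_closed_form(self):
        assert pl.stouffer_meta([2.0, 2.0], [100, 100]) == pytest.approx(
            2.0 * np.sqrt(2))

    def test_scale_invariance_in_sample_sizes(self):
        z, n = [1.5, -2.5, 0.7], [40, 160, 90]
        a = pl.stouffer_meta(z, n)
        b = pl.stouffer_meta(z, [10 * v for v in n])
        assert a == pytest.approx(b, rel=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(pl.ValidationError):
            pl.stouffer_meta([1.0, 2.0], [10])


class TestPFromZ:
    def test_zero_gives_one(self):
        assert pl.p_from_z(0.0) == 1.0

    def test_strictly_decreasing_in_magnitude(self):
        # strict above the double-precision underflow floor, monotone below
        zs = np.linspace(0, 37, 200)
        ps = pl.p_from_z(zs)
        assert (np.diff(ps) < 0).all()
        assert pl.p_from_z(39.0) <= ps[-1]

    def test_far_tail_does_not_underflow(self):
        assert pl.p_from_z(10.0) == pytest.approx(2 * stats.norm.sf(10.0),
                                                  rel=1e-10)
        assert pl.p_from_z(37.0) > 0.0

    def test_quantile_self_consistency(self):
        for p in [0.5, 1e-3, 1e-10, 1e-50, 1e-200, 1e-300]:
            z = float(stats.norm.isf(p / 2))
            assert pl.p_from_z(z) == pytest.approx(p, rel=1e-6)


class TestStratumScreen:
    def _dataset(self, n=20, seed=0, n_probes=5):
        rng = np.random.default_rng(seed)
        ga = np.linspace(10, 40, n)
        values = rng.random((n, n_probes))
        values[:, 0] = (ga - ga.min()) / (ga.max() - ga.min())  # exact signal
        beta = pl.BetaMatrix(values, [f"s{i}" for i in range(n)],
                             [f"cg{j}" for j in range(n_probes)])
        return beta, make_sheet(beta.sample_ids, ga=ga)

    def test_perfect_signal_probe(self):
        beta, sheet = self._dataset()
        tab = pl.stratum_screen(beta, sheet, "control")
        assert tab.loc["cg0", "p"] < 1e-10
        assert tab.loc["cg0", "z"] > 6
        assert (tab["n"] == 20).all()

    def test_z_and_p_mutually_consistent(self):
        rng = np.random.default_rng(3)
        beta = pl.BetaMatrix(rng.random((30, 40)),
                             [f"s{i}" for i in range(30)],
                             [f"cg{j}" for j in range(40)])
        sheet = make_sheet(beta.sample_ids, ga=rng.uniform(6, 42, 30))
        tab = pl.stratum_screen(beta, sheet, "control")
        ok = tab["z"].abs() < 8
        np.testing.assert_allclose(pl.p_from_z(tab.loc[ok, "z"].to_numpy()),
                                   tab.loc[ok, "p"], rtol=0, atol=1e-9)
        assert (np.sign(tab["z"]) == np.sign(tab["bicor"])).all()

    def test_null_probes_type_one_error_rate(self):
        rng = np.random.default_rng(4)
        n, p = 50, 1000
        beta = pl.BetaMatrix(rng.random((n, p)), [f"s{i}" for i in range(n)],
                             [f"cg{j}" for j in range(p)])
        sheet = make_sheet(beta.sample_ids, ga=rng.uniform(6, 42, n))
        tab = pl.stratum_screen(beta, sheet, "control")
        frac = (tab["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / p)

    def test_pairwise_complete_counts(self):
        beta, sheet = self._dataset()
        values = beta.values.copy()
        values[:4, 1] = np.nan
        beta2 = pl.BetaMatrix(values, beta.sample_ids, beta.probe_ids)
        tab = pl.stratum_screen(beta2, sheet, "control")
        assert tab.loc["cg1", "n"] == 16
        assert tab.loc["cg0", "n"] == 20

    def test_absent_stratum_raises(self):
        beta, sheet = self._dataset()
        with pytest.raises(pl.ValidationError, match="trisomy"):
            pl.stratum_screen(beta, sheet, "trisomy")


class TestRunEwas:
    def test_single_stratum_meta_equals_stratum(self):
        rng = np.random.default_rng(5)
        beta = pl.BetaMatrix(rng.random((25, 10)),
                             [f"s{i}" for i in range(25)],
                             [f"cg{j}" for j in range(10)])
        sheet = make_sheet(beta.sample_ids, ga=rng.uniform(6, 42, 25))
        tab = pl.run_ewas(beta, sheet, pl.EwasConfig(strata=["control"]))
        np.testing.assert_allclose(tab["meta_z"], tab["control_z"], atol=1e-12)
        np.testing.assert_allclose(tab["meta_p"], pl.p_from_z(tab["control_z"].to_numpy()))
        assert tab["meta_p"].is_monotonic_increasing

    def test_sample_order_invariance(self, presets):
        cfg = pl.SimConfig(n_samples=60, n_probes=40, n_clock_probes=10,
                           seed=6, conditions=[
                               pl.ConditionSpec("preeclampsia", 0.3)])
        beta, sheet, _ = pl.simulate_dataset(cfg)
        config = pl.EwasConfig(strata=["control", "preeclampsia"])
        a = pl.run_ewas(beta, sheet, config)
        rng = np.random.default_rng(7)
        perm = rng.permutation(beta.sample_ids).tolist()
        b = pl.run_ewas(beta.subset(samples=perm), sheet, config)
        pd.testing.assert_frame_equal(a, b.loc[a.index], atol=1e-12)

    def test_truth_ranked_first_and_null_controlled(self):
        cfg = pl.SimConfig(n_samples=200, n_probes=2000, n_clock_probes=40,
                           slope_range=(0.005, 0.02), seed=8)
        beta, sheet, truth = pl.simulate_dataset(cfg)
        tab = pl.run_ewas(beta, sheet, pl.EwasConfig(strata=["control"]))
        true = set(truth.clock_probe_ids)
        assert set(tab.index[:20]) <= true
        sig_null = tab.index[tab["significant"]].difference(true)
        assert len(sig_null) == 0  # expectation 2000 * 1e-7 << 1


class TestAnnotateAndTabulate:
    def _manifest(self):
        return pl.ProbeManifest(pd.DataFrame({
            "probe_id": ["cg1", "cg2", "cg3", "cg4"],
            "chromosome": ["1", "2", "3", "4"],
            "island_relation": ["Island", "Island", "N_Shore", "OpenSea"],
            "genes": ["GENE1;GENE2", "GENE2", "GENE3", ""],
        }))

    def _table(self, sig_probes, all_probes=("cg1", "cg2", "cg3", "cg4", "cg9")):
        return pd.DataFrame(
            {"significant": [p in sig_probes for p in all_probes]},
            index=pd.Index(all_probes, name="probe_id"))

    def test_island_counts(self):
        out = pl.annotate_and_tabulate(self._table({"cg1", "cg2", "cg3"}),
                                       self._manifest())
        assert out["island_relation_counts"] == {"Island": 2, "N_Shore": 1}

    def test_multigene_probe_counts_for_each_gene(self):
        out = pl.annotate_and_tabulate(self._table({"cg1", "cg2"}),
                                       self._manifest())
        assert out["gene_counts"] == {"GENE1": 1, "GENE2": 2}
        assert out["top_genes"][0] == ("GENE2", 2)

    def test_counts_conservation(self):
        out = pl.annotate_and_tabulate(
            self._table({"cg1", "cg3", "cg4", "cg9"}), self._manifest())
        annotated = out["n_significant"] - out["n_unannotated"]
        assert sum(out["island_relation_counts"].values()) == annotated
        assert out["n_unannotated"] == 1  # cg9 absent from the manifest
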