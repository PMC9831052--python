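"""Evaluation criteria, subsampling robustness, bootstrap comparison."""

import numpy as np
import pytest

from netshy import (
    DegenerateInputError,
    ProfileMatrix,
    ScheduleError,
    SimulationConfig,
    bootstrap_correlation_difference,
    correlation_with_phenotype,
    evaluate_methods,
    optimal_baseline,
    proportion_variance_explained,
    real_data_robustness,
    run_scenario1,
    subsampling_study,
    summarize_nonet,
)
from netshy.evaluate import write_results_table

from conftest import make_profiles


class TestCorrelation:
    def test_identical_vectors(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        assert correlation_with_phenotype(y, y) == pytest.approx(1.0)

    def test_sign_flip_gives_absolute_value(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        assert correlation_with_phenotype(-y, y) == pytest.approx(1.0)

    def test_matches_hand_computed_pearson(self):
        z = np.array([1.0, 2.0, 4.0, 3.0, 6.0, 5.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0, 9.0])
        zc, yc = z - z.mean(), y - y.mean()
        expected = abs(np.sum(zc * yc) / np.sqrt(np.sum(zc**2) * np.sum(yc**2)))
        assert correlation_with_phenotype(z, y) == pytest.approx(expected)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlation_with_phenotype(np.ones(5), np.arange(5.0))


class TestPVE:
    def test_single_active_column_basis_vector(self):
        V = np.zeros((6, 3))
        V[:, 1] = np.arange(6.0)
        X0 = ProfileMatrix(tuple(f"s{i}" for i in range(6)), tuple("abc"), V)
        phi = np.array([0.0, 1.0, 0.0])
        assert proportion_variance_explained(phi, X0) == pytest.approx(1.0)

    def test_top_singular_vector_gives_spectral_ratio(self, profiles_8x5):
        C = profiles_8x5.values - profiles_8x5.values.mean(axis=0)
        s = np.linalg.svd(C, compute_uv=False)
        phi = np.linalg.svd(C)[2][0]
        expected = s[0] ** 2 / np.sum(s**2)
        assert proportion_variance_explained(phi, profiles_8x5) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_no_unit_loading_beats_top_direction(self, seed, profiles_8x5):
        C = profiles_8x5.values - profiles_8x5.values.mean(axis=0)
        top = np.linalg.svd(C)[2][0]
        bound = proportion_variance_explained(top, profiles_8x5)
        rng = np.random.default_rng(seed)
        for _ in range(50):
            phi = rng.standard_normal(5)
            phi /= np.linalg.norm(phi)
            assert proportion_variance_explained(phi, profiles_8x5) <= bound + 1e-12

    def test_non_unit_loading_rejected(self, profiles_8x5):
        with pytest.raises(DegenerateInputError, match="unit"):
            proportion_variance_explained(np.full(5, 0.9), profiles_8x5)


class TestOptimalBaseline:
    def test_composes_summarizer_and_criteria(self, profiles_8x5):
        y = np.random.default_rng(0).standard_normal(8)
        rho_opt, pve_opt, res = optimal_baseline(profiles_8x5, y)
        direct = summarize_nonet(profiles_8x5)
        assert rho_opt == pytest.approx(
            correlation_with_phenotype(direct.scores, y)
        )
        assert pve_opt == pytest.approx(
            proportion_variance_explained(direct.loading, profiles_8x5)
        )
        assert res.method == "opt"

    def test_rank_one_noiseless_extreme(self):
        u = np.array([0.2, -1.0, 0.7, 2.0, -0.5])
        v = np.array([0.8, 0.6])
        X0 = ProfileMatrix(
            tuple(f"s{i}" for i in range(5)), ("a", "b"), np.outer(u, v)
        )
        scores = summarize_nonet(X0).scores
        rho_opt, pve_opt, _ = optimal_baseline(X0, scores)
        assert rho_opt == pytest.approx(1.0)
        assert pve_opt == pytest.approx(1.0)


class TestEvaluateMethods:
    def test_noise_free_observation_attains_optimum(self):
        config = SimulationConfig(p=12, n_master=80, sigma_e=0.0, seed=2)
        ds = run_scenario1(config)
        by_method = {r.method: r for r in evaluate_methods(ds)}
        assert by_method["nonet"].rho_ratio == pytest.approx(1.0, abs=1e-8)
        assert by_method["nonet"].pve_ratio == pytest.approx(1.0, abs=1e-8)

    def test_subject_reordering_invariance(self):
        ds = run_scenario1(SimulationConfig(p=10, n_master=60, seed=3))
        perm = np.random.default_rng(1).permutation(60)
        from netshy import SimulatedDataset

        ds_perm = SimulatedDataset(
            net=ds.net,
            model=ds.model,
            X0=ds.X0.take_subjects(perm),
            X=ds.X.take_subjects(perm),
            Y0=ds.Y0[perm],
            beta0=ds.beta0,
            beta=ds.beta,
            config=ds.config,
        )
        for a, b in zip(evaluate_methods(ds), evaluate_methods(ds_perm)):
            assert a.method == b.method
            assert a.rho == pytest.approx(b.rho, abs=1e-9)
            assert a.pve == pytest.approx(b.pve, abs=1e-9)

    def test_hub_included_on_request(self):
        ds = run_scenario1(SimulationConfig(p=10, n_master=50, seed=1))
        methods = {r.method for r in evaluate_methods(ds, include_hub=True)}
        assert methods == {"nonet", "netshy", "hub"}


@pytest.fixture(scope="module")
def small_ds():
    return run_scenario1(SimulationConfig(p=10, n_master=300, seed=11))


class TestSubsamplingStudy:
    def test_bit_reproducible(self, small_ds):
        a = subsampling_study(small_ds, sizes=(100, 50), iterations=20, seed=5)
        b = subsampling_study(small_ds, sizes=(100, 50), iterations=20, seed=5)
        assert a.table.equals(b.table)

    def test_near_master_subsamples_vary_less_than_small_ones(self, small_ds):
        # 295-of-300 subsets overlap almost completely, so per-iteration
        # criteria are nearly constant compared with 50-subject subsets
        st = subsampling_study(small_ds, sizes=(295, 50), iterations=40, seed=0)
        for method in ("nonet", "netshy"):
            for metric in ("rho_ratio", "pve_ratio"):
                assert st.stat(method, metric, 295, "sd") < st.stat(
                    method, metric, 50, "sd"
                )

    def test_pve_ratio_never_exceeds_one(self, small_ds):
        st = subsampling_study(small_ds, sizes=(100, 50), iterations=30, seed=2)
        pve = st.table[st.table["metric"] == "pve_ratio"]["mean"]
        assert (pve <= 1.0 + 1e-8).all()

    def test_reduced_iterations_agree_within_monte_carlo_error(self, small_ds):
        lo = subsampling_study(small_ds, sizes=(60,), iterations=100, seed=3)
        hi = subsampling_study(small_ds, sizes=(60,), iterations=400, seed=4)
        for method in ("nonet", "netshy"):
            for metric in ("rho_ratio", "pve_ratio"):
                m_lo = lo.stat(method, metric, 60)
                m_hi = hi.stat(method, metric, 60)
                se = lo.stat(method, metric, 60, "sd") / np.sqrt(100)
                assert abs(m_lo - m_hi) < 4 * se

    def test_oversized_schedule_rejected(self, small_ds):
        with pytest.raises(ScheduleError):
            subsampling_study(small_ds, sizes=(400,), iterations=5, seed=0)

    def test_results_table_round_trip(self, small_ds, tmp_path):
        import pandas as pd

        st = subsampling_study(small_ds, sizes=(50,), iterations=10, seed=0)
        path = tmp_path / "results.tsv"
        write_results_table(st, path, scenario="1", p=10, alpha0=0.3)
        back = pd.read_csv(path, sep="\t")
        assert len(back) == len(st.table)
        assert set(back["metric"]) == {"rho_ratio", "pve_ratio"}


@pytest.fixture(scope="module")
def xy():
    ds = run_scenario1(SimulationConfig(p=10, n_master=200, seed=21))
    return ds.X, ds.net, ds.Y0


class TestRealDataRobustness:
    def test_reports_raw_rho_only(self, xy):
        X, net, Y = xy
        st = real_data_robustness(X, net, Y, sizes=(80, 40), iterations=10, seed=0)
        assert set(st.table["metric"]) == {"rho"}
        assert set(st.table["method"]) == {"nonet", "netshy"}

    def test_deterministic_and_dropping_rate_computable(self, xy):
        X, net, Y = xy
        a = real_data_robustness(X, net, Y, sizes=(80, 40), iterations=15, seed=1)
        b = real_data_robustness(X, net, Y, sizes=(80, 40), iterations=15, seed=1)
        assert a.table.equals(b.table)
        for method in ("nonet", "netshy"):
            drop = a.stat(method, "rho", 200) - a.stat(method, "rho", 40)
            assert np.isfinite(drop)


class TestBootstrap:
    def test_p_value_within_bounds(self):
        ds = run_scenario1(SimulationConfig(p=8, n_master=60, seed=31))
        p = bootstrap_correlation_difference(ds.X, ds.net, ds.Y0, B=100, seed=0)
        assert 1 / 100 <= p <= 1.0

    def test_deterministic_given_seed(self):
        ds = run_scenario1(SimulationConfig(p=8, n_master=60, seed=32))
        a = bootstrap_correlation_difference(ds.X, ds.net, ds.Y0, B=100, seed=7)
        b = bootstrap_correlation_difference(ds.X, ds.net, ds.Y0, B=100, seed=7)
        assert a == b

    def test_rejects_tiny_resample_count(self):
        ds = run_scenario1(SimulationConfig(p=8, n_master=60, seed=33))
        with pytest.raises(ValueError):
            bootstrap_correlation_difference(ds.X, ds.net, ds.Y0, B=10, seed=0)

    def test_level_is_valid_under_independence_null(self):
        # the absolute-correlation difference sits at the |.|-kink under
        # this null, which makes the percentile bootstrap conservative;
        # the guarantee it does give is that rejections stay below level
        pvals = []
        for s in range(60):
            ds = run_scenario1(
                SimulationConfig(p=8, alpha0=0.5, n_master=100, seed=700 + s)
            )
            y = np.random.default_rng(900 + s).standard_normal(100)
            pvals.append(
                bootstrap_correlation_difference(ds.X, ds.net, y, B=100, seed=s)
            )
        assert np.mean(np.asarray(pvals) <= 0.05) <= 0.05 + 2 * np.sqrt(
            0.05 * 0.95 / 60
        )
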