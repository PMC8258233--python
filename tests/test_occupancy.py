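import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from avisurvey import occupancy as occ
from avisurvey import survey_data as sd


def make_history(n_sites=8, n_occ=5, seed=0, aru_block=True,
                 zero_covariates=False) -> occ.DetectionHistory:
    """Random small history; occasions 1..n_occ-1 of the ARU block carry the
    within-day lag structure."""
    rng = np.random.default_rng(seed)
    shape = (n_sites, n_occ)
    z = (lambda: np.zeros(shape)) if zero_covariates else (lambda: rng.normal(0, 1, shape))
    method = np.zeros(shape)
    lag_prev = np.zeros(shape, dtype=bool)
    if aru_block:
        method[:, 1:] = 1.0          # occasion 0 is a PC, the rest one ARU day
        lag_prev[:, 2:] = True
    dh = occ.DetectionHistory(
        family="fam", site_ids=[f"s{i}" for i in range(n_sites)],
        y=np.zeros(shape), method=method, wind=z(), hour=z(), date=z(),
        canopy=z(), lag=np.zeros(shape), lag_prev=lag_prev,
        elevation=rng.normal(0, 1, n_sites) if not zero_covariates else np.zeros(n_sites),
        canopy_resid=rng.normal(0, 1, n_sites) if not zero_covariates else np.zeros(n_sites),
        scalers={k: (0.0, 1.0) for k in
                 ("wind", "hour", "date", "canopy", "elevation", "canopy_resid")},
    )
    return dh


def sim_history(dh, spec, params, seed):
    """Simulate detections (with proper sequential lag) from given parameters."""
    dummy = occ.OccupancyFit(spec=spec, params=np.asarray(params, float),
                             param_names=[], vcov=None, loglik=0.0,
                             K=len(params), converged=True, n_sites=dh.n_sites,
                             scalers=dh.scalers)
    return occ.simulate_history(dummy, dh, np.random.default_rng(seed))


def latent_state_loglik(params, dh, spec):
    """Oracle: explicit sum over the latent occupancy state per site."""
    X_psi, X_det, _ = occ.build_design(dh, spec)
    n_psi = X_psi.shape[1]
    alpha, beta = params[:n_psi], params[n_psi:]
    total = 0.0
    for i in range(dh.n_sites):
        psi = expit(X_psi[i] @ alpha)
        lik = 0.0
        for zstate in (0, 1):
            pz = psi if zstate else 1 - psi
            cond = 1.0
            for j in range(dh.n_occasions):
                if np.isnan(dh.y[i, j]):
                    continue
                p = expit(X_det[i, j] @ beta) if zstate else 0.0
                yij = dh.y[i, j]
                cond *= p if yij == 1 else 1 - p
            lik += pz * cond
        total += np.log(lik)
    return total


BASE = occ.ModelSpec("baseline")


class TestLoglik:
    def test_perfect_detection_zero_loglik(self):
        dh = make_history(n_sites=1, n_occ=2, zero_covariates=True, aru_block=False)
        dh.y[:] = 1.0
        k = len(BASE.occupancy_terms()) + len(BASE.detection_terms())
        params = np.zeros(k)
        params[0] = 500.0   # psi intercept
        params[3] = 500.0   # p intercept
        assert occ.loglik(params, dh, BASE) == pytest.approx(0.0, abs=1e-9)

    def test_hand_value_half_half(self):
        # psi = p = 0.5, one site, y = (0, 0): L = 0.5 * 0.25 + 0.5 = 0.625
        dh = make_history(n_sites=1, n_occ=2, zero_covariates=True, aru_block=False)
        dh.y[:] = 0.0
        k = len(BASE.occupancy_terms()) + len(BASE.detection_terms())
        assert occ.loglik(np.zeros(k), dh, BASE) == pytest.approx(np.log(0.625))

    def test_matches_latent_state_oracle(self):
        rng = np.random.default_rng(5)
        for rep in range(30):
            n_occ = int(rng.integers(2, 13))
            dh = make_history(n_sites=int(rng.integers(2, 7)), n_occ=n_occ, seed=rep)
            spec = occ.model_set()[int(rng.integers(0, 9))]
            k = len(spec.occupancy_terms()) + len(spec.detection_terms())
            params = rng.normal(0, 1, k)
            dh = sim_history(dh, spec, params, seed=1000 + rep)
            # knock out a few occasions to exercise missing handling
            miss = rng.random(dh.y.shape) < 0.15
            dh.y[miss] = np.nan
            assert occ.loglik(params, dh, spec) == pytest.approx(
                latent_state_loglik(params, dh, spec), abs=1e-10)

    def test_lag_zero_reduces_to_standard_model(self):
        # with the lag coefficient at 0, permuting within-day occasion order
        # leaves the likelihood unchanged (standard single-season model)
        dh = make_history(n_sites=6, n_occ=5, seed=3)
        spec = BASE
        k = len(spec.occupancy_terms()) + len(spec.detection_terms())
        rng = np.random.default_rng(4)
        params = rng.normal(0, 1, k)
        params[3 + 8] = 0.0  # lag coefficient
        dh = sim_history(dh, spec, params, seed=9)
        ll = occ.loglik(params, dh, spec)
        perm = rng.permutation(dh.n_occasions)
        dh2 = make_history(n_sites=6, n_occ=5, seed=3)
        for attr in ("y", "method", "wind", "hour", "date", "canopy"):
            setattr(dh2, attr, getattr(dh, attr)[:, perm])
        dh2.lag = np.zeros_like(dh.lag)
        dh2.lag_prev = np.zeros_like(dh.lag_prev)
        assert occ.loglik(params, dh2, spec) == pytest.approx(ll, abs=1e-9)

    def test_nonfinite_covariates_error(self):
        dh = make_history()
        dh.wind[0, 0] = np.inf
        k = len(BASE.occupancy_terms()) + len(BASE.detection_terms())
        with pytest.raises(ValueError, match="non-finite"):
            occ.loglik(np.zeros(k), dh, BASE)


class TestModelSet:
    def test_exactly_nine_models(self):
        specs = occ.model_set()
        assert len(specs) == 9
        assert len({s.name for s in specs}) == 9

    def test_baseline_terms(self):
        terms = occ.ModelSpec("baseline").detection_terms()
        assert terms == ["(Intercept)", "wind", "hour", "hour2", "date",
                         "date2", "canopy", "canopy2", "lag"]

    def test_interaction_requires_main_effect(self):
        with pytest.raises(ValueError):
            occ.ModelSpec("bad", method_effect=False, interactions=("date",))

    def test_full_model_is_largest(self):
        specs = occ.model_set()
        assert max(s.K for s in specs) == occ.full_model().K == 12 + 1 + 6


class TestBuildHistory:
    def test_occasion_count_range(self, bc_dataset):
        dh = occ.build_history(bc_dataset, "Parulidae", ("montane", "subalpine"))
        counts = dh.mask.sum(axis=1)
        assert counts.min() == 3      # PC-only sites
        assert counts.max() == 23     # 5 x 4-day ARU + 3 PC

    def test_pc_occasions_have_zero_lag(self, bc_dataset):
        dh = occ.build_history(bc_dataset, "Parulidae", ("montane", "subalpine"))
        assert not dh.lag_prev[dh.method == 0].any()
        assert (dh.lag[dh.method == 0] == 0).all()

    def test_first_of_day_lag_zero(self, bc_dataset):
        dh = occ.build_history(bc_dataset, "Turdidae", ("montane", "subalpine"))
        first_aru = (dh.method == 1) & ~dh.lag_prev
        assert (dh.lag[first_aru] == 0).all()

    def test_all_zero_rows_retained(self, bc_dataset):
        dh = occ.build_history(bc_dataset, "Regulidae", ("montane", "subalpine"))
        assert (np.nansum(dh.y, axis=1) == 0).any()
        assert dh.n_sites == (bc_dataset.sites["habitat"]
                              .isin(["montane", "subalpine"])).sum()

    def test_unknown_family_errors(self, bc_dataset):
        with pytest.raises(ValueError, match="absent"):
            occ.build_history(bc_dataset, "Nosuchidae", ("montane",))


class TestFit:
    def test_recovers_intercepts_single_run(self):
        dh = make_history(n_sites=400, n_occ=5, seed=11)
        k = len(BASE.occupancy_terms()) + len(BASE.detection_terms())
        true = np.zeros(k)
        true[0] = logit(0.6)
        true[3] = logit(0.35)
        dh = sim_history(dh, BASE, true, seed=12)
        f = occ.fit(BASE, dh, seed=13)
        assert expit(f.params[0]) == pytest.approx(0.6, abs=0.12)
        assert expit(f.params[3]) == pytest.approx(0.35, abs=0.08)
        assert f.K == k

    def test_site_order_invariance(self):
        dh = make_history(n_sites=40, n_occ=5, seed=21)
        k = len(BASE.occupancy_terms()) + len(BASE.detection_terms())
        true = np.zeros(k)
        true[0], true[3] = 0.3, -0.4
        dh = sim_history(dh, BASE, true, seed=22)
        f1 = occ.fit(BASE, dh, seed=1)
        perm = np.random.default_rng(2).permutation(dh.n_sites)
        for attr in ("y", "method", "wind", "hour", "date", "canopy", "lag", "lag_prev"):
            setattr(dh, attr, getattr(dh, attr)[perm])
        dh.elevation = dh.elevation[perm]
        dh.canopy_resid = dh.canopy_resid[perm]
        f2 = occ.fit(BASE, dh, seed=1)
        assert f1.params == pytest.approx(f2.params, abs=1e-4)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-7)

    def test_insufficient_data_errors(self):
        dh = make_history(n_sites=3, n_occ=4, seed=31)
        dh.y[:] = 0.0
        dh.y[0, 0] = 1.0
        with pytest.raises(occ.DataInsufficientError):
            occ.fit(BASE, dh)


class TestChatQaic:
    def test_qaic_hand_values(self):
        assert occ.qaic(-100.0, 1.0, K=5) == pytest.approx(212.0)
        assert occ.qaic(-100.0, 2.0, K=5) == pytest.approx(112.0)

    def test_chat_floor_at_one(self):
        assert occ.qaic(-100.0, 0.5, K=5) == occ.qaic(-100.0, 1.0, K=5)

    def test_qaic_reduces_to_aic_at_one(self):
        dh = make_history(n_sites=60, n_occ=5, seed=41)
        k = len(BASE.occupancy_terms()) + len(BASE.detection_terms())
        true = np.zeros(k)
        true[0], true[3] = 0.5, 0.0
        dh = sim_history(dh, BASE, true, seed=42)
        f = occ.fit(BASE, dh, seed=43)
        assert occ.qaic(f, 1.0) == pytest.approx(f.aic + 2.0)  # +2 for c-hat

    def test_chat_seed_determinism(self):
        dh = make_history(n_sites=50, n_occ=5, seed=51)
        k = len(BASE.occupancy_terms()) + len(BASE.detection_terms())
        true = np.zeros(k)
        true[0], true[3] = 0.8, -0.2
        dh = sim_history(dh, BASE, true, seed=52)
        f = occ.fit(BASE, dh, seed=53)
        c1 = occ.estimate_chat(f, dh, n_boot=15, seed=7)
        c2 = occ.estimate_chat(f, dh, n_boot=15, seed=7)
        assert c1 == c2 and c1 > 0

    def test_all_zero_history_errors(self):
        dh = make_history(n_sites=5, n_occ=4, seed=61)
        dh.y[:] = 0.0
        f = occ.OccupancyFit(spec=BASE, params=np.zeros(12), param_names=[],
                             vcov=None, loglik=0.0, K=12, converged=True,
                             n_sites=5, scalers=dh.scalers)
        with pytest.raises(ValueError):
            occ.estimate_chat(f, dh, n_boot=5, seed=1)


class TestSelectModel:
    def _fitted_history(self, seed=71):
        dh = make_history(n_sites=80, n_occ=6, seed=seed)
        k = len(BASE.occupancy_terms()) + len(BASE.detection_terms())
        true = np.zeros(k)
        true[0], true[3] = 0.6, -0.1
        return sim_history(dh, BASE, true, seed=seed + 1)

    def test_flags(self):
        dh = self._fitted_history()
        _, _, flag_hi = occ.select_model(dh, chat=5.0, n_starts=2, seed=1)
        assert flag_hi == "lack_of_fit"
        _, _, flag_lo = occ.select_model(dh, chat=0.2, n_starts=2, seed=1)
        assert flag_lo == "insufficient_data"
        _, _, flag_ok = occ.select_model(dh, chat=1.0, n_starts=2, seed=1)
        assert flag_ok is None

    def test_table_ranked_and_complete(self):
        dh = self._fitted_history(81)
        table, best, _ = occ.select_model(dh, chat=1.0, n_starts=2, seed=2)
        assert len(table) == 9
        assert (table["QAIC"].diff().dropna() >= -1e-9).all()
        assert table.loc[0, "dQAIC"] == 0.0
        assert best.spec.name == table.loc[0, "model"]


class TestSimulationChecks:
    def test_chat_self_consistency(self):
        # data simulated from the fitted model itself -> c-hat near 1 on average
        true = np.zeros(12)
        true[0], true[3] = 0.8, -0.4
        chats = []
        for r in range(25):
            dh = make_history(n_sites=120, n_occ=6, seed=500 + r)
            dh = sim_history(dh, BASE, true, seed=600 + r)
            f = occ.fit(BASE, dh, n_starts=1, compute_vcov=False, seed=r)
            chats.append(occ.estimate_chat(f, dh, n_boot=20, seed=700 + r))
        assert 0.8 <= np.mean(chats) <= 1.35

    def test_zero_method_effect_ci_coverage(self):
        # true method coefficient 0: Wald 95% CI covers 0 in >= 90% of reps
        spec = occ.ModelSpec("method", method_effect=True)
        k = len(spec.occupancy_terms()) + len(spec.detection_terms())
        true = np.zeros(k)
        true[0], true[3] = 0.7, -0.3
        cover = 0
        n = 100
        for r in range(n):
            dh = make_history(n_sites=200, n_occ=6, seed=900 + r)
            dh = sim_history(dh, spec, true, seed=1000 + r)
            f = occ.fit(spec, dh, n_starts=1, seed=r)
            i = f.param_names.index("p:method")
            se = np.sqrt(max(f.vcov[i, i], 0.0))
            if f.params[i] - 1.96 * se <= 0 <= f.params[i] + 1.96 * se:
                cover += 1
        assert cover / n >= 0.90


class TestPredictDetection:
    def _toy_fit(self):
        dh = make_history(n_sites=150, n_occ=6, seed=91)
        spec = occ.ModelSpec("method", method_effect=True)
        k = len(spec.occupancy_terms()) + len(spec.detection_terms())
        true = np.zeros(k)
        true[0], true[3], true[-1] = 0.8, -0.5, 0.9
        dh = sim_history(dh, spec, true, seed=92)
        return occ.fit(spec, dh, seed=93), dh

    def test_bounds_and_chat_one_identity(self):
        f, _ = self._toy_fit()
        grid = pd.DataFrame({"hours_after_sunrise": np.linspace(-2, 2, 9)})
        a = occ.predict_detection(f, grid, "ARU", chat=1.0)
        b = occ.predict_detection(f, grid, "ARU", chat=0.5)
        for col in ("p_hat", "lo84", "hi84", "lo95", "hi95"):
            assert ((a[col] >= 0) & (a[col] <= 1)).all()
            assert a[col].to_numpy() == pytest.approx(b[col].to_numpy())

    def test_chat_inflates_bands(self):
        f, _ = self._toy_fit()
        grid = pd.DataFrame({"hours_after_sunrise": [0.0, 1.0]})
        a = occ.predict_detection(f, grid, "PC", chat=1.0)
        b = occ.predict_detection(f, grid, "PC", chat=4.0)
        assert (b["hi95"] - b["lo95"] > a["hi95"] - a["lo95"]).all()

    def test_delta_method_matches_mc_oracle(self):
        # 2-parameter toy: eta = b0 + b1 x; compare SE(p) to parametric draws
        rng = np.random.default_rng(5)
        beta = np.array([0.4, -0.7])
        V = np.array([[0.04, 0.01], [0.01, 0.09]])
        x = 0.8
        draws = rng.multivariate_normal(beta, V, size=100_000)
        p_draws = expit(draws[:, 0] + draws[:, 1] * x)
        mc_se_logit = np.std(draws[:, 0] + draws[:, 1] * x)
        X = np.array([1.0, x])
        delta_se = np.sqrt(X @ V @ X)
        assert delta_se == pytest.approx(mc_se_logit, rel=0.05)
        # and the transformed interval stays inside [0, 1]
        assert 0 < expit(beta @ X - 2 * delta_se) < expit(beta @ X + 2 * delta_se) < 1
        assert np.mean(p_draws) == pytest.approx(expit(beta @ X), abs=0.02)
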