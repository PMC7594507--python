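import numpy as np
import pytest

from akgp import SimulationSpec, simulate_phenotypes
from akgp.brr_engine import ChainSettings
from akgp.pipelines import (AnalysisConfig, fit_apge, fit_apse, fit_fgge,
                            fit_fgse, forward_cycle_prediction)
from akgp.synthetic_data import simulate_markers


def _cfg(method, m=None, seed=0, n_iter=1500, **kw):
    return AnalysisConfig(method=method, m=m, seed=seed,
                          chain=ChainSettings(n_iter, 300, 2, seed), **kw)


@pytest.fixture(scope="module")
def se_data():
    spec = SimulationSpec(n_per_env=[150], p=60, sigma2_g=0.6, sigma2_eps=0.4,
                          mu=1.0, seed=31)
    return simulate_phenotypes(simulate_markers(spec), spec)


@pytest.fixture(scope="module")
def ge_data():
    spec = SimulationSpec(n_per_env=[60] * 3, p=60, shared_lines=True, mu=2.0,
                          sigma2_e=0.5, sigma2_g=1.0, sigma2_ge=0.5,
                          sigma2_eps=0.5, seed=32)
    return simulate_phenotypes(simulate_markers(spec), spec)


class TestFGSE:
    def test_noise_free_interpolation(self):
        spec = SimulationSpec(n_per_env=[200], p=60, sigma2_g=1.0,
                              sigma2_eps=0.0, seed=33)
        ds = simulate_phenotypes(simulate_markers(spec), spec)
        res = fit_fgse(ds.y, ds.X_obs, np.arange(200), np.array([], int),
                       _cfg("fgse", n_iter=3000))
        r = np.corrcoef(res.predictions, ds.y)[0, 1]
        assert r > 0.999
        assert np.mean((res.predictions - ds.y) ** 2) < 0.01 * ds.y.var()

    def test_permuted_phenotypes_predict_nothing(self, se_data):
        rng = np.random.default_rng(0)
        corrs = []
        for r in range(8):
            y = rng.permutation(se_data.y)
            te = np.arange(r * 15, r * 15 + 30)
            tr = np.setdiff1d(np.arange(len(y)), te)
            res = fit_fgse(y, se_data.X_obs, tr, te,
                           _cfg("fgse", seed=r, n_iter=800))
            corrs.append(res.test_corr)
        assert abs(np.mean(corrs)) < 0.15

    def test_holdout_accuracy_matches_closed_form_gblup(self, se_data):
        from akgp import build_gblup_kernel
        y, X = se_data.y, se_data.X_obs
        te = np.arange(0, 30)
        tr = np.setdiff1d(np.arange(len(y)), te)
        res = fit_fgse(y, X, tr, te, _cfg("fgse", n_iter=4000))
        # closed-form transductive GBLUP oracle at the true variance ratio
        K = build_gblup_kernel(X).values
        K = K / np.mean(np.diag(K))
        lam = 0.4 / 0.6
        Ktr = K[np.ix_(tr, tr)]
        alpha = np.linalg.solve(Ktr + lam * np.eye(len(tr)), y[tr] - y[tr].mean())
        pred = y[tr].mean() + K[np.ix_(te, tr)] @ alpha
        oracle = np.corrcoef(pred, y[te])[0, 1]
        assert res.test_corr == pytest.approx(oracle, abs=0.05)


class TestAPSE:
    def test_full_inducing_set_matches_fgse(self, se_data):
        y, X = se_data.y, se_data.X_obs
        te = np.arange(0, 30)
        tr = np.setdiff1d(np.arange(len(y)), te)
        a = fit_fgse(y, X, tr, te, _cfg("fgse", n_iter=3000))
        b = fit_apse(y, X, tr, te, len(tr), _cfg("apse", m=len(tr), n_iter=3000))
        assert np.corrcoef(a.predictions[te], b.predictions[te])[0, 1] >= 0.99

    def test_single_inducing_line_still_runs(self, se_data):
        y, X = se_data.y, se_data.X_obs
        te = np.arange(0, 30)
        tr = np.setdiff1d(np.arange(len(y)), te)
        res = fit_apse(y, X, tr, te, 1, _cfg("apse", m=1, n_iter=600))
        assert np.isfinite(res.test_corr)
        assert res.m == 1

    def test_phi_reported_when_requested(self, se_data):
        y, X = se_data.y, se_data.X_obs
        te = np.arange(0, 30)
        tr = np.setdiff1d(np.arange(len(y)), te)
        res = fit_apse(y, X, tr, te, 40,
                       _cfg("apse", m=40, n_iter=600, report_phi=True))
        assert res.phi is not None and 0 < res.phi <= 100


class TestFGGE:
    def test_single_environment_redirects_to_fgse(self, se_data):
        with pytest.raises(ValueError, match="fgse"):
            fit_fgge(se_data.y, se_data.env, se_data.X_obs,
                     np.arange(100), np.arange(100, 150), _cfg("fgge"))

    def test_variance_components_recovered_roughly(self, ge_data):
        res = fit_fgge(ge_data.y, ge_data.env, ge_data.X_obs,
                       np.arange(len(ge_data.y)), np.array([], int),
                       _cfg("fgge", n_iter=2500), lines=ge_data.lines)
        sv = res.scaled_variance_components
        assert 0.3 < sv["g"] < 2.0
        assert res.sigma2_eps < 1.5

    def test_null_interaction_shrinks_ge_below_g(self):
        ests = []
        for seed in range(3):
            spec = SimulationSpec(n_per_env=[50] * 3, p=50, shared_lines=True,
                                  sigma2_e=0.3, sigma2_g=1.0, sigma2_ge=0.0,
                                  sigma2_eps=0.5, seed=40 + seed)
            ds = simulate_phenotypes(simulate_markers(spec), spec)
            res = fit_fgge(ds.y, ds.env, ds.X_obs, np.arange(len(ds.y)),
                           np.array([], int), _cfg("fgge", seed=seed,
                                                   n_iter=2000),
                           lines=ds.lines)
            sv = res.scaled_variance_components
            ests.append(sv["ge"] < sv["g"])
        assert np.median(ests) == 1.0

    def test_unseen_environment_without_shared_lines_warns(self):
        spec = SimulationSpec(n_per_env=[40] * 3, p=40, shared_lines=False,
                              sigma2_e=0.3, sigma2_g=1.0, sigma2_ge=0.3,
                              sigma2_eps=0.5, seed=44)
        ds = simulate_phenotypes(simulate_markers(spec), spec)
        te = np.where(ds.env == "E3")[0]
        tr = np.setdiff1d(np.arange(len(ds.y)), te)
        with pytest.warns(UserWarning, match="main effects only"):
            fit_fgge(ds.y, ds.env, ds.X_obs, tr, te,
                     _cfg("fgge", n_iter=600), lines=ds.lines)


class TestAPGE:
    def test_full_inducing_set_matches_fgge(self, ge_data):
        y, X, env = ge_data.y, ge_data.X_obs, ge_data.env
        # hold out equally per environment so the stratified inducing set
        # can take the whole training set
        te = np.concatenate([np.arange(0, 12), np.arange(60, 72),
                             np.arange(120, 132)])
        tr = np.setdiff1d(np.arange(len(y)), te)
        a = fit_fgge(y, env, X, tr, te, _cfg("fgge", n_iter=3000),
                     lines=ge_data.lines)
        b = fit_apge(y, env, X, tr, te, len(tr),
                     _cfg("apge", m=len(tr), n_iter=3000))
        assert np.corrcoef(a.predictions[te], b.predictions[te])[0, 1] >= 0.99

    def test_single_environment_warns_but_fits(self, se_data):
        y, X = se_data.y, se_data.X_obs
        te = np.arange(0, 30)
        tr = np.setdiff1d(np.arange(len(y)), te)
        with pytest.warns(UserWarning, match="unidentifiable"):
            res = fit_apge(y, np.array(["E1"] * len(y)), X, tr, te, 30,
                           _cfg("apge", m=30, n_iter=600))
        assert np.isfinite(res.test_corr)

    def test_stratified_selection_covers_every_environment(self, ge_data):
        y, X, env = ge_data.y, ge_data.X_obs, ge_data.env
        te = np.arange(0, 18)
        tr = np.setdiff1d(np.arange(len(y)), te)
        res = fit_apge(y, env, X, tr, te, 30, _cfg("apge", m=30, n_iter=600))
        assert res.m == 30
        assert set(res.per_env_corr) <= set(env)


class TestForwardCycle:
    def _cycle_data(self, sigma2_ge=0.0, seed=50):
        spec = SimulationSpec(n_per_env=[60] * 3, p=50, shared_lines=False,
                              sigma2_e=0.2, sigma2_g=1.0,
                              sigma2_ge=sigma2_ge, sigma2_eps=0.5, seed=seed)
        return simulate_phenotypes(simulate_markers(spec), spec)

    def test_target_cycle_shape_contract(self):
        ds = self._cycle_data()
        res = forward_cycle_prediction(ds.y, ds.env, ds.X_obs, "E3",
                                       method="apge", m=30,
                                       config=_cfg("apge", m=30, n_iter=800))
        te = res.metadata["kept_indices"]
        assert res.metadata["target_cycle"] == "E3"
        assert len(res.predictions) == len(te)
        assert np.isfinite(res.test_corr)

    def test_earliest_cycle_rejected(self):
        ds = self._cycle_data()
        with pytest.raises(ValueError, match="earliest"):
            forward_cycle_prediction(ds.y, ds.env, ds.X_obs, "E1")

    def test_duplicated_cycles_do_not_hurt(self):
        # appending an identical copy of the training cycle can only add
        # information about the target
        ds = self._cycle_data(seed=51)
        cfg = _cfg("fgge", n_iter=1500)
        single = forward_cycle_prediction(ds.y, ds.env, ds.X_obs, "E2",
                                          method="fgge", config=cfg)
        keep = ds.env != "E3"
        y2 = np.concatenate([ds.y[keep], ds.y[ds.env == "E1"]])
        env2 = np.concatenate([ds.env[keep],
                               np.array(["E0b"] * (ds.env == "E1").sum())])
        # E0b duplicates E1 but sorts after it in first-appearance order;
        # rebuild with E1's copy first so it trains
        env_order = np.concatenate([np.array(["E1c"] * (ds.env == "E1").sum()),
                                    ds.env[keep]])
        y_order = np.concatenate([ds.y[ds.env == "E1"], ds.y[keep]])
        from akgp import MarkerMatrix
        X = ds.X_obs
        rows = np.concatenate([np.where(ds.env == "E1")[0], np.where(keep)[0]])
        ids = np.array([f"O{i}" for i in range(len(rows))])
        X2 = MarkerMatrix(ids, X.marker_ids, X.values[rows])
        double = forward_cycle_prediction(y_order, env_order, X2, "E2",
                                          method="fgge", config=cfg)
        assert double.test_corr >= single.test_corr - 0.1
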