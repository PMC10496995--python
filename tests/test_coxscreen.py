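import numpy as np
import pandas as pd
import pytest

from oracles import grid_search_cox_beta, naive_cox_loglik
from stemscore import (
    SurvivalTable,
    fit_cox_univariate,
    generate_bulk,
    random_gene_sets,
    score_all,
    screen_gene_sets,
)


def _surv(times, events):
    ids = [f"s{i}" for i in range(len(times))]
    return SurvivalTable(
        pd.DataFrame({"time": times, "event": events}, index=ids)
    )


def _random_dataset(rng, n=None, tie_prone=False):
    n = n or int(rng.integers(8, 25))
    x = rng.normal(size=n)
    t = rng.exponential(5, size=n)
    if tie_prone:
        t = np.ceil(t)  # integer times force ties
    e = (rng.random(n) < 0.75).astype(int)
    if e.sum() < 3:
        e[:3] = 1
    return x, t, e


class TestFitCoxUnivariate:
    def test_three_subject_analytic_fixture(self):
        # deaths in time order with the middle subject exposed: the score
        # equation reduces to 2 - exp(2*beta) = 0, so beta = ln(sqrt 2)
        surv = _surv([1.0, 2.0, 3.0], [1, 1, 1])
        fit = fit_cox_univariate(np.array([0.0, 1.0, 0.0]), surv)
        assert fit.beta == pytest.approx(np.log(np.sqrt(2)), abs=1e-6)
        assert fit.hr == pytest.approx(np.sqrt(2), abs=1e-6)
        assert fit.hr == pytest.approx(np.exp(fit.beta), rel=1e-12)

    def test_symmetric_groups_give_null_fit(self):
        surv = _surv([1, 1, 2, 2, 3, 3], [1, 1, 1, 1, 1, 1])
        fit = fit_cox_univariate(np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0]), surv)
        assert fit.beta == pytest.approx(0.0, abs=1e-8)
        assert fit.wald_p == pytest.approx(1.0, abs=1e-6)

    def test_recovers_true_hazard_ratio_in_simulation(self):
        rng = np.random.default_rng(123)
        n = 1000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.1 * np.exp(np.log(2.0) * x)))
        fit = fit_cox_univariate(x, _surv(t, np.ones(n, int)))
        assert abs(fit.beta - np.log(2.0)) < 3 * fit.se

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_agrees_with_grid_search_oracle(self, ties):
        rng = np.random.default_rng(77)
        for _ in range(20):
            x, t, e = _random_dataset(rng, tie_prone=bool(rng.integers(0, 2)))
            fit = fit_cox_univariate(x, _surv(t, e), ties=ties)
            if not fit.converged:
                continue
            oracle = grid_search_cox_beta(x, t, e, ties=ties)
            assert fit.beta == pytest.approx(oracle, abs=1e-6)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(5)
        x, t, e = _random_dataset(rng, n=30)  # continuous times: no ties
        fe = fit_cox_univariate(x, _surv(t, e), ties="efron")
        fb = fit_cox_univariate(x, _surv(t, e), ties="breslow")
        assert fe.beta == pytest.approx(fb.beta, abs=1e-10)
        assert fe.se == pytest.approx(fb.se, abs=1e-10)

    def test_matches_lifelines_cross_check(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(31)
        x, t, e = _random_dataset(rng, n=60, tie_prone=True)
        fit = fit_cox_univariate(x, _surv(t, e))
        df = pd.DataFrame({"x": x, "time": t, "event": e})
        cph = CoxPHFitter().fit(df, "time", "event")
        assert fit.beta == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert fit.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-5)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(9)
        x, t, e = _random_dataset(rng, n=40)
        base = fit_cox_univariate(x, _surv(t, e))
        for c in (0.1, 7.0):
            scaled = fit_cox_univariate(c * x, _surv(t, e))
            assert scaled.beta == pytest.approx(base.beta / c, rel=1e-8)
            assert scaled.se == pytest.approx(base.se / c, rel=1e-8)
            assert scaled.wald_p == pytest.approx(base.wald_p, abs=1e-8)

    def test_loglik_machinery_matches_naive(self):
        from stemscore.coxscreen import _partial_likelihood_quantities

        rng = np.random.default_rng(17)
        for ties in ("efron", "breslow"):
            x, t, e = _random_dataset(rng, tie_prone=True)
            order = np.argsort(t)
            for beta in (-0.8, 0.0, 1.3):
                ll, _, _ = _partial_likelihood_quantities(
                    beta, x[order], t[order], e[order], ties
                )
                assert ll == pytest.approx(naive_cox_loglik(beta, x, t, e, ties), abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            fit_cox_univariate(np.array([0.0, 1.0, 2.0]), _surv([1, 2, 3], [0, 0, 0]))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cox_univariate(np.ones(4), _surv([1, 2, 3, 4], [1, 1, 1, 1]))

    def test_separating_covariate_flagged_nonconverged(self):
        # covariate perfectly ordered with event times: monotone likelihood
        n = 12
        t = np.arange(1, n + 1, dtype=float)
        x = -t  # highest covariate dies first
        fit = fit_cox_univariate(x, _surv(t, np.ones(n, int)))
        assert not fit.converged


class TestScreenGeneSets:
    def test_planted_risk_and_protective_directions(self):
        expr, surv, _ = generate_bulk(
            n_samples=300, seed=2026, effects={"SET01": 0.8, "SET02": -0.8}
        )
        sets = random_gene_sets(expr.gene_ids, 36, 25, seed=2026)
        results = screen_gene_sets(score_all(expr, sets), surv)
        by_name = {r.set_name: r for r in results}
        assert by_name["SET01"].direction == "risk"
        assert by_name["SET02"].direction == "protective"
        for r in results:
            if r.direction != "dropped":
                assert r.wald_p < 0.05
                assert (r.hr > 1) == (r.direction == "risk")

    def test_zero_threshold_rejects_everything(self):
        expr, surv, _ = generate_bulk(n_samples=100, seed=4)
        sets = random_gene_sets(expr.gene_ids, 8, 25, seed=4)
        em = score_all(expr, sets)
        with pytest.raises(ValueError, match="no gene set passed"):
            screen_gene_sets(em, surv, p_threshold=0.0)

    def test_too_few_shared_samples_rejected(self, exp_surv):
        nes = pd.DataFrame(
            np.random.default_rng(0).normal(size=(3, 5)),
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(5)],
        )
        with pytest.raises(ValueError, match="<10"):
            screen_gene_sets(nes, exp_surv)
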