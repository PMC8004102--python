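"""Multi-start fitting, staged pipeline, sensitivity, opening/closing rates."""

import numpy as np
import pytest

import onoffslide as oos
from onoffslide.dynamics import ParameterVector
from onoffslide.fitting import (
    FitConfig,
    fit_stage1,
    fit_stage2,
    fit_stage3,
    opening_closing_report,
    run_staged_pipeline,
    sensitivity_analysis,
)
from onoffslide.likelihoods import ConfigCounts, log10lik_config, perfect_fit_loglik


class TestStage1:
    def test_single_rate_analytic_mle(self):
        """{A const, D reg}: per state the occupancy is Bernoulli(1/(1+rD))
        per site, so the MLE of rD is the empty/occupied site-count odds."""
        model = oos.ModelSpec.make(("A", "D"), ("D",))
        rng = np.random.default_rng(0)
        gt_rates = {"repressed": 0.25, "weakly_activated": 1.0, "activated": 4.0}
        counts = np.zeros((3, 8), dtype=int)
        space = oos.build_configuration_space()
        for k, s in enumerate(oos.STATES):
            occ_p = 1 / (1 + gt_rates[s])
            probs = [np.prod([occ_p if o else 1 - occ_p for o in cfg.occupancy])
                     for cfg in space.configurations]
            counts[k] = rng.multinomial(400, probs)
        cc = ConfigCounts(counts)
        fit = fit_stage1(model, cc, FitConfig(n_starts=3, seed=2))
        for k, s in enumerate(oos.STATES):
            occupied = sum(counts[k, cfg.index - 1] * sum(cfg.occupancy)
                           for cfg in space.configurations)
            empty = 3 * counts[k].sum() - occupied
            assert fit.params.rate("D", s) == pytest.approx(empty / occupied,
                                                            rel=1e-4)

    def test_self_consistency_r1_small_for_exact_frequencies(self, ground_truth):
        """Counts proportional to the model's steady states make R1 -> 0."""
        asg = oos.resolve_governance(ground_truth.model)
        counts = np.zeros((3, 8), dtype=int)
        n = 10 ** 6
        for k, s in enumerate(oos.STATES):
            p = oos.steady_state(oos.build_rate_matrix(asg, ground_truth.params, s))
            counts[k] = np.round(n * p).astype(int)
            counts[k, 0] += n - counts[k].sum()
        cc = ConfigCounts(counts)
        fit = fit_stage1(ground_truth.model, cc, FitConfig(n_starts=3, seed=4))
        assert fit.R1 < 0.05
        assert fit.R1 >= -1e-6

    def test_seed_reproducibility(self, ground_truth, synthetic_data):
        counts, _, _ = synthetic_data
        cfg = FitConfig(n_starts=3, seed=9)
        a = fit_stage1(ground_truth.model, counts, cfg)
        b = fit_stage1(ground_truth.model, counts, cfg)
        assert a.R1 == b.R1
        assert np.array_equal(a.diagnostics["x_best"], b.diagnostics["x_best"])


class TestStage2:
    def test_recovers_foldchanges_with_tiny_noise(self, ground_truth):
        from onoffslide.likelihoods import FoldChangeObservations, model_foldchanges
        asg = oos.resolve_governance(ground_truth.model)
        counts = oos.sample_config_counts(ground_truth)
        f_true = model_foldchanges(asg, ground_truth.params, ground_truth.kappas)
        fc = FoldChangeObservations(f_true, np.full((2, 2), 0.03 ** 2))
        f1 = fit_stage1(ground_truth.model, counts, FitConfig(n_starts=3, seed=5))
        f2 = fit_stage2(ground_truth.model, counts, fc,
                        FitConfig(n_starts=3, seed=5), warm=f1)
        # the fold-change term costs (almost) nothing at the optimum
        assert f2.R2 - f2.R1 < 0.05
        f_fit = model_foldchanges(asg, f2.params, f2.kappas)
        assert np.abs(f_fit - f_true).max() < 0.05


class TestStage3:
    def test_gauge_rescaling_leaves_likelihood_unchanged(self, ground_truth,
                                                         synthetic_data):
        """Physical rates s*r are the only thing the data see: scaling all
        relative rates by c and the time scale by 1/c is a no-op (checked
        directly on the likelihoods with the normalization released)."""
        from onoffslide.likelihoods import (log10lik_config, log10lik_exchange,
                                            log10lik_foldchange)
        counts, fc, ex = synthetic_data
        asg = oos.resolve_governance(ground_truth.model)
        p1 = ground_truth.params.copy()
        c = 2.5
        rates2 = {}
        for pid, v in p1.rates.items():
            if isinstance(v, dict):
                rates2[pid] = {s: x * c for s, x in v.items()}
            else:
                rates2[pid] = v * c
        p2 = ParameterVector(rates2, p1.time_scale / c)
        for f in (lambda p: log10lik_config(asg, p, counts),
                  lambda p: log10lik_foldchange(asg, p, ground_truth.kappas, fc),
                  lambda p: log10lik_exchange(asg, p, ex)):
            assert f(p1) == pytest.approx(f(p2), abs=1e-6)

    def test_time_scale_recovery_within_profile_interval(self, ground_truth,
                                                         synthetic_data):
        """The fitted time scale agrees with the truth up to the sloppiness
        of its own likelihood profile (scanned on the time-scale axis)."""
        counts, fc, ex = synthetic_data
        cfg = FitConfig(n_starts=2, seed=6)
        f1 = fit_stage1(ground_truth.model, counts, cfg)
        f2 = fit_stage2(ground_truth.model, counts, fc, cfg, warm=f1)
        f3 = fit_stage3(ground_truth.model, counts, fc, ex, cfg, warm=f2)
        assert f3.success
        from onoffslide.likelihoods import (log10lik_config, log10lik_exchange,
                                            log10lik_foldchange)
        asg = oos.resolve_governance(ground_truth.model)

        def neg_loglik_of_log10_s(ls):
            p = f3.params.copy()
            p.time_scale = 10.0 ** float(ls)
            return -(log10lik_config(asg, p, counts)
                     + log10lik_foldchange(asg, p, f3.kappas, fc)
                     + log10lik_exchange(asg, p, ex))

        scan = sensitivity_analysis(lambda x: neg_loglik_of_log10_s(x[0]),
                                    np.array([np.log10(f3.time_scale)]),
                                    ["time_scale"])
        lo = np.log10(f3.time_scale) - scan.loc["time_scale", "err_minus"]
        hi = np.log10(f3.time_scale) + scan.loc["time_scale", "err_plus"]
        assert lo - 0.3 <= np.log10(ground_truth.params.time_scale) <= hi + 0.3


@pytest.fixture(scope="module")
def small_pipeline(ground_truth, synthetic_data):
    counts, fc, ex = synthetic_data
    # a small catalog guaranteed to contain the generating model
    others = [m for m in oos.enumerate_models(5)[:6]]
    models = others + [ground_truth.model]
    cfg = FitConfig(n_starts=2, seed=3)
    return models, run_staged_pipeline(models, counts, fc, ex, cfg)


class TestPipeline:
    def test_survivor_sets_shrink_across_stages(self, small_pipeline):
        _, result = small_pipeline
        s = result.survivors
        assert set(s[2]) <= set(s[1])
        assert set(s[3]) <= set(s[2])

    def test_generating_model_survives_all_stages(self, ground_truth,
                                                  small_pipeline):
        _, result = small_pipeline
        assert ground_truth.model in result.survivors[3]

    def test_generating_model_ranks_best(self, ground_truth, small_pipeline):
        models, result = small_pipeline
        idx = models.index(ground_truth.model)
        r1 = {i: f.R1 for i, f in result.fits[1].items()}
        assert r1[idx] == pytest.approx(min(r1.values()), abs=2.0)

    def test_records_table_is_complete(self, small_pipeline):
        models, result = small_pipeline
        assert len(result.records) == len(models)
        assert {"R1", "survived_stage1", "param_count"} <= set(result.records)


class TestSensitivity:
    def test_quadratic_closed_form(self):
        """1-D quadratic: the 0.30-drop half width is sqrt(2*0.30/c)."""
        c = 4.0
        f = lambda x: 0.5 * c * float((x[0] - 0.2) ** 2)
        df = sensitivity_analysis(f, np.array([0.2]), ["p"], step0=0.001,
                                  growth=1.2)
        expected = np.sqrt(2 * 0.30 / c)
        assert df.loc["p", "err_plus"] == pytest.approx(expected, rel=0.1)
        assert df.loc["p", "err_minus"] == pytest.approx(expected, rel=0.1)
        assert not df.loc["p", "sloppy"]

    def test_flat_direction_raises_sloppy_flag(self):
        """A duplicated parameter gives an exactly flat direction."""
        f = lambda x: float((x[0] - x[1]) ** 2)
        df = sensitivity_analysis(f, np.zeros(2), ["a", "b"])
        assert df["sloppy"].any()

    def test_boundary_optimum_scans_over_the_bound(self):
        """With the optimum on a bound (linear slope), the uphill direction
        crosses the 0.30 drop at 0.15 while the downhill direction only
        improves the likelihood and is flagged sloppy."""
        f = lambda x: float(2.0 * x[0])
        df = sensitivity_analysis(f, np.zeros(1), ["p"])
        assert df.loc["p", "err_plus"] == pytest.approx(0.15, rel=0.2)
        assert df.loc["p", "sloppy"]


class TestOpeningClosing:
    def test_bare_model_closed_form(self):
        """{A reg, D}: opening rate s*(rA_act+rD), closing s*(rA_rep+rD)."""
        model = oos.ModelSpec.make(("A", "D"), ("A",))
        params = ParameterVector(
            {"A": {"repressed": 4.0, "weakly_activated": 2.0, "activated": 1.0},
             "D": 0.5}, time_scale=2.0)
        rep = opening_closing_report(oos.resolve_governance(model), params)
        assert rep["opening_rate"] == pytest.approx(2.0 * 1.5)
        assert rep["closing_rate"] == pytest.approx(2.0 * 4.5)
        assert rep["ratio_closing_over_opening"] == pytest.approx(3.0)

    def test_ratio_is_time_scale_invariant(self, ground_truth):
        asg = oos.resolve_governance(ground_truth.model)
        p1 = ground_truth.params.copy()
        p2 = ground_truth.params.copy()
        p2.time_scale = 17.0
        r1 = opening_closing_report(asg, p1)["ratio_closing_over_opening"]
        r2 = opening_closing_report(asg, p2)["ratio_closing_over_opening"]
        assert r1 == pytest.approx(r2, rel=1e-12)
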