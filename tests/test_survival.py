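import dataclasses

import numpy as np
import pandas as pd
import pytest

from lncmodnet import errors
from lncmodnet.io import ClinicalTable, ExpressionMatrix
from lncmodnet.network import Module
from lncmodnet.survival import (
    ScreenThresholds,
    cox_fit,
    evaluate_signature,
    km_curve,
    logrank,
    median_split,
    module_signature,
    pooled_signature,
    screen_lncrnas,
    signature_weights,
    time_auc,
)
from lncmodnet.synthetic import (
    PlantedModule,
    SyntheticConfig,
    generate_clinical,
    generate_expression,
)


def _series(vals, prefix="s"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


class TestMedianSplit:
    def test_even(self):
        g = median_split(_series([1, 2, 3, 4]))
        assert list(g) == ["low", "low", "high", "high"]

    def test_odd_median_goes_low(self):
        g = median_split(_series([1, 2, 3, 4, 5]))
        assert g["s2"] == "low" and (g == "high").sum() == 2

    def test_constant_rejected(self):
        with pytest.raises(errors.DegenerateSplitError):
            median_split(_series([2, 2, 2, 2]))

    def test_too_few(self):
        with pytest.raises(errors.InsufficientDataError):
            median_split(_series([1, 2, 3]))


def _logrank_oracle(times_a, events_a, times_b, events_b):
    """Hand O-E / hypergeometric-variance computation of the log-rank statistic."""
    t = np.concatenate([times_a, times_b])
    e = np.concatenate([events_a, events_b])
    grp = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    o_minus_e, var = 0.0, 0.0
    for tj in np.unique(t[e == 1]):
        at_risk = t >= tj
        n = at_risk.sum()
        n_a = (at_risk & (grp == 0)).sum()
        d = ((t == tj) & (e == 1)).sum()
        d_a = ((t == tj) & (e == 1) & (grp == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        times = pd.Series([3.0, 5, 8, 3, 5, 8], index=list("abcdef"))
        events = pd.Series([1, 1, 0, 1, 1, 0], index=list("abcdef"))
        groups = pd.Series(list("AAABBB"), index=list("abcdef"))
        stat, p = logrank(groups, times, events)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        ta, ea = np.array([1.0, 2.0]), np.array([1, 1])
        tb, eb = np.array([10.0, 20.0]), np.array([1, 1])
        idx = list("abcd")
        stat, _ = logrank(
            pd.Series(list("AABB"), index=idx),
            pd.Series(np.concatenate([ta, tb]), index=idx),
            pd.Series(np.concatenate([ea, eb]), index=idx),
        )
        assert stat == pytest.approx(_logrank_oracle(ta, ea, tb, eb), rel=1e-9)

    def test_label_swap_invariance(self, rng):
        n = 40
        idx = [f"s{i}" for i in range(n)]
        times = pd.Series(rng.exponential(10, n), index=idx)
        events = pd.Series(rng.integers(0, 2, n), index=idx)
        groups = pd.Series(rng.choice(["high", "low"], n), index=idx)
        swapped = groups.map({"high": "low", "low": "high"})
        assert logrank(groups, times, events) == pytest.approx(
            logrank(swapped, times, events)
        )

    def test_power_under_strong_effect(self, rng):
        """Simulated hazard ratio 3 at n = 400 is essentially always detected."""
        rejected = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            idx = [f"s{i}" for i in range(400)]
            grp = np.repeat(["low", "high"], 200)
            lam = np.where(grp == "high", 3.0, 1.0)
            times = pd.Series(r.exponential(1 / lam), index=idx)
            events = pd.Series(np.ones(400, dtype=int), index=idx)
            _, p = logrank(pd.Series(grp, index=idx), times, events)
            rejected += p < 0.001
        assert rejected >= 19


def _cox_loglik(beta, x, times, events):
    """Written-out partial likelihood for distinct event times."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCoxFit:
    def test_null_covariate(self, rng):
        n = 600
        idx = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame({"x": rng.normal(size=n)}, index=idx)
        times = pd.Series(rng.exponential(5, n), index=idx)
        events = pd.Series(np.ones(n, dtype=int), index=idx)
        fit = cox_fit(cov, times, events)
        assert abs(fit.loc["x", "beta"]) < 0.15
        assert fit.loc["x", "ci_low"] < 1.0 < fit.loc["x", "ci_high"]

    def test_brute_force_partial_likelihood(self):
        """Six subjects, no ties: fit matches grid maximization within 1e-4."""
        x = np.array([1.0, 0, 1, 0, 1, 0])
        times = np.array([2.0, 5.0, 3.0, 9.0, 7.0, 11.0])
        events = np.array([1, 1, 1, 0, 1, 1])
        idx = [f"s{i}" for i in range(6)]
        fit = cox_fit(
            pd.DataFrame({"x": x}, index=idx),
            pd.Series(times, index=idx),
            pd.Series(events, index=idx),
        )
        grid = np.arange(-5, 5, 1e-4)
        lls = np.array([_cox_loglik(b, x, times, events) for b in grid])
        assert fit.loc["x", "beta"] == pytest.approx(grid[lls.argmax()], abs=1e-4)

    def test_constant_covariate_rejected(self):
        idx = list("abcd")
        with pytest.raises(errors.FitError):
            cox_fit(
                pd.DataFrame({"x": [1.0, 1, 1, 1]}, index=idx),
                pd.Series([1.0, 2, 3, 4], index=idx),
                pd.Series([1, 1, 1, 1], index=idx),
            )

    def test_hr_recovery_smoke(self):
        """Binary covariate with true hazard ratio 2 recovered at n = 1000."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 1000
            idx = [f"s{i}" for i in range(n)]
            x = rng.integers(0, 2, n)
            times = pd.Series(rng.exponential(1 / np.exp(np.log(2) * x)), index=idx)
            fit = cox_fit(
                pd.DataFrame({"x": x.astype(float)}, index=idx),
                times,
                pd.Series(np.ones(n, dtype=int), index=idx),
            )
            assert 1.7 < fit.loc["x", "hr"] < 2.3


class TestKmCurve:
    def test_no_events(self):
        sf = km_curve(_series([5.0, 8.0, 12.0]), _series([0, 0, 0]))
        assert (sf == 1.0).all()

    def test_product_limit_by_hand(self):
        sf = km_curve(_series([5.0, 8.0, 12.0]), _series([1, 0, 1]))
        assert sf.loc[5.0] == pytest.approx(2 / 3)
        assert sf.loc[12.0] == pytest.approx(0.0)

    def test_reduces_to_ecdf_complement(self, rng):
        times = np.sort(rng.uniform(1, 10, 8))
        sf = km_curve(_series(times), _series(np.ones(8, dtype=int)))
        for i, t in enumerate(times):
            assert sf.loc[t] == pytest.approx(1 - (i + 1) / 8)

    def test_monotone_in_unit_interval(self, rng):
        sf = km_curve(
            _series(rng.exponential(5, 50)), _series(rng.integers(0, 2, 50))
        )
        assert sf.iloc[0] == 1.0
        assert (sf.diff().dropna() <= 1e-12).all()
        assert ((sf >= 0) & (sf <= 1)).all()


def _pair_count_auc(scores, times, events, t):
    cases = (times <= t) & (events == 1)
    controls = times > t
    num = den = 0.0
    for si in scores[cases]:
        for sj in scores[controls]:
            num += (si > sj) + 0.5 * (si == sj)
            den += 1.0
    return num / den


class TestTimeAuc:
    def test_perfect_marker(self, rng):
        n = 50
        times = rng.uniform(1, 100, n)
        scores = _series(-times)  # higher score = earlier event
        auc = time_auc(
            scores, _series(times), _series(np.ones(n, dtype=int)), [20.0, 50.0, 80.0]
        )
        assert all(v == pytest.approx(1.0) for v in auc.values())

    def test_pair_counting_oracle_no_censoring(self, rng):
        n = 120
        times = rng.uniform(1, 100, n)
        scores = np.round(rng.normal(size=n), 1)  # rounded -> ties exercised
        events = np.ones(n, dtype=int)
        auc = time_auc(_series(scores), _series(times), _series(events), [25.0, 60.0])
        for t, got in auc.items():
            assert got == pytest.approx(
                _pair_count_auc(scores, times, events, t), abs=1e-10
            )

    def test_matches_sksurv_under_censoring(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 300
        times = rng.uniform(1, 100, n)
        events = rng.random(n) < 0.7
        scores = rng.normal(size=n)
        eval_times = [30.0, 60.0]
        auc = time_auc(
            _series(scores),
            _series(times),
            _series(events.astype(int)),
            eval_times,
        )
        y = Surv.from_arrays(events, times)
        expected, _ = cumulative_dynamic_auc(y, y, scores, eval_times)
        for t, e in zip(eval_times, expected):
            assert auc[t] == pytest.approx(e, abs=1e-6)

    def test_protective_score_flipped(self, rng):
        n = 60
        times = rng.uniform(1, 100, n)
        auc = time_auc(
            _series(times),  # higher value = later event = protective
            _series(times),
            _series(np.ones(n, dtype=int)),
            [50.0],
            higher_score_is_riskier=False,
        )
        assert auc[50.0] == pytest.approx(1.0)

    def test_undefined_before_first_event(self, rng):
        times = _series([10.0, 20.0, 30.0, 40.0])
        auc = time_auc(
            _series([1.0, 2, 3, 4]), times, _series([1, 1, 1, 1]), [5.0]
        )
        assert np.isnan(auc[5.0])

    def test_null_scores_near_half(self):
        inside = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 500
            times = rng.uniform(1, 100, n)
            auc = time_auc(
                _series(rng.normal(size=n)),
                _series(times),
                _series(np.ones(n, dtype=int)),
                [50.0],
            )
            inside += 0.45 < auc[50.0] < 0.55
        assert inside >= 9


# ---------------------------------------------------------------------------
# screening and signatures on planted data


def _truth_modules(truth, orientation="negative"):
    ids = sorted(set(truth.module_membership.values()))
    return [
        Module(f"N{i}", frozenset(truth.module_members(m)), orientation)
        for i, m in enumerate(ids, start=1)
    ]


class TestScreen:
    def test_positive_control_planted_effects_pass(self, planted_dataset):
        tumour, normal, clinical, truth = planted_dataset
        modules = _truth_modules(truth)
        results = screen_lncrnas(tumour, normal, clinical, modules)
        frac = np.mean([r.passed for r in results])
        assert frac > 0.8
        # planted protective modules come out favourable
        by_mod = {}
        for r in results:
            if r.passed:
                by_mod.setdefault(r.module_id, []).append(r.direction)
        assert set(by_mod["N1"]) == {"favourable"}

    def test_negative_control_null_effects(self):
        cfg = SyntheticConfig(
            n_tumour_samples=200,
            n_normal_samples=60,
            n_lnc=40,
            n_mrna=150,
            modules=[PlantedModule(5, 20, 20)],  # all effects zero
            seed=11,
        )
        tumour, normal, truth = generate_expression(cfg)
        clinical = generate_clinical(cfg, tumour, truth)
        results = screen_lncrnas(tumour, normal, clinical, _truth_modules(truth))
        assert np.mean([r.passed for r in results]) <= 0.2

    def test_stage_independent_lncrna_excluded(self, planted_dataset):
        """Survival-significant but stage-independent genes fail step 3."""
        tumour, normal, clinical, truth = planted_dataset
        modules = _truth_modules(truth)
        strict = ScreenThresholds(stage=1e-300)  # nothing is stage-dependent enough
        results = screen_lncrnas(tumour, normal, clinical, modules, strict)
        assert not any(r.passed for r in results)
        assert any(r.logrank_p < 0.05 for r in results)

    def test_missing_clinical_field_named(self, planted_dataset):
        tumour, normal, clinical, truth = planted_dataset
        broken = ClinicalTable.__new__(ClinicalTable)
        broken.data = clinical.data.drop(columns=["age"])
        with pytest.raises(errors.InputError, match="age"):
            screen_lncrnas(tumour, normal, broken, _truth_modules(truth))


def _tiny_clinical(rng, samples):
    n = len(samples)
    return ClinicalTable(
        pd.DataFrame(
            {
                "os_time": rng.exponential(50, n) + 0.1,
                "os_event": rng.integers(0, 2, n),
                "pfs_time": rng.exponential(25, n) + 0.1,
                "pfs_event": rng.integers(0, 2, n),
                "age": rng.uniform(50, 80, n),
                "stage": rng.integers(1, 5, n).astype(float),
                "tissue": "tumour",
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )


class TestSignatures:
    def test_score_is_weighted_expression_sum(self, rng):
        samples = [f"s{i}" for i in range(40)]
        idx = pd.Index(["l1", "l2"], name="gene_id")
        vals = pd.DataFrame(rng.uniform(1, 5, (2, 40)), index=idx, columns=samples)
        em = ExpressionMatrix(vals, pd.Series(["lncRNA", "lncRNA"], index=idx))
        clin = _tiny_clinical(rng, samples)
        weights = {"l1": 0.5, "l2": -0.2}
        res = evaluate_signature("sig", weights, em, clin)
        expected = 0.5 * vals.loc["l1"] + (-0.2) * vals.loc["l2"]
        np.testing.assert_allclose(res.scores.to_numpy(), expected.to_numpy())

    def test_single_lncrna_grouping_matches_expression_split(self, rng):
        samples = [f"s{i}" for i in range(40)]
        idx = pd.Index(["l1"], name="gene_id")
        vals = pd.DataFrame(rng.uniform(1, 5, (1, 40)), index=idx, columns=samples)
        em = ExpressionMatrix(vals, pd.Series(["lncRNA"], index=idx))
        clin = _tiny_clinical(rng, samples)
        res = evaluate_signature("sig", {"l1": 2.0}, em, clin)
        direct = median_split(vals.loc["l1"])
        assert (res.group == direct).all()

    def test_zero_weights_degenerate(self, rng):
        samples = [f"s{i}" for i in range(40)]
        idx = pd.Index(["l1"], name="gene_id")
        vals = pd.DataFrame(rng.uniform(1, 5, (1, 40)), index=idx, columns=samples)
        em = ExpressionMatrix(vals, pd.Series(["lncRNA"], index=idx))
        with pytest.raises(errors.DegenerateSplitError):
            evaluate_signature("sig", {"l1": 0.0}, em, _tiny_clinical(rng, samples))

    def test_pooled_score_is_sum_of_disjoint_module_scores(self, planted_dataset):
        tumour, normal, clinical, truth = planted_dataset
        modules = _truth_modules(truth)[:2]
        screen = screen_lncrnas(tumour, normal, clinical, modules)
        sigs = [
            module_signature(tumour, clinical, m, screen) for m in modules
        ]
        sigs = [s for s in sigs if s is not None]
        assert len(sigs) == 2
        pooled = pooled_signature(tumour, clinical, sigs)
        np.testing.assert_allclose(
            pooled.scores.to_numpy(),
            (sigs[0].scores + sigs[1].scores).to_numpy(),
            rtol=1e-10,
        )

    def test_pooled_single_module_is_identity(self, planted_dataset):
        tumour, normal, clinical, truth = planted_dataset
        modules = _truth_modules(truth)[:1]
        screen = screen_lncrnas(tumour, normal, clinical, modules)
        sig = module_signature(tumour, clinical, modules[0], screen)
        pooled = pooled_signature(tumour, clinical, [sig])
        np.testing.assert_allclose(pooled.scores.to_numpy(), sig.scores.to_numpy())
        assert pooled.hr == pytest.approx(sig.hr)

    def test_pooled_effect_at_least_single_module(self):
        """Pooling two prognostic modules usually strengthens the hazard ratio."""
        wins = 0
        for seed in range(20):
            cfg = SyntheticConfig(
                n_tumour_samples=300,
                n_normal_samples=30,
                n_lnc=30,
                n_mrna=100,
                modules=[
                    PlantedModule(5, 15, 15, survival_beta=-0.7, tumour_shift=1.0),
                    PlantedModule(5, 15, 15, survival_beta=-0.7, tumour_shift=1.0),
                ],
                seed=1000 + seed,
            )
            tumour, normal, truth = generate_expression(cfg)
            clinical = generate_clinical(cfg, tumour, truth)
            sigs = []
            for mod in _truth_modules(truth):
                w = signature_weights(tumour, clinical, sorted(mod.members))
                sigs.append(evaluate_signature(mod.module_id, w, tumour, clinical))
            pooled = pooled_signature(tumour, clinical, sigs)
            if all(abs(np.log(pooled.hr)) >= abs(np.log(s.hr)) for s in sigs):
                wins += 1
        assert wins >= 16
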