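"""Pairwise phase differences, transforms and the random-intercept model."""

import numpy as np
import pandas as pd
import pytest

from hoglog import (
    PhaseCalendar,
    apply_transform,
    build_diffset,
    estimate_changes,
    fit_random_intercept,
    pairwise_diffs,
    summarize_changes,
)


def diff_frame(by_individual: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.concat(
        [pd.DataFrame({"individual_id": k, "diff": v}) for k, v in by_individual.items()],
        ignore_index=True,
    )


class TestPairwiseDiffs:
    def test_enumeration(self):
        assert sorted(pairwise_diffs([1, 2], [4])) == [2, 3]

    def test_19_by_19_gives_361(self):
        assert pairwise_diffs(np.arange(19), np.arange(19)).size == 361

    def test_constant_phases_give_zero(self):
        assert (pairwise_diffs([3.0] * 5, [3.0] * 4) == 0.0).all()

    def test_empty_phase_raises(self):
        with pytest.raises(ValueError, match="usable daily value"):
            pairwise_diffs([], [1.0])


class TestTransforms:
    def test_di_log_shift(self):
        assert apply_transform("DI", [0.0])[0] == pytest.approx(0.0, abs=1e-5)

    def test_di_at_minus_one_requires_eps(self):
        with pytest.raises(ValueError, match="eps"):
            apply_transform("DI", [-1.0], eps=0.0)
        assert np.isfinite(apply_transform("DI", [-1.0])[0])

    def test_tsdusk_shift_by_abs_min(self):
        out = apply_transform("TSdusk", [-30.0, 10.0])
        assert out.tolist() == [0.0, 40.0]

    def test_odba_zscore(self, rng):
        out = apply_transform("ODBA", rng.normal(5.0, 2.0, 500))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0)

    def test_unknown_parameter_is_identity(self):
        assert apply_transform("kde50", [1.0, 2.0]).tolist() == [1.0, 2.0]


class TestRandomIntercept:
    def test_reml_matches_balanced_anova_closed_form(self, rng):
        m, n = 6, 20
        b = rng.normal(0, 1.5, m)
        y = np.concatenate([-2 + bi + rng.normal(0, 3, n) for bi in b])
        ids = np.repeat([f"g{i}" for i in range(m)], n)
        df = pd.DataFrame({"individual_id": ids, "diff": y})
        est = fit_random_intercept(df)
        ybar = df.groupby("individual_id")["diff"].mean()
        grand = y.mean()
        msb = n * ((ybar - grand) ** 2).sum() / (m - 1)
        msw = (
            sum(((df[df["individual_id"] == g]["diff"] - ybar[g]) ** 2).sum() for g in ybar.index)
            / (m * (n - 1))
        )
        assert est.mu == pytest.approx(grand, abs=1e-9)
        assert est.sigma2_e == pytest.approx(msw, abs=1e-6)
        assert est.sigma2_b == pytest.approx((msb - msw) / n, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self, rng):
        """Independent cross-check against a generic REML implementation."""
        import warnings

        import statsmodels.api as sm

        y = np.concatenate([rng.normal(mu, 2.0, 15) for mu in (-1.0, 0.5, 2.0, -2.0)])
        ids = np.repeat(list("abcd"), 15)
        est = fit_random_intercept(pd.DataFrame({"individual_id": ids, "diff": y}))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, np.ones((len(y), 1)), groups=ids).fit(reml=True)
        assert est.mu == pytest.approx(float(fit.fe_params[0]), abs=1e-6)
        assert est.sigma2_b == pytest.approx(float(np.asarray(fit.cov_re)[0, 0]), abs=1e-3)
        assert est.sigma2_e == pytest.approx(float(fit.scale), abs=1e-3)

    def test_blup_shrinkage_lies_between_zero_and_raw_deviation(self, rng):
        y = np.concatenate([rng.normal(mu, 3.0, 12) for mu in (-2.0, 0.0, 1.0, 4.0)])
        ids = np.repeat(list("abcd"), 12)
        df = pd.DataFrame({"individual_id": ids, "diff": y})
        est = fit_random_intercept(df)
        raw = df.groupby("individual_id")["diff"].mean()
        for row in est.table.itertuples():
            b_hat = row.pred_change - est.mu
            raw_dev = raw[row.individual_id] - est.mu
            assert 0.0 <= b_hat / raw_dev <= 1.0  # same sign, shrunken

    def test_noise_free_limit_recovers_each_individual_exactly(self):
        df = diff_frame(
            {k: np.full(10, c) + np.random.default_rng(1).normal(0, 1e-8, 10)
             for k, c in (("a", -3.0), ("b", 1.0), ("c", 2.0))}
        )
        est = fit_random_intercept(df, ci_method="conditional")
        got = dict(zip(est.table["individual_id"], est.table["pred_change"]))
        assert got["a"] == pytest.approx(-3.0, abs=1e-4)
        assert got["b"] == pytest.approx(1.0, abs=1e-4)
        # with vanishing residual noise the conditional intervals collapse
        widths = est.table["ci_hi"] - est.table["ci_lo"]
        assert (widths < 1e-3).all()

    def test_parameter_recovery_and_conditional_coverage(self):
        """mu recovered near -2 on average; conditional BLUP intervals cover
        the true individual effects at close to the nominal rate on
        independent replicates."""
        mus, covered, total = [], 0, 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            b = rng.normal(0, 1.0, 8)
            y = np.concatenate([-2 + bi + rng.normal(0, 3.0, 50) for bi in b])
            ids = np.repeat([f"g{i}" for i in range(8)], 50)
            est = fit_random_intercept(
                pd.DataFrame({"individual_id": ids, "diff": y}), ci_method="conditional"
            )
            mus.append(est.mu)
            for i, row in enumerate(est.table.itertuples()):
                total += 1
                covered += row.ci_lo <= -2 + b[i] <= row.ci_hi
        assert np.mean(mus) == pytest.approx(-2.0, abs=0.25)
        assert 0.90 <= covered / total <= 0.99

    def test_duplicating_an_individuals_data_keeps_its_prediction(self):
        base = {
            "a": np.full(8, -2.0) + np.random.default_rng(2).normal(0, 1e-6, 8),
            "b": np.full(8, 1.0),
            "c": np.full(8, 3.0),
        }
        est1 = fit_random_intercept(diff_frame(base))
        doubled = dict(base)
        doubled["a"] = np.concatenate([base["a"], base["a"]])
        est2 = fit_random_intercept(diff_frame(doubled))
        p1 = est1.table.set_index("individual_id")["pred_change"]
        p2 = est2.table.set_index("individual_id")["pred_change"]
        assert p1["a"] == pytest.approx(p2["a"], abs=1e-3)

    def test_too_few_individuals_raise(self):
        with pytest.raises(ValueError, match=">= 2 individuals"):
            fit_random_intercept(diff_frame({"a": np.arange(5.0)}))


class TestEndToEnd:
    @staticmethod
    def _daily(effects_by_ind, seed=0, n_days=10):
        cal = PhaseCalendar()
        rng = np.random.default_rng(seed)
        rows = []
        for ind, eff in effects_by_ind.items():
            for d in cal.pre_dates[:n_days]:
                rows.append((ind, d, 5.0 + rng.normal(0, 0.5)))
            for d in cal.festival_dates[:n_days]:
                rows.append((ind, d, 5.0 + eff + rng.normal(0, 0.5)))
        return pd.DataFrame(rows, columns=["individual_id", "date", "value"])

    def test_sign_convention_festival_minus_pre(self):
        daily = self._daily({"a": -2.0, "b": -2.0, "c": -2.0})
        est = estimate_changes(daily, PhaseCalendar())
        assert (est.table["pred_change"] < 0).all()
        assert est.mu == pytest.approx(-2.0, abs=0.3)

    def test_summary_matches_injected_signs(self):
        daily = self._daily({"a": -3.0, "b": -3.0, "c": 3.0, "d": 3.0})
        est = estimate_changes(daily, PhaseCalendar())
        summary = summarize_changes({"toy": est}).iloc[0]
        assert summary["n_decrease"] == 2
        assert summary["n_increase"] == 2
        assert summary["n_no_change"] == 0

    def test_build_diffset_row_counts(self):
        daily = self._daily({"a": 0.0, "b": 0.0}, n_days=7)
        diffs = build_diffset(daily, PhaseCalendar())
        assert (diffs.groupby("individual_id").size() == 49).all()

    def test_individual_with_empty_phase_is_excluded_with_warning(self):
        daily = self._daily({"a": 0.0, "b": 0.0, "c": 0.0})
        daily = daily[
            ~((daily["individual_id"] == "c") & (pd.to_datetime(daily["date"]) < "2016-08-29"))
        ]
        with pytest.warns(UserWarning, match="c: no usable days"):
            diffs = build_diffset(daily, PhaseCalendar())
        assert set(diffs["individual_id"]) == {"a", "b"}
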