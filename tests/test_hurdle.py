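import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from schurdle import (
    CellTable,
    DesignSpec,
    PHASE_ORDER,
    SimulationSpec,
    attach_truth_et,
    bonferroni_adjust,
    deviance_ratio,
    estimate_peaktime,
    fit_hurdle,
    lrt_cycle,
    simulate_dataset,
    union_test,
)
from schurdle.hurdle import build_design
from schurdle.hurdle import test_all_genes as run_cycle_tests


@pytest.fixture(scope="module")
def effect_table():
    """One gene with a planted cycle effect of size 1, 900 cells."""
    spec = SimulationSpec(
        n_genes=6, cells_per_group=100, plates_per_batch=1, n_batches=1,
        cycle_effect_genes=(0,), cycle_effect_size=1.0, seed=11,
    )
    table, truth = simulate_dataset(spec)
    return attach_truth_et(table, truth), truth


class TestFitHurdle:
    def test_null_gene_coefficients_near_zero(self, effect_table):
        table, _ = effect_table
        fit = fit_hurdle(table, "G003", DesignSpec())  # no planted cycle effect
        for coef, se in ((fit.coef_cont, fit.se_cont), (fit.coef_disc, fit.se_disc)):
            for name, c, s in zip(fit.names, coef, se):
                if name.startswith("cycle"):
                    assert abs(c) < 3 * s, f"{name}: {c} vs SE {s}"

    def test_planted_cycle_effect_recovered_within_3_se(self, effect_table):
        table, truth = effect_table
        fit = fit_hurdle(table, "G000", DesignSpec())
        for j, phase in enumerate(PHASE_ORDER[:2]):
            i = fit.names.index(f"cycle[{phase}]")
            assert abs(fit.coef_cont[i] - truth.cycle_mean[0][j]) < 3 * fit.se_cont[i]
            assert abs(fit.coef_disc[i] - truth.cycle_logit[0][j]) < 3 * fit.se_disc[i]

    def test_deviance_is_minus_two_total_loglik(self, effect_table):
        table, _ = effect_table
        fit = fit_hurdle(table, "G000", DesignSpec())
        assert abs(fit.deviance + 2 * (fit.loglik_disc + fit.loglik_cont)) < 1e-10

    def test_fully_expressed_gene_drops_discrete_part(self):
        rng = np.random.default_rng(8)
        n = 120
        df = pd.DataFrame(
            dict(
                cell_id=[f"c{i}" for i in range(n)],
                gene_id="g1",
                cell_line=rng.choice(["A", "B"], n),
                cycle=rng.choice(list(PHASE_ORDER), n),
                ngeneson=rng.uniform(0.5, 0.9, n),
                et=rng.normal(8, 1, n),
            )
        )
        fit = fit_hurdle(CellTable(df), "g1", DesignSpec())
        assert "discrete_degenerate" in fit.flags and fit.loglik_disc == 0.0
        res = lrt_cycle(fit, fit_hurdle(CellTable(df), "g1", DesignSpec().without_cycle()))
        assert res.lambda_d == 0.0 and res.df_d == 0 and res.df_c == 2


class TestLRT:
    def test_full_equals_reduced_gives_zero(self, effect_table):
        table, _ = effect_table
        fit = fit_hurdle(table, "G000", DesignSpec())
        res = lrt_cycle(fit, fit)
        assert res.lam == 0.0 and res.p_combined == 1.0

    def test_combined_statistic_is_sum_of_component_lrts(self, effect_table):
        """Matches independently computed logistic-only and OLS-only LRTs."""
        table, _ = effect_table
        df = table.df[table.df["gene_id"] == "G000"]
        full_spec = DesignSpec().resolve(df)
        Xf, _ = build_design(df, full_spec)
        Xr, _ = build_design(df, full_spec.without_cycle())
        y = (df["et"] > 0).astype(float).to_numpy()
        lam_d = 2 * (
            sm.GLM(y, Xf, family=sm.families.Binomial()).fit().llf
            - sm.GLM(y, Xr, family=sm.families.Binomial()).fit().llf
        )
        pos = df["et"].to_numpy() > 0
        yp = df["et"].to_numpy()[pos]
        n = pos.sum()
        lam_c = n * np.log(
            sm.OLS(yp, Xr[pos]).fit().ssr / sm.OLS(yp, Xf[pos]).fit().ssr
        )
        res = lrt_cycle(
            fit_hurdle(table, "G000", DesignSpec()),
            fit_hurdle(table, "G000", DesignSpec().without_cycle()),
        )
        assert abs(res.lam - (res.lambda_d + res.lambda_c)) == 0.0
        assert abs(res.lambda_d - lam_d) < 1e-8
        assert abs(res.lambda_c - lam_c) < 1e-6

    def test_four_degrees_of_freedom_for_three_phases(self, effect_table):
        table, _ = effect_table
        res = lrt_cycle(
            fit_hurdle(table, "G000", DesignSpec()),
            fit_hurdle(table, "G000", DesignSpec().without_cycle()),
        )
        assert res.df_d == 2 and res.df_c == 2 and res.df == 4

    def test_statistic_invariant_to_factor_level_order(self, effect_table):
        """Sum-to-zero coding makes the test reference-level free."""
        table, _ = effect_table
        base = DesignSpec()
        rotated = DesignSpec(cycle_levels=("S", "G2/M", "G0/G1"),
                             line_levels=("PC3", "H9", "MB231"))
        r1 = lrt_cycle(
            fit_hurdle(table, "G000", base),
            fit_hurdle(table, "G000", base.without_cycle()),
        )
        r2 = lrt_cycle(
            fit_hurdle(table, "G000", rotated),
            fit_hurdle(table, "G000", rotated.without_cycle()),
        )
        assert abs(r1.lam - r2.lam) < 1e-6

    def test_non_nested_designs_raise(self, effect_table):
        table, _ = effect_table
        full = fit_hurdle(table, "G000", DesignSpec(ngeneson=False))
        reduced = fit_hurdle(table, "G000", DesignSpec().without_cycle())
        with pytest.raises(ValueError, match="nested"):
            lrt_cycle(full, reduced)


class TestUnionAndAdjust:
    @pytest.mark.parametrize(
        "p_d,p_c,alpha,expected",
        [(0.001, 0.9, 0.05, True), (0.5, 0.5, 0.05, False), (0.026, 0.9, 0.05, False),
         (0.025, 0.9, 0.05, True)],
    )
    def test_union_rejects_on_component_at_half_alpha(self, p_d, p_c, alpha, expected):
        assert union_test(p_d, p_c, alpha) is expected

    def test_union_component_level_override(self):
        assert union_test(0.04, 0.9, alpha=0.05, component_level=0.05)

    def test_invalid_pvalues_raise(self):
        with pytest.raises(ValueError):
            union_test(-0.1, 0.5)

    @pytest.mark.parametrize(
        "p,m,expected", [(0.0001, 253, 0.0253), (0.5, 253, 1.0), (0.3, 1, 0.3)]
    )
    def test_bonferroni(self, p, m, expected):
        adj = bonferroni_adjust(np.full(m, p))
        assert np.isclose(adj[0], expected)


class TestDevianceRatio:
    def test_equals_ols_r2_when_fully_continuous(self):
        rng = np.random.default_rng(5)
        n = 300
        df = pd.DataFrame(
            dict(
                cell_id=[f"c{i}" for i in range(n)],
                gene_id="g1",
                cell_line=rng.choice(["A", "B", "C"], n),
                cycle=rng.choice(list(PHASE_ORDER), n),
                ngeneson=rng.uniform(0.4, 0.9, n),
            )
        )
        spec = DesignSpec(interactions=True).resolve(df)
        X, _ = build_design(df, spec)
        df["et"] = 5 + X @ rng.normal(0, 0.5, X.shape[1]) + rng.normal(0, 1, n)
        dec = deviance_ratio(CellTable(df), "g1", spec)
        Xr, _ = build_design(df, spec.without_cycle())
        r2 = 1 - sm.OLS(df["et"], X).fit().ssr / sm.OLS(df["et"], Xr).fit().ssr
        assert abs(dec.ratio - r2) < 1e-8
        assert "discrete_degenerate" in dec.flags

    def test_null_gene_ratio_is_small(self, effect_table):
        table, _ = effect_table
        dec = deviance_ratio(table, "G004", DesignSpec(interactions=True))
        assert dec.ratio < 0.03

    def test_pure_cycle_signal_ratio_approaches_one(self):
        n_per = 60
        rows = []
        means = {"G0/G1": 4.0, "S": 8.0, "G2/M": 12.0}
        rng = np.random.default_rng(1)
        for phase, mu in means.items():
            for i in range(n_per):
                rows.append(
                    dict(
                        cell_id=f"{phase}{i}", gene_id="g1", cell_line="A",
                        cycle=phase, ngeneson=0.5,
                        et=mu + rng.normal(0, 1e-3),
                    )
                )
        dec = deviance_ratio(
            CellTable(pd.DataFrame(rows)), "g1", DesignSpec(cell_line=False, ngeneson=False)
        )
        assert dec.ratio > 0.999

    def test_deflated_ratio_scaling(self, effect_table):
        table, _ = effect_table
        dec = deviance_ratio(table, "G000", DesignSpec(interactions=True), max_ratio=0.27)
        assert np.isclose(dec.deflated_ratio, dec.ratio / 0.27)

    def test_omitting_ngeneson_attenuates_the_ratio(self):
        """Unmodeled efficiency variation inflates residual deviance."""
        spec = SimulationSpec(
            n_genes=8, cells_per_group=35, cycle_effect_genes=(0, 1, 2),
            efficiency_sd=0.7, seed=9,
        )
        table, truth = simulate_dataset(spec)
        tt = attach_truth_et(table, truth)
        with_ng, without_ng = [], []
        for g in ("G000", "G001", "G002"):
            with_ng.append(deviance_ratio(tt, g, DesignSpec(interactions=True)).ratio)
            without_ng.append(
                deviance_ratio(tt, g, DesignSpec(interactions=True, ngeneson=False)).ratio
            )
        assert np.median(without_ng) < np.median(with_ng)


class TestPeaktime:
    def _table_with_means(self, means):
        rows = []
        for phase, mu in zip(PHASE_ORDER, means):
            for i in range(20):
                rows.append(
                    dict(cell_id=f"{phase}{i}", gene_id="g1", cycle=phase, et=float(mu))
                )
        return CellTable(pd.DataFrame(rows))

    def test_argmax_phase(self):
        peak, tie = estimate_peaktime(self._table_with_means([2, 2, 5]), "g1")
        assert peak == "G2/M" and not tie

    def test_all_equal_means_tie_to_first_phase(self):
        peak, tie = estimate_peaktime(self._table_with_means([3, 3, 3]), "g1")
        assert peak == "G0/G1" and tie

    def test_planted_peak_recovered_in_simulation(self):
        hits = 0
        for r in range(100):
            spec = SimulationSpec(
                n_genes=4, cells_per_group=25, cycle_effect_genes=(2,),
                cycle_effect_size=1.5, seed=r,
            )
            table, truth = simulate_dataset(spec)
            tt = attach_truth_et(table, truth)
            peak, _ = estimate_peaktime(tt, "G002")
            hits += peak == PHASE_ORDER[truth.peak_phase[2]]
        assert hits / 100 >= 0.95


def test_combined_test_dominates_components_under_two_part_effects():
    """With effects in both parts, the combined LRT rejects at least as
    often as either component test or the union test at the same level."""
    spec = SimulationSpec(
        n_genes=60, cells_per_group=35, cycle_effect_genes=tuple(range(60)),
        cycle_effect_size=0.5, freq_range=(0.3, 0.6), seed=77,
    )
    table, truth = simulate_dataset(spec)
    tt = attach_truth_et(table, truth)
    res = run_cycle_tests(tt)
    n_combined = int((res["p"] < 0.05).sum())
    n_disc = int((stats.chi2.sf(res["lambda_d"], 2) < 0.05).sum())
    n_cont = int((stats.chi2.sf(res["lambda_c"], 2) < 0.05).sum())
    n_union = int(res["union_reject"].sum())
    assert n_combined >= max(n_disc, n_cont, n_union)
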