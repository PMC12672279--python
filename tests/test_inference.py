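"""ANOVA bookkeeping, Tukey HSD, correlations — with an independent
first-principles oracle for the balanced two-way decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import droughtscreen as ds
from droughtscreen.inference import UnbalancedDesignError, format_p


def manual_anova(df):
    """Balanced two-way (+ replication block) ANOVA by direct mean sums."""
    y = df["value"]
    gm = y.mean()
    n_g = df["genotype"].nunique()
    n_t = df["treatment"].nunique()
    n_r = df["replicate"].nunique()
    ss_g = n_t * n_r * ((df.groupby("genotype")["value"].mean() - gm) ** 2).sum()
    ss_t = n_g * n_r * ((df.groupby("treatment")["value"].mean() - gm) ** 2).sum()
    ss_r = n_g * n_t * ((df.groupby("replicate")["value"].mean() - gm) ** 2).sum()
    cell = df.groupby(["genotype", "treatment"])["value"].mean()
    gmean = df.groupby("genotype")["value"].mean()
    tmean = df.groupby("treatment")["value"].mean()
    ss_gt = n_r * sum(
        (cell[g, t] - gmean[g] - tmean[t] + gm) ** 2
        for g, t in cell.index
    )
    ss_tot = ((y - gm) ** 2).sum()
    ss_e = ss_tot - ss_g - ss_t - ss_r - ss_gt
    return {"Genotypes": ss_g, "Treatments": ss_t, "Replication": ss_r,
            "Genotypes x Treatments": ss_gt, "Error": ss_e, "Total": ss_tot}


class TestAnova:
    def test_df_bookkeeping_full_design(self, cohort):
        a = ds.anova_glm(cohort, "DSG")
        assert a.table["df"].tolist() == [36, 2, 2, 72, 220, 332]

    def test_df_bookkeeping_two_treatment_design(self, cohort):
        a = ds.anova_glm(cohort, "MDA")
        assert a.table.loc["Treatments", "df"] == 1
        assert a.table.loc["Genotypes x Treatments", "df"] == 36
        assert a.table.loc["Total", "df"] == 221

    @pytest.mark.parametrize("trait", ["TDW", "Pro", "R/S"])
    def test_matches_first_principles_oracle(self, cohort, trait):
        a = ds.anova_glm(cohort, trait)
        oracle = manual_anova(cohort.trait_frame(trait))
        for src, ss in oracle.items():
            assert a.table.loc[src, "ss"] == pytest.approx(ss, rel=1e-8), src

    def test_ss_additive(self, cohort):
        a = ds.anova_glm(cohort, "NSR")
        parts = a.table.loc[
            ["Genotypes", "Treatments", "Replication", "Genotypes x Treatments", "Error"],
            "ss",
        ].sum()
        assert parts == pytest.approx(a.table.loc["Total", "ss"], rel=1e-8)
        assert (
            a.table["ss"].iloc[:5] / a.table["df"].iloc[:5]
        ).tolist() == pytest.approx(a.table["ms"].iloc[:5].tolist())

    def test_constant_response_degenerate(self):
        rows = [
            (f"G{g}", t, r, "RL", 5.0)
            for g in range(3) for t in ("T0", "T1", "T2") for r in (1, 2)
        ]
        t = ds.TraitTable(
            pd.DataFrame(rows, columns=["genotype", "treatment", "replicate", "trait", "value"]),
            require_balanced=False,
        )
        a = ds.anova_glm(t, "RL")
        assert a.degenerate
        assert (a.table["ss"] == 0).all()
        assert a.table["f"].isna().all()

    def test_unbalanced_refused_with_cell_report(self, cohort):
        df = cohort.data
        mask = ~(
            (df.genotype == "G1") & (df.treatment == "T2")
            & (df.replicate == 3) & (df.trait == "RL")
        )
        broken = ds.TraitTable(df[mask], require_balanced=False)
        with pytest.raises(UnbalancedDesignError, match="G1"):
            ds.anova_glm(broken, "RL")

    def test_p_floor_formatting(self):
        assert format_p(1e-20) == "<1e-16"
        assert format_p(0.034) == "0.034"


class TestTukey:
    def _flat_table(self, mu, seed, n_g=8, n_r=3):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(n_g):
            for t, m in mu.items():
                for r in range(1, n_r + 1):
                    rows.append((f"G{g+1}", t, r, "RL", max(m + rng.normal(0, 0.5), 0.0)))
        return ds.TraitTable(
            pd.DataFrame(rows, columns=["genotype", "treatment", "replicate", "trait", "value"]),
            require_balanced=False,
        )

    def test_identical_populations_share_letter(self):
        t = self._flat_table({"T0": 5.0, "T1": 5.0, "T2": 5.0}, seed=0)
        tk = ds.tukey_treatments(t, "RL")
        assert len(set(tk.letters.values())) == 1

    def test_forced_separation_distinct_letters(self):
        t = self._flat_table({"T0": 5.0, "T1": 10.0, "T2": 15.0}, seed=1)
        tk = ds.tukey_treatments(t, "RL")
        assert sorted(tk.letters.values()) == ["a", "b", "c"]
        # letters ordered from the largest mean down
        assert tk.letters["T2"] == "a"

    def test_adjusted_p_not_below_unadjusted_t(self):
        t = self._flat_table({"T0": 5.0, "T1": 5.4, "T2": 6.0}, seed=2)
        tk = ds.tukey_treatments(t, "RL")
        a = ds.anova_glm(t, "RL")
        ms_e, df_e = a.table.loc["Error", "ms"], int(a.table.loc["Error", "df"])
        n = len(t.trait_frame("RL")) / 3
        for row in tk.comparisons.itertuples():
            tstat = abs(row.diff) / np.sqrt(2 * ms_e / n)
            p_t = 2 * stats.t.sf(tstat, df_e)
            assert row.p_adj >= p_t - 1e-12

    def test_studentized_range_probability_against_simulation(self):
        # independent check of the p machinery: P(range of k=3 normal
        # group means / SE > q_obs) by Monte Carlo with known variance
        rng = np.random.default_rng(7)
        k, n, reps = 3, 30, 4000
        sims = rng.normal(size=(reps, k, n)).mean(axis=2) * np.sqrt(n)
        q = sims.max(axis=1) - sims.min(axis=1)
        q_obs = 3.0
        mc = (q > q_obs).mean()
        exact = stats.studentized_range.sf(q_obs, k, np.inf)
        assert mc == pytest.approx(exact, abs=3 * np.sqrt(exact * (1 - exact) / reps))


class TestCorrelations:
    def test_duplicated_and_negated_traits(self, cohort):
        df = cohort.data
        dup = df[df.trait == "RL"].assign(trait="Chla")  # reuse a slot
        neg = df[df.trait == "RL"].assign(trait="Chlb", value=lambda d: d.value.max() - d.value)
        t = ds.TraitTable(
            pd.concat([df[df.trait == "RL"], dup, neg]), require_balanced=False
        )
        cm = ds.correlation_by_treatment(t, ["RL", "Chla", "Chlb"], "T0")
        assert cm.r.loc["RL", "Chla"] == pytest.approx(1.0)
        assert cm.r.loc["RL", "Chlb"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_psd(self, cohort):
        cm = ds.correlation_by_treatment(cohort, list(ds.GROWTH_ROOT_TRAITS), "T0")
        r = cm.r.to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert np.linalg.eigvalsh(r).min() >= -1e-10
        assert cm.n == 37

    def test_zero_variance_flagged(self):
        rows = [(f"G{g}", "T0", 1, "RL", float(g)) for g in range(5)]
        rows += [(f"G{g}", "T0", 1, "SL", 4.0) for g in range(5)]
        t = ds.TraitTable(
            pd.DataFrame(rows, columns=["genotype", "treatment", "replicate", "trait", "value"]),
            require_balanced=False,
        )
        cm = ds.correlation_by_treatment(t, ["RL", "SL"], "T0")
        assert cm.degenerate == ("SL",)
        assert np.isnan(cm.r.loc["RL", "SL"])


class TestShiftSummary:
    def _mat(self, vals):
        r = pd.DataFrame(
            [[1.0, vals[0]], [vals[0], 1.0]], index=["A", "B"], columns=["A", "B"]
        )
        return r

    def _matrices(self, triple):
        from droughtscreen.inference import CorrelationMatrix

        return {
            t: CorrelationMatrix(t, ("A", "B"), self._mat([v]), 10)
            for t, v in zip(("T0", "T1", "T2"), triple)
        }

    @pytest.mark.parametrize(
        "triple, expected",
        [
            ((0.8, 0.3, -0.5), "decreasing"),
            ((-0.2, 0.3, 0.7), "increasing"),
            ((0.5, 0.5, 0.5), "non-monotone"),
            ((0.2, 0.6, 0.4), "non-monotone"),
        ],
    )
    def test_classification(self, triple, expected):
        out = ds.correlation_shift_summary(self._matrices(triple))
        assert out.iloc[0]["classification"] == expected
        if expected == "non-monotone" and len(set(triple)) == 1:
            assert out.iloc[0]["span"] == 0.0

    def test_mismatched_traits_rejected(self):
        from droughtscreen.inference import CorrelationMatrix

        mats = self._matrices((0.1, 0.2, 0.3))
        mats["T2"] = CorrelationMatrix("T2", ("A", "C"), self._mat([0.3]), 10)
        with pytest.raises(ValueError):
            ds.correlation_shift_summary(mats)
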