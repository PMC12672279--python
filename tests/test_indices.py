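"""Tolerance indices: definitions, inversion, composite score, auditor."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import droughtscreen as ds
from droughtscreen.indices import PRINT_TOL, cohort_means


MEANS = ds.CohortMeans(xc=1.0, xt=0.5)


class TestComputeIndices:
    def test_no_stress_effect_case(self):
        v = ds.compute_indices(ds.DryWeightPair(1.0, 1.0), MEANS)
        assert (v.ssi, v.mpi, v.gmpi, v.hmi, v.sti, v.ti, v.si) == (0, 1, 1, 1, 1, 0, 1)

    def test_total_loss_case(self):
        v = ds.compute_indices(ds.DryWeightPair(1.0, 0.0), MEANS)
        assert (v.si, v.gmpi, v.hmi, v.ti, v.mpi, v.ssi) == (0, 0, 0, 1, 0.5, 2)

    def test_published_row_back_derivation(self):
        # recover (c, t) from one published row's MPI/SI, recompute all
        pair = ds.recover_c_t(mpi=0.173, si=0.891)
        assert pair.c == pytest.approx(0.18297, abs=5e-5)
        assert pair.t == pytest.approx(0.16303, abs=5e-5)
        v = ds.compute_indices(pair, ds.CohortMeans(0.1663, 0.1448))
        assert v.ti == pytest.approx(0.020, abs=PRINT_TOL)
        assert v.hmi == pytest.approx(0.172, abs=PRINT_TOL)
        assert v.sti == pytest.approx(1.079, abs=5e-3)
        assert v.ssi == pytest.approx(0.842, abs=5e-3)
        as_pub = ds.compute_indices(pair, ds.CohortMeans(0.1663, 0.1448), mode="as_published")
        assert as_pub.gmpi == pytest.approx(0.0298, abs=2e-4)

    def test_equal_cohort_means_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ds.compute_indices(ds.DryWeightPair(1.0, 0.5), ds.CohortMeans(1.0, 1.0))

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            ds.DryWeightPair(0.0, 0.5)

    def test_brute_force_toy_cohort(self):
        cs = [0.9, 1.1, 1.0, 1.3, 0.7]
        ts = [0.5, 0.8, 0.2, 1.3, 0.6]
        xc, xt = np.mean(cs), np.mean(ts)
        for c, t in zip(cs, ts):
            v = ds.compute_indices(ds.DryWeightPair(c, t), ds.CohortMeans(xc, xt))
            assert v.ssi == (1 - t / c) / (1 - xt / xc)
            assert v.mpi == (c + t) / 2
            assert v.gmpi == np.sqrt(c * t)
            assert v.hmi == 2 * c * t / (c + t)
            assert v.sti == c * t / xc**2
            assert v.ti == c - t
            assert v.si == t / c


class TestSts:
    def test_zero_components(self):
        v = ds.IndexVector(0, 0, 0, 0, 0, 0, 0)
        assert ds.compute_sts(v) == 0.0

    def test_published_spot_rows(self, published_indices_t1):
        sts = ds.compute_sts(published_indices_t1)
        assert sts["G45"] == pytest.approx(4.464, abs=1e-9)
        assert sts["G51"] == pytest.approx(4.107, abs=1e-9)

    def test_standardized_mode_sums_zscores(self, published_indices_t1):
        z = ds.compute_sts(published_indices_t1, mode="standardized")
        assert z.sum() == pytest.approx(0.0, abs=1e-9)
        # independent recomputation of one row's z-score sum
        m = published_indices_t1[list(ds.datasets.INDEX_COLUMNS)]
        expected = ((m.loc["G45"] - m.mean()) / m.std(ddof=0)).sum()
        assert z["G45"] == pytest.approx(expected)


class TestRecovery:
    def test_symmetric_case(self):
        p = ds.recover_c_t(1.0, 1.0)
        assert (p.c, p.t) == (1.0, 1.0)

    def test_stress_exceeding_control(self):
        p = ds.recover_c_t(0.142, 2.036)
        assert p.c == pytest.approx(0.0935, abs=5e-4)
        assert p.t == pytest.approx(0.1905, abs=5e-4)
        assert p.t > p.c  # consistent with a negative published TI

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ds.recover_c_t(0.0, 0.5)
        with pytest.raises(ValueError):
            ds.recover_c_t(0.1, -1.0)

    @given(
        st.floats(0.01, 10.0),
        st.floats(0.0, 10.0),
    )
    def test_round_trip_property(self, c, t):
        v = ds.compute_indices(ds.DryWeightPair(c, t), MEANS)
        back = ds.recover_c_t(v.mpi, v.si)
        assert back.c == pytest.approx(c, rel=1e-12, abs=1e-12)
        assert back.t == pytest.approx(t, rel=1e-12, abs=1e-12)


class TestOrderingAndScaling:
    @given(st.floats(0.01, 10.0), st.floats(0.001, 10.0))
    def test_am_gm_hm_ordering(self, c, t):
        v = ds.compute_indices(ds.DryWeightPair(c, t), MEANS)
        assert v.hmi <= v.gmpi + 1e-12 <= v.mpi + 1e-12
        if abs(c - t) > 1e-6:
            assert v.hmi < v.mpi

    @given(st.floats(0.01, 10.0), st.floats(0.001, 10.0), st.floats(0.1, 10.0))
    def test_scale_behavior(self, c, t, k):
        means = ds.CohortMeans(2.0, 1.0)
        v = ds.compute_indices(ds.DryWeightPair(c, t), means)
        vk = ds.compute_indices(
            ds.DryWeightPair(k * c, k * t), ds.CohortMeans(2.0 * k, 1.0 * k)
        )
        assert vk.si == pytest.approx(v.si, rel=1e-9)
        assert vk.ssi == pytest.approx(v.ssi, rel=1e-9)
        assert vk.sti == pytest.approx(v.sti, rel=1e-9)
        for name in ("mpi", "gmpi", "hmi", "ti"):
            assert getattr(vk, name) == pytest.approx(k * getattr(v, name), rel=1e-9)

    def test_mpi_ti_identities(self):
        v = ds.compute_indices(ds.DryWeightPair(0.9, 0.4), MEANS)
        assert v.mpi + v.ti / 2 == pytest.approx(0.9)
        assert v.mpi - v.ti / 2 == pytest.approx(0.4)
        assert v.sti == pytest.approx(v.gmpi**2 / MEANS.xc**2)


class TestIndexMatrix:
    def test_from_cohort(self, cohort):
        im = ds.index_matrix(cohort, "T2")
        assert list(im.columns) == list(ds.datasets.INDEX_COLUMNS) + ["STS"]
        assert len(im) == 37
        assert im.notna().all().all()
        np.testing.assert_allclose(
            im["STS"], im[list(ds.datasets.INDEX_COLUMNS)].sum(axis=1)
        )
        cm = cohort_means(cohort, "T2")
        g = im.index[0]
        c = cohort.genotype_means("TDW", "T0")[g]
        t = cohort.genotype_means("TDW", "T2")[g]
        assert im.loc[g, "STI"] == pytest.approx(c * t / cm.xc**2)


class TestAuditor:
    def test_round_trip_matrix_audits_clean(self, cohort):
        im = ds.index_matrix(cohort, "T1", mode="as_published")
        report = ds.audit_published_table(im, means=cohort_means(cohort, "T1"))
        # exact inputs: all deviations are numerically zero
        assert report.deviations.max().max() < 1e-9
        assert report.gmpi_matches_product

    def test_published_tables_sts_and_gmpi(self, published_indices_t1, published_indices_t2):
        for pub in (published_indices_t1, published_indices_t2):
            a = ds.audit_published_table(pub)
            assert a.gmpi_matches_product  # product, not sqrt
            assert a.sts_is_row_sum
            # TI and HMI reproduce at printed precision for every row
            assert not a.flagged["TI"].any()
            assert not a.flagged["HMI"].any()
            # STI is explained by input rounding of the 3-dp MPI/SI
            assert not a.envelope_exceeded["STI"].any()
            # the SSI column is NOT consistent with the SI column: a
            # genuine inconsistency of the published table
            assert a.envelope_exceeded["SSI"].all()

    def test_inferred_control_mean_matches_descriptives(self, published_indices_t1):
        a = ds.audit_published_table(published_indices_t1)
        assert round(a.inferred_xc, 2) == 0.17

    def test_non_invertible_rows_listed_not_fatal(self, published_indices_t1):
        broken = published_indices_t1.copy()
        broken.loc["G1", "SI"] = -1.0
        a = ds.audit_published_table(broken)
        assert a.non_invertible == ("G1",)
        assert len(a.recomputed) == 36
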