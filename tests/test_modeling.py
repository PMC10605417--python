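import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from episig.core import AnalysisConfig, BetaMatrix, ConfigError, DesignError, MValueMatrix, SampleSheet
from episig.modeling import (
    DesignMatrix,
    EbPrior,
    ModeratedFit,
    bh_fdr,
    build_design,
    call_signature,
    compare_signatures,
    ebayes_moderate,
    estimate_prior,
    fit_probewise,
    group_delta_beta,
    levene_scan,
)
from episig.resources import human_ks1_overlap_sites, mouse_ks1_overlap_sites


def _mvm(vals, samples=None):
    probes = pd.Index([f"p{i}" for i in range(vals.shape[0])], name="probe_id")
    samples = samples or [f"s{i}" for i in range(vals.shape[1])]
    return MValueMatrix(pd.DataFrame(vals, index=probes, columns=pd.Index(samples)))


class TestBuildDesign:
    def test_genotype_day_coding(self, tiny_sheet):
        d = build_design(tiny_sheet, "genotype")
        assert list(d.columns) == ["intercept", "genotype", "day"]
        assert d.frame["genotype"].tolist() == [0, 0, 1, 1]
        assert d.frame["day"].tolist() == [0, 1, 0, 1]

    def test_constant_day_dropped_with_warning(self, tiny_sheet):
        sheet = SampleSheet(tiny_sheet.data.assign(day_of_sacrifice=1))
        with pytest.warns(UserWarning, match="day"):
            d = build_design(sheet, "genotype")
        assert "day" not in d.columns

    def test_constant_main_effect_rejected(self, tiny_sheet):
        sheet = SampleSheet(tiny_sheet.data.assign(genotype="WT"))
        with pytest.raises(DesignError, match="constant"):
            build_design(sheet, "genotype")

    def test_volume_model_rejects_svs(self, tiny_sheet):
        from episig.surrogate import SurrogateSet

        sheet = SampleSheet(tiny_sheet.data.assign(total_brain_volume_mm3=[400.0, 410, 380, 390]))
        svs = SurrogateSet(sheet.data.index, 1,
                           pd.DataFrame({"SV1": [0.5, -0.5, 0.5, -0.5]}, index=sheet.data.index),
                           np.array([0.5]))
        with pytest.raises(DesignError, match="volume"):
            build_design(sheet, "total_brain_volume", svs=svs)

    def test_volume_is_centered_and_missing_rows_dropped(self, tiny_sheet):
        sheet = SampleSheet(tiny_sheet.data.assign(total_brain_volume_mm3=[400.0, 410, np.nan, 390]))
        with pytest.warns(UserWarning, match="volume"):
            d = build_design(sheet, "total_brain_volume")
        assert len(d.frame) == 3
        assert d.frame["total_brain_volume"].mean() == pytest.approx(0.0)


class TestFitProbewise:
    def _design(self, n=4):
        frame = pd.DataFrame(
            {"intercept": 1.0, "genotype": [0.0, 0.0, 1.0, 1.0][:n]},
            index=pd.Index([f"s{i}" for i in range(n)]),
        )
        return DesignMatrix(frame, "genotype")

    def test_perfect_fit_gives_unit_coefficient_zero_variance(self):
        fits = fit_probewise(_mvm(np.array([[0.0, 0.0, 1.0, 1.0]])), self._design())
        assert fits["b"].iloc[0] == pytest.approx(1.0)
        assert fits["s2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_least_squares_with_missingness(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(30, 4))
        vals[0, 1] = np.nan
        d = self._design()
        fits = fit_probewise(_mvm(vals), d)
        # probe 0 by hand on its 3 complete cases
        keep = [0, 2, 3]
        X = d.values[keep]
        y = vals[0, keep]
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fits.loc["p0", "b"] == pytest.approx(b[1], abs=1e-12)
        assert fits.loc["p0", "n_used"] == 3

    def test_insufficient_complete_cases_give_missing_stats(self):
        vals = np.array([[0.1, np.nan, np.nan, 0.4]])
        fits = fit_probewise(_mvm(vals), self._design())
        assert np.isnan(fits["b"].iloc[0]) and np.isnan(fits["s2"].iloc[0])

    def test_null_probes_rarely_significant(self):
        rng = np.random.default_rng(3)
        n = 40
        frame = pd.DataFrame({"intercept": 1.0, "genotype": np.repeat([0.0, 1.0], 20)},
                             index=pd.Index([f"s{i}" for i in range(n)]))
        fits = fit_probewise(_mvm(rng.normal(size=(500, n))), DesignMatrix(frame, "genotype"))
        t = fits["b"] / np.sqrt(fits["s2"] * fits["v"])
        assert (np.abs(t) > 3.6).mean() < 0.01  # ~0.1% nominal at df=38


class TestEmpiricalBayes:
    def test_matches_limma_oracle_on_frozen_fixture(self):
        """Frozen cross-check against the Bioconductor limma fit on one fixture.

        Fixture: seed-42 scaled-inverse-chi-square variances (d0=4,
        s0^2=0.05), 200 probes x 12 samples, two groups.  The reference
        numbers below were produced by limma::eBayes(lmFit(...)).
        """
        rng = np.random.default_rng(42)
        P, n = 200, 12
        sg2 = 4 * 0.05 / stats.chi2.rvs(4, size=P, random_state=rng)
        Y = rng.normal(0, np.sqrt(sg2)[:, None], (P, n))
        group = np.repeat([0.0, 1.0], 6)
        Y[:20] += np.outer(rng.normal(0.5, 0.1, 20), group)
        frame = pd.DataFrame({"intercept": 1.0, "genotype": group},
                             index=pd.Index([f"s{i}" for i in range(n)]))
        fits = fit_probewise(_mvm(Y), DesignMatrix(frame, "genotype"))
        prior, mod = ebayes_moderate(fits)
        assert prior.d0 == pytest.approx(4.228973, rel=1e-5)
        assert prior.s0_sq == pytest.approx(0.04886709, rel=1e-5)
        expected_t = [2.3679022603, 4.5675146589, 4.09997855963, 6.30692698719, 3.6415991525]
        assert mod["t"].to_numpy()[:5] == pytest.approx(expected_t, abs=1e-9)

    def test_recovers_known_hyperparameters(self):
        rng = np.random.default_rng(0)
        d0, s0 = 4.0, 0.05
        sg2 = d0 * s0 / stats.chi2.rvs(d0, size=200, random_state=rng)
        s2 = sg2 * stats.chi2.rvs(10, size=200, random_state=rng) / 10
        prior = estimate_prior(s2, np.full(200, 10.0))
        assert prior.d0 == pytest.approx(d0, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0, rel=0.25)

    def test_equal_variances_give_degenerate_prior_and_classical_t(self):
        fits = pd.DataFrame({
            "b": np.linspace(-1, 1, 200), "s2": np.full(200, 0.04),
            "df": np.full(200, 10.0), "v": np.full(200, 0.2),
            "n_used": np.full(200, 12),
        }, index=[f"p{i}" for i in range(200)])
        prior, mod = ebayes_moderate(fits)
        assert np.isinf(prior.d0)
        assert mod["s2_post"].to_numpy() == pytest.approx(0.04)
        classical = fits["b"] / np.sqrt(fits["s2"] * fits["v"])
        assert mod["t"].to_numpy() == pytest.approx(classical.to_numpy(), abs=1e-12)

    def test_forced_no_shrinkage_prior_reproduces_classical_t(self):
        rng = np.random.default_rng(1)
        fits = pd.DataFrame({
            "b": rng.normal(size=150), "s2": rng.uniform(0.01, 0.2, 150),
            "df": np.full(150, 8.0), "v": np.full(150, 0.3),
            "n_used": np.full(150, 10),
        }, index=[f"p{i}" for i in range(150)])
        _, mod = ebayes_moderate(fits, prior=EbPrior(np.inf, None))
        classical = fits["b"] / np.sqrt(fits["s2"] * fits["v"])
        assert mod["t"].to_numpy() == pytest.approx(classical.to_numpy(), abs=1e-12)

    def test_too_few_probes_refused(self):
        fits = pd.DataFrame({"b": [1.0], "s2": [0.1], "df": [5.0], "v": [0.2], "n_used": [7]})
        with pytest.raises(ConfigError):
            ebayes_moderate(fits)


class TestBhFdr:
    def test_textbook_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_value(self):
        assert bh_fdr([1.0]) == pytest.approx([1.0])

    @staticmethod
    def _brute_force(p):
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        for rank_pos, i in enumerate(order, start=1):
            q[i] = min(
                min(m * p[j] / (list(order).index(j) + 1) for j in order[rank_pos - 1:]), 1.0
            )
        return q

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_equals_brute_force_stepup(self, pvals):
        p = np.asarray(pvals)
        assert bh_fdr(p) == pytest.approx(self._brute_force(p), abs=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=40))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_rank_and_bounded(self, pvals):
        p = np.asarray(pvals)
        q = bh_fdr(p)
        assert (q <= 1.0).all() and (q >= 0.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_missing_values_excluded_from_m(self):
        q = bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(0.02)  # m = 2, not 3


class TestDeltaBetaAndCalling:
    def test_group_means_difference(self, tiny_bm, tiny_sheet):
        delta = group_delta_beta(tiny_bm, tiny_sheet, ("KS1", "vehicle"), ("WT", "vehicle"))
        assert delta.loc["p1"] == pytest.approx(0.85 - 0.15)
        assert delta.loc["p2"] == pytest.approx(0.0)

    def test_insufficient_group_gives_missing(self, tiny_bm, tiny_sheet):
        bm = tiny_bm
        bm.beta.loc["p1", ["s3", "s4"]] = np.nan
        delta = group_delta_beta(bm, tiny_sheet, ("KS1", "vehicle"), ("WT", "vehicle"))
        assert np.isnan(delta.loc["p1"])

    @pytest.mark.parametrize("q,db,included", [
        (0.04, 0.06, True),
        (0.04, 0.03, False),
        (0.06, 0.20, False),
    ])
    def test_threshold_boundaries(self, q, db, included):
        table = pd.DataFrame({"q": [q], "delta_beta": [db]}, index=["p0"])
        sig = call_signature(ModeratedFit(table, EbPrior(np.inf, None), "genotype"),
                             AnalysisConfig())
        assert ("p0" in sig.probe_ids) == included
        if included:
            assert sig.direction_of("p0") == "hyper"


class TestLeveneScan:
    def _scan(self, a, b, center="median"):
        vals = np.concatenate([a, b])[None, :]
        probes = pd.Index(["p0"], name="probe_id")
        cols = pd.Index([f"s{i}" for i in range(vals.shape[1])])
        bm = BetaMatrix(pd.DataFrame(vals, index=probes, columns=cols))
        sheet = SampleSheet(pd.DataFrame({
            "genotype": ["WT"] * len(a) + ["KS1"] * len(b),
            "treatment": "vehicle", "day_of_sacrifice": 1,
        }, index=cols))
        return levene_scan(bm, sheet, ["p0"], center=center)

    def test_spread_difference_detected(self):
        out = self._scan(np.array([0.1, 0.5, 0.9]), np.array([0.5, 0.5, 0.5]))
        assert out["W"].iloc[0] > 3 and out["p"].iloc[0] < 0.2
        assert out["larger_range"].iloc[0] == "WT"

    def test_identical_groups_null(self):
        out = self._scan(np.array([0.4, 0.5, 0.6]), np.array([0.4, 0.5, 0.6]))
        assert out["W"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0
        assert out["larger_range"].iloc[0] == "tie"

    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_matches_scipy_levene(self, center):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(0, 1, 13), rng.uniform(0, 1, 10)
        out = self._scan(a, b, center=center)
        ref = stats.levene(a, b, center=center)
        assert out["W"].iloc[0] == pytest.approx(ref.statistic, abs=1e-10)
        assert out["p"].iloc[0] == pytest.approx(ref.pvalue, abs=1e-10)


class TestCompareSignatures:
    def test_published_tables_overlap(self):
        overlap = compare_signatures(mouse_ks1_overlap_sites(), human_ks1_overlap_sites())
        assert overlap.n_overlap == 19
        assert overlap.n_agree == 15
        assert bool(overlap.table.loc["ADO", "agree"]) is True
        assert bool(overlap.table.loc["DLG4", "agree"]) is False

    def test_case_insensitive_gene_matching(self):
        sig = pd.DataFrame({"gene": ["Ado"], "direction": ["hypo"]})
        ref = pd.DataFrame({"gene": ["ADO"], "direction": ["hypo"]})
        assert compare_signatures(sig, ref).n_agree == 1

    def test_mixed_direction_gene_never_agrees(self):
        sig = pd.DataFrame({"gene": ["G1", "G1"], "direction": ["hypo", "hyper"]})
        ref = pd.DataFrame({"gene": ["G1"], "direction": ["hypo"]})
        out = compare_signatures(sig, ref)
        assert out.table.loc["G1", "direction"] == "mixed"
        assert out.n_agree == 0
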