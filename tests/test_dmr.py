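import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episig.core import AnalysisConfig, ProbeManifest
from episig.dmr import (
    AcfEstimate,
    DmrRecord,
    estimate_acf,
    filter_dmrs,
    find_regions,
    genome_span_tested,
    score_region,
    slk_adjust,
)


def _manifest(positions, chrom="chr1"):
    probes = pd.Index([f"p{i}" for i in range(len(positions))], name="probe_id")
    chroms = [chrom] * len(positions) if isinstance(chrom, str) else chrom
    return ProbeManifest(pd.DataFrame({"chrom": chroms, "pos": positions}, index=probes))


def _flat_acf(cfg, value=0.0):
    edges = np.arange(cfg.acf_bin_bp, cfg.dmr_max_gap_bp + cfg.acf_bin_bp, cfg.acf_bin_bp)
    edges = np.unique(np.minimum(edges, cfg.dmr_max_gap_bp))
    return AcfEstimate(edges, np.full(len(edges), float(value)), np.zeros(len(edges)))


class TestEstimateAcf:
    def test_independent_pvalues_give_near_zero_correlation(self, acfg):
        rng = np.random.default_rng(0)
        pos = np.arange(3000) * 120 + 1  # dense grid: many pairs per bin
        man = _manifest(pos)
        p = pd.Series(rng.uniform(1e-6, 1, 3000), index=man.probe_ids)
        acf = estimate_acf(p, man, acfg)
        assert (np.abs(acf.correlations) < 0.05).all()

    def test_duplicated_pvalues_at_paired_positions_correlate(self, acfg):
        rng = np.random.default_rng(1)
        base = rng.uniform(1e-6, 1, 40)
        pvals, pos = [], []
        for i, b in enumerate(base):  # pairs 50 bp apart, pairs 5 kb from each other
            pos += [i * 5000 + 1, i * 5000 + 51]
            pvals += [b, b]
        man = _manifest(pos)
        acf = estimate_acf(pd.Series(pvals, index=man.probe_ids), man, acfg)
        assert acf.correlations[0] == pytest.approx(1.0, abs=1e-9)

    def test_single_probe_per_chromosome_warns_zero_pairs(self, acfg):
        man = _manifest([100, 200], chrom=["chr1", "chr2"])
        with pytest.warns(UserWarning, match="no intra-chromosome"):
            acf = estimate_acf(pd.Series([0.5, 0.5], index=man.probe_ids), man, acfg)
        assert (acf.correlations == 0).all()


class TestSlkAdjust:
    def test_isolated_probe_keeps_raw_p(self, acfg):
        man = _manifest([1000, 50_000])
        p = pd.Series([0.037, 0.81], index=man.probe_ids)
        adj = slk_adjust(p, man, _flat_acf(acfg), acfg)
        assert adj.to_numpy() == pytest.approx(p.to_numpy(), abs=1e-9)

    def test_independent_neighbors_stouffer(self, acfg):
        man = _manifest([1000, 1100])
        z = 1.0
        p_each = float(stats.norm.sf(z))
        adj = slk_adjust(pd.Series([p_each] * 2, index=man.probe_ids), man,
                         _flat_acf(acfg, 0.0), acfg)
        expected = stats.norm.sf(2 * z / np.sqrt(2.0))
        assert adj.to_numpy() == pytest.approx([expected] * 2, abs=1e-12)

    def test_perfect_correlation_collapses_evidence(self, acfg):
        man = _manifest([1000, 1100])
        z = 1.0
        p_each = float(stats.norm.sf(z))
        adj = slk_adjust(pd.Series([p_each] * 2, index=man.probe_ids), man,
                         _flat_acf(acfg, 1.0), acfg)
        expected = stats.norm.sf(2 * z / np.sqrt(4.0))  # z_comb = 1
        assert adj.to_numpy() == pytest.approx([expected] * 2, abs=1e-12)


class TestFindRegions:
    def test_contiguous_low_pvalues_form_one_region(self, acfg):
        man = _manifest([1000, 1080, 1160, 1240, 1320])
        adj = pd.Series(0.001, index=man.probe_ids)
        regions = find_regions(adj, man, acfg)
        assert len(regions) == 1 and len(regions[0].probe_ids) == 5
        assert regions[0].start == 1000 and regions[0].end == 1320

    def test_high_middle_probe_splits_region(self, acfg):
        man = _manifest([1000, 1080, 1160, 1240, 1320])
        adj = pd.Series([0.001, 0.001, 0.5, 0.001, 0.001], index=man.probe_ids)
        regions = find_regions(adj, man, acfg)
        assert [len(r.probe_ids) for r in regions] == [2, 2]

    def test_large_gap_splits_region(self, acfg):
        man = _manifest([1000, 1080, 6080, 6160])
        adj = pd.Series(0.001, index=man.probe_ids)
        regions = find_regions(adj, man, acfg)
        assert [len(r.probe_ids) for r in regions] == [2, 2]


class TestScoreRegion:
    def test_sidak_closed_form(self, acfg):
        man = _manifest([1000])
        region = DmrRecord("chr1", 1000, 1099, ["p0"])  # span 100 bp
        raw = pd.Series([0.01], index=man.probe_ids)
        scored = score_region(region, raw, man, _flat_acf(acfg), genome_span=1000)
        assert scored.slk_p == pytest.approx(0.01, abs=1e-12)
        assert scored.sidak_p == pytest.approx(1 - 0.99**10, abs=1e-12)

    def test_whole_span_region_keeps_slk_p(self, acfg):
        man = _manifest([1000, 1099])
        region = DmrRecord("chr1", 1000, 1099, ["p0", "p1"])
        raw = pd.Series([0.02, 0.04], index=man.probe_ids)
        scored = score_region(region, raw, man, _flat_acf(acfg), genome_span=100)
        assert scored.sidak_p == pytest.approx(scored.slk_p, abs=1e-12)

    def test_unit_pvalue_stays_unit(self, acfg):
        man = _manifest([1000])
        scored = score_region(DmrRecord("chr1", 1000, 1000, ["p0"]),
                              pd.Series([1.0], index=man.probe_ids), man,
                              _flat_acf(acfg), genome_span=1000)
        assert scored.sidak_p == 1.0

    def test_independent_acf_matches_classical_stouffer(self, acfg):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 0.5, 6)
        man = _manifest(np.arange(6) * 90 + 1000)
        region = DmrRecord("chr1", 1000, 1450, list(man.probe_ids))
        scored = score_region(region, pd.Series(p, index=man.probe_ids), man,
                              _flat_acf(acfg, 0.0), genome_span=451)
        z = stats.norm.isf(p)
        classical = stats.norm.sf(z.sum() / np.sqrt(len(z)))
        assert scored.slk_p == pytest.approx(classical, abs=1e-12)


class TestFilterDmrs:
    def _region(self, probe_ids, sidak):
        r = DmrRecord("chr1", 1000, 1400, probe_ids)
        r.sidak_p = sidak
        r.slk_p = sidak / 10
        return r

    @pytest.mark.parametrize("deltas,sig_members,sidak,kept", [
        ([0.1, 0.1, 0.1], ["p0"], 0.001, True),        # 3 hyper, 1 signature
        ([0.1, 0.1, -0.1, -0.1], ["p0"], 0.001, False),  # no direction reaches 3
        ([0.1, 0.1, 0.1, -0.1, -0.1], ["p0"], 0.004, True),  # bidirectional but 3 hyper
        ([0.1, 0.1, 0.1], [], 0.001, False),            # no signature member
        ([0.1, 0.1, 0.1], ["p0"], 0.01, False),         # fails Sidak threshold
    ])
    def test_filter_rules(self, acfg, deltas, sig_members, sidak, kept):
        ids = [f"p{i}" for i in range(len(deltas))]
        region = self._region(ids, sidak)
        final = filter_dmrs([region], pd.Series(deltas, index=ids), sig_members, acfg)
        assert (len(final) == 1) == kept
        if deltas == [0.1, 0.1, 0.1, -0.1, -0.1] and kept:
            assert region.n_hyper == 3 and region.n_hypo == 2


def test_genome_span_sums_per_chromosome():
    man = _manifest([100, 400, 100, 200], chrom=["chr1", "chr1", "chr2", "chr2"])
    assert genome_span_tested(man, man.probe_ids) == (301 + 101)
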