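"""Differentially methylated region detection from probewise p-values.

Raw per-probe p-values are converted to z-scores, spatially smoothed with
the Stouffer-Liptak-Kechris combination using a distance-binned
autocorrelation (ACF) estimate, and runs of low adjusted p-values are
grown into candidate regions.  Each region is scored by the SLK
combination of its members' raw p-values and Sidak-corrected for the
fraction of the tested genome span it covers, then filtered by the
study's bespoke rules: a Sidak p below threshold, at least three members
methylated in the same direction, and at least one member in the
probewise signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, ProbeManifest, ValidationError

_PCLIP = 1e-15


@dataclass
class AcfEstimate:
    """Distance-binned correlation of p-value z-scores; lag 0 is fixed at 1."""

    bin_edges: np.ndarray  # right edges, bp; bins are (left, right]
    correlations: np.ndarray
    n_pairs: np.ndarray

    def corr_for_distance(self, dist: float) -> float:
        if dist <= 0:
            return 1.0
        idx = int(np.searchsorted(self.bin_edges, dist, side="left"))
        if idx >= len(self.correlations):
            return 0.0
        return float(self.correlations[idx])


@dataclass
class DmrRecord:
    chrom: str
    start: int  # 1-based inclusive (first probe position)
    end: int  # 1-based inclusive (last probe position)
    probe_ids: List[str]
    n_hyper: int = 0
    n_hypo: int = 0
    slk_p: float = np.nan
    sidak_p: float = np.nan
    contains_signature_cpg: bool = False
    passes_filters: bool = False
    underflow: bool = False

    def __post_init__(self) -> None:
        if len(self.probe_ids) < 1:
            raise ValidationError("a DMR needs at least one member probe")
        if self.start > self.end:
            raise ValidationError("DMR start must not exceed end")

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


def _aligned(pvals: pd.Series, manifest: ProbeManifest):
    """Sort probes by (chrom, pos) and return aligned positions and z-scores."""
    man = manifest.sorted_by_position().table
    man = man.loc[man.index.intersection(pvals.index)]
    p = pvals.reindex(man.index).to_numpy(dtype=float)
    if np.nanmin(p, initial=1.0) <= 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValidationError("p-values must lie in (0, 1]")
    z = stats.norm.isf(np.clip(p, _PCLIP, 1 - _PCLIP))
    return man, p, z


def estimate_acf(pvals: pd.Series, manifest: ProbeManifest, cfg: AnalysisConfig) -> AcfEstimate:
    """Correlation of z-scores for intra-chromosome probe pairs, by distance bin."""
    man, _, z = _aligned(pvals, manifest)
    edges = np.arange(cfg.acf_bin_bp, cfg.dmr_max_gap_bp + cfg.acf_bin_bp, cfg.acf_bin_bp)
    edges = np.minimum(edges, cfg.dmr_max_gap_bp)
    edges = np.unique(edges)
    pairs: List[List[Tuple[float, float]]] = [[] for _ in edges]

    pos_all = man["pos"].to_numpy()
    for _, idx in man.groupby("chrom", sort=False).indices.items():
        pos = pos_all[idx]
        zz = z[idx]
        for a in range(len(idx)):
            b = a + 1
            while b < len(idx) and pos[b] - pos[a] <= cfg.dmr_max_gap_bp:
                d = pos[b] - pos[a]
                bin_i = int(np.searchsorted(edges, d, side="left"))
                pairs[bin_i].append((zz[a], zz[b]))
                b += 1

    corr = np.zeros(len(edges))
    n_pairs = np.array([len(p) for p in pairs])
    if n_pairs.sum() == 0:
        warnings.warn("no intra-chromosome probe pairs within the ACF window; "
                      "combination degenerates to independence", stacklevel=2)
        return AcfEstimate(edges, corr, n_pairs)
    prev = 1.0  # zero-distance limit
    for i, bucket in enumerate(pairs):
        if len(bucket) >= 10:
            arr = np.asarray(bucket)
            both = np.concatenate([arr, arr[:, ::-1]])  # symmetrize the pair set
            prev = float(np.corrcoef(both[:, 0], both[:, 1])[0, 1])
        corr[i] = prev
    return AcfEstimate(edges, np.clip(corr, -1.0, 1.0), n_pairs)


def _slk_combine(z: np.ndarray, dists: np.ndarray, acf: AcfEstimate) -> float:
    """Stouffer-Liptak-Kechris z combination with ACF-based pair correlations.

    ``dists`` is the condensed pairwise distance vector (upper triangle).
    Falls back to independence if the correlation mass is nonpositive.
    """
    m = len(z)
    if m == 1:
        return float(z[0])
    sigma_sum = float(m)  # diagonal
    for d in dists:
        sigma_sum += 2.0 * acf.corr_for_distance(d)
    if sigma_sum <= 0:
        warnings.warn("nonpositive correlation mass in SLK; falling back to independence",
                      stacklevel=3)
        sigma_sum = float(m)
    return float(z.sum() / np.sqrt(sigma_sum))


def slk_adjust(
    pvals: pd.Series, manifest: ProbeManifest, acf: AcfEstimate, cfg: AnalysisConfig
) -> pd.Series:
    """Neighborhood-combined p-value per probe (window = dmr_max_gap_bp)."""
    man, p, z = _aligned(pvals, manifest)
    pos_all = man["pos"].to_numpy()
    adjusted = np.empty(len(man))
    for _, idx in man.groupby("chrom", sort=False).indices.items():
        pos = pos_all[idx]
        zz = z[idx]
        left = 0
        right = 0
        for a in range(len(idx)):
            while pos[a] - pos[left] > cfg.dmr_max_gap_bp:
                left += 1
            right = max(right, a)
            while right + 1 < len(idx) and pos[right + 1] - pos[a] <= cfg.dmr_max_gap_bp:
                right += 1
            w = slice(left, right + 1)
            wpos = pos[w]
            dists = np.abs(wpos[:, None] - wpos[None, :])[np.triu_indices(len(wpos), k=1)]
            zc = _slk_combine(zz[w], dists, acf)
            adjusted[idx[a]] = stats.norm.sf(zc)
    return pd.Series(adjusted, index=man.index, name="slk_adjusted_p")


def find_regions(
    adjusted_p: pd.Series, manifest: ProbeManifest, cfg: AnalysisConfig
) -> List[DmrRecord]:
    """Maximal runs of consecutive probes with adjusted p below the seed threshold."""
    man = manifest.sorted_by_position().table
    man = man.loc[man.index.intersection(adjusted_p.index)]
    p = adjusted_p.reindex(man.index).to_numpy()
    pos_all = man["pos"].to_numpy()
    regions: List[DmrRecord] = []
    for chrom, idx in man.groupby("chrom", sort=False).indices.items():
        pos = pos_all[idx]
        members: List[int] = []
        for a in range(len(idx)):
            hit = p[idx[a]] < cfg.dmr_seed_p
            contiguous = bool(members) and pos[a] - pos[members[-1]] <= cfg.dmr_max_gap_bp
            if hit and (not members or contiguous):
                members.append(a)
            else:
                if members:
                    regions.append(
                        DmrRecord(str(chrom), int(pos[members[0]]), int(pos[members[-1]]),
                                  [man.index[idx[i]] for i in members])
                    )
                members = [a] if hit else []
        if members:
            regions.append(
                DmrRecord(str(chrom), int(pos[members[0]]), int(pos[members[-1]]),
                          [man.index[idx[i]] for i in members])
            )
    return regions


def genome_span_tested(manifest: ProbeManifest, probe_ids: Sequence[str]) -> int:
    """Total bases covered by tested probes: per-chromosome spans, summed."""
    man = manifest.table.loc[pd.Index(probe_ids)]
    spans = man.groupby("chrom")["pos"].agg(lambda s: int(s.max()) - int(s.min()) + 1)
    return int(spans.sum())


def score_region(
    region: DmrRecord, raw_pvals: pd.Series, manifest: ProbeManifest,
    acf: AcfEstimate, genome_span: int,
) -> DmrRecord:
    """SLK-combined raw p of the members plus Sidak regional correction."""
    p = raw_pvals.loc[region.probe_ids].to_numpy(dtype=float)
    z = stats.norm.isf(np.clip(p, _PCLIP, 1 - _PCLIP))
    pos = manifest.table.loc[region.probe_ids, "pos"].to_numpy()
    dists = np.abs(pos[:, None] - pos[None, :])[np.triu_indices(len(pos), k=1)]
    zc = _slk_combine(z, dists, acf)
    slk_p = float(stats.norm.sf(zc))
    underflow = slk_p <= 0.0
    if underflow:
        slk_p = float(np.finfo(float).tiny)
    exponent = genome_span / region.span_bp
    sidak_p = float(-np.expm1(exponent * np.log1p(-min(slk_p, 1.0 - 1e-16))))
    sidak_p = min(max(sidak_p, 0.0), 1.0)
    if slk_p >= 1.0:
        sidak_p = 1.0
    region.slk_p = slk_p
    region.sidak_p = sidak_p
    region.underflow = underflow
    return region


def filter_dmrs(
    regions: List[DmrRecord],
    delta_beta: pd.Series,
    signature_probe_ids,
    cfg: AnalysisConfig,
) -> List[DmrRecord]:
    """Apply the regional significance, direction-count and signature-overlap rules."""
    sig = set(signature_probe_ids)
    kept = []
    for r in regions:
        db = delta_beta.reindex(r.probe_ids)
        r.n_hyper = int((db > 0).sum())
        r.n_hypo = int((db < 0).sum())
        r.contains_signature_cpg = any(p in sig for p in r.probe_ids)
        r.passes_filters = (
            r.sidak_p < cfg.dmr_sidak_max
            and (r.n_hyper >= 3 or r.n_hypo >= 3)
            and r.contains_signature_cpg
        )
        if r.passes_filters:
            kept.append(r)
    return kept


def run_dmr_scan(
    raw_pvals: pd.Series,
    delta_beta: pd.Series,
    manifest: ProbeManifest,
    signature_probe_ids,
    cfg: AnalysisConfig,
) -> Tuple[List[DmrRecord], List[DmrRecord], AcfEstimate]:
    """Full chain: ACF -> SLK adjustment -> region growth -> scoring -> filters."""
    valid = raw_pvals.dropna()
    acf = estimate_acf(valid, manifest, cfg)
    adjusted = slk_adjust(valid, manifest, acf, cfg)
    candidates = find_regions(adjusted, manifest, cfg)
    span = genome_span_tested(manifest, valid.index)
    scored = [score_region(r, valid, manifest, acf, span) for r in candidates]
    final = filter_dmrs(scored, delta_beta, signature_probe_ids, cfg)
    return scored, final, acf


def dmr_table(regions: List[DmrRecord]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "n_probes": len(r.probe_ids), "n_hyper": r.n_hyper, "n_hypo": r.n_hypo,
            "slk_p": r.slk_p, "sidak_p": r.sidak_p,
            "contains_signature_cpg": r.contains_signature_cpg,
            "passes_filters": r.passes_filters,
            "probe_ids": ";".join(map(str, r.probe_ids)),
        }
        for r in regions
    ]
    return pd.DataFrame(rows)
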