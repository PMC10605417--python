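"""QC masking, probe filtering, M-value transform and sample-outlier removal.

The cleaning rules mirror standard Infinium practice: individual beta
calls are masked (set missing) when the detection p-value exceeds 0.05 or
fewer than three beads support the call; probes on mitochondrial DNA are
dropped while sex-chromosome probes are kept (all-male cohort); probes
left with too many missing calls are dropped so per-probe complete-case
fits keep a floor of observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    AnnotationError,
    BetaMatrix,
    ConfigError,
    MValueMatrix,
    ProbeManifest,
    ValidationError,
)


@dataclass
class QcReport:
    n_masked_detection: int = 0
    n_masked_beads: int = 0
    n_probes_removed_mito: int = 0
    n_probes_removed_missing: int = 0
    n_probes_remaining: int = 0
    outlier_sample_ids: List[str] = field(default_factory=list)
    sample_distances: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def apply_qc_mask(bm: BetaMatrix, cfg: AnalysisConfig) -> tuple[BetaMatrix, QcReport]:
    """Mask beta where detection p > threshold (strict) or beads < minimum."""
    if bm.detection_p is None or bm.bead_count is None:
        raise ConfigError("QC masking requires detection-p and bead-count layers")
    beta = bm.beta.to_numpy(copy=True)
    detp = bm.detection_p.to_numpy()
    beads = bm.bead_count.to_numpy()
    present = ~np.isnan(beta)
    mask_detp = present & (detp > cfg.detection_p_max)
    mask_beads = present & (beads < cfg.min_beads)
    beta[mask_detp | mask_beads] = np.nan
    report = QcReport(
        n_masked_detection=int(mask_detp.sum()),
        n_masked_beads=int(mask_beads.sum()),
        n_probes_remaining=beta.shape[0],
    )
    out = BetaMatrix(
        pd.DataFrame(beta, index=bm.probe_ids, columns=bm.sample_ids),
        bm.detection_p,
        bm.bead_count,
    )
    return out, report


def filter_probes(
    bm: BetaMatrix, manifest: ProbeManifest, cfg: AnalysisConfig
) -> tuple[BetaMatrix, QcReport]:
    """Drop mitochondrial probes and probes with too many missing calls."""
    missing_in_manifest = bm.probe_ids.difference(manifest.probe_ids)
    if len(missing_in_manifest):
        head = list(missing_in_manifest[:10])
        raise AnnotationError(f"probes absent from manifest (first 10): {head}")
    mito = manifest.is_mitochondrial().reindex(bm.probe_ids).fillna(False)
    frac_missing = bm.beta.isna().mean(axis=1)
    too_missing = frac_missing > cfg.max_probe_missing
    keep = ~(mito.to_numpy() | too_missing.to_numpy())
    report = QcReport(
        n_probes_removed_mito=int(mito.sum()),
        n_probes_removed_missing=int((too_missing & ~mito).sum()),
        n_probes_remaining=int(keep.sum()),
    )
    return bm.subset_probes(bm.probe_ids[keep]), report


def beta_to_m(bm: BetaMatrix, cfg: AnalysisConfig) -> MValueMatrix:
    """M = log2((beta + eps) / (1 - beta + eps)); missing propagates."""
    beta = bm.beta.to_numpy()
    eps = cfg.m_offset
    if eps == 0 and ((beta == 0) | (beta == 1)).any():
        raise ValidationError("m_offset = 0 with boundary beta values would give infinite M")
    with np.errstate(invalid="ignore"):
        m = np.log2((beta + eps) / (1.0 - beta + eps))
    return MValueMatrix(pd.DataFrame(m, index=bm.probe_ids, columns=bm.sample_ids))


def detect_outliers(m: MValueMatrix, cfg: AnalysisConfig) -> tuple[pd.Index, QcReport]:
    """Flag samples far from the mean profile (single pass).

    The per-sample Euclidean distance to the column-mean profile is
    computed over probes with no missing value in any sample; samples
    whose distance exceeds ``outlier_multiplier`` times the median
    distance are removed.
    """
    vals = m.m.to_numpy()
    if vals.shape[1] < 4:
        raise ValidationError("outlier detection needs at least 4 samples")
    complete = ~np.isnan(vals).any(axis=1)
    profile = vals[complete]
    centroid = profile.mean(axis=1, keepdims=True)
    dist = np.sqrt(((profile - centroid) ** 2).sum(axis=0))
    med = float(np.median(dist))
    flagged = dist > cfg.outlier_multiplier * med if med > 0 else np.zeros(len(dist), bool)
    kept = m.sample_ids[~flagged]
    report = QcReport(
        outlier_sample_ids=list(m.sample_ids[flagged]),
        sample_distances=pd.Series(dist, index=m.sample_ids),
        n_probes_remaining=int(complete.sum()),
    )
    return kept, report


def run_preprocessing(
    bm: BetaMatrix, manifest: ProbeManifest, cfg: AnalysisConfig
) -> tuple[BetaMatrix, MValueMatrix, QcReport]:
    """Full cleaning chain: mask -> probe filters -> M transform -> outliers."""
    masked, rep_mask = apply_qc_mask(bm, cfg)
    filtered, rep_probes = filter_probes(masked, manifest, cfg)
    mvals = beta_to_m(filtered, cfg)
    kept, rep_out = detect_outliers(mvals, cfg)
    report = QcReport(
        n_masked_detection=rep_mask.n_masked_detection,
        n_masked_beads=rep_mask.n_masked_beads,
        n_probes_removed_mito=rep_probes.n_probes_removed_mito,
        n_probes_removed_missing=rep_probes.n_probes_removed_missing,
        n_probes_remaining=rep_probes.n_probes_remaining,
        outlier_sample_ids=rep_out.outlier_sample_ids,
        sample_distances=rep_out.sample_distances,
    )
    clean = filtered.subset_samples(kept)
    return clean, MValueMatrix(mvals.m[kept]), report
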