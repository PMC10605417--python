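"""Brain-volume statistics and the methylation-to-volume association.

Two layers: per-structure group statistics on a precomputed volume table
(absolute and relative volumes, genotype x treatment interaction models,
BH across structures), and the signature-restricted scan for CpGs whose
methylation tracks total brain volume, followed by the PC1 trend test
that contrasts the strength of the volume relationship between
genotypes.

The volume scan adjusts for genotype: total brain volume is strongly
collinear with genotype in this cohort (the mutant brains are ~10%
smaller), so without the adjustment every genotype-differential probe
would masquerade as volume-associated through the group mean shift.  The
adjusted scan isolates within-genotype coupling; set
``adjust_genotype=False`` for the unadjusted variant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, BetaMatrix, MValueMatrix, SampleSheet, ValidationError
from .modeling import (
    ModeratedFit,
    Signature,
    bh_fdr,
    build_design,
    ebayes_moderate,
    fit_probewise,
)

logger = logging.getLogger(__name__)


@dataclass
class StructureStats:
    absolute: pd.DataFrame
    relative: pd.DataFrame


@dataclass
class VolumeAssociation:
    probe_table: pd.DataFrame  # slope (M and beta scale), p, q, scaled effect, selected
    selected_probes: pd.Index
    trend: Optional[pd.DataFrame] = None  # per genotype: slope, F, p, n
    pc1_scores: Optional[pd.Series] = None


def _structure_table(
    volumes: pd.DataFrame, sheet: SampleSheet, weight: Optional[pd.Series]
) -> pd.DataFrame:
    """Group stats + interaction model per structure (one scale)."""
    import statsmodels.api as sm

    d = sheet.data.loc[volumes.index]
    geno = (d["genotype"] == "KS1").astype(float)
    treat = (d["treatment"] == "AR42").astype(float)
    X = np.column_stack([np.ones(len(d)), geno, treat, geno * treat])
    veh = d["treatment"] == "vehicle"
    rows = []
    items = list(volumes.items())
    if weight is not None:
        items.append(("body_weight_g", weight.loc[volumes.index]))
    for name, col in items:
        y = col.astype(float)
        okv = y.notna()
        if not okv.any():
            warnings.warn(f"structure {name!r} is all-missing; dropped", stacklevel=3)
            continue
        wt_v = y[veh & (d["genotype"] == "WT") & okv]
        ks_v = y[veh & (d["genotype"] == "KS1") & okv]
        pct = (ks_v.mean() - wt_v.mean()) / wt_v.mean() * 100.0 if len(wt_v) else np.nan
        t_p = (
            stats.ttest_ind(ks_v, wt_v, equal_var=False).pvalue
            if len(wt_v) >= 2 and len(ks_v) >= 2
            else np.nan
        )
        fit = sm.OLS(y[okv].to_numpy(), X[okv.to_numpy()]).fit()
        rows.append(
            {
                "structure": name,
                "mean_wt_vehicle": wt_v.mean(),
                "mean_ks1_vehicle": ks_v.mean(),
                "pct_diff": pct,
                "p": t_p,
                "p_genotype": fit.pvalues[1],
                "p_treatment": fit.pvalues[2],
                "p_interaction": fit.pvalues[3],
            }
        )
    out = pd.DataFrame(rows).set_index("structure")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["q_interaction"] = bh_fdr(out["p_interaction"].to_numpy())
    return out


def structure_group_stats(sheet: SampleSheet, cfg: AnalysisConfig) -> StructureStats:
    """Absolute and relative per-structure statistics with interaction models.

    Relative volumes are each structure as a percent of total brain
    volume; body weight rides along as a pseudo-structure row in the
    absolute table.
    """
    if sheet.structure_volumes is None:
        raise ValidationError("sample sheet carries no structure-volume table")
    vols = sheet.structure_volumes
    total = sheet.data.loc[vols.index, "total_brain_volume_mm3"].astype(float)
    weight = sheet.data.get("weight_g")
    absolute = _structure_table(vols, sheet, weight)
    relative = _structure_table(vols.div(total, axis=0) * 100.0, sheet, None)
    return StructureStats(absolute, relative)


def volume_methylation_scan(
    bm: BetaMatrix,
    m: MValueMatrix,
    sheet: SampleSheet,
    signature: Signature,
    cfg: AnalysisConfig,
    adjust_genotype: bool = True,
) -> VolumeAssociation:
    """Signature-restricted scan for CpGs whose methylation tracks brain volume.

    Vehicle-treated samples only; centered total brain volume is the main
    effect with day as covariate and no surrogate variables; q-values are
    computed over exactly the signature probes.  The effect size is the
    beta-scale slope times the observed volume range (the continuous
    analogue of a group delta-beta), thresholded at delta_beta_threshold.
    """
    veh = sheet.data.index[sheet.data["treatment"] == "vehicle"].intersection(bm.sample_ids)
    sub = sheet.subset(veh)
    has_vol = sub.data["total_brain_volume_mm3"].notna()
    if not has_vol.all():
        logger.info("dropping %d sample(s) without brain volume", int((~has_vol).sum()))
    sub = sheet.subset(sub.data.index[has_vol])
    extra = None
    if adjust_genotype:
        extra = pd.DataFrame(
            {"genotype_adj": (sub.data["genotype"] == "KS1").astype(float)}
        )
    design = build_design(sub, "total_brain_volume", svs=None, extra=extra)

    probes = signature.probe_ids
    m_sig = MValueMatrix(m.m.loc[probes, list(design.sample_ids)])
    fits = fit_probewise(m_sig, design)
    prior, moderated = ebayes_moderate(fits)
    moderated["q"] = bh_fdr(moderated["p"].to_numpy())

    # beta-scale slope from the same design applied to beta values
    beta_fits = fit_probewise(
        MValueMatrix(bm.beta.loc[probes, list(design.sample_ids)]), design
    )
    vols = sub.data["total_brain_volume_mm3"].astype(float)
    vol_range = float(vols.max() - vols.min())
    moderated["slope_beta"] = beta_fits["b"]
    moderated["scaled_effect"] = beta_fits["b"].abs() * vol_range
    moderated["selected"] = (
        (moderated["q"] < cfg.q_threshold)
        & (moderated["scaled_effect"] > cfg.delta_beta_threshold)
    ).fillna(False)
    selected = moderated.index[moderated["selected"]]
    return VolumeAssociation(moderated, selected)


def pc1_volume_trend(
    bm: BetaMatrix, sheet: SampleSheet, selected_probes: Sequence[str]
) -> VolumeAssociation:
    """Per-genotype regression of PC1 scores (over selected CpGs) on volume.

    Betas are centered per probe over the included vehicle-treated
    samples; PC1 scores come from the leading principal axis; within each
    genotype an ordinary regression of PC1 on volume yields the slope and
    F(1, n-2).  PC1's sign is fixed so its pooled correlation with volume
    is nonnegative.
    """
    probes = pd.Index(selected_probes)
    if len(probes) < 2:
        raise ValidationError("PC1 trend needs at least 2 selected probes")
    veh = sheet.data.index[sheet.data["treatment"] == "vehicle"].intersection(bm.sample_ids)
    sub = sheet.data.loc[veh]
    ok = sub["total_brain_volume_mm3"].notna()
    veh = sub.index[ok]
    for g in ("WT", "KS1"):
        if (sheet.data.loc[veh, "genotype"] == g).sum() < 3:
            raise ValidationError(f"PC1 trend needs >= 3 vehicle-treated {g} samples")

    betas = bm.beta.loc[probes, list(veh)].to_numpy()
    betas = betas - np.nanmean(betas, axis=1, keepdims=True)
    betas = np.nan_to_num(betas)
    # PC1 scores: leading right singular vector scaled by its singular value
    u, s, vt = np.linalg.svd(betas, full_matrices=False)
    scores = pd.Series(s[0] * vt[0], index=veh)
    vols = sheet.data.loc[veh, "total_brain_volume_mm3"].astype(float)
    if np.corrcoef(scores, vols)[0, 1] < 0:
        scores = -scores

    rows = []
    for g in ("WT", "KS1"):
        gmask = sheet.data.loc[veh, "genotype"] == g
        y = scores[gmask].to_numpy()
        x = vols[gmask].to_numpy()
        n = len(y)
        res = stats.linregress(x, y)
        f_stat = float(res.rvalue**2 / (1.0 - res.rvalue**2) * (n - 2)) if abs(res.rvalue) < 1 else np.inf
        rows.append({"genotype": g, "slope": res.slope, "F": f_stat, "p": res.pvalue, "n": n})
    trend = pd.DataFrame(rows).set_index("genotype")
    return VolumeAssociation(pd.DataFrame(index=probes), probes, trend, scores)
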