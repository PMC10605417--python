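"""Probewise moderated linear models, FDR, signature calling and variance scan.

Statistics are computed on M-values (log2 odds); effect sizes are
group-mean differences on the beta scale (delta-beta), mirroring the
field's dual-scale convention.  Per-probe ordinary least squares is
followed by empirical-Bayes variance moderation: residual variances are
shrunk toward a prior estimated across probes by method of moments on
log s^2, and the moderated t statistic gains the prior degrees of
freedom.  Significant probes must pass both the BH q-value threshold and
the minimum delta-beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import (
    AnalysisConfig,
    AnnotationError,
    BetaMatrix,
    ConfigError,
    DesignError,
    MValueMatrix,
    SampleSheet,
    ValidationError,
)
from .surrogate import SurrogateSet, construct_svs, estimate_n_sv

MAIN_EFFECTS = ("genotype", "treatment", "total_brain_volume")


@dataclass
class DesignMatrix:
    """Samples-by-covariates matrix with a designated main-effect column."""

    frame: pd.DataFrame
    main_effect: str

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> pd.Index:
        return self.frame.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def main_index(self) -> int:
        return int(self.frame.columns.get_loc(self.main_effect))


@dataclass
class EbPrior:
    """Empirical-Bayes prior: d0 degrees of freedom (may be inf), s0^2 variance.

    ``s0_sq=None`` together with ``d0=inf`` denotes the degenerate
    "no-shrinkage" prior under which each probe keeps its own variance and
    the moderated t reduces to the classical t.
    """

    d0: float
    s0_sq: Optional[float]

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValidationError("prior df must be positive")
        if self.s0_sq is not None and not self.s0_sq > 0:
            raise ValidationError("prior variance must be positive")


@dataclass
class ModeratedFit:
    """Per-probe fit table (b, s2, df, v, n_used, s2_post, t, p, q, delta_beta)."""

    table: pd.DataFrame
    prior: EbPrior
    main_effect: str


@dataclass
class Signature:
    """Significant probes with direction; the unit passed between analyses."""

    table: pd.DataFrame  # index probe_id; direction, q, delta_beta[, gene]

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_hyper(self) -> int:
        return int((self.table["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.table["direction"] == "hypo").sum())

    def direction_of(self, probe_id: str) -> str:
        return str(self.table.loc[probe_id, "direction"])


def build_design(
    sheet: SampleSheet,
    main_effect: str,
    svs: Optional[SurrogateSet] = None,
    include_day: bool = True,
    extra: Optional[pd.DataFrame] = None,
) -> DesignMatrix:
    """Intercept + main effect (+ day + SVs + extra covariates).

    Categorical effects are coded 0/1 with WT / vehicle as reference;
    total brain volume enters centered.  Volume models reject SVs.
    """
    if main_effect not in MAIN_EFFECTS:
        raise DesignError(f"main_effect must be one of {MAIN_EFFECTS}")
    d = sheet.data
    if main_effect == "total_brain_volume":
        if svs is not None and svs.k > 0:
            raise DesignError(
                "surrogate variables are excluded from models where total brain "
                "volume is the main effect; pass svs=None"
            )
        col = "total_brain_volume_mm3"
        if col not in d.columns:
            raise DesignError("sample sheet carries no total_brain_volume_mm3 column")
        present = d[col].notna()
        if not present.all():
            warnings.warn(
                f"dropping {int((~present).sum())} sample(s) lacking brain volume",
                stacklevel=2,
            )
            d = d[present]
        main = d[col].astype(float)
        main = main - main.mean()
    elif main_effect == "genotype":
        main = (d["genotype"] == "KS1").astype(float)
    else:
        main = (d["treatment"] == "AR42").astype(float)

    if main.nunique() < 2:
        raise DesignError(f"main effect {main_effect!r} is constant over the samples")

    frame = pd.DataFrame({"intercept": 1.0, main_effect: main}, index=d.index)
    if include_day:
        day = (d["day_of_sacrifice"] == 2).astype(float)
        if day.nunique() < 2:
            warnings.warn("day_of_sacrifice is constant; dropping the day column", stacklevel=2)
        else:
            frame["day"] = day
    if extra is not None:
        for name in extra.columns:
            frame[name] = extra.loc[frame.index, name].astype(float)
    if svs is not None and svs.k > 0:
        for name in svs.sv.columns:
            frame[name] = svs.sv.loc[frame.index, name]
    X = frame.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(f"design matrix is rank deficient; columns: {list(frame.columns)}")
    return DesignMatrix(frame, main_effect)


def fit_probewise(m: MValueMatrix, design: DesignMatrix) -> pd.DataFrame:
    """Per-probe OLS on complete cases (vectorized over probes).

    Returns a DataFrame with the main-effect coefficient ``b``, residual
    variance ``s2`` with ``df`` degrees of freedom, the unscaled
    coefficient variance ``v`` and ``n_used``.  Probes with fewer complete
    cases than columns + 1 carry missing statistics.
    """
    X = design.values
    n, p = X.shape
    Y = m.m[design.sample_ids].to_numpy()
    mask = ~np.isnan(Y)
    Y0 = np.nan_to_num(Y)
    n_used = mask.sum(axis=1)
    ok = n_used >= p + 1

    maskf = mask.astype(float)
    XtX = np.einsum("fi,ip,iq->fpq", maskf, X, X, optimize=True)
    Xty = (Y0 * maskf) @ X
    with np.errstate(all="ignore"):
        XtX_inv = np.linalg.pinv(XtX)
    b_all = np.einsum("fpq,fq->fp", XtX_inv, Xty)
    rss = np.clip((Y0**2 * maskf).sum(axis=1) - (b_all * Xty).sum(axis=1), 0.0, None)
    df = n_used - p
    j = design.main_index
    v = XtX_inv[:, j, j]
    ok &= v > 0

    out = pd.DataFrame(index=m.probe_ids)
    out["b"] = np.where(ok, b_all[:, j], np.nan)
    out["s2"] = np.where(ok, rss / np.maximum(df, 1), np.nan)
    out["df"] = np.where(ok, df, np.nan)
    out["v"] = np.where(ok, v, np.nan)
    out["n_used"] = n_used
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> EbPrior:
    """Method-of-moments fit of (d0, s0^2) on log residual variances."""
    valid = np.isfinite(s2) & np.isfinite(df) & (s2 > 0) & (df > 0)
    if valid.sum() < 100:
        raise ConfigError(
            f"hyperparameter estimation needs >= 100 probes with positive s2; got {int(valid.sum())}"
        )
    s2v, dfv = s2[valid], df[valid]
    z = np.log(s2v)
    e = z - special.digamma(dfv / 2.0) + np.log(dfv / 2.0)
    ebar = e.mean()
    nv = len(e)
    rhs = np.mean((e - ebar) ** 2 * nv / (nv - 1) - special.polygamma(1, dfv / 2.0))
    if rhs <= 0:
        # degenerate prior: no excess spread in log s2, so the common variance
        # is simply the geometric mean of the observed s2
        return EbPrior(np.inf, float(np.exp(np.mean(z))))
    d0 = 2.0 * _trigamma_inverse(rhs)
    s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EbPrior(float(d0), s0_sq)


def ebayes_moderate(
    fits: pd.DataFrame, prior: Optional[EbPrior] = None
) -> Tuple[EbPrior, pd.DataFrame]:
    """Moderate per-probe variances and compute moderated t and p.

    When ``prior`` is None it is estimated from the fits.  A supplied
    prior with ``d0=inf, s0_sq=None`` disables shrinkage (classical t).
    """
    s2 = fits["s2"].to_numpy(float)
    df = fits["df"].to_numpy(float)
    if prior is None:
        prior = estimate_prior(s2, df)

    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq) if prior.s0_sq is not None else s2.copy()
        s2_post[~np.isfinite(s2)] = np.nan
        df_total = np.where(np.isfinite(df), np.inf, np.nan)
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df

    out = fits.copy()
    with np.errstate(all="ignore"):
        t = fits["b"].to_numpy(float) / np.sqrt(s2_post * fits["v"].to_numpy(float))
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out["s2_post"] = s2_post
    out["t"] = t
    out["p"] = p
    return prior, out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; missing p-values stay missing."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.clip(qv, 0.0, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[ok] = out
    return q


def _group_columns(sheet: SampleSheet, group) -> pd.Index:
    if isinstance(group, tuple):
        genotype, treatment = group
        mask = sheet.group_mask(genotype=genotype, treatment=treatment)
        return sheet.data.index[mask]
    return pd.Index(group)


def group_delta_beta(
    bm: BetaMatrix, sheet: SampleSheet, case_group, control_group
) -> pd.Series:
    """Mean beta(case) - mean beta(control); missing when a group has < 2 values."""
    case_cols = _group_columns(sheet, case_group)
    ctrl_cols = _group_columns(sheet, control_group)
    case = bm.beta[list(case_cols)].to_numpy()
    ctrl = bm.beta[list(ctrl_cols)].to_numpy()
    n_case = (~np.isnan(case)).sum(axis=1)
    n_ctrl = (~np.isnan(ctrl)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        delta = np.nanmean(case, axis=1) - np.nanmean(ctrl, axis=1)
    delta[(n_case < 2) | (n_ctrl < 2)] = np.nan
    return pd.Series(delta, index=bm.probe_ids, name="delta_beta")


def call_signature(
    modfit: ModeratedFit, cfg: AnalysisConfig, gene: Optional[pd.Series] = None
) -> Signature:
    """Probes with q < threshold and |delta-beta| > threshold, sorted by (q, id)."""
    t = modfit.table
    if "q" not in t.columns or "delta_beta" not in t.columns:
        raise ValidationError("moderated fit must carry q and delta_beta columns")
    sel = (t["q"] < cfg.q_threshold) & (t["delta_beta"].abs() > cfg.delta_beta_threshold)
    sel &= t["q"].notna() & t["delta_beta"].notna()
    sig = t.loc[sel, ["q", "delta_beta"]].copy()
    sig["direction"] = np.where(sig["delta_beta"] > 0, "hyper", "hypo")
    if gene is not None:
        sig["gene"] = gene.reindex(sig.index)
    sig["_pid"] = sig.index
    sig = sig.sort_values(["q", "_pid"], kind="mergesort").drop(columns="_pid")
    return Signature(sig[["direction", "q", "delta_beta"] + (["gene"] if gene is not None else [])])


def levene_scan(
    bm: BetaMatrix, sheet: SampleSheet, probes: Sequence[str], center: str = "mean"
) -> pd.DataFrame:
    """Levene variance-difference scan between genotypes.

    One-way ANOVA F on absolute deviations of beta values from the group
    center, vectorized across probes; BH correction over the scanned
    set; also reports which genotype shows the larger range.  Mean
    centering (the classical test) is the default: the median-centered
    Brown-Forsythe variant, selectable with ``center='median'``, is
    noticeably conservative at this study's group sizes (13 vs 10).
    """
    if center not in ("mean", "median"):
        raise ValidationError("center must be 'mean' or 'median'")
    probes = pd.Index(probes)
    groups = []
    for g in ("WT", "KS1"):
        cols = sheet.data.index[sheet.data["genotype"] == g].intersection(bm.sample_ids)
        groups.append(bm.beta.loc[probes, list(cols)].to_numpy())
    a, b = groups
    center_fn = np.nanmean if center == "mean" else np.nanmedian
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        za = np.abs(a - center_fn(a, axis=1, keepdims=True))
        zb = np.abs(b - center_fn(b, axis=1, keepdims=True))
        na = (~np.isnan(za)).sum(axis=1).astype(float)
        nb = (~np.isnan(zb)).sum(axis=1).astype(float)
        ma = np.nanmean(za, axis=1)
        mb = np.nanmean(zb, axis=1)
        grand = (na * ma + nb * mb) / (na + nb)
        ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
        ssw = np.nansum((za - ma[:, None]) ** 2, axis=1) + np.nansum(
            (zb - mb[:, None]) ** 2, axis=1
        )
        dfw = na + nb - 2.0
        with np.errstate(all="ignore"):
            W = (ssb / 1.0) / (ssw / dfw)
            p = stats.f.sf(W, 1.0, dfw)
        degenerate = ssw <= 0
        W = np.where(degenerate & (ssb <= 1e-300), 0.0, W)
        p = np.where(degenerate & (ssb <= 1e-300), 1.0, p)
        p = np.where(degenerate & (ssb > 1e-300), 0.0, p)
        invalid = (na < 3) | (nb < 3)
        W[invalid] = np.nan
        p[invalid] = np.nan
        range_a = np.nanmax(a, axis=1) - np.nanmin(a, axis=1)
        range_b = np.nanmax(b, axis=1) - np.nanmin(b, axis=1)
    out = pd.DataFrame(
        {
            "W": W,
            "p": p,
            "q": bh_fdr(p),
            "larger_range": np.where(range_b > range_a, "KS1", np.where(range_a > range_b, "WT", "tie")),
        },
        index=probes,
    )
    return out


@dataclass
class OverlapTable:
    """Gene-level overlap between two signatures with direction agreement."""

    table: pd.DataFrame
    n_overlap: int
    n_agree: int


def _gene_directions(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-site calls to one (direction, n_sites) row per gene.

    Majority direction wins; exact ties are labeled 'mixed' and never
    count as agreement.
    """
    if "gene" not in table.columns or "direction" not in table.columns:
        raise AnnotationError("signature table must carry gene and direction columns")
    t = table.dropna(subset=["gene"])
    if t.empty:
        raise AnnotationError("signature carries no gene annotation")
    rows = []
    for gene, grp in t.groupby(t["gene"].astype(str).str.upper()):
        n_hyper = int((grp["direction"] == "hyper").sum())
        n_hypo = int((grp["direction"] == "hypo").sum())
        if n_hyper > n_hypo:
            direction = "hyper"
        elif n_hypo > n_hyper:
            direction = "hypo"
        else:
            direction = "mixed"
        rows.append({"gene": gene, "n_sites": len(grp), "direction": direction})
    return pd.DataFrame(rows).set_index("gene")


def compare_signatures(sig, reference: pd.DataFrame) -> OverlapTable:
    """Gene overlap of a signature with a reference (gene, direction) table."""
    if isinstance(sig, Signature):
        sig = sig.table
    left = _gene_directions(sig)
    right = _gene_directions(reference)
    shared = left.index.intersection(right.index)
    table = pd.DataFrame(
        {
            "n_sites": left.loc[shared, "n_sites"],
            "direction": left.loc[shared, "direction"],
            "ref_n_sites": right.loc[shared, "n_sites"],
            "ref_direction": right.loc[shared, "direction"],
        }
    )
    table["agree"] = (
        (table["direction"] == table["ref_direction"])
        & (table["direction"] != "mixed")
    )
    return OverlapTable(table, n_overlap=len(table), n_agree=int(table["agree"].sum()))


def derive_signature(
    bm: BetaMatrix,
    m: MValueMatrix,
    sheet: SampleSheet,
    cfg: AnalysisConfig,
    main_effect: str = "genotype",
    case_group=("KS1", "vehicle"),
    control_group=("WT", "vehicle"),
    gene: Optional[pd.Series] = None,
) -> Tuple[ModeratedFit, Signature, int]:
    """Full modeling stack on one sample subset: SVA -> moderated fit -> calling.

    Surrogate variables are re-estimated on exactly the samples present in
    ``sheet`` (the subset entering the comparison).
    """
    base = build_design(sheet, main_effect, svs=None)
    k = estimate_n_sv(MValueMatrix(m.m[base.sample_ids]), base, cfg)
    svs = construct_svs(MValueMatrix(m.m[base.sample_ids]), base, k) if k else None
    design = build_design(sheet, main_effect, svs=svs)
    fits = fit_probewise(m, design)
    prior, moderated = ebayes_moderate(fits)
    moderated["q"] = bh_fdr(moderated["p"].to_numpy())
    moderated["delta_beta"] = group_delta_beta(bm, sheet, case_group, control_group)
    modfit = ModeratedFit(moderated, prior, main_effect)
    return modfit, call_signature(modfit, cfg, gene=gene), k
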