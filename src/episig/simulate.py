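"""Synthetic cohort generator emulating the Kabuki (Kmt2d+/betaGeo) blood study.

The generator plants, on an Infinium-like probe grid scaled down to a
configurable number of CpGs:

* a bidirectional genotype signature (group-mean beta differences of
  0.05-0.20, ~48% hypermethylated) including a 5-probe hypermethylated
  cluster spaced 80-100 bp apart for region-detection tests;
* two latent cell-composition-like factors loading on disjoint probe
  subsets (the structure surrogate-variable analysis is meant to absorb);
* a day-of-sacrifice batch shift on a probe subset;
* a partial treatment rescue of the signature in the mutant treated arm;
* genotype-specific methylation-to-brain-volume coupling at a subset of
  signature probes, with total brain volumes drawn per genotype from
  triangular distributions matched to the study's printed
  (median, min, max) summaries.

Effects are planted on the beta scale and carried through the log-odds
(logit) scale so that per-sample means stay inside (0, 1); per-sample
noise is Beta-distributed around the planted mean with a configurable
concentration.  The configured ``rescue_fraction`` is the *expected
observed* fraction of signature probes whose treated-mutant group mean
lands closer to wildtype than the untreated-mutant mean: because a probe
with no planted rescue is counted "rescued" with probability one half by
symmetry, the truly shrunk subset has size
``round(n_signature * max(0, 2*rescue_fraction - 1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import BetaMatrix, ConfigError, ProbeManifest, SampleSheet

#: printed per-genotype total-brain-volume summaries, mm^3: (median, min, max)
DEFAULT_VOLUME_PARAMS: Mapping[str, Tuple[float, float, float]] = {
    "WT": (425.4, 402.7, 442.5),
    "KS1": (388.7, 327.5, 417.9),
}

_CHROMS = tuple(f"chr{i}" for i in range(1, 20)) + ("chrX",)


@dataclass
class SimulationConfig:
    """Cohort structure and planted-effect sizes (defaults = study conditions)."""

    n_probes: int = 20000
    # (WT vehicle, KS1 vehicle, WT AR-42, KS1 AR-42) after outlier removal
    n_per_group: Tuple[int, int, int, int] = (13, 10, 8, 9)
    n_signature: int = 500
    frac_hyper: float = 0.48
    delta_beta_range: Tuple[float, float] = (0.05, 0.20)
    n_latent_factors: int = 2
    latent_sd: float = 0.2  # logit-scale loading SD per confounded probe
    n_confounded_per_factor: int = 1000
    batch_effect_size: float = 0.02  # beta-scale day-2 shift
    n_batch_probes: int = 2000
    rescue_fraction: float = 0.69  # expected observed fraction (see module docstring)
    rescue_shrinkage: float = 0.7
    n_volume_coupled: int = 27
    volume_coupling_slope: float = 0.0015  # beta per mm^3, sign randomized per probe
    precision: float = 625.0  # Beta-noise concentration; SD ~ 0.02 at mid-range means
    volume_params: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_PARAMS)
    )
    missing_rate: float = 0.01
    n_outliers: int = 0
    dmr_cluster_hypo: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ConfigError("every group needs at least 2 samples")
        if not 0 < self.frac_hyper < 1:
            raise ConfigError("frac_hyper must lie in (0, 1)")
        if not 0 <= self.rescue_fraction <= 1:
            raise ConfigError("rescue_fraction must lie in [0, 1]")
        lo, hi = self.delta_beta_range
        if not (0 < lo <= hi < 0.5):
            raise ConfigError("delta_beta_range must lie within (0, 0.5)")
        if self.n_signature > self.n_probes:
            raise ConfigError("n_signature cannot exceed n_probes")
        if self.precision <= 0:
            raise ConfigError("precision must be positive")

    @property
    def n_rescued(self) -> int:
        return int(round(self.n_signature * max(0.0, 2.0 * self.rescue_fraction - 1.0)))


@dataclass
class SimulationTruth:
    """Ground truth of every planted effect, for parameter-recovery tests."""

    signature: pd.DataFrame  # index probe_id; direction, delta_beta (signed), baseline
    latent_scores: pd.DataFrame  # samples x factors
    confounded_loadings: Dict[str, pd.Series]  # factor -> probe loadings (logit scale)
    rescued_probe_ids: pd.Index
    volume_coupled: pd.Series  # probe -> slope (beta per mm^3)
    batch_shift_probe_ids: pd.Index
    baseline_means: pd.Series  # probe -> baseline beta mean
    rescue_shrinkage: float
    expected_beta: Optional[pd.DataFrame] = None  # planted per-(probe, sample) means

    def __post_init__(self) -> None:
        sig = set(self.signature.index)
        if not set(self.rescued_probe_ids) <= sig:
            raise ConfigError("rescued probes must be signature probes")
        if not set(self.volume_coupled.index) <= sig:
            raise ConfigError("volume-coupled probes must be signature probes")
        if (self.signature["delta_beta"] == 0).any():
            raise ConfigError("planted delta-beta must be nonzero")

    @property
    def signature_probe_ids(self) -> pd.Index:
        return self.signature.index


def planted_group_means(truth: SimulationTruth, probe_id: str) -> Dict[str, float]:
    """Noiseless per-group beta means implied by the genotype/treatment planting."""
    if probe_id not in truth.baseline_means.index:
        raise KeyError(f"unknown probe {probe_id!r}")
    mu0 = float(truth.baseline_means.loc[probe_id])
    if probe_id in truth.signature.index:
        delta = float(truth.signature.loc[probe_id, "delta_beta"])
    else:
        delta = 0.0
    shrink = truth.rescue_shrinkage if probe_id in truth.rescued_probe_ids else 0.0
    return {
        "WT_vehicle": mu0,
        "WT_AR42": mu0,
        "KS1_vehicle": mu0 + delta,
        "KS1_AR42": mu0 + delta * (1.0 - shrink),
    }


def _triangular_mode(median: float, lo: float, hi: float) -> float:
    """Mode of a triangular distribution with the given support and median."""
    span = hi - lo
    mode = lo + 2.0 * (median - lo) ** 2 / span  # branch: median <= mode
    if mode >= median:
        return min(mode, hi)
    return max(lo, hi - 2.0 * (hi - median) ** 2 / span)  # median > mode


def _build_manifest(cfg: SimulationConfig, probe_ids: pd.Index, rng) -> Tuple[ProbeManifest, list, list]:
    """Probe coordinates: one (or two) tight 5-probe clusters, the rest >= 2 kb apart."""
    chrom = np.empty(cfg.n_probes, dtype=object)
    pos = np.zeros(cfg.n_probes, dtype=int)

    hyper_cluster = list(range(0, 5))
    spacing = rng.integers(80, 101, size=4)
    chrom[hyper_cluster] = "chr1"
    pos[hyper_cluster] = 1000 + np.concatenate([[0], np.cumsum(spacing)])

    hypo_cluster: list = []
    next_i = 5
    if cfg.dmr_cluster_hypo and cfg.n_probes >= 10:
        hypo_cluster = list(range(5, 10))
        spacing = rng.integers(80, 101, size=4)
        chrom[hypo_cluster] = "chr2"
        pos[hypo_cluster] = 1000 + np.concatenate([[0], np.cumsum(spacing)])
        next_i = 10

    rest = np.arange(next_i, cfg.n_probes)
    chrom[rest] = np.asarray(_CHROMS, dtype=object)[rest % len(_CHROMS)]
    pos[rest] = 10_000 + 3000 * (rest // len(_CHROMS))

    strand = rng.choice(["+", "-"], size=cfg.n_probes)
    table = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "strand": strand, "gene": pd.NA}, index=probe_ids
    )
    table.index.name = "probe_id"
    return ProbeManifest(table), hyper_cluster, hypo_cluster


def generate_cohort(
    cfg: SimulationConfig,
) -> Tuple[BetaMatrix, ProbeManifest, SampleSheet, SimulationTruth]:
    """Generate one synthetic cohort plus its ground truth (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    P = cfg.n_probes
    groups = [("WT", "vehicle"), ("KS1", "vehicle"), ("WT", "AR42"), ("KS1", "AR42")]

    genotype, treatment, day = [], [], []
    for (g, t), n in zip(groups, cfg.n_per_group):
        genotype += [g] * n
        treatment += [t] * n
        day += [1 + (i % 2) for i in range(n)]  # ~half/half within each group
    n_samples = len(genotype)
    sample_ids = pd.Index([f"m{i + 1:02d}" for i in range(n_samples)], name="sample_id")
    genotype = np.array(genotype)
    treatment = np.array(treatment)
    day = np.array(day)
    probe_ids = pd.Index([f"cg{i + 1:06d}" for i in range(P)], name="probe_id")

    manifest, hyper_cluster, hypo_cluster = _build_manifest(cfg, probe_ids, rng)

    # --- baseline means: bimodal with a minority of intermediate probes ---
    mode = rng.choice(3, size=P, p=[0.45, 0.45, 0.10])
    mu0 = np.where(
        mode == 0,
        rng.uniform(0.03, 0.20, size=P),
        np.where(mode == 1, rng.uniform(0.80, 0.97, size=P), rng.uniform(0.30, 0.70, size=P)),
    )

    # --- signature probes: clusters first, rest drawn at random ---
    n_hyper = int(round(cfg.frac_hyper * cfg.n_signature))
    n_hypo = cfg.n_signature - n_hyper
    cluster_idx = hyper_cluster + hypo_cluster
    if cfg.n_signature < len(cluster_idx) or n_hyper < len(hyper_cluster) or n_hypo < len(hypo_cluster):
        # signature too small to carry the planted clusters; they stay null probes
        cluster_idx, hyper_cluster, hypo_cluster = [], [], []
    pool = np.setdiff1d(np.arange(P), cluster_idx)
    extra = rng.choice(pool, size=cfg.n_signature - len(cluster_idx), replace=False)
    n_extra_hyper = n_hyper - len(hyper_cluster)
    sig_idx = np.concatenate([cluster_idx, extra]).astype(int)
    direction = np.array(
        ["hyper"] * len(hyper_cluster)
        + ["hypo"] * len(hypo_cluster)
        + ["hyper"] * n_extra_hyper
        + ["hypo"] * (n_hypo - len(hypo_cluster))
    )
    delta_mag = rng.uniform(*cfg.delta_beta_range, size=cfg.n_signature)
    delta_mag[: len(cluster_idx)] = 0.15  # fixed planted cluster effect
    delta = np.where(direction == "hyper", delta_mag, -delta_mag)
    # keep planted means inside (0, 1) with room for the noise model
    mu0[sig_idx[delta > 0]] = rng.uniform(0.20, 0.70, size=int((delta > 0).sum()))
    mu0[sig_idx[delta < 0]] = rng.uniform(0.30, 0.80, size=int((delta < 0).sum()))

    # --- disjoint planted probe subsets for confounders and batch ---
    remaining = np.setdiff1d(pool, extra)
    rng.shuffle(remaining)
    offset = 0
    confounded: Dict[str, pd.Series] = {}
    loadings = np.zeros((P, cfg.n_latent_factors))
    for f in range(cfg.n_latent_factors):
        idx = remaining[offset : offset + cfg.n_confounded_per_factor]
        offset += cfg.n_confounded_per_factor
        w = rng.normal(0.0, cfg.latent_sd, size=len(idx))
        loadings[idx, f] = w
        confounded[f"factor_{f + 1}"] = pd.Series(w, index=probe_ids[idx])
    batch_idx = remaining[offset : offset + cfg.n_batch_probes]
    scores = rng.standard_normal((n_samples, cfg.n_latent_factors))

    # --- rescue and volume-coupling subsets of the signature ---
    sig_order = rng.permutation(cfg.n_signature)
    rescued_local = sig_order[: cfg.n_rescued]
    n_coupled = min(cfg.n_volume_coupled, cfg.n_signature)
    coupled_local = sig_order[cfg.n_signature - n_coupled :] if n_coupled else sig_order[:0]
    # severity coupling: smaller brains show the more extreme methylation deviation,
    # so the slope against volume opposes each probe's planted disease direction
    coupled_slopes = -cfg.volume_coupling_slope * np.sign(delta[coupled_local])

    # --- phenotypes ---
    volumes = np.zeros(n_samples)
    for g in ("WT", "KS1"):
        med, lo, hi = cfg.volume_params[g]
        sel = genotype == g
        volumes[sel] = rng.triangular(lo, _triangular_mode(med, lo, hi), hi, size=sel.sum())
    weight = np.where(genotype == "WT", rng.normal(22.0, 1.5, n_samples), rng.normal(19.0, 1.5, n_samples))

    # --- planted per-(probe, sample) means on the beta scale ---
    mean_beta = np.tile(mu0[:, None], (1, n_samples))
    is_ks1 = genotype == "KS1"
    is_ks1_treated = is_ks1 & (treatment == "AR42")
    rescued_mask = np.zeros(cfg.n_signature, dtype=bool)
    rescued_mask[rescued_local] = True
    full = np.outer(delta, is_ks1.astype(float))
    shrunk = np.where(rescued_mask[:, None], 1.0 - cfg.rescue_shrinkage, 1.0)
    full[:, is_ks1_treated] *= shrunk
    mean_beta[sig_idx] += full

    shift = np.clip(mu0[batch_idx] + cfg.batch_effect_size, 0.01, 0.99) - mu0[batch_idx]
    mean_beta[np.ix_(batch_idx, np.flatnonzero(day == 2))] += shift[:, None]

    ks1_cols = np.flatnonzero(is_ks1)
    vol_centered = volumes[ks1_cols] - volumes[ks1_cols].mean()
    mean_beta[np.ix_(sig_idx[coupled_local], ks1_cols)] += np.outer(coupled_slopes, vol_centered)

    mean_beta = np.clip(mean_beta, 0.005, 0.995)

    # --- latent factors act on the log-odds scale ---
    lo_scale = logit(mean_beta) + loadings @ scores.T
    if cfg.n_outliers > 0:
        out_cols = rng.choice(n_samples, size=cfg.n_outliers, replace=False)
        lo_scale[:, out_cols] += rng.normal(0.0, 1.0, size=(P, cfg.n_outliers))
    mean_final = np.clip(expit(lo_scale), 1e-4, 1.0 - 1e-4)

    beta = rng.beta(mean_final * cfg.precision, (1.0 - mean_final) * cfg.precision)

    # --- QC layers with planted failures ---
    detection_p = 10.0 ** (-rng.uniform(2.0, 6.0, size=(P, n_samples)))
    bead_count = rng.poisson(15.0, size=(P, n_samples)).astype(float)
    bead_count[bead_count < 3] = 3.0
    fail = rng.random((P, n_samples)) < cfg.missing_rate
    kind = rng.random((P, n_samples)) < 0.5
    detection_p[fail & kind] = rng.uniform(0.051, 0.5, size=int((fail & kind).sum()))
    bead_count[fail & ~kind] = rng.integers(0, 3, size=int((fail & ~kind).sum()))

    bm = BetaMatrix(
        pd.DataFrame(beta, index=probe_ids, columns=sample_ids),
        pd.DataFrame(detection_p, index=probe_ids, columns=sample_ids),
        pd.DataFrame(bead_count, index=probe_ids, columns=sample_ids),
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "genotype": genotype,
                "treatment": treatment,
                "day_of_sacrifice": day,
                "weight_g": weight,
                "total_brain_volume_mm3": volumes,
            },
            index=sample_ids,
        )
    )
    truth = SimulationTruth(
        signature=pd.DataFrame(
            {"direction": direction, "delta_beta": delta, "baseline": mu0[sig_idx]},
            index=probe_ids[sig_idx],
        ),
        latent_scores=pd.DataFrame(
            scores,
            index=sample_ids,
            columns=[f"factor_{f + 1}" for f in range(cfg.n_latent_factors)],
        ),
        confounded_loadings=confounded,
        rescued_probe_ids=probe_ids[sig_idx[rescued_local]],
        volume_coupled=pd.Series(coupled_slopes, index=probe_ids[sig_idx[coupled_local]]),
        batch_shift_probe_ids=probe_ids[batch_idx],
        baseline_means=pd.Series(mu0, index=probe_ids),
        rescue_shrinkage=cfg.rescue_shrinkage,
        expected_beta=pd.DataFrame(mean_final, index=probe_ids, columns=sample_ids),
    )
    return bm, manifest, sheet, truth
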