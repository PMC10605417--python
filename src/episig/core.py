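"""Shared data containers for the methylation-episignature pipeline.

All matrices are pandas DataFrames with probes as rows and samples as
columns; missing values are NaN (never sentinel numbers).  Beta values are
methylation fractions in [0, 1]; detection p-values come from the array
scanner and bead counts are the number of beads supporting each call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping, Optional

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "KS1")
TREATMENTS = ("vehicle", "AR42")
DAYS = (1, 2)

#: chromosome labels treated as mitochondrial (case-insensitive)
MITO_CHROMS = frozenset({"chrm", "mt", "chrmt", "m"})


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PipelineError):
    """A value violates a container invariant (e.g. beta outside [0, 1])."""


class DimensionError(PipelineError):
    """Two aligned layers disagree in shape or labels."""


class DesignError(PipelineError):
    """A design matrix cannot be built (collinear / constant columns)."""


class AnnotationError(PipelineError):
    """Probe or gene annotation required for an operation is missing."""


class ConfigError(PipelineError):
    """An analysis or simulation configuration is inconsistent."""


def _check_axis(ref: pd.Index, other: pd.Index, axis: str, layer: str) -> None:
    if len(ref) != len(other) or not ref.equals(other):
        raise DimensionError(
            f"layer '{layer}' disagrees with beta on the {axis} axis "
            f"({len(other)} vs {len(ref)} labels)"
        )


@dataclass
class BetaMatrix:
    """Probe-by-sample beta values with parallel detection-p and bead layers."""

    beta: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    bead_count: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.beta = self.beta.astype(float)
        if not self.beta.index.is_unique:
            raise ValidationError("probe ids are not unique")
        if not self.beta.columns.is_unique:
            raise ValidationError("sample ids are not unique")
        bad = self._first_out_of_range(self.beta)
        if bad is not None:
            raise ValidationError(
                f"beta outside [0, 1] at probe {bad[0]!r}, sample {bad[1]!r}"
            )
        for name in ("detection_p", "bead_count"):
            layer = getattr(self, name)
            if layer is None:
                continue
            layer = layer.astype(float)
            _check_axis(self.beta.index, layer.index, "probes", name)
            _check_axis(self.beta.columns, layer.columns, "samples", name)
            setattr(self, name, layer)
        if self.detection_p is not None:
            bad = self._first_out_of_range(self.detection_p)
            if bad is not None:
                raise ValidationError(
                    f"detection p outside [0, 1] at probe {bad[0]!r}, sample {bad[1]!r}"
                )
        if self.bead_count is not None:
            vals = self.bead_count.to_numpy()
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError("bead counts must be nonnegative")

    @staticmethod
    def _first_out_of_range(df: pd.DataFrame):
        vals = df.to_numpy()
        bad = (vals < 0) | (vals > 1)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            return df.index[i], df.columns[j]
        return None

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        take = lambda df: None if df is None else df.loc[probe_ids]
        return BetaMatrix(self.beta.loc[probe_ids], take(self.detection_p), take(self.bead_count))

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        take = lambda df: None if df is None else df[list(sample_ids)]
        return BetaMatrix(self.beta[list(sample_ids)], take(self.detection_p), take(self.bead_count))


@dataclass
class MValueMatrix:
    """log2 odds of methylation, same shape contract as :class:`BetaMatrix`."""

    m: pd.DataFrame

    def __post_init__(self) -> None:
        self.m = self.m.astype(float)
        vals = self.m.to_numpy()
        if np.isinf(vals).any():
            raise ValidationError("M values must be finite where non-missing")

    @property
    def probe_ids(self) -> pd.Index:
        return self.m.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.m.columns


@dataclass
class ProbeManifest:
    """Genomic coordinates (1-based) and optional gene annotation per probe."""

    table: pd.DataFrame  # index probe_id; columns chrom, pos, strand, gene

    def __post_init__(self) -> None:
        t = self.table
        if not t.index.is_unique:
            raise ValidationError("manifest probe ids are not unique")
        for col in ("chrom", "pos"):
            if col not in t.columns:
                raise ValidationError(f"manifest lacks required column {col!r}")
        if (t["pos"] < 1).any():
            raise ValidationError("manifest positions must be >= 1")
        if t["chrom"].astype(str).str.len().eq(0).any():
            raise ValidationError("manifest chromosomes must be non-empty")
        if "strand" not in t.columns:
            t = t.assign(strand="*")
        if "gene" not in t.columns:
            t = t.assign(gene=pd.NA)
        self.table = t

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def sorted_by_position(self) -> "ProbeManifest":
        # mergesort keeps equal positions in input order (stable)
        t = self.table.sort_values(["chrom", "pos"], kind="mergesort")
        return ProbeManifest(t)

    def is_mitochondrial(self) -> pd.Series:
        return self.table["chrom"].astype(str).str.lower().isin(MITO_CHROMS)


@dataclass
class SampleSheet:
    """Per-sample genotype / treatment / day metadata plus optional phenotypes."""

    data: pd.DataFrame  # index sample_id
    structure_volumes: Optional[pd.DataFrame] = None  # index sample_id, one col / structure

    def __post_init__(self) -> None:
        d = self.data
        if not d.index.is_unique:
            dup = d.index[d.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in sample sheet")
        for col in ("genotype", "treatment"):
            if col not in d.columns:
                raise ValidationError(f"sample sheet lacks required column {col!r}")
        bad_g = set(d["genotype"]) - set(GENOTYPES)
        if bad_g:
            raise ValidationError(
                f"unknown genotype {sorted(bad_g)}; allowed: {list(GENOTYPES)}"
            )
        bad_t = set(d["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise ValidationError(
                f"unknown treatment {sorted(bad_t)}; allowed: {list(TREATMENTS)}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def group_mask(self, genotype: str | None = None, treatment: str | None = None) -> pd.Series:
        mask = pd.Series(True, index=self.data.index)
        if genotype is not None:
            mask &= self.data["genotype"] == genotype
        if treatment is not None:
            mask &= self.data["treatment"] == treatment
        return mask

    def subset(self, sample_ids) -> "SampleSheet":
        sv = None
        if self.structure_volumes is not None:
            sv = self.structure_volumes.loc[
                self.structure_volumes.index.intersection(sample_ids)
            ]
        return SampleSheet(self.data.loc[list(sample_ids)], sv)


@dataclass
class AnalysisConfig:
    """Thresholds and tuning knobs for the full analysis pipeline.

    Defaults mirror the study's printed thresholds: significance at
    q < 0.05 with a minimum group-mean beta difference of 5%, detection
    p masking above 0.05, a minimum of 3 beads, and a regional (Sidak)
    DMR threshold of 0.005.
    """

    q_threshold: float = 0.05
    q_threshold_relaxed: float = 0.1
    delta_beta_threshold: float = 0.05
    detection_p_max: float = 0.05
    min_beads: int = 3
    outlier_multiplier: float = 2.0
    max_probe_missing: float = 0.5
    m_offset: float = 0.01
    dmr_seed_p: float = 0.01
    dmr_max_gap_bp: int = 1000
    acf_bin_bp: int = 310
    dmr_sidak_max: float = 0.005
    sva_permutations: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "q_threshold",
            "q_threshold_relaxed",
            "delta_beta_threshold",
            "detection_p_max",
            "dmr_seed_p",
            "dmr_sidak_max",
            "max_probe_missing",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1); got {v}")
        if self.min_beads < 1:
            raise ConfigError("min_beads must be >= 1")
        if self.dmr_max_gap_bp < self.acf_bin_bp:
            raise ConfigError("dmr_max_gap_bp must be >= acf_bin_bp")
        if self.m_offset < 0:
            raise ConfigError("m_offset must be nonnegative")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))
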