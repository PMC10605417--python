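"""Text I/O for matrices, sample sheets, manifests and DMR BED output.

Matrices are CSV or TSV with probes as rows (first column ``probe_id``)
and samples as columns.  Missing values are written as empty fields.
Floats are written with 10 significant digits, enough for a bit-identical
text round trip of the values the pipeline produces.
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    BetaMatrix,
    DimensionError,
    ProbeManifest,
    SampleSheet,
    ValidationError,
)

FLOAT_FMT = "%.10g"


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt", ".bed")) else ","


def _read_matrix(path, index_name: str = "probe_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index.name = index_name
    return df


def _write_matrix(df: pd.DataFrame, path, index_label: str = "probe_id") -> None:
    df.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FMT, index_label=index_label)


def read_beta_bundle(beta_path, detp_path=None, beads_path=None) -> BetaMatrix:
    """Read beta / detection-p / bead-count matrices sharing identical headers."""
    beta = _read_matrix(beta_path)

    def aligned(path, name):
        if path is None:
            return None
        layer = _read_matrix(path)
        if not layer.columns.equals(beta.columns):
            raise DimensionError(
                f"{name} file disagrees with beta on the samples axis "
                f"({len(layer.columns)} vs {len(beta.columns)} columns)"
            )
        if not layer.index.equals(beta.index):
            raise DimensionError(
                f"{name} file disagrees with beta on the probes axis "
                f"({len(layer.index)} vs {len(beta.index)} rows)"
            )
        return layer

    return BetaMatrix(
        beta,
        detection_p=aligned(detp_path, "detection-p"),
        bead_count=aligned(beads_path, "bead-count"),
    )


def write_beta_bundle(bm: BetaMatrix, beta_path, detp_path=None, beads_path=None) -> None:
    _write_matrix(bm.beta, beta_path)
    if detp_path is not None and bm.detection_p is not None:
        _write_matrix(bm.detection_p, detp_path)
    if beads_path is not None and bm.bead_count is not None:
        _write_matrix(bm.bead_count, beads_path)


_GENOTYPE_ALIASES = {"wt": "WT", "wildtype": "WT", "ks1": "KS1", "kmt2d": "KS1"}
_TREATMENT_ALIASES = {"vehicle": "vehicle", "veh": "vehicle", "ar42": "AR42", "ar-42": "AR42"}


def read_sample_sheet(path) -> SampleSheet:
    """Read a sample sheet CSV; genotype/treatment parsed case-insensitively."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample_id", "genotype", "treatment", "day_of_sacrifice"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet lacks required columns: {sorted(missing)}")

    def canon(series: pd.Series, aliases: dict, what: str) -> pd.Series:
        keys = series.astype(str).str.strip().str.lower()
        unknown = sorted(set(keys) - set(aliases))
        if unknown:
            raise ValidationError(
                f"unknown {what} label(s) {unknown}; allowed: {sorted(set(aliases.values()))}"
            )
        return keys.map(aliases)

    df = df.copy()
    df["genotype"] = canon(df["genotype"], _GENOTYPE_ALIASES, "genotype")
    df["treatment"] = canon(df["treatment"], _TREATMENT_ALIASES, "treatment")
    df["day_of_sacrifice"] = df["day_of_sacrifice"].astype(int)
    df = df.set_index("sample_id")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, float_format=FLOAT_FMT, index_label="sample_id")


def read_manifest(path) -> ProbeManifest:
    df = pd.read_csv(path, sep=_sep_for(path))
    if "probe_id" not in df.columns:
        raise ValidationError("manifest lacks a probe_id column")
    df = df.set_index("probe_id")
    df["pos"] = df["pos"].astype(int)
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path) -> None:
    manifest.table.to_csv(path, float_format=FLOAT_FMT, index_label="probe_id")


def read_structure_volumes(path) -> pd.DataFrame:
    """Structure-volume table: sample_id column plus one column per structure."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise ValidationError("structure-volume table lacks a sample_id column")
    return df.set_index("sample_id").astype(float)


def read_config(path) -> AnalysisConfig:
    """Analysis config as YAML key-value text mirroring AnalysisConfig fields."""
    import yaml

    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_mapping(mapping)


def bed_score(sidak_p: float) -> int:
    """BED score column: -10*log10(sidak p), capped at 1000."""
    if sidak_p <= 0:
        return 1000
    return int(min(1000.0, round(-10.0 * math.log10(sidak_p))))


def write_dmr_bed(dmrs: Iterable, path) -> None:
    """Write DMRs as BED6+ (0-based half-open) with SLK/Sidak statistics.

    Extra columns: n_probes, n_hyper, n_hypo, slk_p, sidak_p.
    """
    lines = []
    for i, d in enumerate(dmrs, start=1):
        start0 = d.start - 1  # 1-based inclusive -> 0-based half-open
        end0 = d.end
        if end0 <= start0:
            raise ValidationError(
                f"DMR {d.chrom}:{d.start}-{d.end} has nonpositive extent in BED coordinates"
            )
        lines.append(
            "\t".join(
                [
                    str(d.chrom),
                    str(start0),
                    str(end0),
                    f"dmr_{i}",
                    str(bed_score(d.sidak_p)),
                    ".",
                    str(len(d.probe_ids)),
                    str(d.n_hyper),
                    str(d.n_hypo),
                    FLOAT_FMT % d.slk_p,
                    FLOAT_FMT % d.sidak_p,
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
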