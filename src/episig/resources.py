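"""Published gene-level signature calls used for cross-species comparison.

The mouse blood KS1 signature and the human blood KS1 signature
(Butcher et al. 2017) share 19 genes with differential methylation;
these tables carry, for each shared gene, the number of signature sites
and the direction of methylation change reported for each species.
They are inputs to :func:`episig.modeling.compare_signatures`.
"""

from __future__ import annotations

import pandas as pd

# (mouse gene, mouse n sites, mouse direction, human gene, human n sites, human direction)
_OVERLAP_ROWS = [
    ("Ado", 1, "hypo", "ADO", 2, "hypo"),
    ("Dlg4", 1, "hyper", "DLG4", 1, "hypo"),
    ("Hlx", 1, "hypo", "HLX", 1, "hypo"),
    ("Hnrnpa1", 2, "hypo", "HNRNPA1", 1, "hypo"),
    ("Il17re", 2, "hypo", "IL17RE", 1, "hyper"),
    ("Kirrel3", 1, "hypo", "KIRREL3", 1, "hyper"),
    ("Ksr1", 1, "hyper", "KSR1", 1, "hyper"),
    ("Rab11fip3", 1, "hypo", "RAB11FIP3", 1, "hypo"),
    ("Rai1", 1, "hyper", "RAI1", 1, "hyper"),
    ("Rps8", 3, "hypo", "RPS8", 1, "hypo"),
    ("Rrp12", 1, "hypo", "RRP12", 2, "hypo"),
    ("Sema6b", 3, "hypo", "SEMA6B", 1, "hypo"),
    ("Sh3rf3", 1, "hypo", "SH3RF3", 2, "hypo"),
    ("Slitrk5", 1, "hyper", "SLITRK5", 3, "hyper"),
    ("Slmap", 2, "hypo", "SLMAP", 1, "hypo"),
    ("Tnfaip2", 1, "hypo", "TNFAIP2", 3, "hypo"),
    ("Vac14", 1, "hyper", "VAC14", 1, "hypo"),
    ("Zbtb46", 2, "hypo", "ZBTB46", 1, "hypo"),
    ("Zmiz1", 3, "hyper", "ZMIZ1", 4, "hyper"),
]


def _site_level(gene_col: int, n_col: int, dir_col: int) -> pd.DataFrame:
    """Expand per-gene counts into one row per signature site."""
    rows = []
    for rec in _OVERLAP_ROWS:
        for _ in range(rec[n_col]):
            rows.append({"gene": rec[gene_col], "direction": rec[dir_col]})
    return pd.DataFrame(rows)


def mouse_ks1_overlap_sites() -> pd.DataFrame:
    """Mouse-signature sites (gene, direction) at the 19 shared genes."""
    return _site_level(0, 1, 2)


def human_ks1_overlap_sites() -> pd.DataFrame:
    """Human-signature sites (gene, direction) at the 19 shared genes."""
    return _site_level(3, 4, 5)
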