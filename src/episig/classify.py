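"""Leave-one-out cross-validation of the signature by correlation to group profiles.

Each vehicle-treated sample is held out in turn; the signature (including
surrogate variables) is re-derived on the remaining samples with the full
modeling stack, group mean beta profiles are built from the training
samples at the fold's signature probes, and the held-out sample is
assigned to the genotype whose profile it correlates with more strongly
(Pearson, beta scale).  Exact ties or undefined correlations yield an
explicit "unclassifiable" label rather than an arbitrary pick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core import AnalysisConfig, BetaMatrix, MValueMatrix, SampleSheet, ValidationError
from .modeling import derive_signature
from .preprocess import beta_to_m

UNCLASSIFIABLE = "unclassifiable"


@dataclass
class CvReport:
    folds: pd.DataFrame  # per held-out sample
    sensitivity: float
    specificity: float
    accuracy: float


def correlation_classify(
    test_betas: pd.Series, wt_profile: pd.Series, case_profile: pd.Series
) -> Tuple[str, float, float]:
    """Label the test vector by its stronger Pearson correlation to a profile."""
    joint = pd.concat([test_betas, wt_profile, case_profile], axis=1).dropna()
    if len(joint) < 3:
        raise ValidationError("need at least 3 jointly non-missing probes to classify")
    x, w, c = (joint.iloc[:, i].to_numpy() for i in range(3))
    # tolerance guards: an effectively constant vector or an effective tie must
    # yield an explicit non-call, never an arbitrary float-noise pick
    if np.std(x) < 1e-12 or np.std(w) < 1e-12 or np.std(c) < 1e-12:
        return UNCLASSIFIABLE, np.nan, np.nan
    r_wt = float(np.corrcoef(x, w)[0, 1])
    r_case = float(np.corrcoef(x, c)[0, 1])
    if abs(r_wt - r_case) < 1e-12:
        return UNCLASSIFIABLE, r_wt, r_case
    return ("WT" if r_wt > r_case else "KS1"), r_wt, r_case


def loo_crossvalidate(
    bm: BetaMatrix,
    sheet: SampleSheet,
    cfg: AnalysisConfig,
    m: Optional[MValueMatrix] = None,
) -> CvReport:
    """LOO-CV over vehicle-treated samples with per-fold signature re-derivation."""
    vehicle = sheet.data.index[sheet.data["treatment"] == "vehicle"]
    vehicle = vehicle.intersection(bm.sample_ids)
    geno = sheet.data.loc[vehicle, "genotype"]
    for g in ("WT", "KS1"):
        if (geno == g).sum() < 3:
            raise ValidationError(f"need >= 3 vehicle-treated {g} samples for LOO-CV")
    if m is None:
        m = beta_to_m(bm, cfg)

    rows = []
    for held in vehicle:
        train = vehicle.drop(held)
        bm_tr = bm.subset_samples(train)
        m_tr = MValueMatrix(m.m[list(train)])
        sheet_tr = sheet.subset(train)
        _, sig, k = derive_signature(bm_tr, m_tr, sheet_tr, cfg)
        truth = sheet.data.loc[held, "genotype"]
        if len(sig.probe_ids) == 0:
            rows.append(
                dict(sample_id=held, true_label=truth, predicted=UNCLASSIFIABLE,
                     r_wt=np.nan, r_case=np.nan, n_probes=0, n_sv=k,
                     reason="empty signature")
            )
            continue
        probes = sig.probe_ids
        wt_cols = train[sheet.data.loc[train, "genotype"] == "WT"]
        ks_cols = train[sheet.data.loc[train, "genotype"] == "KS1"]
        wt_profile = bm.beta.loc[probes, list(wt_cols)].mean(axis=1)
        ks_profile = bm.beta.loc[probes, list(ks_cols)].mean(axis=1)
        label, r_wt, r_case = correlation_classify(
            bm.beta.loc[probes, held], wt_profile, ks_profile
        )
        rows.append(
            dict(sample_id=held, true_label=truth, predicted=label, r_wt=r_wt,
                 r_case=r_case, n_probes=len(probes), n_sv=k, reason="")
        )

    folds = pd.DataFrame(rows).set_index("sample_id")
    correct = folds["predicted"] == folds["true_label"]
    is_case = folds["true_label"] == "KS1"
    sensitivity = float(correct[is_case].mean()) if is_case.any() else np.nan
    specificity = float(correct[~is_case].mean()) if (~is_case).any() else np.nan
    accuracy = float(correct.mean())
    return CvReport(folds, sensitivity, specificity, accuracy)
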