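"""Quantify HDACi (AR-42) rescue of the methylation signature.

Two readouts: the threshold-free fraction of signature CpGs whose
treated-mutant mean lands closer to wildtype than the untreated-mutant
mean, and a moderated vehicle-vs-treated contrast within mutant animals
with FDR over the signature scan.  Note the 50% noise baseline of the
first statistic: with no treatment effect either arm is closer half the
time, so only the excess above one half is evidence of rescue.
"""

from episig import AnalysisConfig, SimulationConfig, generate_cohort
from episig.modeling import Signature
from episig.preprocess import beta_to_m
from episig.treatment import rescue_flags, rescue_fraction_recovery_check, treated_contrast
import pandas as pd

bm, manifest, sheet, truth = generate_cohort(SimulationConfig(n_probes=6000, seed=2))
cfg = AnalysisConfig(rng_seed=2)
signature = Signature(pd.DataFrame({
    "direction": truth.signature["direction"],
    "q": 0.0, "delta_beta": truth.signature["delta_beta"],
}, index=truth.signature_probe_ids))

report = rescue_flags(bm, sheet, signature)
print(f"rescued {report.n_rescued}/{report.n_evaluated} "
      f"({100 * report.fraction_rescued:.1f}%) of signature CpGs")
print(f"  hypermethylated sites: {100 * report.fraction_rescued_hyper:.1f}% rescued")
print(f"  hypomethylated sites:  {100 * report.fraction_rescued_hypo:.1f}% rescued")
print("recovery vs planted:", rescue_fraction_recovery_check(truth, report))

m = beta_to_m(bm, cfg)
_, called = treated_contrast(bm, m, sheet, signature, cfg)
print(f"{len(called.probe_ids)} CpGs reach per-probe significance in the "
      f"vehicle-vs-treated mutant contrast")
# The observed fraction tracks the planted 69% and is direction-agnostic,
# while only the most strongly shrunk CpGs clear per-probe significance.
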