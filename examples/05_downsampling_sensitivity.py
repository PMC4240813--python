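"""How much coverage does INDEL detection need, by zygosity?

Thins each call's allele coverages binomially to emulate downsampling and
asks what fraction of the truth set stays detectable (>= 3 alternate-allele
reads).  Heterozygous calls, whose alternate allele carries only ~half the
locus depth, need more coverage than homozygous ones.
"""

from indelqc import sensitivity_curve
from indelqc.simdata import (
    WGS_LIKE, generate_callset, generate_reference, generate_truth_indels,
)

spec = [("A", 8, 40), ("T", 8, 40), ("C", 6, 8), ("G", 6, 8),
        ("CA", 10, 16), ("AAG", 9, 8)]
ref = generate_reference(60_000, spec, seed=8)
truth = generate_truth_indels(ref, n=300, seed=9)
wgs = generate_callset(truth, WGS_LIKE, ref, seed=10)

curves = sensitivity_curve(wgs.callset, full_mean=WGS_LIKE.mean_depth,
                           levels=(10, 20, 32, 45, 57), seed=11, strata=True)
header = "  ".join(f"{lvl:5.0f}X" for lvl in curves["all"].coverage_levels)
print(f"{'stratum':14s} {header}")
for name, curve in curves.items():
    row = "  ".join(f"{100 * s:5.1f}%" for s in curve.sensitivity)
    print(f"{name:14s} {row}")
print("Sensitivity at the full coverage is 1 by construction of the "
      "denominator; the heterozygous curve lags the homozygous one at "
      "every thinned level.")
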