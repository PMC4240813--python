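"""Score and classify a small INDEL call set with the k-mer Chi-Square filter.

Builds a synthetic benchmark whose calls are planted into the high- and
low-quality tiers with known error rates (7% and 51%), classifies them, and
recovers the planted rates from the hidden truth labels.
"""

from indelqc import chi_square_score, classify, classify_callset, ppv_by_class
from indelqc.simdata import generate_quality_benchmark

# the score on a single call: balanced coverages are trustworthy (chi2 ~ 0),
# imbalanced ones are suspect
for cov_ref, cov_alt in [(12, 12), (10, 2), (60, 3)]:
    chi2 = chi_square_score(cov_ref, cov_alt)
    print(f"cov_ref={cov_ref:3d} cov_alt={cov_alt:3d} chi2={chi2:6.2f} "
          f"-> {classify(cov_alt, chi2)}")

cs = generate_quality_benchmark(n_high=500, n_low=500, seed=1)
classify_callset(cs)
for cls, value in sorted(ppv_by_class(cs).items()):
    print(f"{cls:5s} quality: empirical PPV {value:.1f}% "
          f"(error rate {100 - value:.1f}%)")
print("High-tier calls validate ~93% of the time, low-tier only ~49%: the "
      "two coverage/score cutoffs separate reliable calls from artifacts.")
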