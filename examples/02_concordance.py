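"""Compare two platform-flavored call sets derived from one truth set.

Exact-match concordance between a uniform-coverage (WGS-like) and a
capture-skewed (WES-like) call set rises as shallow loci are filtered out,
because discordance concentrates where one platform barely covered the
locus.
"""

from indelqc import compare_callsets, multiple_signatures, union_callset
from indelqc.simdata import (
    WES_LIKE, WGS_LIKE, generate_callset, generate_reference,
    generate_truth_indels,
)

spec = [("A", 8, 40), ("T", 8, 40), ("C", 6, 8), ("G", 6, 8),
        ("CA", 10, 16), ("AAG", 9, 8)]
ref = generate_reference(60_000, spec, seed=1)
truth = generate_truth_indels(ref, n=250, seed=2)
wgs = generate_callset(truth, WGS_LIKE, ref, seed=3)
wes = generate_callset(truth, WES_LIKE, ref, seed=4)

print(f"truth {len(truth)} | WGS-like {len(wgs.callset)} calls "
      f"({wgs.n_false} false) | WES-like {len(wes.callset)} calls "
      f"({wes.n_false} false)")

for floor in (0, 1, 20, 40):
    r = compare_callsets(wgs.callset, wes.callset, mode="exact",
                         depth_a=wgs.depth, depth_b=wes.depth,
                         depth_floor=floor)
    print(f"depth floor >= {floor:2d}: concordant {r.rate_concordant:5.1f}%  "
          f"WGS-only {r.rate_a_specific:5.1f}%  WES-only {r.rate_b_specific:5.1f}%")

loci = multiple_signatures(union_callset(wgs.callset, wes.callset))
print(f"{len(loci)} positions carry multiple INDEL signatures "
      "(at most one per locus can be real; the surplus are presumptive errors).")
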