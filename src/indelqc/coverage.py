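"""Coverage-uniformity statistics over region sets.

Three summaries describe how evenly a region is sequenced: the mean per-base
depth, the coverage fraction at X (the proportion of bases covered by at
least X reads), and the coefficient of variation

    CV = 100 * (1 + 1/(4n)) * s / xbar   [percent]

where s is the sample standard deviation (n-1 denominator) and xbar the
sample mean.  The (1 + 1/(4n)) factor is the small-sample bias correction;
it is negligible for the region sizes typical of sequencing data (n > 10^4)
but kept for exactness.  Lower CV means more uniform coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import RegionSet

logger = logging.getLogger(__name__)

DEFAULT_FRACTION_RANGE = range(1, 52)

DepthTable = dict[tuple[str, int], int]


def cv_estimator(depths) -> float:
    """Bias-corrected coefficient of variation of a depth vector, in percent."""
    d = np.asarray(depths, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("CV requires at least two observations")
    mean = d.mean()
    if mean <= 0:
        raise ValueError("CV undefined for zero mean depth")
    s = d.std(ddof=1)
    return 100.0 * (1.0 + 1.0 / (4.0 * n)) * (s / mean)


def coverage_fraction(depths, x: int) -> float:
    """Proportion of bases covered with at least ``x`` reads."""
    if x < 0:
        raise ValueError("x must be non-negative")
    d = np.asarray(depths)
    if d.size == 0:
        raise ValueError("empty depth vector")
    return float(np.mean(d >= x))


@dataclass
class CoverageProfile:
    """Per-base depths over a region set with derived summary statistics."""

    depths: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)
    cv: float = field(init=False)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=int)
        if np.any(self.depths < 0):
            raise ValueError("negative depths")
        self.mean = float(self.depths.mean()) if self.depths.size else 0.0
        self.sd = float(self.depths.std(ddof=1)) if self.depths.size > 1 else 0.0
        self.cv = (
            cv_estimator(self.depths)
            if self.depths.size > 1 and self.mean > 0
            else 0.0
        )

    @property
    def n(self) -> int:
        return int(self.depths.size)

    def fraction_at(self, x: int) -> float:
        return coverage_fraction(self.depths, x)

    def fraction_curve(self, xs=DEFAULT_FRACTION_RANGE) -> dict[int, float]:
        return {int(x): self.fraction_at(int(x)) for x in xs}


def read_depth_tsv(path: str) -> DepthTable:
    """Read a (chrom, pos, depth) TSV — 1-based positions — into a depth map."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "depth"], comment="#"
    )
    return {
        (str(r.chrom), int(r.pos)): int(r.depth)
        for r in df.itertuples(index=False)
    }


def write_depth_tsv(depth: DepthTable, path: str) -> None:
    with open(path, "w") as fh:
        for (chrom, pos), d in sorted(depth.items()):
            fh.write(f"{chrom}\t{pos}\t{d}\n")


def profile_region(depth_source: DepthTable, regions: RegionSet) -> CoverageProfile:
    """Assemble the per-base depth vector over merged regions.

    ``depth_source`` maps (chrom, 1-based pos) to depth; bases absent from it
    count as depth 0 with a logged tally.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    depths = []
    n_missing = 0
    for chrom, start, end in regions:
        for pos0 in range(start, end):
            d = depth_source.get((chrom, pos0 + 1))
            if d is None:
                n_missing += 1
                d = 0
            depths.append(d)
    if n_missing:
        logger.info("profile_region: %d bases missing from depth source (depth 0)", n_missing)
    return CoverageProfile(depths=np.array(depths, dtype=int))
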