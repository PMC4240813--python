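"""Coverage-downsampling sensitivity analysis against a trusted truth set.

Sensitivity at mean coverage X is the fraction of truth INDELs (those
recoverable at full coverage) still recovered after the data are thinned to
X.  Re-aligning and re-assembling reads at every level is deliberately out
of scope; instead each call's per-allele coverages are binomially thinned at
rate X / full_mean and a call counts as detected when its thinned alternate
coverage clears a minimum (default 3 reads, the usual micro-assembly
``--mincov`` floor).  This surrogate reproduces the qualitative behaviour of
read-level downsampling — curves rise with coverage and heterozygous calls,
whose alternate allele carries only ~half the reads, need more coverage than
homozygous ones — but makes no claim to reproduce absolute coverage
requirements measured on real data.

Zygosity strata: heterozygous calls are detected from roughly half the locus
depth, homozygous calls from all of it, so the homozygous curve dominates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .variants import (
    CallSet,
    HETEROZYGOUS,
    HOMOZYGOUS,
    IndelCall,
    UNKNOWN,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_ALT = 3
DEFAULT_REPLICATES = 25
ALL = "all"


def sensitivity_at(truth: CallSet, called: CallSet, mode: str = "exact") -> float:
    """|truth ∩ called| / |truth| under exact matching."""
    if len(truth) == 0:
        raise ValueError("empty truth set")
    if mode != "exact":
        raise ValueError("sensitivity is defined under exact matching")
    return len(truth.keys() & called.keys()) / len(truth)


def thin_coverages(
    calls: CallSet,
    full_mean: float,
    target_mean: float,
    seed: int | np.random.Generator = 0,
) -> CallSet:
    """Binomially thin each call's allele coverages at rate target/full.

    Each read survives independently with probability ``target_mean /
    full_mean``, emulating read-level downsampling at the call level.
    Deterministic under ``seed``.
    """
    if not 0 <= target_mean <= full_mean:
        raise ValueError("need 0 <= target_mean <= full_mean")
    rate = target_mean / full_mean
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    thinned = [
        dc_replace(
            c,
            cov_ref=int(rng.binomial(c.cov_ref, rate)),
            cov_alt=int(rng.binomial(c.cov_alt, rate)),
        )
        for c in calls.calls
    ]
    return CallSet(
        label=f"{calls.label}@{target_mean:g}X",
        sample_id=calls.sample_id,
        calls=thinned,
        target_regions=calls.target_regions,
    )


def detectable(call: IndelCall, min_alt: int = DEFAULT_MIN_ALT) -> bool:
    """Surrogate detection rule: enough alternate-allele coverage remains."""
    return call.cov_alt >= min_alt


@dataclass(frozen=True)
class SensitivityCurve:
    """Mean sensitivity per coverage level for one zygosity stratum."""

    stratum: str
    coverage_levels: tuple[float, ...]
    sensitivity: tuple[float, ...]
    sd: tuple[float, ...]
    truth_size: int

    def as_dict(self) -> dict[float, float]:
        return dict(zip(self.coverage_levels, self.sensitivity))


def _curve_for(
    calls: list[IndelCall],
    full_mean: float,
    levels: tuple[float, ...],
    min_alt: int,
    replicates: int,
    rng: np.random.Generator,
    stratum: str,
) -> SensitivityCurve:
    base = CallSet(label=stratum, calls=calls)
    # denominator: truth calls recoverable at full coverage
    denom = [c for c in base.calls if detectable(c, min_alt)]
    if not denom:
        raise ValueError(f"no detectable truth calls in stratum {stratum!r}")
    denom_set = CallSet(label=stratum, calls=denom)
    means, sds = [], []
    for level in levels:
        if level >= full_mean:
            means.append(1.0)
            sds.append(0.0)
            continue
        reps = []
        for _ in range(replicates):
            thinned = thin_coverages(denom_set, full_mean, level, seed=rng)
            hit = sum(1 for c in thinned.calls if detectable(c, min_alt))
            reps.append(hit / len(denom))
        means.append(float(np.mean(reps)))
        sds.append(float(np.std(reps, ddof=1)) if replicates > 1 else 0.0)
    return SensitivityCurve(
        stratum=stratum,
        coverage_levels=tuple(float(v) for v in levels),
        sensitivity=tuple(means),
        sd=tuple(sds),
        truth_size=len(denom),
    )


def sensitivity_curve(
    truth: CallSet,
    full_mean: float,
    levels=(20.0, 32.0, 45.0, 57.0),
    min_alt: int = DEFAULT_MIN_ALT,
    seed: int = 0,
    strata: bool = False,
    replicates: int = DEFAULT_REPLICATES,
) -> dict[str, SensitivityCurve]:
    """Sensitivity-vs-coverage curves, averaged over thinning replicates.

    ``levels`` are target mean coverages; the full coverage level is appended
    and equals 1.0 by construction of the denominator.  With ``strata=True``
    separate heterozygous and homozygous curves are returned (calls of
    unknown zygosity are excluded with a logged count).
    """
    levels = tuple(sorted(set(float(v) for v in levels) | {float(full_mean)}))
    rng = np.random.default_rng(seed)
    curves = {
        ALL: _curve_for(list(truth.calls), full_mean, levels, min_alt,
                        replicates, rng, ALL)
    }
    if strata:
        unknown = [c for c in truth.calls if c.zygosity == UNKNOWN]
        if unknown:
            logger.info("excluding %d calls of unknown zygosity from strata", len(unknown))
        for zyg in (HETEROZYGOUS, HOMOZYGOUS):
            sub = [c for c in truth.calls if c.zygosity == zyg]
            if sub:
                curves[zyg] = _curve_for(sub, full_mean, levels, min_alt,
                                         replicates, rng, zyg)
    return curves
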