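"""Synthetic references, truth INDEL sets, and platform-flavored call sets.

The generator gives every pipeline stage a test surface that needs no
sequencing data.  It emulates the contrasts that drive INDEL error profiles
in real short-read data: whole-genome-like coverage is moderate but uniform;
exome-capture-like coverage is deep but overdispersed, drops a sizeable
fraction of its target outright, under-recovers large (>5 bp) INDELs, and
produces false calls preferentially inside homopolymer A/T tracts.

Depth model: negative binomial parameterized by (mean, CV) — overdispersed
counts reproduce capture-induced skew.  Heterozygous alternate coverage is
Binomial(depth, 0.5); homozygous calls take the full depth.  False calls
draw their depth from a reduced mean (errors concentrate where sequencing is
poor) and a low alternate-allele fraction, which inflates their Chi-Square
allele-balance scores.  All randomness flows from one numpy Generator, so a
seed makes every output byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from . import context as ctx
from .variants import (
    CallSet,
    DictReference,
    HETEROZYGOUS,
    HOMOZYGOUS,
    IndelCall,
    RegionSet,
    left_normalize,
)

_BASES = "ACGT"

DEFAULT_CONTEXT_MIX: dict[str, float] = {
    ctx.POLY_A: 0.12,
    ctx.POLY_T: 0.12,
    ctx.POLY_C: 0.02,
    ctx.POLY_G: 0.02,
    ctx.OTHER_STR: 0.12,
    ctx.NON_STR: 0.60,
}

# Heterozygous share of a diploid truth set: ~1.6-fold more heterozygous
# than homozygous INDELs (1000 vs 635 per sample).
DEFAULT_HET_FRAC = 1000 / 1635


def default_size_dist(rng: np.random.Generator) -> int:
    """Geometric(p=0.35) truncated to 1..100 bp: small-indel skew, long tail."""
    return int(min(rng.geometric(0.35), 100))


@dataclass(frozen=True)
class PlatformProfile:
    """Coverage and error structure of one sequencing platform flavor.

    ``cv_target`` is a fraction (0.39 = 39%); ``fdr_by_context`` gives the
    false-call fraction among emitted calls per context label;
    ``large_indel_capture_penalty`` is the probability that a >5 bp truth
    INDEL is lost to capture.
    """

    label: str
    mean_depth: float
    cv_target: float
    dropout_frac: float = 0.0
    fdr_by_context: Mapping[str, float] = field(default_factory=dict)
    large_indel_capture_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        rates = [self.dropout_frac, self.large_indel_capture_penalty,
                 *self.fdr_by_context.values()]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")


# Mean depth / CV values follow the exonic summaries of deep short-read
# platform comparisons: uniform WGS (71X, CV 39%), skewed captured WES
# (337X, CV 109%, 16% of targets unrecovered, most large INDELs missed),
# and PCR-free WGS with damped homopolymer error rates.
WGS_LIKE = PlatformProfile(
    label="WGS-like", mean_depth=71, cv_target=0.394, dropout_frac=0.001,
    large_indel_capture_penalty=0.05,
    fdr_by_context={ctx.POLY_A: 0.15, ctx.POLY_T: 0.15, ctx.POLY_C: 0.05,
                    ctx.POLY_G: 0.05, ctx.OTHER_STR: 0.08, ctx.NON_STR: 0.03},
)
WES_LIKE = PlatformProfile(
    label="WES-like", mean_depth=337, cv_target=1.093, dropout_frac=0.16,
    large_indel_capture_penalty=0.70,
    fdr_by_context={ctx.POLY_A: 0.45, ctx.POLY_T: 0.45, ctx.POLY_C: 0.10,
                    ctx.POLY_G: 0.10, ctx.OTHER_STR: 0.15, ctx.NON_STR: 0.05},
)
PCRFREE_LIKE = PlatformProfile(
    label="PCR-free-like", mean_depth=50, cv_target=0.35, dropout_frac=0.0,
    large_indel_capture_penalty=0.05,
    fdr_by_context={ctx.POLY_A: 0.06, ctx.POLY_T: 0.06, ctx.POLY_C: 0.03,
                    ctx.POLY_G: 0.03, ctx.OTHER_STR: 0.05, ctx.NON_STR: 0.02},
)


@dataclass
class SyntheticReference:
    """A generated chromosome with its planted repeat-tract truth."""

    chrom: str
    sequence: str
    tracts: list[ctx.RepeatTract]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom != self.chrom:
            raise KeyError(chrom)
        return self.sequence[max(start, 0):max(end, 0)]

    def get_reference_length(self, chrom: str) -> int:
        return len(self.sequence)

    def as_dict_reference(self) -> DictReference:
        return DictReference({self.chrom: self.sequence})

    def tract_regions(self, pad: int = 0) -> RegionSet:
        if not self.tracts:
            return RegionSet()
        return ctx.tracts_to_regionset(self.tracts).pad(pad)


def find_all_tracts(seq: str, chrom: str = "") -> list[ctx.RepeatTract]:
    """All tracts either detector reports, sorted."""
    tracts = ctx.find_homopolymers(seq, chrom=chrom) + ctx.find_strs(seq, chrom=chrom)
    return sorted(set(tracts), key=lambda t: (t.start, t.end, t.motif))


def _repeat_free_background(length: int, rng: np.random.Generator,
                            chrom: str, max_rounds: int = 60) -> list[str]:
    """Random sequence scrubbed of any detectable repeat tract.

    Detected tracts get a middle base mutated until a fresh scan is clean;
    this makes planted tract coordinates equal detector output exactly.
    """
    seq = list(rng.choice(list(_BASES), size=length))
    for _ in range(max_rounds):
        found = find_all_tracts("".join(seq), chrom)
        if not found:
            return seq
        for t in found:
            mid = (t.start + t.end) // 2
            forbidden = {seq[mid]}
            if mid > 0:
                forbidden.add(seq[mid - 1])
            if mid + 1 < length:
                forbidden.add(seq[mid + 1])
            choices = [b for b in _BASES if b not in forbidden] or [
                b for b in _BASES if b != seq[mid]
            ]
            seq[mid] = choices[int(rng.integers(len(choices)))]
    raise RuntimeError("could not scrub background of incidental repeat tracts")


def generate_reference(
    length: int,
    tract_spec: list[tuple[str, int, int]],
    seed: int | np.random.Generator = 0,
    chrom: str = "chr1",
) -> SyntheticReference:
    """Random reference with planted repeat tracts at recorded coordinates.

    ``tract_spec`` lists (motif, tract_span_bp, count) triples: a 1-base
    motif plants homopolymers, a 2-6 bp motif plants STR tracts.  The
    background is scrubbed of incidental tracts, so the detectors report
    exactly the planted coordinates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    jobs: list[tuple[str, int]] = []
    for motif, span, count in tract_spec:
        motif = motif.upper()
        if not set(motif) <= set(_BASES) or not 1 <= len(motif) <= 6:
            raise ValueError(f"bad motif {motif!r}")
        if len(motif) == 1 and span < ctx.DEFAULT_HOMOPOLYMER_MIN_LEN:
            raise ValueError(f"homopolymer span {span} below detectable minimum")
        if len(motif) > 1 and (span < ctx.DEFAULT_STR_MIN_SPAN
                               or span / len(motif) < ctx.DEFAULT_STR_MIN_COPIES):
            raise ValueError(f"STR span {span} below detectable minimum for {motif!r}")
        jobs += [(motif, span)] * count

    buffer = 12
    need = sum(span + buffer for _, span in jobs) + buffer
    if need > length:
        raise ValueError(f"tracts ({need} bp incl. spacing) overflow length {length}")

    seq = _repeat_free_background(length, rng, chrom)

    # place tracts left to right with random gaps
    placements: list[tuple[int, str, int]] = []
    if jobs:
        order = rng.permutation(len(jobs))
        jobs = [jobs[i] for i in order]
        slack = length - need
        gaps = rng.multinomial(slack, np.ones(len(jobs) + 1) / (len(jobs) + 1))
        cursor = int(gaps[0]) + buffer
        for (motif, span), extra in zip(jobs, gaps[1:]):
            m = len(motif)
            tile = (motif * math.ceil(span / m))[:span]
            seq[cursor:cursor + span] = list(tile)
            # break the repeat at both boundaries
            left_bad = {tile[0], tile[m - 1] if m > 1 else tile[0]}
            right_bad = {tile[-1], tile[span - m] if m > 1 else tile[-1]}
            seq[cursor - 1] = next(b for b in _BASES if b not in left_bad)
            if cursor + span < length:
                seq[cursor + span] = next(b for b in _BASES if b not in right_bad)
            placements.append((cursor, motif, span))
            cursor += span + buffer + int(extra)

    # scrub any incidental tract the planting may have induced nearby
    planted_iv = {(p, p + s) for p, _, s in placements}
    for _ in range(60):
        found = find_all_tracts("".join(seq), chrom)
        spurious = [t for t in found if (t.start, t.end) not in planted_iv]
        if not spurious:
            break
        for t in spurious:
            inside = [
                i for i in range(t.start, t.end)
                if not any(s - 2 <= i < e + 2 for s, e in planted_iv)
            ]
            if not inside:  # abuts a planted tract closer than the guard
                inside = [
                    i for i in range(t.start, t.end)
                    if not any(s <= i < e for s, e in planted_iv)
                ] or [t.start]
            mid = inside[len(inside) // 2]
            forbidden = {seq[mid]}
            if mid > 0:
                forbidden.add(seq[mid - 1])
            if mid + 1 < length:
                forbidden.add(seq[mid + 1])
            choices = [b for b in _BASES if b not in forbidden] or [
                b for b in _BASES if b != seq[mid]
            ]
            seq[mid] = choices[int(rng.integers(len(choices)))]
    sequence = "".join(seq)
    tracts = find_all_tracts(sequence, chrom)
    if {(t.start, t.end) for t in tracts} != planted_iv:
        raise RuntimeError("planted tracts do not round-trip through the detectors")
    return SyntheticReference(chrom=chrom, sequence=sequence, tracts=tracts)


class _BlockedPositions:
    """Fast chromless membership over padded tract intervals."""

    def __init__(self, tracts: list[ctx.RepeatTract], pad: int):
        self._ivs = sorted((t.start - pad, t.end + pad) for t in tracts)
        self._starts = [s for s, _ in self._ivs]

    def contains_chromless(self, pos: int) -> bool:
        import bisect
        i = bisect.bisect_right(self._starts, pos) - 1
        return i >= 0 and self._ivs[i][0] <= pos < self._ivs[i][1]

    def contains(self, chrom: str, pos: int) -> bool:  # RegionSet-compatible
        return self.contains_chromless(pos)


def generate_truth_indels(
    reference: SyntheticReference,
    n: int,
    size_dist: Callable[[np.random.Generator], int] | None = None,
    het_frac: float = DEFAULT_HET_FRAC,
    context_mix: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> CallSet:
    """``n`` normalized truth INDELs with planted zygosity and context mix.

    Contexts place calls inside planted tracts of the matching kind (sizes
    clip to what a tract accommodates); non-STR calls avoid all tracts by an
    8 bp margin.  Positions are unique after normalization.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    size_dist = size_dist or default_size_dist
    mix = dict(context_mix or DEFAULT_CONTEXT_MIX)
    if abs(sum(mix.values()) - 1) > 1e-9:
        raise ValueError("context_mix must sum to 1")

    homos_by_base = {
        b: [t for t in reference.tracts if t.kind == ctx.HOMOPOLYMER and t.motif == b]
        for b in _BASES
    }
    strs = [t for t in reference.tracts if t.kind == ctx.STR_KIND]
    for label, frac in mix.items():
        if frac > 0:
            if label.startswith("poly-") and not homos_by_base[label[-1]]:
                raise ValueError(f"context_mix requests {label} but no such tract planted")
            if label == ctx.OTHER_STR and not strs:
                raise ValueError("context_mix requests other-STR but no STR tract planted")

    blocked = _BlockedPositions(reference.tracts, pad=8)
    seqlen = len(reference.sequence)
    labels = list(mix)
    probs = np.array([mix[l] for l in labels])
    used_pos: set[int] = set()
    ref_src = reference
    calls: list[IndelCall] = []
    attempts = 0
    while len(calls) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise ValueError(f"could not place {n} INDELs on this reference")
        label = labels[int(rng.choice(len(labels), p=probs))]
        size = max(1, int(size_dist(rng)))
        is_del = bool(rng.random() < 0.5)
        zyg = HETEROZYGOUS if rng.random() < het_frac else HOMOZYGOUS

        if label.startswith("poly-"):
            tract = homos_by_base[label[-1]][int(rng.integers(len(homos_by_base[label[-1]])))]
            base = tract.motif
            if is_del:
                size = min(size, tract.span - 1)
                start0 = tract.start  # delete the first `size` bases of the run
                anchor0 = start0 - 1
                ref_allele = reference.sequence[anchor0:start0 + size]
                alt_allele = reference.sequence[anchor0]
                pos = anchor0 + 1
            else:
                anchor0 = tract.start - 1
                ref_allele = reference.sequence[anchor0]
                alt_allele = ref_allele + base * size
                pos = anchor0 + 1
        elif label == ctx.OTHER_STR:
            tract = strs[int(rng.integers(len(strs)))]
            m = len(tract.motif)
            anchor0 = tract.start - 1
            if is_del:
                del_len = min(size, tract.span - 1)
                ref_allele = reference.sequence[anchor0:tract.start + del_len]
                alt_allele = reference.sequence[anchor0]
            else:
                tile = (tract.motif * math.ceil(size / m))[:size]
                ref_allele = reference.sequence[anchor0]
                alt_allele = ref_allele + tile
            pos = anchor0 + 1
        else:  # non-STR
            if is_del:
                start0 = _free_start(rng, seqlen, size, blocked, used_pos)
                if start0 is None:
                    continue
                anchor0 = start0 - 1
                ref_allele = reference.sequence[anchor0:start0 + size]
                alt_allele = reference.sequence[anchor0]
                pos = anchor0 + 1
            else:
                start0 = _free_start(rng, seqlen, 1, blocked, used_pos)
                if start0 is None:
                    continue
                anchor0 = start0 - 1
                ref_allele = reference.sequence[anchor0]
                ins = _nonrepetitive_insert(rng, size, ref_allele)
                alt_allele = ref_allele + ins
                pos = anchor0 + 1

        try:
            call = IndelCall(
                chrom=reference.chrom, pos=pos, ref_allele=ref_allele,
                alt_allele=alt_allele, zygosity=zyg, truth=True,
            )
            call = left_normalize(call, ref_src)
        except ValueError:
            continue
        if call.pos in used_pos:
            continue
        used_pos.add(call.pos)
        ctx.annotate_context(call, ref_src)
        calls.append(call)

    return CallSet(label="truth", calls=calls)


def _free_start(rng, seqlen, size, blocked: _BlockedPositions, used: set[int],
                pad: int = 4) -> int | None:
    for _ in range(50):
        start = int(rng.integers(10, seqlen - size - 10))
        if any((start + k) in used for k in range(-2, size + 3)):
            continue
        if any(blocked.contains_chromless(start + k) for k in range(-pad, size + pad)):
            continue
        return start
    return None


def _nonrepetitive_insert(rng: np.random.Generator, size: int, anchor: str) -> str:
    """Random insertion allele avoiding runs that would read as a repeat."""
    out: list[str] = []
    prev2 = ["", anchor]
    for _ in range(size):
        choices = [b for b in _BASES if b != prev2[-1] and b != prev2[-2]]
        b = choices[int(rng.integers(len(choices)))]
        out.append(b)
        prev2 = [prev2[-1], b]
    return "".join(out)


def draw_depth(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Overdispersed per-locus depths: negative binomial with the given mean/CV.

    Falls back to Poisson when the requested variance (cv*mean)^2 is at or
    below the mean (the negative binomial cannot be underdispersed).
    """
    var = (cv * mean) ** 2
    if var <= mean:
        return rng.poisson(mean, size=size)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


@dataclass
class SimulatedCallSet:
    """A platform-flavored call set plus the bookkeeping tests rely on."""

    callset: CallSet
    depth: dict[tuple[str, int], int]  # per-locus total depth, truth loci included
    profile: PlatformProfile
    n_true: int
    n_false: int
    n_dropped_dropout: int
    n_dropped_large: int


def generate_callset(
    truth: CallSet,
    profile: PlatformProfile,
    reference: SyntheticReference,
    seed: int | np.random.Generator = 0,
    window_bp: int = 1000,
) -> SimulatedCallSet:
    """Pass a truth set through one platform's coverage and error structure.

    Truth calls in dropped-out capture windows vanish with depth 0; large
    (>5 bp) calls are additionally lost with the capture penalty; surviving
    calls draw a locus depth from the (mean, CV) negative-binomial model and
    an alternate coverage from their zygosity.  False calls are injected per
    context at the profile's false-call fraction, placed inside matching
    tracts, with low-depth, allele-imbalanced coverages.  Every emitted call
    carries a hidden ``truth`` label.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqlen = len(reference.sequence)
    n_windows = math.ceil(seqlen / window_bp)
    n_drop = int(round(profile.dropout_frac * n_windows))
    dropped_windows = set(
        int(w) for w in rng.choice(n_windows, size=n_drop, replace=False)
    ) if n_drop else set()

    depth_map: dict[tuple[str, int], int] = {}
    emitted: list[IndelCall] = []
    n_dropout = n_large_lost = 0
    depths = draw_depth(rng, profile.mean_depth, profile.cv_target, len(truth.calls))
    for call, depth in zip(truth.calls, depths):
        locus = call.position_key
        if (call.pos - 1) // window_bp in dropped_windows:
            n_dropout += 1
            depth_map[locus] = 0
            continue
        if call.size > 5 and rng.random() < profile.large_indel_capture_penalty:
            n_large_lost += 1
            depth_map[locus] = 0
            continue
        depth = int(depth)
        depth_map[locus] = depth
        if call.zygosity == HETEROZYGOUS:
            cov_alt = int(rng.binomial(depth, 0.5))
        else:
            cov_alt = depth
        if cov_alt == 0:
            continue
        emitted.append(
            IndelCall(
                chrom=call.chrom, pos=call.pos, ref_allele=call.ref_allele,
                alt_allele=call.alt_allele, cov_ref=depth - cov_alt,
                cov_alt=cov_alt, zygosity=call.zygosity, normalized=True,
                context=call.context, truth=True,
            )
        )

    # inject false calls per context at the profile's false-call fraction
    homos_by_base = {
        b: [t for t in reference.tracts if t.kind == ctx.HOMOPOLYMER and t.motif == b]
        for b in _BASES
    }
    strs = [t for t in reference.tracts if t.kind == ctx.STR_KIND]
    blocked = _BlockedPositions(reference.tracts, pad=8)
    used = {c.pos for c in emitted} | {c.pos for c in truth.calls}
    n_false = 0
    by_context: dict[str, int] = {}
    for c in emitted:
        by_context[c.context] = by_context.get(c.context, 0) + 1
    for label, f in sorted(profile.fdr_by_context.items()):
        if f <= 0:
            continue
        n_true_label = by_context.get(label, 0)
        k = int(round(f / (1 - f) * n_true_label)) if f < 1 else n_true_label
        for _ in range(k):
            call = _make_false_call(rng, reference, label, homos_by_base, strs,
                                    blocked, used)
            if call is None:
                continue
            depth = int(draw_depth(rng, profile.mean_depth * 0.3,
                                    max(profile.cv_target, 0.3), 1)[0])
            depth = max(depth, 2)
            cov_alt = max(1, int(rng.binomial(depth, 0.12)))
            call.cov_ref = depth - cov_alt
            call.cov_alt = cov_alt
            depth_map[call.position_key] = depth
            used.add(call.pos)
            emitted.append(call)
            n_false += 1

    cs = CallSet(label=profile.label, calls=emitted)
    return SimulatedCallSet(
        callset=cs, depth=depth_map, profile=profile,
        n_true=sum(1 for c in cs.calls if c.truth),
        n_false=sum(1 for c in cs.calls if c.truth is False),
        n_dropped_dropout=n_dropout, n_dropped_large=n_large_lost,
    )


def _make_false_call(rng, reference: SyntheticReference, label: str,
                     homos_by_base, strs, blocked, used: set[int]) -> IndelCall | None:
    """A 1-2 bp spurious call placed in a region matching ``label``."""
    size = int(rng.integers(1, 3))
    for _ in range(50):
        if label.startswith("poly-"):
            tracts = homos_by_base[label[-1]]
            if not tracts:
                return None
            t = tracts[int(rng.integers(len(tracts)))]
            offset = int(rng.integers(0, max(1, t.span - size)))
            start0 = t.start + offset
            is_del = bool(rng.random() < 0.5)
            ins_seq = t.motif * size
        elif label == ctx.OTHER_STR:
            if not strs:
                return None
            t = strs[int(rng.integers(len(strs)))]
            m = len(t.motif)
            start0 = t.start
            is_del = bool(rng.random() < 0.5)
            size = m
            ins_seq = t.motif
        else:
            start0 = _free_start(rng, len(reference.sequence), size, blocked, used)
            if start0 is None:
                return None
            is_del = bool(rng.random() < 0.5)
            ins_seq = _nonrepetitive_insert(rng, size, reference.sequence[start0 - 1])
        anchor0 = start0 - 1
        if anchor0 < 1 or start0 + size >= len(reference.sequence):
            continue
        if is_del:
            ref_allele = reference.sequence[anchor0:start0 + size]
            alt_allele = reference.sequence[anchor0]
        else:
            ref_allele = reference.sequence[anchor0]
            alt_allele = ref_allele + ins_seq
        try:
            call = IndelCall(chrom=reference.chrom, pos=anchor0 + 1,
                             ref_allele=ref_allele, alt_allele=alt_allele,
                             truth=False)
            call = left_normalize(call, reference)
        except ValueError:
            continue
        if call.pos in used:
            continue
        ctx.annotate_context(call, reference)
        return call
    return None


def generate_quality_benchmark(
    n_high: int,
    n_low: int,
    error_high: float = 0.07,
    error_low: float = 0.51,
    seed: int | np.random.Generator = 0,
    chrom: str = "chrSim",
) -> CallSet:
    """Calls planted into the high/low quality classes with known error rates.

    Coverage pairs are rejection-sampled until they classify as requested
    (high calls spread over all three coverage tiers); each call's hidden
    ``truth`` label is Bernoulli(1 - error rate) for its class, so empirical
    per-class PPV recovers 100*(1-error) up to binomial noise.
    """
    from .quality import DEFAULT_THRESHOLDS, chi_square_score, classify

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calls: list[IndelCall] = []
    pos = 1

    def _sample(target: str, err: float) -> IndelCall:
        nonlocal pos
        while True:
            if target == "high":
                tier = int(rng.integers(3))
                if tier == 0:
                    cov_alt = int(rng.integers(11, 41))
                    cov_ref = max(0, cov_alt + int(rng.integers(-6, 7)))
                elif tier == 1:
                    cov_alt = int(rng.integers(6, 11))
                    cov_ref = max(0, cov_alt + int(rng.integers(-4, 5)))
                else:
                    cov_alt = int(rng.integers(1, 6))
                    cov_ref = max(0, cov_alt + int(rng.integers(-2, 3)))
            else:
                cov_alt = int(rng.integers(1, 11))
                cov_ref = cov_alt + int(rng.integers(15, 80))
            chi2 = chi_square_score(cov_ref, cov_alt)
            if classify(cov_alt, chi2, DEFAULT_THRESHOLDS) == target:
                break
        call = IndelCall(chrom=chrom, pos=pos * 10 + 1, ref_allele="A",
                         alt_allele="AT", cov_ref=cov_ref, cov_alt=cov_alt,
                         normalized=True, truth=bool(rng.random() >= err))
        pos += 1
        return call

    for _ in range(n_high):
        calls.append(_sample("high", error_high))
    for _ in range(n_low):
        calls.append(_sample("low", error_low))
    return CallSet(label="quality-benchmark", calls=calls)
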