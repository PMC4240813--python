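"""Homopolymer / STR tract detection and sequence-context labels for INDELs.

Every call receives exactly one of six labels: poly-A, poly-C, poly-G,
poly-T (homopolymer runs of length >= 5 on the reference strand), other-STR
(perfect tandem repeats of a 2-6 bp motif), or non-STR.  Homopolymer and STR
errors dominate INDEL false calls — poly-A/T tracts especially — so these
labels drive most of the downstream error profiling.

The built-in detectors scan the reference directly with declared defaults
(motif 2-6 bp, >= 3 copies, tract span >= 8 bp); they are a self-contained
approximation of external STR reference catalogs, not a reproduction of any
particular one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .variants import CallSet, IndelCall, RegionSet

POLY_A, POLY_C, POLY_G, POLY_T = "poly-A", "poly-C", "poly-G", "poly-T"
OTHER_STR = "other-STR"
NON_STR = "non-STR"
CONTEXT_LABELS = (POLY_A, POLY_C, POLY_G, POLY_T, OTHER_STR, NON_STR)

HOMOPOLYMER = "homopolymer"
STR_KIND = "other-STR"

DEFAULT_HOMOPOLYMER_MIN_LEN = 5
DEFAULT_STR_MIN_COPIES = 3
DEFAULT_STR_MIN_SPAN = 8
DEFAULT_ADJACENCY_GAP = 1
DEFAULT_WINDOW = 50


@dataclass(frozen=True)
class RepeatTract:
    """A maximal perfect repeat tract, half-open 0-based on the reference."""

    chrom: str
    start: int
    end: int
    motif: str
    kind: str  # HOMOPOLYMER or STR_KIND

    def __post_init__(self) -> None:
        if self.end - self.start < len(self.motif):
            raise ValueError("tract shorter than its motif")

    @property
    def copies(self) -> float:
        return (self.end - self.start) / len(self.motif)

    @property
    def span(self) -> int:
        return self.end - self.start


def find_homopolymers(
    seq: str,
    min_len: int = DEFAULT_HOMOPOLYMER_MIN_LEN,
    chrom: str = "",
    offset: int = 0,
) -> list[RepeatTract]:
    """Maximal single-base runs of length >= ``min_len`` (N runs excluded).

    ``offset`` shifts reported coordinates, so windows of a chromosome can be
    scanned in place.
    """
    seq = seq.upper()
    tracts = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] in "ACGT":
            tracts.append(
                RepeatTract(chrom=chrom, start=offset + i, end=offset + j,
                            motif=seq[i], kind=HOMOPOLYMER)
            )
        i = j
    return tracts


def _primitive(motif: str) -> bool:
    """True unless the motif is itself a repeat of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def find_strs(
    seq: str,
    motif_len_range: tuple[int, int] = (2, 6),
    min_copies: float = DEFAULT_STR_MIN_COPIES,
    min_span: int = DEFAULT_STR_MIN_SPAN,
    chrom: str = "",
    offset: int = 0,
) -> list[RepeatTract]:
    """Maximal perfect tandem tracts with primitive 2-6 bp motifs.

    A tract qualifies with >= ``min_copies`` copies (fractional trailing
    copies count) and a span of >= ``min_span`` bases.  Tracts are maximal:
    not extendable by one base in either direction at their period.
    """
    seq = seq.upper()
    n = len(seq)
    tracts = []
    lo, hi = motif_len_range
    for m in range(lo, hi + 1):
        i = 0
        while i + m <= n:
            # skip positions inside a run: left-extendable at period m
            if i > 0 and seq[i - 1] == seq[i + m - 1]:
                i += 1
                continue
            j = i + m
            while j < n and seq[j] == seq[j - m]:
                j += 1
            span = j - i
            motif = seq[i:i + m]
            if (
                span >= max(min_span, 2 * m)
                and span / m >= min_copies
                and _primitive(motif)
                and set(motif) <= set("ACGT")
            ):
                tracts.append(
                    RepeatTract(chrom=chrom, start=offset + i, end=offset + j,
                                motif=motif, kind=STR_KIND)
                )
            i += 1
    # homopolymer precedence: suppress STR tracts lying inside a long
    # single-base run (cannot arise with primitive motifs, kept as a guard)
    homos = find_homopolymers(seq, chrom=chrom, offset=offset)
    spans = [(h.start, h.end) for h in homos]
    tracts = [
        t for t in tracts
        if not any(s <= t.start and t.end <= e for s, e in spans)
    ]
    return sorted(set(tracts), key=lambda t: (t.start, t.end, t.motif))


def _intersects_or_abuts(
    iv_start: int, iv_end: int, tract: RepeatTract, gap: int
) -> bool:
    """Variant interval and tract intersect or lie within ``gap`` bases.

    Zero-length insertion intervals are treated as the point between two
    bases, so an insertion extending a tract (interval boundary touching the
    tract) counts as adjacent.
    """
    return iv_start <= tract.end + gap and tract.start <= iv_end + gap


def annotate_context(
    call: IndelCall,
    reference,
    window: int = DEFAULT_WINDOW,
    hp_min_len: int = DEFAULT_HOMOPOLYMER_MIN_LEN,
    adjacency_gap: int = DEFAULT_ADJACENCY_GAP,
) -> str:
    """Assign one of the six context labels and record it on the call.

    The reference window of +-``window`` bp around the variant is scanned for
    tracts; the call is poly-N if its variant interval intersects or lies
    within ``adjacency_gap`` bases of a homopolymer of base N, else other-STR
    if it intersects/abuts an STR tract, else non-STR.  When several
    homopolymers qualify, the one with the largest overlap (ties: nearest,
    then leftmost) decides the base.  Contig edges truncate the window.
    """
    iv_start, iv_end = call.variant_interval()
    win_start = max(0, iv_start - window)
    win_end = iv_end + window
    seq = reference.fetch(call.chrom, win_start, win_end).upper()

    homos = [
        t for t in find_homopolymers(seq, min_len=hp_min_len,
                                     chrom=call.chrom, offset=win_start)
        if _intersects_or_abuts(iv_start, iv_end, t, adjacency_gap)
    ]
    if homos:
        def _rank(t: RepeatTract) -> tuple:
            overlap = min(iv_end, t.end) - max(iv_start, t.start)
            dist = max(t.start - iv_end, iv_start - t.end, 0)
            return (-overlap, dist, t.start)

        best = min(homos, key=_rank)
        label = f"poly-{best.motif}"
    else:
        strs = [
            t for t in find_strs(seq, chrom=call.chrom, offset=win_start)
            if _intersects_or_abuts(iv_start, iv_end, t, adjacency_gap)
        ]
        label = OTHER_STR if strs else NON_STR
    call.context = label
    return label


def annotate_callset(cs: CallSet, reference, **kwargs) -> CallSet:
    for call in cs.calls:
        annotate_context(call, reference, **kwargs)
    return cs


def expand_regions(exons: RegionSet, pad: int = 20) -> RegionSet:
    """Pad each interval by ``pad`` bp on both sides and merge.

    With the default 20 bp this builds the 'exonic targeted regions' that
    extend capture-design exons over their splice sites.
    """
    return exons.pad(pad)


def flank_regions(calls: CallSet, pad: int = 25) -> RegionSet:
    """Merged +-``pad`` bp windows around each call's anchored position."""
    return RegionSet(
        (c.chrom, max(0, (c.pos - 1) - pad), (c.pos - 1) + pad + 1) for c in calls
    )


def context_composition(
    cs: CallSet, stratum: str | None = None
) -> dict[str, dict[str, float | int]]:
    """Counts/proportions over the six context labels, plus the poly-A/T aggregate.

    ``stratum`` restricts to calls of one quality class ("high"/"moderate"/
    "low"); ``None`` uses every call.  All calls considered must be annotated.
    """
    calls = [c for c in cs.calls if stratum is None or c.quality_class == stratum]
    if any(c.context not in CONTEXT_LABELS for c in calls):
        raise ValueError("unannotated calls present; run annotate_callset first")
    n = len(calls)
    out: dict[str, dict[str, float | int]] = {}
    for label in CONTEXT_LABELS:
        k = sum(1 for c in calls if c.context == label)
        out[label] = {"count": k, "proportion": k / n if n else 0.0}
    at = out[POLY_A]["count"] + out[POLY_T]["count"]
    out["poly-A/T"] = {"count": at, "proportion": at / n if n else 0.0}
    return out


def tracts_to_regionset(tracts: list[RepeatTract]) -> RegionSet:
    return RegionSet((t.chrom, t.start, t.end) for t in tracts)
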