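"""Exact-match / position-match concordance between two INDEL call sets.

Two normalized calls position-match when they share chromosome and anchored
position; they exact-match when additionally both allele strings agree.  A
third predicate, validation-match, requires the position plus the same type
of variation (insertion vs deletion) — the rule used when scoring calls
against re-sequencing truth data.

Concordance between two call sets is reported as three rates over the union:
intersection, A-specific and B-specific, optionally after removing loci whose
per-locus depth falls below a floor in either data set.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

from .variants import CallSet, IndelCall

logger = logging.getLogger(__name__)

EXACT = "exact"
POSITION = "position"
VALIDATION = "validation"

DEFAULT_DEPTH_FLOORS = (0, 1, 20, 40, 60, 80)

DepthMap = dict[tuple[str, int], int]


def _require_normalized(*calls: IndelCall) -> None:
    for c in calls:
        if not c.normalized:
            raise ValueError(
                f"call {c.chrom}:{c.pos} is not left-normalized; "
                "matching un-normalized calls is unsafe"
            )


def match_position(a: IndelCall, b: IndelCall) -> bool:
    """Same chromosome and normalized anchor position."""
    _require_normalized(a, b)
    return a.position_key == b.position_key


def match_exact(a: IndelCall, b: IndelCall) -> bool:
    """Position match plus identical reference and alternate alleles."""
    _require_normalized(a, b)
    return a.key == b.key


def match_validation(a: IndelCall, b: IndelCall) -> bool:
    """Position match plus the same type of variation (insertion/deletion)."""
    _require_normalized(a, b)
    return a.position_key == b.position_key and a.itype == b.itype


@dataclass(frozen=True)
class ConcordanceResult:
    """Counts and union-denominated rates for one pair of call sets."""

    n_intersection: int
    n_a_specific: int
    n_b_specific: int
    rate_concordant: float
    rate_a_specific: float
    rate_b_specific: float
    mode: str
    depth_floor: int = 0

    @property
    def n_union(self) -> int:
        return self.n_intersection + self.n_a_specific + self.n_b_specific


def _depth_at(depth: DepthMap | None, locus: tuple[str, int], floor: int) -> int:
    if depth is None:
        return 0
    d = depth.get(locus)
    if d is None:
        if floor > 0:
            logger.debug("locus %s missing from depth map; treated as depth 0", locus)
        return 0
    return d


def _filter_by_depth(
    cs: CallSet, depth_a: DepthMap | None, depth_b: DepthMap | None, floor: int
) -> list[IndelCall]:
    if floor <= 0:
        return list(cs.calls)
    kept = []
    for c in cs.calls:
        if (
            _depth_at(depth_a, c.position_key, floor) >= floor
            and _depth_at(depth_b, c.position_key, floor) >= floor
        ):
            kept.append(c)
    return kept


def compare_callsets(
    a: CallSet,
    b: CallSet,
    mode: str = EXACT,
    depth_a: DepthMap | None = None,
    depth_b: DepthMap | None = None,
    depth_floor: int = 0,
) -> ConcordanceResult:
    """Set-compare two normalized call sets under exact or position matching.

    Loci whose depth is below ``depth_floor`` in *either* data set drop from
    both sides before the set algebra.  Rates are percentages of the union,
    rounded to one decimal; in position mode a locus carrying multiple
    signatures counts once toward the intersection and its surplus signatures
    count as set-specific, keeping the three counts a partition of the union.
    """
    _require_normalized(*a.calls, *b.calls)
    if depth_floor > 0 and (depth_a is None or depth_b is None):
        raise ValueError("depth maps are required when depth_floor > 0")
    calls_a = _filter_by_depth(a, depth_a, depth_b, depth_floor)
    calls_b = _filter_by_depth(b, depth_a, depth_b, depth_floor)

    if mode == EXACT:
        keys_a = {c.key for c in calls_a}
        keys_b = {c.key for c in calls_b}
        n_int = len(keys_a & keys_b)
        n_a = len(keys_a - keys_b)
        n_b = len(keys_b - keys_a)
    elif mode == POSITION:
        by_pos_a: dict[tuple, set] = defaultdict(set)
        by_pos_b: dict[tuple, set] = defaultdict(set)
        for c in calls_a:
            by_pos_a[c.position_key].add(c.key)
        for c in calls_b:
            by_pos_b[c.position_key].add(c.key)
        n_int = n_a = n_b = 0
        for pos in set(by_pos_a) | set(by_pos_b):
            ka, kb = len(by_pos_a.get(pos, ())), len(by_pos_b.get(pos, ()))
            if ka and kb:
                n_int += 1
                n_a += ka - 1
                n_b += kb - 1
            elif ka:
                n_a += ka
            else:
                n_b += kb
    else:
        raise ValueError(f"unknown match mode {mode!r}")

    union = n_int + n_a + n_b
    if union == 0:
        rates = (0.0, 0.0, 0.0)
    else:
        rates = tuple(round(100.0 * n / union, 1) for n in (n_int, n_a, n_b))
    return ConcordanceResult(
        n_intersection=n_int,
        n_a_specific=n_a,
        n_b_specific=n_b,
        rate_concordant=rates[0],
        rate_a_specific=rates[1],
        rate_b_specific=rates[2],
        mode=mode,
        depth_floor=depth_floor,
    )


def mean_concordance(
    results: list[ConcordanceResult],
) -> dict[str, tuple[float, float | None]]:
    """Unweighted per-sample mean and sample SD of each concordance rate.

    With a single sample the mean is defined and the SD is ``None``.
    """
    if not results:
        raise ValueError("no per-sample results given")
    out: dict[str, tuple[float, float | None]] = {}
    for attr in ("rate_concordant", "rate_a_specific", "rate_b_specific"):
        vals = [getattr(r, attr) for r in results]
        mean = sum(vals) / len(vals)
        if len(vals) < 2:
            sd: float | None = None
        else:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        out[attr] = (round(mean, 1), None if sd is None else round(sd, 2))
    return out


@dataclass(frozen=True)
class SignatureLocus:
    """A genomic position carrying two or more distinct INDEL signatures.

    At most one signature can be the true variant, so the surplus ones are
    presumptive false-positive calls.
    """

    chrom: str
    pos: int
    signatures: tuple[tuple[str, str], ...]
    contexts: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.signatures)) < 2:
            raise ValueError("a signature locus needs >= 2 distinct signatures")


def multiple_signatures(union: CallSet) -> list[SignatureLocus]:
    """Positions in a (union) call set where more than one INDEL was called."""
    _require_normalized(*union.calls)
    by_pos: dict[tuple[str, int], list[IndelCall]] = defaultdict(list)
    for c in union.calls:
        by_pos[c.position_key].append(c)
    loci = []
    for (chrom, pos), calls in sorted(by_pos.items()):
        sigs = sorted({(c.ref_allele, c.alt_allele) for c in calls})
        if len(sigs) >= 2:
            ctx_by_sig = {(c.ref_allele, c.alt_allele): c.context for c in calls}
            loci.append(
                SignatureLocus(
                    chrom=chrom,
                    pos=pos,
                    signatures=tuple(sigs),
                    contexts=tuple(ctx_by_sig[s] for s in sigs),
                )
            )
    return loci


def union_callset(a: CallSet, b: CallSet, label: str = "union") -> CallSet:
    """Deduplicated union of two call sets (exact-key dedup)."""
    return CallSet(label=label, calls=list(a.calls) + list(b.calls))
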