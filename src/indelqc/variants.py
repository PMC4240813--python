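"""Core INDEL data model, left-normalization, and VCF/BED/FASTA I/O.

Coordinates follow the two standards they touch: :class:`IndelCall` stores the
1-based anchored VCF position, :class:`RegionSet` stores half-open 0-based BED
intervals.  Conversion between the two happens only inside this module.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

INSERTION = "insertion"
DELETION = "deletion"

HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"
UNKNOWN = "unknown"

_BASES = frozenset("ACGT")


class ReferenceMismatchError(ValueError):
    """The call's reference allele does not match the reference sequence."""


@dataclass
class DictReference:
    """In-memory reference: maps chromosome name to an uppercase sequence.

    Exposes the same ``fetch(chrom, start, end)`` (0-based, half-open)
    interface as :class:`pysam.FastaFile`, so normalization and context
    annotation work identically on files and synthetic sequences.
    """

    sequences: Mapping[str, str]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        return seq[max(start, 0):max(end, 0)]

    def get_reference_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def references(self) -> list[str]:
        return list(self.sequences)


@dataclass
class IndelCall:
    """A single biallelic insertion or deletion in anchored VCF representation.

    ``pos`` is the 1-based position of the anchor base; ``ref_allele`` and
    ``alt_allele`` both start with the anchor base after normalization (unless
    the variant abuts the start of the contig).  ``cov_ref``/``cov_alt`` hold
    the observed per-allele (k-mer) coverages C_o^Ref and C_o^Alt.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    cov_ref: int = 0
    cov_alt: int = 0
    zygosity: str = UNKNOWN
    chi2: float | None = None
    quality_class: str = "unset"
    context: str = "unset"
    normalized: bool = False
    truth: bool | None = None  # hidden label used by the synthetic generator

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if len(self.ref_allele) == len(self.alt_allele):
            raise ValueError(
                f"not an INDEL at {self.chrom}:{self.pos} "
                f"({self.ref_allele}>{self.alt_allele}): alleles have equal length"
            )
        for allele in (self.ref_allele, self.alt_allele):
            if allele and not set(allele) <= _BASES:
                raise ValueError(f"non-ACGT allele {allele!r} at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if self.cov_ref < 0 or self.cov_alt < 0:
            raise ValueError("allele coverages must be non-negative")
        if int(self.cov_ref) != self.cov_ref or int(self.cov_alt) != self.cov_alt:
            raise ValueError("allele coverages must be integers")

    @property
    def size(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def itype(self) -> str:
        return INSERTION if len(self.alt_allele) > len(self.ref_allele) else DELETION

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def position_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def variant_interval(self) -> tuple[int, int]:
        """Half-open 0-based interval of the altered bases.

        Deletions span the deleted reference bases; insertions are the
        zero-length point between the anchor base and the next one.
        """
        if self.itype == DELETION:
            return (self.pos, self.pos + self.size)
        return (self.pos, self.pos)


def indel_size(call: IndelCall) -> int:
    """Absolute length difference between reference and alternate alleles."""
    return call.size


def is_large(call: IndelCall) -> bool:
    """Large INDEL: size strictly greater than 5 bp."""
    return call.size > 5


class RegionSet:
    """Sorted, self-merged set of half-open 0-based genomic intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._intervals: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._intervals[chrom] = merged

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._intervals):
            for s, e in self._intervals[chrom]:
                yield (chrom, s, e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._intervals.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._intervals == other._intervals

    def total_bases(self) -> int:
        return sum(e - s for ivs in self._intervals.values() for s, e in ivs)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        ivs = self._intervals.get(chrom)
        if not ivs:
            return False
        i = bisect.bisect_right(ivs, (pos0, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos0 < ivs[i][1]

    def contains_call(self, call: IndelCall) -> bool:
        """Membership of a call by its anchored 1-based position."""
        return self.contains(call.chrom, call.pos - 1)

    def pad(self, pad: int) -> "RegionSet":
        """Expand every interval by ``pad`` bases on both sides, then merge."""
        return RegionSet(
            (chrom, max(0, s - pad), e + pad) for chrom, s, e in self
        )

    @classmethod
    def from_bed(cls, path: str) -> "RegionSet":
        intervals = []
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{line_no}: BED line has <3 columns")
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(intervals)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self:
                fh.write(f"{chrom}\t{s}\t{e}\n")


@dataclass
class CallSet:
    """A named, deduplicated collection of :class:`IndelCall`.

    Duplicates on (chrom, pos, ref, alt) collapse keeping the record with the
    highest alternate-allele coverage.  When ``target_regions`` is set the
    calls are guaranteed to lie inside it.
    """

    label: str = ""
    sample_id: str = ""
    calls: list[IndelCall] = field(default_factory=list)
    target_regions: RegionSet | None = None

    def __post_init__(self) -> None:
        seen: dict[tuple, IndelCall] = {}
        for call in self.calls:
            prev = seen.get(call.key)
            if prev is None or call.cov_alt > prev.cov_alt:
                seen[call.key] = call
        if len(seen) != len(self.calls):
            logger.info(
                "%s: collapsed %d duplicate records", self.label, len(self.calls) - len(seen)
            )
        self.calls = sorted(seen.values(), key=lambda c: c.key)
        if self.target_regions is not None:
            outside = [c for c in self.calls if not self.target_regions.contains_call(c)]
            if outside:
                raise ValueError(
                    f"{len(outside)} calls lie outside the attached target regions"
                )

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[IndelCall]:
        return iter(self.calls)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {c.key for c in self.calls}

    def position_keys(self) -> set[tuple[str, int]]:
        return {c.position_key for c in self.calls}


def restrict_to_regions(cs: CallSet, regions: RegionSet) -> CallSet:
    """Keep calls whose anchored position falls inside ``regions``."""
    kept = [c for c in cs.calls if regions.contains_call(c)]
    removed = len(cs.calls) - len(kept)
    if removed:
        logger.info("%s: removed %d calls outside target regions", cs.label, removed)
    return CallSet(label=cs.label, sample_id=cs.sample_id, calls=kept, target_regions=regions)


def left_normalize(call: IndelCall, reference) -> IndelCall:
    """Return the maximally left-shifted, minimally trimmed representation.

    Implements the standard left-align-and-trim procedure: shared trailing
    bases are removed (extending leftward from the reference whenever an
    allele empties), then shared leading bases are removed down to a single
    anchor base.  The returned edit reconstructs the same alternate haplotype
    as the input edit.  Idempotent.
    """
    pos, ref, alt = call.pos, call.ref_allele, call.alt_allele
    observed = reference.fetch(call.chrom, pos - 1, pos - 1 + len(ref)).upper()
    if observed != ref:
        raise ReferenceMismatchError(
            f"{call.chrom}:{pos} ref allele {ref!r} != reference {observed!r}"
        )

    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if not ref or not alt:
            if pos == 1:
                # Variant abuts the contig start: VCF anchors on the base
                # *after* the event instead.
                anchor = reference.fetch(call.chrom, len(ref), len(ref) + 1).upper()
                ref, alt = ref + anchor, alt + anchor
                break
            left = reference.fetch(call.chrom, pos - 2, pos - 1).upper()
            ref, alt = left + ref, left + alt
            pos -= 1
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    return replace(call, pos=pos, ref_allele=ref, alt_allele=alt, normalized=True)


def normalize_callset(cs: CallSet, reference) -> CallSet:
    """Left-normalize every call; duplicates arising from normalization collapse."""
    return CallSet(
        label=cs.label,
        sample_id=cs.sample_id,
        calls=[left_normalize(c, reference) for c in cs.calls],
        target_regions=cs.target_regions,
    )


def apply_edit(window: str, window_start0: int, call: IndelCall) -> str:
    """Apply a call's edit to a reference window (0-based ``window_start0``).

    Test oracle for normalization equivalence: two representations of the
    same variant produce identical alternate haplotypes.
    """
    off = call.pos - 1 - window_start0
    if off < 0 or off + len(call.ref_allele) > len(window):
        raise ValueError("call does not fit inside the window")
    if window[off:off + len(call.ref_allele)] != call.ref_allele:
        raise ReferenceMismatchError("window does not match the ref allele")
    return window[:off] + call.alt_allele + window[off + len(call.ref_allele):]


# --- VCF I/O -----------------------------------------------------------------

DEFAULT_COV_REF_KEY = "COVREF"
DEFAULT_COV_ALT_KEY = "COVALT"

_ZYG_MAP = {
    "het": HETEROZYGOUS,
    "heterozygous": HETEROZYGOUS,
    "hom": HOMOZYGOUS,
    "homozygous": HOMOZYGOUS,
}


def _zygosity_from_record(rec, key: str | None) -> str:
    if key is None:
        return UNKNOWN
    try:  # pysam raises on keys absent from the header
        val = rec.info.get(key)
    except (KeyError, ValueError):
        return UNKNOWN
    if val is None:
        return UNKNOWN
    if isinstance(val, tuple):
        val = val[0]
    return _ZYG_MAP.get(str(val).lower(), UNKNOWN)


def read_vcf(
    path: str,
    cov_ref_key: str = DEFAULT_COV_REF_KEY,
    cov_alt_key: str = DEFAULT_COV_ALT_KEY,
    zygosity_key: str | None = "ZYG",
    label: str = "",
    sample_id: str = "",
) -> CallSet:
    """Read a VCF into a :class:`CallSet` of raw (un-normalized) INDELs.

    Multi-allelic records split into one biallelic record per alternate;
    records where reference and alternate have equal length (SNP/MNP) drop
    with a logged count.  Per-allele coverages come from the configured INFO
    keys (Scalpel-style defaults ``COVREF``/``COVALT``); per-alternate tuple
    values index by allele.  Missing coverage keys warn once and leave the
    coverages at 0.
    """
    calls: list[IndelCall] = []
    n_dropped = n_missing_cov = 0
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for i, alt in enumerate(rec.alts):
                if alt is None or set(alt.upper()) - _BASES:
                    n_dropped += 1  # symbolic / non-sequence alternate
                    continue
                if len(rec.ref) == len(alt):
                    n_dropped += 1
                    continue

                def _cov(key: str) -> tuple[int, bool]:
                    try:  # pysam raises on keys absent from the header
                        val = rec.info.get(key)
                    except (KeyError, ValueError):
                        return 0, True
                    if val is None:
                        return 0, True
                    if isinstance(val, tuple):
                        val = val[i] if i < len(val) else val[0]
                    return int(round(float(val))), False

                cov_ref, miss_r = _cov(cov_ref_key)
                cov_alt, miss_a = _cov(cov_alt_key)
                if miss_r or miss_a:
                    n_missing_cov += 1
                calls.append(
                    IndelCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        cov_ref=cov_ref,
                        cov_alt=cov_alt,
                        zygosity=_zygosity_from_record(rec, zygosity_key),
                    )
                )
    if n_dropped:
        logger.info("%s: dropped %d non-INDEL or symbolic records", path, n_dropped)
    if n_missing_cov:
        logger.warning(
            "%s: %d records lacked coverage keys (%s/%s); coverages set to 0",
            path, n_missing_cov, cov_ref_key, cov_alt_key,
        )
    return CallSet(label=label or path, sample_id=sample_id, calls=calls)


def write_vcf(
    cs: CallSet,
    path: str,
    contig_lengths: Mapping[str, int] | None = None,
    cov_ref_key: str = DEFAULT_COV_REF_KEY,
    cov_alt_key: str = DEFAULT_COV_ALT_KEY,
) -> None:
    """Write a call set as VCF 4.2 with coverages, score, class and context in INFO."""
    header = pysam.VariantHeader()
    chroms: dict[str, int] = {}
    for c in cs.calls:
        need = c.pos + len(c.ref_allele) + 1
        chroms[c.chrom] = max(chroms.get(c.chrom, 0), need)
    if contig_lengths:
        chroms.update(contig_lengths)
    for chrom in sorted(chroms):
        header.contigs.add(chrom, length=chroms[chrom])
    header.info.add(cov_ref_key, 1, "Integer", "Reference-allele k-mer coverage")
    header.info.add(cov_alt_key, 1, "Integer", "Alternate-allele k-mer coverage")
    header.info.add("CHI2", 1, "Float", "K-mer coverage Chi-Square score")
    header.info.add("QCLASS", 1, "String", "Quality class (high/moderate/low)")
    header.info.add("CONTEXT", 1, "String", "Sequence context label")
    header.info.add("ZYG", 1, "String", "Zygosity")
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in cs.calls:
            rec = out.new_record(
                contig=c.chrom, start=c.pos - 1, alleles=(c.ref_allele, c.alt_allele)
            )
            rec.info[cov_ref_key] = c.cov_ref
            rec.info[cov_alt_key] = c.cov_alt
            if c.chi2 is not None:
                rec.info["CHI2"] = float(c.chi2)
            if c.quality_class != "unset":
                rec.info["QCLASS"] = c.quality_class
            if c.context != "unset":
                rec.info["CONTEXT"] = c.context
            if c.zygosity != UNKNOWN:
                rec.info["ZYG"] = c.zygosity
            out.write(rec)


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    """Write sequences as an (unindexed) FASTA file."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
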