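"""Shared fixtures: deterministic synthetic references and VCF builders."""

from __future__ import annotations

import numpy as np
import pytest

from indelqc import simdata


@pytest.fixture(scope="session")
def small_reference():
    """A 30 kb reference with a planted mix of homopolymer and STR tracts."""
    spec = [
        ("A", 8, 20), ("T", 8, 20), ("C", 6, 6), ("G", 6, 6),
        ("CA", 10, 10), ("AAG", 9, 6), ("AT", 12, 4),
    ]
    return simdata.generate_reference(30_000, spec, seed=101)


@pytest.fixture(scope="session")
def small_truth(small_reference):
    return simdata.generate_truth_indels(small_reference, n=150, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def write_vcf_text(path, records, info_fields=("COVREF", "COVALT")):
    """Write a minimal VCF 4.2 by hand (independent of the package's writer)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=1000000>",
        "##contig=<ID=chr2,length=1000000>",
        '##INFO=<ID=COVREF,Number=1,Type=Integer,Description="ref cov">',
        '##INFO=<ID=COVALT,Number=1,Type=Integer,Description="alt cov">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for chrom, pos, ref, alt, info in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}")
    path.write_text("\n".join(lines) + "\n")
    return str(path)
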