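from __future__ import annotations

import random
import sys
from pathlib import Path

import pysam
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from pseudopipe.mod_format import ModFile, ModInstruction
from pseudopipe.pseudogenome import build_pseudogenome


def random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def fig1_source() -> str:
    # 24-base toy source carrying the worked variant set: SNPs at 2 and 19,
    # a 3-base deletion at 8-10, an insertion after 17
    rng = random.Random(42)
    return random_sequence(rng, 24)


@pytest.fixture
def fig1_mod(fig1_source) -> ModFile:
    src = fig1_source
    insts = [
        ModInstruction("s", "chr1", 2, (src[2], "A" if src[2] != "A" else "C")),
        ModInstruction("s", "chr1", 19, (src[19], "A" if src[19] != "A" else "C")),
        ModInstruction("d", "chr1", 8, src[8]),
        ModInstruction("d", "chr1", 9, src[9]),
        ModInstruction("d", "chr1", 10, src[10]),
        ModInstruction("i", "chr1", 17, "GGT"),
    ]
    return ModFile(
        header={"version": "1.0", "source": "ref", "destination": "founderA"},
        instructions=insts,
    )


@pytest.fixture
def fig1_build(fig1_source, fig1_mod):
    return build_pseudogenome({"chr1": fig1_source}, fig1_mod)


def make_remapped_record(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    pos: int,
    cigar: str,
    oc: str,
    om: int,
    seq_len: int | None = None,
    flag: int = 0,
    next_ref: tuple[str, int] | None = None,
) -> pysam.AlignedSegment:
    """A reference-space record carrying the preservation tags merge needs."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = flag
    rec.reference_name = chrom
    rec.reference_start = pos
    rec.mapping_quality = 60
    rec.cigarstring = cigar
    length = seq_len or sum(
        int(n) for n, op in _cigar_items(cigar) if op in "MIS=X"
    )
    rec.query_sequence = "A" * length
    rec.query_qualities = pysam.qualitystring_to_array("I" * length)
    rec.set_tag("NM", om, "i")
    rec.set_tag("oc", oc, "Z")
    rec.set_tag("om", om, "i")
    rec.set_tag("op", pos, "i")
    if next_ref:
        rec.next_reference_name = next_ref[0]
        rec.next_reference_start = next_ref[1]
    return rec


def _cigar_items(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


def simple_header(chrom_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "queryname"},
            "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()],
        }
    )


def write_sam(path, header: pysam.AlignmentHeader, records) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)
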