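"""Liftover of pseudogenome alignments back to reference coordinates.

Each record aligned to a founder pseudogenome is translated to the reference
coordinate system by walking its CIGAR footprint left-to-right through the
:class:`~pseudopipe.pseudogenome.RegionMap`:

* pseudogenome bases inside correspondence blocks keep their op (M/D/N);
* destination-only (inserted) bases under an M op become I — the read carries
  sequence the reference lacks; under D/N they vanish;
* source-only (deleted) bases crossed by the footprint are spliced in as D
  (or N when crossed inside an intron gap), because the reference carries
  bases the pseudogenome lacks.

The rewritten record keeps the original pseudogenome mapping as tags — CIGAR
(``oc``), edit distance (``om``), 0-based start (``op``) and pseudogenome
index (``og``) — so the merge stage can regenerate the aligner's score
without re-reading any pseudogenome file, and recomputes NM against the
reference so the emitted record is internally coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pysam

from pseudopipe.pseudogenome import RegionMap

__all__ = [
    "RemapError",
    "UnmappableInInsertion",
    "RemapTags",
    "RemapStats",
    "rewrite_cigar",
    "recompute_edit_distance",
    "remap_alignment",
    "remap_file",
]

# pysam cigartuples op codes
_OP_CHARS = "MIDNSHP=X"
_REF_CONSUMING = frozenset("MDN=X")
_READ_CONSUMING = frozenset("MIS=X")


class RemapError(ValueError):
    pass


class UnmappableInInsertion(RemapError):
    """The alignment footprint lies entirely within inserted sequence."""


def _parse_cigar(cigar: str | Sequence[tuple[int, int]]) -> list[tuple[str, int]]:
    if isinstance(cigar, str):
        out: list[tuple[str, int]] = []
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
            else:
                if not num or ch not in _OP_CHARS:
                    raise RemapError(f"malformed CIGAR {cigar!r}")
                out.append((ch, int(num)))
                num = ""
        if num:
            raise RemapError(f"malformed CIGAR {cigar!r}")
        return out
    return [(_OP_CHARS[op], ln) for op, ln in cigar]


def _format_cigar(ops: list[tuple[str, int]]) -> str:
    return "".join(f"{ln}{op}" for op, ln in ops) or "*"


def _merge_adjacent(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, ln in ops:
        if ln == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def rewrite_cigar(
    cigar: str | Sequence[tuple[int, int]],
    start: int,
    rm: RegionMap,
    chrom: str,
) -> tuple[int, str]:
    """Rewrite a pseudogenome-space CIGAR into reference space.

    Parameters
    ----------
    cigar:
        CIGAR string (or pysam cigartuples) of the pseudogenome alignment.
    start:
        0-based alignment start in pseudogenome coordinates.
    rm:
        Region map whose *destination* is the pseudogenome the record was
        aligned to and whose *source* is the reference.
    chrom:
        Chromosome name (shared between the two genomes).

    Returns ``(new_start, new_cigar)`` with ``new_start`` the 0-based
    reference coordinate of the first reference-consuming base.  Raises
    :class:`UnmappableInInsertion` when the whole footprint lies inside
    inserted sequence and no reference base is touched.
    """
    if chrom not in rm.blocks:
        raise RemapError(f"chromosome {chrom!r} absent from region map")
    ops = _parse_cigar(cigar)
    blocks = rm.blocks[chrom]
    dst_len = rm.dst_lengths[chrom]
    span = sum(ln for op, ln in ops if op in "MDN=X")
    if start < 0 or start + span > dst_len:
        raise RemapError(
            f"alignment footprint [{start}, {start + span}) extends past "
            f"{chrom} pseudogenome end ({dst_len})"
        )

    out: list[tuple[str, int]] = []
    new_start: int | None = None
    last_src: int | None = None  # src coord just past the last emitted ref-consuming base
    cur = start  # dst cursor
    idx = rm.find_block(chrom, start, "dst")

    def emit_ref(op: str, src_pos: int, ln: int) -> None:
        nonlocal new_start, last_src
        if last_src is not None and src_pos > last_src:
            # source-only bases crossed between correspondence runs
            gap_op = "N" if op == "N" else "D"
            out.append((gap_op, src_pos - last_src))
        if new_start is None:
            new_start = src_pos
        out.append((op, ln))
        last_src = src_pos + ln

    for op, ln in ops:
        if op in "=X":
            op = "M"
        if op in "SHI":
            out.append((op, ln))
            continue
        if op == "P":
            continue
        if op not in "MDN":
            raise RemapError(f"unsupported CIGAR op {op!r}")
        remaining = ln
        while remaining > 0:
            # advance idx to the last block starting at/before cur
            while idx + 1 < len(blocks) and blocks[idx + 1].dst_start <= cur:
                idx += 1
            if idx >= 0 and cur < blocks[idx].dst_end:
                b = blocks[idx]
                take = min(b.dst_end - cur, remaining)
                if op == "M":
                    emit_ref("M", b.src_start + (cur - b.dst_start), take)
                else:
                    emit_ref(op, b.src_start + (cur - b.dst_start), take)
            else:
                # cur lies in a destination-only (inserted) run
                gap_end = blocks[idx + 1].dst_start if idx + 1 < len(blocks) else dst_len
                take = min(gap_end - cur, remaining)
                if take <= 0:  # footprint past last block
                    take = remaining
                if op == "M":
                    out.append(("I", take))
                # D/N over inserted bases: consumed in the pseudogenome,
                # nonexistent in the reference — emit nothing
            cur += take
            remaining -= take

    if new_start is None:
        raise UnmappableInInsertion(
            f"alignment at {chrom}:{start} lies entirely within inserted sequence"
        )

    out = _merge_adjacent(out)
    # strip leading/trailing D/N (can arise when the footprint edge abuts a gap)
    changed = True
    while changed and out:
        changed = False
        # locate first op after clips
        i = 0
        while i < len(out) and out[i][0] in "SH":
            i += 1
        if i < len(out) and out[i][0] in "DN":
            new_start += out[i][1]
            del out[i]
            changed = True
        j = len(out) - 1
        while j >= 0 and out[j][0] in "SH":
            j -= 1
        if j >= 0 and out[j][0] in "DN":
            del out[j]
            changed = True
        if not changed:
            # leading/trailing I becomes soft clip (read bases with no
            # reference counterpart at the alignment edge)
            if i < len(out) and out[i][0] == "I":
                out[i] = ("S", out[i][1])
                changed = True
            if j >= 0 and out[j][0] == "I":
                out[j] = ("S", out[j][1])
                changed = True
        out = _merge_adjacent(out)
    if not any(op in "M=X" for op, _ in out):
        raise UnmappableInInsertion(
            f"alignment at {chrom}:{start} has no aligned reference base after rewrite"
        )
    return new_start, _format_cigar(out)


def recompute_edit_distance(
    cigar: str | Sequence[tuple[int, int]],
    start: int,
    read_seq: str,
    reference: Mapping[str, str],
    chrom: str,
) -> int:
    """NM in reference space: mismatching M bases plus I and D lengths."""
    ops = _parse_cigar(cigar)
    ref = reference[chrom]
    nm = 0
    rpos = start
    qpos = 0
    for op, ln in ops:
        if op in "M=X":
            if rpos + ln > len(ref):
                raise RemapError(f"alignment runs past {chrom} end")
            for k in range(ln):
                if read_seq[qpos + k].upper() != ref[rpos + k].upper():
                    nm += 1
            rpos += ln
            qpos += ln
        elif op == "I":
            nm += ln
            qpos += ln
        elif op == "D":
            nm += ln
            rpos += ln
        elif op == "N":
            rpos += ln
        elif op == "S":
            qpos += ln
        # H/P consume nothing here
    return nm


@dataclass(frozen=True)
class RemapTags:
    """User-space SAM tag names preserving the pseudogenome mapping."""

    original_cigar: str = "oc"
    original_nm: str = "om"
    original_start: str = "op"
    genome_index: str = "og"


@dataclass
class RemapStats:
    remapped: int = 0
    unmapped_passthrough: int = 0
    dropped_in_insertion: int = 0


def remap_alignment(
    rec: pysam.AlignedSegment,
    rm: RegionMap,
    reference: Mapping[str, str],
    pseudo_index: int,
    header: pysam.AlignmentHeader,
    tags: RemapTags = RemapTags(),
    stats: RemapStats | None = None,
) -> pysam.AlignedSegment:
    """Translate one pseudogenome record to reference coordinates.

    Flags, sequence, qualities and MAPQ pass through unchanged; position,
    CIGAR and NM are rewritten; preservation tags are added.  Unmapped
    records pass through untouched.  A record aligned entirely within
    inserted sequence is returned unmapped with reason tag ``ur:Z:insertion``.
    """
    out = pysam.AlignedSegment(header)
    out.query_name = rec.query_name
    out.flag = rec.flag
    out.query_sequence = rec.query_sequence
    out.query_qualities = rec.query_qualities
    out.mapping_quality = rec.mapping_quality
    if rec.is_unmapped:
        if stats:
            stats.unmapped_passthrough += 1
        return out

    chrom = rec.reference_name
    old_cigar = rec.cigarstring
    old_start = rec.reference_start
    old_nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
    try:
        new_start, new_cigar = rewrite_cigar(rec.cigartuples, old_start, rm, chrom)
    except UnmappableInInsertion:
        out.is_unmapped = True
        out.set_tag("ur", "insertion", "Z")
        out.set_tag(tags.original_cigar, old_cigar, "Z")
        out.set_tag(tags.original_nm, int(old_nm), "i")
        out.set_tag(tags.original_start, int(old_start), "i")
        out.set_tag(tags.genome_index, pseudo_index, "i")
        if stats:
            stats.dropped_in_insertion += 1
        return out

    out.reference_name = chrom
    out.reference_start = new_start
    out.cigarstring = new_cigar
    nm = recompute_edit_distance(new_cigar, new_start, rec.query_sequence or "", reference, chrom)
    out.set_tag("NM", nm, "i")
    out.set_tag(tags.original_cigar, old_cigar, "Z")
    out.set_tag(tags.original_nm, int(old_nm), "i")
    out.set_tag(tags.original_start, int(old_start), "i")
    out.set_tag(tags.genome_index, pseudo_index, "i")

    if rec.is_paired and not rec.mate_is_unmapped and rec.next_reference_name:
        mchrom = rec.next_reference_name
        out.next_reference_name = mchrom
        if mchrom in rm.blocks:
            from pseudopipe.pseudogenome import GapReport, project_position

            proj = project_position(rm, mchrom, rec.next_reference_start, "dst2src")
            out.next_reference_start = (
                proj.right if isinstance(proj, GapReport) else proj
            )
        else:
            out.next_reference_start = rec.next_reference_start
        out.template_length = rec.template_length
    if stats:
        stats.remapped += 1
    return out


def remap_file(
    in_path: str,
    rm: RegionMap,
    reference: Mapping[str, str],
    out_path: str,
    pseudo_index: int = 0,
    tags: RemapTags = RemapTags(),
    provenance: str = "",
) -> RemapStats:
    """Remap a whole SAM/BAM file; output header carries the REFERENCE
    sequence dictionary so downstream merging is name-compatible."""
    stats = RemapStats()
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": chrom, "LN": len(seq)} for chrom, seq in reference.items()
            ],
            "PG": [
                {
                    "ID": "pseudopipe-remap",
                    "PN": "pseudopipe",
                    "CL": provenance or f"remap pseudo_index={pseudo_index}",
                }
            ],
        }
    )
    write_mode = "wb" if str(out_path).endswith(".bam") else "w"
    with pysam.AlignmentFile(in_path, check_sq=False) as src, pysam.AlignmentFile(
        out_path, write_mode, header=header
    ) as dst:
        for rec in src:
            dst.write(remap_alignment(rec, rm, reference, pseudo_index, header, tags, stats))
    return stats
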