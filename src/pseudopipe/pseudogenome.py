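"""Pseudogenome construction and the bidirectional region/offset index.

Executing a MOD file against the reference produces the founder pseudogenome
sequence.  Alongside the sequence we build a :class:`RegionMap`: for every
maximal run of 1:1 base correspondence between source (reference) and
destination (pseudogenome) we record the pair of start offsets and the run
length.  Substitutions preserve correspondence and do not break runs;
deletions and insertions do.  Position projection in either direction is then
a binary-search lookup, which is what makes indel-aware liftover of
alignments cheap.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import bisect
import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from pseudopipe.mod_format import ModFile, ModInstruction, ModValidationError

__all__ = [
    "Block",
    "GapReport",
    "RegionMap",
    "PseudogenomeBuild",
    "BuildIssues",
    "build_pseudogenome",
    "build_region_map",
    "project_position",
    "write_region_map",
    "read_region_map",
]


@dataclass(frozen=True)
class Block:
    """A maximal run of 1:1 base correspondence."""

    src_start: int
    dst_start: int
    length: int

    @property
    def src_end(self) -> int:
        return self.src_start + self.length

    @property
    def dst_end(self) -> int:
        return self.dst_start + self.length


@dataclass(frozen=True)
class GapReport:
    """Returned when a projected position falls between blocks.

    The position has no exact counterpart: going src→dst it lies on a deleted
    base, going dst→src it lies on an inserted base.  ``left`` and ``right``
    are the flanking counterpart coordinates in the *target* system: ``left``
    is the last target position before the gap (−1 if none) and ``right`` the
    first at/after it.
    """

    chrom: str
    pos: int
    left: int
    right: int


class RegionMap:
    """Per-chromosome sorted blocks of corresponding source/destination runs.

    Blocks are non-overlapping and strictly increasing in both coordinate
    systems, so the map is monotone and invertible outside gaps.
    """

    def __init__(
        self,
        blocks: Mapping[str, list[Block]],
        src_lengths: Mapping[str, int],
        dst_lengths: Mapping[str, int],
    ) -> None:
        self.blocks: dict[str, list[Block]] = {
            chrom: sorted(bs, key=lambda b: b.src_start) for chrom, bs in blocks.items()
        }
        self.src_lengths = dict(src_lengths)
        self.dst_lengths = dict(dst_lengths)
        self._src_starts = {c: [b.src_start for b in bs] for c, bs in self.blocks.items()}
        self._dst_starts = {c: [b.dst_start for b in bs] for c, bs in self.blocks.items()}
        self._validate()

    def _validate(self) -> None:
        for chrom, bs in self.blocks.items():
            prev_src = prev_dst = -1
            for b in bs:
                if b.length < 0:
                    raise ValueError(f"negative block length on {chrom}")
                if b.src_start <= prev_src or b.dst_start <= prev_dst:
                    raise ValueError(f"blocks not strictly increasing on {chrom}")
                prev_src, prev_dst = b.src_end - 1, b.dst_end - 1
            matched = sum(b.length for b in bs)
            if chrom in self.src_lengths:
                deleted = self.src_lengths[chrom] - matched
                if deleted < 0:
                    raise ValueError(f"matched bases exceed source length on {chrom}")
            if chrom in self.dst_lengths:
                inserted = self.dst_lengths[chrom] - matched
                if inserted < 0:
                    raise ValueError(f"matched bases exceed destination length on {chrom}")

    def chroms(self) -> list[str]:
        return list(self.blocks)

    def matched_bases(self, chrom: str) -> int:
        return sum(b.length for b in self.blocks[chrom])

    def deleted_bases(self, chrom: str) -> int:
        return self.src_lengths[chrom] - self.matched_bases(chrom)

    def inserted_bases(self, chrom: str) -> int:
        return self.dst_lengths[chrom] - self.matched_bases(chrom)

    def find_block(self, chrom: str, pos: int, direction: str) -> int:
        """Index of the last block whose start is <= pos in the given system.

        Returns −1 if ``pos`` precedes every block.
        """
        starts = self._src_starts[chrom] if direction == "src" else self._dst_starts[chrom]
        return bisect.bisect_right(starts, pos) - 1


def project_position(
    rm: RegionMap, chrom: str, pos: int, direction: str = "src2dst"
) -> int | GapReport:
    """Project a position through the region map.

    ``direction`` is ``"src2dst"`` (reference → pseudogenome) or ``"dst2src"``.
    Inside a block the exact counterpart position is returned.  Inside a gap
    (a deleted base going src→dst, an inserted base going dst→src) a
    :class:`GapReport` with the flanking counterpart coordinates is returned.
    """
    if direction not in ("src2dst", "dst2src"):
        raise ValueError(f"unknown direction {direction!r}")
    if chrom not in rm.blocks:
        raise KeyError(f"chromosome {chrom!r} not in region map")
    fwd = direction == "src2dst"
    limit = (rm.src_lengths if fwd else rm.dst_lengths)[chrom]
    if not 0 <= pos < limit:
        raise ValueError(f"position {pos} out of range for {chrom} (length {limit})")
    blocks = rm.blocks[chrom]
    idx = rm.find_block(chrom, pos, "src" if fwd else "dst")
    if idx >= 0:
        b = blocks[idx]
        start, other = (b.src_start, b.dst_start) if fwd else (b.dst_start, b.src_start)
        offset = pos - start
        if offset < b.length:
            return other + offset
        left = other + b.length - 1
    else:
        left = -1
    right_idx = idx + 1
    if right_idx < len(blocks):
        nb = blocks[right_idx]
        right = nb.dst_start if fwd else nb.src_start
    else:
        right = (rm.dst_lengths if fwd else rm.src_lengths)[chrom]
    return GapReport(chrom=chrom, pos=pos, left=left, right=right)


def _iter_chrom_blocks(
    instructions: Iterable[ModInstruction], src_len: int
) -> tuple[list[Block], int]:
    """Scan one chromosome's sorted instructions, accumulating base shifts.

    Returns the block list and the destination length.  ``s`` instructions
    preserve correspondence and are ignored here; each ``d`` drops one source
    base, each ``i`` splices its payload after the anchor.
    """
    blocks: list[Block] = []
    block_src = 0  # src start of the open block
    block_dst = 0
    src_cursor = 0  # first src position not yet assigned to a block
    dst_cursor = 0

    def close(boundary: int) -> None:
        nonlocal block_src, block_dst, src_cursor, dst_cursor
        length = boundary - block_src
        if length > 0:
            blocks.append(Block(block_src, block_dst, length))
            dst_cursor = block_dst + length
        src_cursor = max(src_cursor, boundary)

    for inst in instructions:
        if inst.kind == "s":
            continue
        if inst.kind == "d":
            if inst.pos >= src_len:
                raise ModValidationError(
                    f"d-instruction at {inst.chrom}:{inst.pos} past chromosome end"
                )
            close(inst.pos)
            src_cursor = inst.pos + 1  # deleted base consumes src only
            block_src, block_dst = src_cursor, dst_cursor
        else:  # i: insert after anchor pos
            boundary = inst.pos + 1
            close(boundary)
            dst_cursor += len(inst.payload)  # type: ignore[arg-type]
            block_src, block_dst = src_cursor, dst_cursor
    close(src_len)
    dst_len = dst_cursor
    return blocks, dst_len


def build_region_map(mod: ModFile, chrom_lengths: Mapping[str, int]) -> RegionMap:
    """Build the offset-pair index for a MOD file without touching sequence.

    Every chromosome in ``chrom_lengths`` gets an entry; chromosomes without
    instructions map identically (one full-length block).
    """
    mod.check_against(chrom_lengths)
    per_chrom = mod.by_chrom()
    blocks: dict[str, list[Block]] = {}
    dst_lengths: dict[str, int] = {}
    for chrom, src_len in chrom_lengths.items():
        bs, dst_len = _iter_chrom_blocks(per_chrom.get(chrom, []), src_len)
        blocks[chrom] = bs
        dst_lengths[chrom] = dst_len
    return RegionMap(blocks, dict(chrom_lengths), dst_lengths)


@dataclass
class BuildIssues:
    """Mismatches tolerated in lenient mode."""

    base_mismatches: list[str] = field(default_factory=list)


@dataclass
class PseudogenomeBuild:
    """The destination sequences plus the region map and provenance."""

    sequences: dict[str, str]
    region_map: RegionMap
    source_name: str = ""
    destination_name: str = ""
    mod_checksum: str = ""
    issues: BuildIssues = field(default_factory=BuildIssues)


def build_pseudogenome(
    reference: Mapping[str, str],
    mod: ModFile,
    strict: bool = True,
) -> PseudogenomeBuild:
    """Execute a MOD file against the reference in one left-to-right pass.

    ``s`` substitutes a base, ``d`` skips one source base, ``i`` appends its
    payload after the anchor.  In strict mode (default) the source base stated
    by each ``s``/``d`` instruction must match the reference; a mismatch
    anywhere else would silently corrupt every downstream liftover.  In
    lenient mode mismatches are recorded in ``issues`` and the stated edit is
    applied anyway.
    """
    chrom_lengths = {c: len(s) for c, s in reference.items()}
    mod.check_against(chrom_lengths)
    per_chrom = mod.by_chrom()
    issues = BuildIssues()
    sequences: dict[str, str] = {}
    for chrom, seq in reference.items():
        seq = seq.upper()
        parts: list[str] = []
        cursor = 0
        for inst in per_chrom.get(chrom, []):
            if inst.kind == "s":
                ref_base, alt_base = inst.payload  # type: ignore[misc]
                actual = seq[inst.pos]
                if actual != ref_base:
                    msg = (
                        f"s-instruction at {chrom}:{inst.pos} expects source base "
                        f"{ref_base!r} but reference has {actual!r}"
                    )
                    if strict:
                        raise ModValidationError(msg)
                    issues.base_mismatches.append(msg)
                parts.append(seq[cursor : inst.pos])
                parts.append(alt_base)
                cursor = inst.pos + 1
            elif inst.kind == "d":
                actual = seq[inst.pos]
                if actual != inst.payload:
                    msg = (
                        f"d-instruction at {chrom}:{inst.pos} expects source base "
                        f"{inst.payload!r} but reference has {actual!r}"
                    )
                    if strict:
                        raise ModValidationError(msg)
                    issues.base_mismatches.append(msg)
                parts.append(seq[cursor : inst.pos])
                cursor = inst.pos + 1
            else:  # i
                boundary = inst.pos + 1
                parts.append(seq[cursor:boundary])
                parts.append(str(inst.payload))
                cursor = max(cursor, boundary)
        parts.append(seq[cursor:])
        sequences[chrom] = "".join(parts)
    region_map = build_region_map(mod, chrom_lengths)
    # length conservation: dst = src − deleted + inserted, per chromosome
    for chrom, built in sequences.items():
        expect = region_map.dst_lengths[chrom]
        if len(built) != expect:
            raise AssertionError(
                f"length conservation violated on {chrom}: built {len(built)}, "
                f"region map expects {expect}"
            )
    checksum = hashlib.sha256(
        "\n".join(t.to_line() for t in mod.instructions).encode()
    ).hexdigest()[:16]
    return PseudogenomeBuild(
        sequences=sequences,
        region_map=region_map,
        source_name=mod.source,
        destination_name=mod.destination,
        mod_checksum=checksum,
        issues=issues,
    )


# ---------------------------------------------------------------------------
# sidecar TSV serialization, so remapping never re-scans the MOD file

_MAP_COLUMNS = "chrom\tsrc_start\tdst_start\tlength"


def write_region_map(rm: RegionMap, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in rm.chroms():
            fh.write(
                f"#chrom_lengths\t{chrom}\t{rm.src_lengths[chrom]}\t{rm.dst_lengths[chrom]}\n"
            )
        fh.write(f"#{_MAP_COLUMNS}\n")
        for chrom, bs in rm.blocks.items():
            for b in bs:
                fh.write(f"{chrom}\t{b.src_start}\t{b.dst_start}\t{b.length}\n")


def read_region_map(path: str) -> RegionMap:
    blocks: dict[str, list[Block]] = {}
    src_lengths: dict[str, int] = {}
    dst_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#chrom_lengths\t"):
                _, chrom, src_len, dst_len = line.split("\t")
                src_lengths[chrom] = int(src_len)
                dst_lengths[chrom] = int(dst_len)
                blocks.setdefault(chrom, [])
                continue
            if line.startswith("#"):
                continue
            chrom, src_start, dst_start, length = line.split("\t")
            blocks.setdefault(chrom, []).append(
                Block(int(src_start), int(dst_start), int(length))
            )
    return RegionMap(blocks, src_lengths, dst_lengths)
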