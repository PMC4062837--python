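"""MOD files: atomic edit transcripts between a source and a destination genome.

A MOD file describes how to transform one genome sequence (the *source*,
typically the reference) into another (the *destination*, typically a founder
pseudogenome).  The body is a list of atomic instructions, each touching at
most one source position:

``s``
    single-base substitution: ``s  chrom  pos  REF/ALT``
``d``
    single-base deletion: ``d  chrom  pos  BASE``
``i``
    insertion of a sequence AFTER the anchor position: ``i  chrom  pos  SEQ``.
    An insertion before the first base of a chromosome uses anchor ``-1``.

Positions are 0-based and always refer to the source coordinate system.
Multi-base deletions are decomposed into runs of single-base ``d``
instructions; insertions are already atomic because they reference only their
anchor.  Header lines start with ``#`` and carry ``key=value`` metadata
(``#version=``, ``#source=``, ``#destination=``) or free-form comments.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ModInstruction",
    "ModFile",
    "ModParseError",
    "ModValidationError",
    "parse_mod",
    "write_mod",
    "read_mod",
    "save_mod",
    "variants_to_mod",
]

VALID_BASES = frozenset("ACGTN")

# d sorts before s before i at one position: a deletion and an insertion at the
# same anchor express a replacement, applied as delete-then-insert.
_KIND_ORDER = {"d": 0, "s": 1, "i": 2}


class ModParseError(ValueError):
    """A body or header line could not be parsed."""


class ModValidationError(ValueError):
    """The instruction set violates a MOD invariant."""


@dataclass(frozen=True, order=False)
class ModInstruction:
    """One atomic edit.

    Parameters
    ----------
    kind:
        ``"s"``, ``"d"`` or ``"i"``.
    chrom:
        Sequence name in the source genome.
    pos:
        0-based source coordinate.  For ``i`` this is the anchor; the payload
        is inserted after it (``-1`` inserts before the first base).
    payload:
        For ``s`` a ``(ref_base, alt_base)`` tuple, for ``d`` the deleted
        base, for ``i`` the inserted sequence.
    """

    kind: str
    chrom: str
    pos: int
    payload: tuple[str, str] | str

    def __post_init__(self) -> None:
        if self.kind not in ("s", "d", "i"):
            raise ModValidationError(f"unknown instruction kind {self.kind!r}")
        if self.kind == "i":
            if self.pos < -1:
                raise ModValidationError(f"negative position {self.pos} for i-instruction")
        elif self.pos < 0:
            raise ModValidationError(f"negative position {self.pos} for {self.kind}-instruction")
        if self.kind == "s":
            ref, alt = self.payload  # type: ignore[misc]
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1:
                raise ModValidationError(
                    f"s-instruction at {self.chrom}:{self.pos} must substitute exactly one base"
                )
            if ref == alt:
                raise ModValidationError(
                    f"s-instruction at {self.chrom}:{self.pos} substitutes {ref} for itself"
                )
            _check_bases(ref + alt, self)
            object.__setattr__(self, "payload", (ref, alt))
        elif self.kind == "d":
            base = str(self.payload).upper()
            if len(base) != 1:
                raise ModValidationError(
                    f"d-instruction at {self.chrom}:{self.pos} must delete exactly one base"
                )
            _check_bases(base, self)
            object.__setattr__(self, "payload", base)
        else:
            seq = str(self.payload).upper()
            if not seq:
                raise ModValidationError(
                    f"i-instruction at {self.chrom}:{self.pos} has an empty insert"
                )
            _check_bases(seq, self)
            object.__setattr__(self, "payload", seq)

    @property
    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.pos, _KIND_ORDER[self.kind])

    def to_line(self) -> str:
        if self.kind == "s":
            ref, alt = self.payload  # type: ignore[misc]
            arg = f"{ref}/{alt}"
        else:
            arg = str(self.payload)
        return f"{self.kind}\t{self.chrom}\t{self.pos}\t{arg}"


def _check_bases(bases: str, inst: "ModInstruction") -> None:
    bad = set(bases) - VALID_BASES
    if bad:
        raise ModValidationError(
            f"{inst.kind}-instruction at {inst.chrom}:{inst.pos} contains "
            f"non-ACGTN base(s) {sorted(bad)}"
        )


@dataclass
class ModFile:
    """A header plus an ordered list of atomic instructions.

    Instructions are kept sorted by ``(chrom, pos, kind)`` with ``d`` before
    ``s`` before ``i`` at one position.  At most one ``s`` or one ``d`` may
    reference a given position (they are mutually exclusive); multiple ``i``
    at one anchor concatenate in file order.
    """

    header: dict[str, str] = field(default_factory=dict)
    instructions: list[ModInstruction] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.instructions = sorted(self.instructions, key=lambda t: t.sort_key)
        self.validate()

    @property
    def source(self) -> str:
        return self.header.get("source", "")

    @property
    def destination(self) -> str:
        return self.header.get("destination", "")

    def validate(self) -> None:
        seen_sd: set[tuple[str, int]] = set()
        for inst in self.instructions:
            if inst.kind in ("s", "d"):
                key = (inst.chrom, inst.pos)
                if key in seen_sd:
                    raise ModValidationError(
                        f"duplicate s/d instruction at {inst.chrom}:{inst.pos}"
                    )
                seen_sd.add(key)

    def counts(self) -> dict[str, int]:
        """Instruction tallies; for ``i`` the total number of inserted bases."""
        out = {"s": 0, "d": 0, "i": 0}
        for inst in self.instructions:
            if inst.kind == "i":
                out["i"] += len(inst.payload)  # type: ignore[arg-type]
            else:
                out[inst.kind] += 1
        return out

    def by_chrom(self) -> dict[str, list[ModInstruction]]:
        out: dict[str, list[ModInstruction]] = {}
        for inst in self.instructions:
            out.setdefault(inst.chrom, []).append(inst)
        return out

    def check_against(self, chrom_lengths: Mapping[str, int]) -> None:
        """Verify instructions fit within a source genome's chromosomes."""
        for inst in self.instructions:
            if inst.chrom not in chrom_lengths:
                raise ModValidationError(
                    f"instruction on unknown chromosome {inst.chrom!r}"
                )
            limit = chrom_lengths[inst.chrom]
            if inst.pos >= limit:
                raise ModValidationError(
                    f"{inst.kind}-instruction at {inst.chrom}:{inst.pos} is past "
                    f"the chromosome end ({limit})"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModFile):
            return NotImplemented
        return (
            self.header == other.header
            and self.instructions == other.instructions
        )


def parse_mod(stream: Iterable[str]) -> ModFile:
    """Parse MOD text lines into a validated :class:`ModFile`.

    Lines beginning ``#`` are header metadata (``#key=value``) or free-form
    comments; body lines are TAB-separated ``kind chrom pos payload``.
    """
    header: dict[str, str] = {}
    comments: list[str] = []
    instructions: list[ModInstruction] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:]
            if "=" in body and " " not in body.split("=", 1)[0]:
                key, value = body.split("=", 1)
                header[key.strip()] = value.strip()
            else:
                comments.append(body.strip())
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ModParseError(
                f"line {lineno}: expected 4 TAB-separated fields, got {len(fields)}"
            )
        kind, chrom, pos_s, arg = fields
        try:
            pos = int(pos_s)
        except ValueError:
            raise ModParseError(f"line {lineno}: non-integer position {pos_s!r}") from None
        try:
            if kind == "s":
                if "/" not in arg:
                    raise ModParseError(
                        f"line {lineno}: s-instruction payload must be REF/ALT, got {arg!r}"
                    )
                ref, alt = arg.split("/", 1)
                inst = ModInstruction("s", chrom, pos, (ref, alt))
            elif kind in ("d", "i"):
                inst = ModInstruction(kind, chrom, pos, arg)
            else:
                raise ModParseError(f"line {lineno}: unknown instruction kind {kind!r}")
        except ModValidationError as exc:
            raise ModParseError(f"line {lineno}: {exc}") from exc
        instructions.append(inst)
    return ModFile(header=header, instructions=instructions, comments=comments)


def write_mod(mod: ModFile, stream: IO[str] | None = None) -> str:
    """Serialize a :class:`ModFile` in canonical form; returns the text.

    Output is deterministic: header keys in insertion order with the three
    standard keys first, instructions in sorted order.
    """
    mod.validate()
    lines: list[str] = []
    emitted = set()
    for key in ("version", "source", "destination"):
        if key in mod.header:
            lines.append(f"#{key}={mod.header[key]}")
            emitted.add(key)
    for key, value in mod.header.items():
        if key not in emitted:
            lines.append(f"#{key}={value}")
    for comment in mod.comments:
        lines.append(f"# {comment}")
    for inst in mod.instructions:
        lines.append(inst.to_line())
    text = "\n".join(lines) + "\n"
    if stream is not None:
        stream.write(text)
    return text


def read_mod(path: str) -> ModFile:
    """Read a MOD file from disk; ``.gz`` paths are decompressed transparently."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        return parse_mod(fh)


def save_mod(mod: ModFile, path: str) -> None:
    """Write a MOD file to disk; ``.gz`` paths are gzip-compressed."""
    text = write_mod(mod)
    if str(path).endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


@dataclass
class VariantConversionStats:
    converted: int = 0
    skipped_multiallelic: int = 0
    skipped_symbolic: int = 0
    skipped_other: int = 0


def variants_to_mod(
    variants: Iterable,
    source_name: str,
    dest_name: str,
    reference: Mapping[str, str] | None = None,
    stats: VariantConversionStats | None = None,
) -> ModFile:
    """Convert VCF-style variant records into a MOD file.

    ``variants`` yields records with 1-based ``pos``, ``chrom``, ``ref`` and
    ``alts`` attributes (:mod:`pysam` ``VariantRecord`` objects or any
    duck-typed equivalent).  Only biallelic SNPs and simple anchored indels
    are converted:

    * SNP at 1-based ``pos`` becomes one ``s`` at 0-based ``pos - 1``.
    * Insertion ``REF=b, ALT=b+S`` becomes one ``i`` anchored at ``pos - 1``
      with payload ``S``.
    * Deletion ``REF=b+S, ALT=b`` is decomposed into ``len(S)`` single-base
      ``d`` instructions at 0-based positions ``pos, pos+1, ...``.

    Multiallelic or symbolic records are skipped and counted in ``stats``.
    When ``reference`` is given, REF fields are checked against it.
    """
    if stats is None:
        stats = VariantConversionStats()
    instructions: list[ModInstruction] = []
    for rec in variants:
        chrom = rec.chrom
        pos1 = rec.pos  # 1-based
        ref = rec.ref.upper()
        alts = tuple(rec.alts or ())
        if len(alts) != 1:
            stats.skipped_multiallelic += 1
            continue
        alt = str(alts[0]).upper()
        if alt.startswith("<") or any(c in alt for c in "[]."):
            stats.skipped_symbolic += 1
            continue
        if not (set(ref) <= VALID_BASES and set(alt) <= VALID_BASES):
            stats.skipped_other += 1
            continue
        if reference is not None:
            seq = reference[chrom]
            actual = seq[pos1 - 1 : pos1 - 1 + len(ref)].upper()
            if actual != ref:
                raise ModValidationError(
                    f"variant at {chrom}:{pos1}: REF {ref!r} does not match "
                    f"source sequence {actual!r}"
                )
        if len(ref) == 1 and len(alt) == 1:
            if ref == alt:
                stats.skipped_other += 1
                continue
            instructions.append(ModInstruction("s", chrom, pos1 - 1, (ref, alt)))
            stats.converted += 1
        elif len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
            # insertion after the anchor base
            instructions.append(ModInstruction("i", chrom, pos1 - 1, alt[1:]))
            stats.converted += 1
        elif len(alt) == 1 and len(ref) > 1 and ref[0] == alt:
            # deletion: decompose into single-base d-instructions
            for k, base in enumerate(ref[1:]):
                instructions.append(ModInstruction("d", chrom, pos1 + k, base))
            stats.converted += 1
        else:
            # complex substitution (MNP or non-anchored indel): not converted
            stats.skipped_other += 1
    header = {"version": "1.0", "source": source_name, "destination": dest_name}
    return ModFile(header=header, instructions=instructions)
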