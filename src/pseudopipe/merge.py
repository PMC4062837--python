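"""Merge N remapped alignment files into one, tagging origin and filter.

All candidate mappings of a read fragment — across founders and across
multi-mapped loci — are gathered from name-sorted inputs, deduplicated when
identical in reference space, and sent through the filter cascade:

``Unique``
    a single candidate remains: output it.
``Quality``
    several candidates: regenerate each one's aligner score from the
    preserved pseudogenome CIGAR and edit distance; a unique best score wins.
``Pileup`` (optional, two-pass)
    among tied-best candidates, pick the one whose reference span has the
    strictly greatest mean coverage from already-resolved fragments.
``Random``
    break remaining ties uniformly at random, reproducibly: the RNG is keyed
    by the global seed and the read name, so the outcome is independent of
    input file order.

Two candidate mappings are *identical* when they agree on reference start,
reference CIGAR, pairing flag, fragment-end flag and regenerated score; they
collapse into one unit whose origin bit flags are OR-ed (for two founders:
01 first parent, 10 second parent, 11 either).  Properly paired mappings are
treated as one unit with one score, and whenever any paired candidate exists
all unpaired candidates are discarded.
"""

from __future__ import annotations

import heapq
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from pseudopipe.remap import RemapTags, _parse_cigar

__all__ = [
    "ScoringScheme",
    "MergeTags",
    "MappingUnit",
    "FragmentMappingSet",
    "FilterDecision",
    "MergeError",
    "encode_origin_flag",
    "regenerate_score",
    "mappings_identical",
    "link_pairs",
    "filter_unique",
    "filter_quality",
    "filter_random",
    "filter_pileup",
    "collect_fragment_sets",
    "merge_alignments",
]


class MergeError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """End-to-end alignment scoring used to regenerate pseudogenome scores.

    Defaults follow the Bowtie2 end-to-end convention: a perfect match scores
    0 and penalties accumulate negatively.  Base qualities are not consulted
    (only the preserved CIGAR and edit distance are available post-liftover).
    """

    mismatch_penalty: int = 6
    gap_open: int = 5
    gap_extend: int = 3


@dataclass(frozen=True)
class MergeTags:
    origin: str = "po"  # integer bit-set: bit k ⇔ supported by founder k
    filter: str = "ft"  # single char U/Q/P/R


def encode_origin_flag(sources: Iterable[int], n_founders: int) -> int:
    """Bit k set iff founder k supports the mapping; N-founder generalization."""
    bits = 0
    for k in sources:
        if not 0 <= k < n_founders:
            raise MergeError(f"founder index {k} out of range for N={n_founders}")
        bits |= 1 << k
    if bits == 0:
        raise MergeError("origin flag must have at least one founder bit set")
    return bits


def regenerate_score(oc: str, om: int, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Recover the aligner's end-to-end score from preserved tags.

    ``om`` counts mismatches plus inserted plus deleted bases in pseudogenome
    space; subtracting the indel bases of the preserved CIGAR leaves the
    mismatch count.  Each I/D run is one gap.  A perfect end-to-end match
    scores 0; higher is better.
    """
    ops = _parse_cigar(oc)
    indel_bases = sum(ln for op, ln in ops if op in "ID")
    mismatches = om - indel_bases
    if mismatches < 0:
        raise MergeError(
            f"inconsistent tags: edit distance {om} < {indel_bases} indel bases in {oc!r}"
        )
    score = -scheme.mismatch_penalty * mismatches
    for op, ln in ops:
        if op in "ID":
            score -= scheme.gap_open + scheme.gap_extend * ln
    return score


def _end_flag(rec: pysam.AlignedSegment) -> int:
    if not rec.is_paired:
        return 0
    return 1 if rec.is_read1 else 2


def _record_key(rec: pysam.AlignedSegment) -> tuple:
    return (rec.reference_name, rec.reference_start, rec.cigarstring)


@dataclass
class MappingUnit:
    """One candidate mapping: a single-end record or a properly-paired pair.

    The pair carries exactly one score, computed once from both ends'
    preserved pseudogenome CIGARs and edit distances.
    """

    records: tuple[pysam.AlignedSegment, ...]
    origin: int
    score: int
    paired: bool
    end_flag: int  # 0 unpaired/single, 1 first end, 2 second end; pairs use 0

    @property
    def key(self) -> tuple:
        """Identity per the five criteria: start, CIGAR, pairing, end, score."""
        return (
            self.paired,
            self.end_flag,
            tuple(_record_key(r) for r in self.records),
            self.score,
        )

    def reference_spans(self) -> list[tuple[str, int, int]]:
        """Reference intervals covered by M/D ops (N gaps excluded)."""
        spans: list[tuple[str, int, int]] = []
        for rec in self.records:
            pos = rec.reference_start
            run_start = pos
            for op, ln in _parse_cigar(rec.cigartuples):
                if op in "MD=X":
                    pos += ln
                elif op == "N":
                    if pos > run_start:
                        spans.append((rec.reference_name, run_start, pos))
                    pos += ln
                    run_start = pos
            if pos > run_start:
                spans.append((rec.reference_name, run_start, pos))
        return spans


@dataclass
class FragmentMappingSet:
    """All surviving candidate mappings of one read fragment."""

    name: str
    units: list[MappingUnit]
    sub: int = 0  # 0: pooled/paired set, 1: first-end set, 2: second-end set


@dataclass
class FilterDecision:
    unit: MappingUnit
    label: str  # U, Q, P or R
    name: str = ""
    sub: int = 0


def mappings_identical(a: MappingUnit, b: MappingUnit) -> bool:
    """True iff start, CIGAR, pairing flag, end flag and score all agree."""
    return a.key == b.key


def _dedupe(units: list[MappingUnit]) -> list[MappingUnit]:
    """Collapse identical units, OR-ing origin flags; stable canonical order."""
    merged: dict[tuple, MappingUnit] = {}
    for u in units:
        if u.key in merged:
            merged[u.key].origin |= u.origin
        else:
            merged[u.key] = MappingUnit(u.records, u.origin, u.score, u.paired, u.end_flag)
    return sorted(merged.values(), key=lambda u: u.key)


def _score_record(rec: pysam.AlignedSegment, scheme: ScoringScheme, tags: RemapTags) -> int:
    if not (rec.has_tag(tags.original_cigar) and rec.has_tag(tags.original_nm)):
        raise MergeError(
            f"record {rec.query_name} lacks preservation tags "
            f"{tags.original_cigar}/{tags.original_nm}; cannot regenerate score"
        )
    return regenerate_score(
        rec.get_tag(tags.original_cigar), rec.get_tag(tags.original_nm), scheme
    )


def _units_from_file_group(
    records: list[pysam.AlignedSegment],
    founder: int,
    n_founders: int,
    scheme: ScoringScheme,
    tags: RemapTags,
) -> list[MappingUnit]:
    """Build units for one read name within one input file.

    Properly paired mates (both flagged proper in this same file) are linked
    into paired units; cross-founder pairs are never formed.  Orphaned proper
    flags are demoted to single-end units.
    """
    origin = encode_origin_flag([founder], n_founders)
    mapped = [r for r in records if not r.is_unmapped]
    proper1 = [r for r in mapped if r.is_paired and r.is_proper_pair and r.is_read1]
    proper2 = [r for r in mapped if r.is_paired and r.is_proper_pair and r.is_read2]
    singles = [
        r for r in mapped if not (r.is_paired and r.is_proper_pair)
    ]
    units: list[MappingUnit] = []
    used2: set[int] = set()
    for r1 in proper1:
        mate_idx = next(
            (
                j
                for j, r2 in enumerate(proper2)
                if j not in used2
                and r2.reference_name == r1.next_reference_name
                and r2.reference_start == r1.next_reference_start
            ),
            None,
        )
        if mate_idx is None:
            mate_idx = next((j for j in range(len(proper2)) if j not in used2), None)
        if mate_idx is None:
            singles.append(r1)  # orphaned proper flag: demote
            continue
        used2.add(mate_idx)
        r2 = proper2[mate_idx]
        score = _score_record(r1, scheme, tags) + _score_record(r2, scheme, tags)
        units.append(MappingUnit((r1, r2), origin, score, True, 0))
    for j, r2 in enumerate(proper2):
        if j not in used2:
            singles.append(r2)
    for rec in singles:
        units.append(
            MappingUnit((rec,), origin, _score_record(rec, scheme, tags), False, _end_flag(rec))
        )
    return units


class _NameGroupReader:
    """Stream (name, records) groups from a name-sorted alignment file."""

    def __init__(self, af: pysam.AlignmentFile, path: str) -> None:
        self.path = path
        self._it = iter(af)
        self._pending: pysam.AlignedSegment | None = next(self._it, None)
        self._last_name: str | None = None

    def next_group(self) -> tuple[str, list[pysam.AlignedSegment]] | None:
        if self._pending is None:
            return None
        name = self._pending.query_name
        if self._last_name is not None and name < self._last_name:
            raise MergeError(
                f"{self.path} is not name-sorted: {name!r} follows {self._last_name!r}"
            )
        self._last_name = name
        group = [self._pending]
        self._pending = None
        for rec in self._it:
            if rec.query_name == name:
                group.append(rec)
            else:
                self._pending = rec
                break
        return name, group


def collect_fragment_sets(
    files: Sequence[pysam.AlignmentFile],
    paths: Sequence[str] | None = None,
    scheme: ScoringScheme = ScoringScheme(),
    tags: RemapTags = RemapTags(),
) -> Iterator[FragmentMappingSet]:
    """K-way merge of N name-sorted inputs into per-fragment candidate sets.

    Yields one :class:`FragmentMappingSet` per read name with ≥1 mapped
    record, with identical mappings already collapsed.  Input order across
    files only affects nothing: units are canonically ordered.
    """
    n = len(files)
    if n < 1:
        raise MergeError("need at least one input")
    paths = list(paths or [f"input{k}" for k in range(n)])
    readers = [_NameGroupReader(af, paths[k]) for k, af in enumerate(files)]
    heads: list[tuple[str, int, list[pysam.AlignedSegment]]] = []
    for k, rd in enumerate(readers):
        grp = rd.next_group()
        if grp is not None:
            heads.append((grp[0], k, grp[1]))
    heapq.heapify(heads)
    while heads:
        name = heads[0][0]
        per_file: dict[int, list[pysam.AlignedSegment]] = {}
        while heads and heads[0][0] == name:
            _, k, group = heapq.heappop(heads)
            per_file[k] = group
            nxt = readers[k].next_group()
            if nxt is not None:
                heapq.heappush(heads, (nxt[0], k, nxt[1]))
        by_end_len: dict[int, set[int]] = {}
        for recs in per_file.values():
            for r in recs:
                if r.query_sequence and not r.is_secondary:
                    by_end_len.setdefault(_end_flag(r), set()).add(len(r.query_sequence))
        for end, lens in by_end_len.items():
            if len(lens) > 1:
                raise MergeError(
                    f"inconsistent read lengths for {name!r} (end {end}): {sorted(lens)}"
                )
        units: list[MappingUnit] = []
        for k, group in per_file.items():
            units.extend(_units_from_file_group(group, k, n, scheme, tags))
        units = _dedupe(units)
        if units:
            yield FragmentMappingSet(name=name, units=units)


def link_pairs(fset: FragmentMappingSet) -> list[FragmentMappingSet]:
    """Apply paired preference, or split unpaired ends into independent sets.

    If any properly-paired unit exists, all unpaired units are removed and one
    set remains.  Otherwise first-end and second-end candidates are filtered
    separately (the two ends of a fragment may be decided by different
    filters); single-end data passes through as one set.
    """
    paired = [u for u in fset.units if u.paired]
    if paired:
        return [FragmentMappingSet(fset.name, paired, sub=0)]
    by_end: dict[int, list[MappingUnit]] = {}
    for u in fset.units:
        by_end.setdefault(u.end_flag, []).append(u)
    if len(by_end) <= 1:
        return [fset]
    return [
        FragmentMappingSet(fset.name, units, sub=end)
        for end, units in sorted(by_end.items())
    ]


def filter_unique(fset: FragmentMappingSet) -> FilterDecision | FragmentMappingSet:
    """Decide fragments whose candidate set is a singleton."""
    if not fset.units:
        raise MergeError(f"empty mapping set for {fset.name!r}")
    if len(fset.units) == 1:
        return FilterDecision(fset.units[0], "U", fset.name, fset.sub)
    return fset

def filter_quality(fset: FragmentMappingSet) -> FilterDecision | FragmentMappingSet:
    """Keep the best regenerated score; decide if it is unique."""
    best = max(u.score for u in fset.units)
    top = [u for u in fset.units if u.score == best]
    if len(top) == 1:
        return FilterDecision(top[0], "Q", fset.name, fset.sub)
    return FragmentMappingSet(fset.name, top, fset.sub)


def _fragment_rng(seed: int, name: str, sub: int) -> np.random.Generator:
    # keyed per fragment so decisions are independent of file order and
    # of how many earlier fragments consumed the stream
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode()), sub])


def filter_random(fset: FragmentMappingSet, seed: int = 0) -> FilterDecision:
    """Uniform tie-break among equal-score candidates; reproducible per seed.

    Candidates are put in canonical (key) order before drawing, so the choice
    is a function of (seed, read name, candidate identities) alone — never of
    input file order.
    """
    units = sorted(fset.units, key=lambda u: u.key)
    rng = _fragment_rng(seed, fset.name, fset.sub)
    idx = int(rng.integers(len(units)))
    return FilterDecision(units[idx], "R", fset.name, fset.sub)


def filter_pileup(
    fset: FragmentMappingSet, coverage: dict[str, np.ndarray]
) -> FilterDecision | FragmentMappingSet:
    """Prefer the candidate with strictly greatest mean supporting depth.

    ``coverage`` is per-base depth accumulated from Unique/Quality decisions
    only.  Ties, or all-zero depth, fall through to the Random filter.
    """
    means = []
    for u in fset.units:
        total = 0.0
        nbases = 0
        for chrom, start, end in u.reference_spans():
            arr = coverage.get(chrom)
            if arr is not None:
                total += float(arr[start:end].sum())
            nbases += end - start
        means.append(total / nbases if nbases else 0.0)
    best = max(means)
    if best <= 0.0 or means.count(best) > 1:
        return fset
    return FilterDecision(fset.units[means.index(best)], "P", fset.name, fset.sub)


def _cascade(
    fset: FragmentMappingSet,
    seed: int,
) -> FilterDecision | FragmentMappingSet:
    """Unique → Quality; returns a decision or the tied-best set."""
    res = filter_unique(fset)
    if isinstance(res, FilterDecision):
        return res
    return filter_quality(res)


def merge_alignments(
    in_paths: Sequence[str],
    out_path: str,
    seed: int = 0,
    scheme: ScoringScheme = ScoringScheme(),
    remap_tags: RemapTags = RemapTags(),
    merge_tags: MergeTags = MergeTags(),
    pileup: bool = False,
    report_path: str | None = None,
) -> pd.DataFrame:
    """Merge N remapped, name-sorted inputs into one output file.

    Every fragment with at least one mapping yields exactly one unit per
    surviving set (one record if single-end, two if paired).  Output records
    carry the origin bit flag and the deciding filter as tags.  Returns the
    summary report: fragment-set counts per (filter × origin) with
    percentages summing to 100.
    """
    files = [pysam.AlignmentFile(p, check_sq=False) for p in in_paths]
    try:
        header = files[0].header.to_dict()
        header.setdefault("HD", {"VN": "1.6"})
        header["HD"]["SO"] = "unknown"
        header.setdefault("PG", []).append(
            {"ID": "pseudopipe-merge", "PN": "pseudopipe", "CL": f"merge seed={seed}"}
        )
        out_header = pysam.AlignmentHeader.from_dict(header)

        decisions: list[FilterDecision] = []
        pending_random: list[FragmentMappingSet] = []
        for fset in collect_fragment_sets(files, in_paths, scheme, remap_tags):
            for sub in link_pairs(fset):
                res = _cascade(sub, seed)
                if isinstance(res, FilterDecision):
                    decisions.append(res)
                else:
                    pending_random.append(res)

        if pileup:
            lengths = {
                sq["SN"]: sq["LN"] for sq in out_header.to_dict().get("SQ", [])
            }
            coverage = {c: np.zeros(l, dtype=np.int32) for c, l in lengths.items()}
            for dec in decisions:
                for chrom, start, end in dec.unit.reference_spans():
                    if chrom in coverage:
                        coverage[chrom][start:end] += 1
            still: list[FragmentMappingSet] = []
            for fset in pending_random:
                res = filter_pileup(fset, coverage)
                if isinstance(res, FilterDecision):
                    decisions.append(res)
                else:
                    still.append(res)
            pending_random = still

        for fset in pending_random:
            decisions.append(filter_random(fset, seed))

        decisions.sort(key=lambda d: (d.name, d.sub))
        write_mode = "wb" if str(out_path).endswith(".bam") else "w"
        with pysam.AlignmentFile(out_path, write_mode, header=out_header) as out:
            for dec in decisions:
                for rec in dec.unit.records:
                    rec.set_tag(merge_tags.origin, dec.unit.origin, "i")
                    rec.set_tag(merge_tags.filter, dec.label, "A")
                    out.write(rec)
    finally:
        for af in files:
            af.close()

    n_founders = len(in_paths)
    rows = []
    for dec in decisions:
        rows.append(
            {
                "filter": dec.label,
                "origin": format(dec.unit.origin, f"0{n_founders}b"),
            }
        )
    frame = pd.DataFrame(rows, columns=["filter", "origin"])
    report = (
        frame.groupby(["filter", "origin"]).size().reset_index(name="fragments")
        if len(frame)
        else pd.DataFrame(columns=["filter", "origin", "fragments"])
    )
    total = int(report["fragments"].sum()) if len(report) else 0
    report["percent"] = 100.0 * report["fragments"] / total if total else 0.0
    if report_path:
        with open(report_path, "w") as fh:
            report.to_csv(fh, sep="\t", index=False)
            fh.write(f"#total_fragment_sets\t{total}\n")
    return report
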