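"""Single-reference pipeline: parent-of-origin by diagnostic allele counting.

The traditional pipeline aligns everything to the standard reference and
assigns each read's origin afterward by looking up known allelic differences
between the founder strains: every diagnostic SNP position covered by an
aligned (M) base increments the count of each founder whose allele the read
base matches.  The read is labeled with the founder holding the strictly
greatest count; zero or tied counts give "can't tell".  Each read is treated
independently, even when paired.  This module exists as the comparison
arm for the multi-alignment pipeline's origin labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import pysam

from pseudopipe.mod_format import ModFile

__all__ = [
    "CANT_TELL",
    "DiagnosticSnpTable",
    "AlleleLabel",
    "diagnostic_table_from_mods",
    "annotate_origin_by_alleles",
    "tabulate_label_comparison",
]

CANT_TELL = "cant_tell"


@dataclass
class DiagnosticSnpTable:
    """Founder alleles at positions where at least two founders disagree.

    ``alleles[(chrom, pos)]`` holds one single-base allele per founder, at
    0-based reference positions.  Positions where all founders carry the same
    base are uninformative and are not stored.
    """

    n_founders: int
    alleles: dict[tuple[str, int], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, al in self.alleles.items():
            if len(al) != self.n_founders:
                raise ValueError(f"position {key} has {len(al)} alleles, expected {self.n_founders}")
            if len(set(al)) < 2:
                raise ValueError(f"position {key} is not diagnostic: alleles {al}")

    def positions_on(self, chrom: str) -> list[int]:
        return sorted(p for c, p in self.alleles if c == chrom)


def diagnostic_table_from_mods(
    mods: Sequence[ModFile], reference: Mapping[str, str]
) -> DiagnosticSnpTable:
    """Derive the diagnostic SNP table from the founders' s-instructions.

    A founder's allele at a substituted position is the s-instruction's ALT;
    founders without a substitution there carry the reference base.  Only
    positions with ≥2 distinct alleles among the founders are kept (a shared
    ALT distinguishes both founders from the reference but not from each
    other, so it cannot resolve origin).
    """
    n = len(mods)
    subs: list[dict[tuple[str, int], str]] = []
    for mod in mods:
        table = {
            (t.chrom, t.pos): t.payload[1]
            for t in mod.instructions
            if t.kind == "s"
        }
        subs.append(table)
    alleles: dict[tuple[str, int], tuple[str, ...]] = {}
    for key in set().union(*subs) if subs else set():
        chrom, pos = key
        ref_base = reference[chrom][pos].upper()
        al = tuple(subs[k].get(key, ref_base) for k in range(n))
        if len(set(al)) >= 2:
            alleles[key] = al
    return DiagnosticSnpTable(n_founders=n, alleles=alleles)


@dataclass
class AlleleLabel:
    """Per-read origin call with the supporting per-founder allele counts."""

    label: str
    counts: tuple[int, ...]


def annotate_origin_by_alleles(
    rec: pysam.AlignedSegment, table: DiagnosticSnpTable
) -> AlleleLabel:
    """Count founder alleles under one reference-aligned record and label it.

    Only M-aligned bases are consulted: no allele calls inside read
    insertions, and deletions simply skip table positions.  Secondary
    mappings should be excluded by the caller (the single-reference pipeline
    discards multi-mapped reads).
    """
    counts = [0] * table.n_founders
    if rec.is_unmapped:
        return AlleleLabel(CANT_TELL, tuple(counts))
    chrom = rec.reference_name
    seq = rec.query_sequence or ""
    for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
        al = table.alleles.get((chrom, rpos))
        if al is None:
            continue
        base = seq[qpos].upper()
        for k, founder_base in enumerate(al):
            if base == founder_base:
                counts[k] += 1
    best = max(counts)
    if best == 0 or counts.count(best) > 1:
        return AlleleLabel(CANT_TELL, tuple(counts))
    return AlleleLabel(f"founder_{counts.index(best)}", tuple(counts))


def tabulate_label_comparison(
    baseline_labels: Mapping[str, str],
    merge_labels: Mapping[str, str],
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cross-tabulate two per-fragment labelings as percentages.

    Rows are the multi-alignment labels, columns the single-reference
    labels; cells are fragment percentages of the shared universe and sum
    to 100.  Raises if the two labelings cover different fragments.
    """
    if set(baseline_labels) != set(merge_labels):
        only_b = set(baseline_labels) - set(merge_labels)
        only_m = set(merge_labels) - set(baseline_labels)
        raise ValueError(
            f"fragment universes differ: {len(only_b)} only in baseline, "
            f"{len(only_m)} only in merge"
        )
    names = sorted(baseline_labels)
    frame = pd.DataFrame(
        {
            "merge": [merge_labels[n] for n in names],
            "baseline": [baseline_labels[n] for n in names],
        }
    )
    if categories is None:
        categories = sorted(set(frame["merge"]) | set(frame["baseline"]))
    tab = pd.crosstab(frame["merge"], frame["baseline"])
    tab = tab.reindex(index=categories, columns=categories, fill_value=0)
    return 100.0 * tab / len(names)
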