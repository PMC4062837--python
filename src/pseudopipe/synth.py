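"""Seeded desk-scale fixtures: reference, founder variants, F1 reads with truth.

The generator emulates the data regime of an F1 hybrid RNA/DNA-seq
experiment with two (or N) inbred founders: a random reference, per-founder
variant sets (SNPs plus short indels), and error-bearing reads drawn from the
founder pseudogenomes.  Because the real aligner is deliberately out of
scope, each read is emitted with its *truth* pseudogenome alignment (all-M,
plus an N gap in intron mode), and with candidate placements on the other
founders' pseudogenomes obtained by projecting the truth locus across
coordinate systems and accepting it when the sequence matches within an
end-to-end mismatch budget — which is what an aligner would report there.
Every stage of the pipeline is therefore testable against known truth
without any external tool.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from pseudopipe.mod_format import ModFile, ModInstruction
from pseudopipe.pseudogenome import (
    GapReport,
    PseudogenomeBuild,
    build_pseudogenome,
    project_position,
)

__all__ = [
    "SimConfig",
    "SimRead",
    "SimFragment",
    "SimResult",
    "generate_reference",
    "generate_founder_variants",
    "simulate_f1_reads",
    "evaluate_origin_labels",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Rates are per source base.  Defaults emulate a wild-derived inbred mouse
    founder against the reference: roughly 1 SNP per 140 bases genome-wide in
    the strains this pipeline targets is scaled here to ``snp_rate`` 0.007,
    with indels an order of magnitude rarer and geometrically short (mean 3).
    Reads are 100 bp with a small uniform base error rate typical of Illumina
    data.
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: {"chr1": 10000})
    n_founders: int = 2
    snp_rate: float = 0.007
    ins_rate: float = 0.0007
    del_rate: float = 0.0007
    indel_mean_len: float = 3.0
    read_length: int = 100
    paired: bool = False
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    coverage: float = 4.0
    base_error_rate: float = 0.002
    intron_rate: float = 0.0
    intron_mean_len: float = 200.0
    max_mismatch_frac: float = 0.06  # aligner end-to-end tolerance

    def __post_init__(self) -> None:
        for name in ("snp_rate", "ins_rate", "del_rate", "base_error_rate", "intron_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length <= 0 or self.indel_mean_len <= 0:
            raise ValueError("lengths must be positive")

    @property
    def mismatch_budget(self) -> int:
        return max(2, int(round(self.max_mismatch_frac * self.read_length)))


def _rng(cfg: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, *stream])


def generate_reference(cfg: SimConfig) -> dict[str, str]:
    """I.i.d. uniform ACGT sequences of the configured lengths."""
    rng = _rng(cfg, 1)
    out = {}
    for chrom, length in cfg.chrom_lengths.items():
        out[chrom] = _BASES[rng.integers(4, size=length)].tobytes().decode()
    return out


def generate_founder_variants(
    cfg: SimConfig, reference: Mapping[str, str]
) -> list[ModFile]:
    """One MOD file per founder: non-overlapping SNPs and short indels.

    Variant sites are drawn per base; indel lengths are geometric with the
    configured mean; a deletion of length k is decomposed into k single-base
    d-instructions.
    """
    mods = []
    p_any = cfg.snp_rate + cfg.ins_rate + cfg.del_rate
    for founder in range(cfg.n_founders):
        rng = _rng(cfg, 2, founder)
        instructions: list[ModInstruction] = []
        for chrom, seq in reference.items():
            length = len(seq)
            pos = 0
            while pos < length:
                u = rng.random()
                if u >= p_any:
                    pos += 1
                    continue
                if u < cfg.snp_rate:
                    ref_base = seq[pos]
                    choices = [b for b in "ACGT" if b != ref_base]
                    alt = choices[int(rng.integers(3))]
                    instructions.append(ModInstruction("s", chrom, pos, (ref_base, alt)))
                    pos += 1
                elif u < cfg.snp_rate + cfg.ins_rate:
                    k = int(rng.geometric(1.0 / cfg.indel_mean_len))
                    payload = _BASES[rng.integers(4, size=k)].tobytes().decode()
                    instructions.append(ModInstruction("i", chrom, pos, payload))
                    pos += 2  # leave the anchor and one spacer untouched
                else:
                    k = int(min(rng.geometric(1.0 / cfg.indel_mean_len), length - pos))
                    for j in range(k):
                        instructions.append(ModInstruction("d", chrom, pos + j, seq[pos + j]))
                    pos += k + 1
        mods.append(
            ModFile(
                header={
                    "version": "1.0",
                    "source": "reference",
                    "destination": f"founder_{founder}",
                },
                instructions=instructions,
            )
        )
    return mods


@dataclass
class SimRead:
    """One sequenced end with its truth alignment and candidate placements."""

    name: str
    end: int  # 0 single, 1 first, 2 second
    founder: int
    chrom: str
    seq: str  # genome-sense, as stored in SAM
    is_reverse: bool
    true_start: int  # pseudogenome coordinate on the true founder
    true_cigar: str
    ref_start: int
    ref_end: int
    n_errors: int
    # founder index -> (pseudogenome start, mismatches vs that pseudogenome)
    placements: dict[int, tuple[int, int]] = field(default_factory=dict)


@dataclass
class SimFragment:
    name: str
    founder: int
    reads: list[SimRead]


@dataclass
class SimResult:
    config: SimConfig
    builds: list[PseudogenomeBuild]
    fragments: list[SimFragment]

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": rd.name,
                "end": rd.end,
                "founder": fr.founder,
                "chrom": rd.chrom,
                "true_start": rd.true_start,
                "true_cigar": rd.true_cigar,
                "ref_start": rd.ref_start,
                "ref_end": rd.ref_end,
                "n_errors": rd.n_errors,
            }
            for fr in self.fragments
            for rd in fr.reads
        ]
        return pd.DataFrame(rows)

    def truth_founders(self) -> dict[str, int]:
        return {fr.name: fr.founder for fr in self.fragments}

    def write_fastq(self, path: str) -> None:
        with open(path, "w") as fh:
            for fr in self.fragments:
                for rd in fr.reads:
                    seq = _revcomp(rd.seq) if rd.is_reverse else rd.seq
                    suffix = f"/{rd.end}" if rd.end else ""
                    fh.write(f"@{rd.name}{suffix}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_truth_tsv(self, path: str) -> None:
        self.truth_frame().to_csv(path, sep="\t", index=False)

    def founder_header(self, founder: int) -> pysam.AlignmentHeader:
        build = self.builds[founder]
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "queryname"},
                "SQ": [
                    {"SN": chrom, "LN": len(seq)}
                    for chrom, seq in build.sequences.items()
                ],
            }
        )

    def write_founder_sam(self, founder: int, path: str) -> int:
        """Write the simulated alignment file against one pseudogenome.

        Contains the truth records of reads drawn from this founder plus the
        projected candidate placements of the other founders' reads; this is
        the stand-in for what an aligner would report, name-sorted.
        """
        header = self.founder_header(founder)
        n = 0
        mode = "wb" if str(path).endswith(".bam") else "w"
        with pysam.AlignmentFile(path, mode, header=header) as out:
            for fr in self.fragments:
                placed = [rd for rd in fr.reads if founder in rd.placements]
                proper = len(placed) == 2 and self.config.paired
                for rd in placed:
                    start, nm = rd.placements[founder]
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = rd.name
                    rec.reference_name = rd.chrom
                    rec.reference_start = start
                    rec.mapping_quality = 60
                    rec.query_sequence = rd.seq
                    rec.query_qualities = pysam.qualitystring_to_array("I" * len(rd.seq))
                    cigar = (
                        rd.true_cigar
                        if founder == fr.founder
                        else f"{len(rd.seq)}M"
                    )
                    rec.cigarstring = cigar
                    flag = 0
                    if rd.end:
                        flag |= 0x1 | (0x40 if rd.end == 1 else 0x80)
                    if rd.is_reverse:
                        flag |= 0x10
                    if proper:
                        flag |= 0x2
                        mate = next(r for r in placed if r is not rd)
                        if mate.is_reverse:
                            flag |= 0x20
                    rec.flag = flag
                    if proper:
                        mate = next(r for r in placed if r is not rd)
                        rec.next_reference_name = mate.chrom
                        rec.next_reference_start = mate.placements[founder][0]
                    rec.set_tag("NM", nm, "i")
                    out.write(rec)
                    n += 1
        return n


def _project_to_founder(
    build_from: PseudogenomeBuild,
    build_to: PseudogenomeBuild,
    chrom: str,
    pos: int,
) -> int:
    """Project a pseudogenome position to another founder via the reference."""
    p = project_position(build_from.region_map, chrom, pos, "dst2src")
    if isinstance(p, GapReport):
        p = p.right
    rm_to = build_to.region_map
    if p >= rm_to.src_lengths[chrom]:
        return rm_to.dst_lengths[chrom]
    q = project_position(rm_to, chrom, p, "src2dst")
    if isinstance(q, GapReport):
        q = q.right
    return q


def _project_ref(build: PseudogenomeBuild, chrom: str, pos: int) -> int:
    p = project_position(build.region_map, chrom, pos, "dst2src")
    return p.right if isinstance(p, GapReport) else p


def simulate_f1_reads(
    cfg: SimConfig,
    builds: Sequence[PseudogenomeBuild],
    mode: str = "f1",
) -> SimResult:
    """Draw fragments from the founder pseudogenomes with planted errors.

    ``mode`` is ``"f1"`` (each fragment from a Bernoulli(1/2) founder — or
    uniform over N founders) or ``"inbred:<k>"`` (all fragments from founder
    k; the negative-control design, where any fragment the merge assigns
    exclusively to another founder is a mislabel).
    """
    n_founders = len(builds)
    if mode == "f1":
        founder_of = None
    elif mode.startswith("inbred:"):
        founder_of = int(mode.split(":", 1)[1])
        if not 0 <= founder_of < n_founders:
            raise ValueError(f"founder index in {mode!r} out of range")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rng = _rng(cfg, 3)
    rl = cfg.read_length
    budget = cfg.mismatch_budget
    total_bases = sum(cfg.chrom_lengths.values())
    reads_per_fragment = 2 if cfg.paired else 1
    n_fragments = max(1, int(cfg.coverage * total_bases / (rl * reads_per_fragment)))
    chroms = list(cfg.chrom_lengths)

    for b in builds:
        for chrom in chroms:
            if len(b.sequences[chrom]) < max(rl + 1, int(cfg.fragment_mean) + 1):
                raise ValueError(
                    f"chromosome {chrom} too short for read length {rl} "
                    f"(pseudogenome length {len(b.sequences[chrom])})"
                )

    weights = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    fragments: list[SimFragment] = []
    for i in range(n_fragments):
        name = f"sim{i:08d}"
        founder = founder_of if founder_of is not None else int(rng.integers(n_founders))
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pseudo = builds[founder].sequences[chrom]
        reads: list[SimRead] = []
        if not cfg.paired:
            intron = cfg.intron_rate > 0 and rng.random() < cfg.intron_rate
            if intron:
                gap = max(10, int(rng.geometric(1.0 / cfg.intron_mean_len)))
                a = int(rng.integers(10, rl - 9))
                span = rl + gap
                start = int(rng.integers(0, len(pseudo) - span))
                seq = pseudo[start : start + a] + pseudo[start + a + gap : start + span]
                cigar = f"{a}M{gap}N{rl - a}M"
            else:
                start = int(rng.integers(0, len(pseudo) - rl + 1))
                seq = pseudo[start : start + rl]
                cigar = f"{rl}M"
            reads.append(
                _make_read(cfg, rng, builds, name, 0, founder, chrom, seq, start, cigar, False, intron)
            )
        else:
            flen = int(np.clip(rng.normal(cfg.fragment_mean, cfg.fragment_sd), 2 * rl, None))
            flen = min(flen, len(pseudo) - 1)
            start = int(rng.integers(0, len(pseudo) - flen + 1))
            s1 = start
            s2 = start + flen - rl
            reads.append(
                _make_read(cfg, rng, builds, name, 1, founder, chrom,
                           pseudo[s1 : s1 + rl], s1, f"{rl}M", False, False)
            )
            reads.append(
                _make_read(cfg, rng, builds, name, 2, founder, chrom,
                           pseudo[s2 : s2 + rl], s2, f"{rl}M", True, False)
            )
        fragments.append(SimFragment(name=name, founder=founder, reads=reads))
    return SimResult(config=cfg, builds=list(builds), fragments=fragments)


def _make_read(
    cfg: SimConfig,
    rng: np.random.Generator,
    builds: Sequence[PseudogenomeBuild],
    name: str,
    end: int,
    founder: int,
    chrom: str,
    seq: str,
    start: int,
    cigar: str,
    is_reverse: bool,
    intron: bool,
) -> SimRead:
    budget = cfg.mismatch_budget
    # plant sequencing errors (genome-sense; always a true mismatch)
    bases = list(seq)
    n_err = int(rng.binomial(len(bases), cfg.base_error_rate))
    err_pos = rng.choice(len(bases), size=n_err, replace=False) if n_err else []
    for p in err_pos:
        cur = bases[p]
        alts = [b for b in "ACGT" if b != cur]
        bases[p] = alts[int(rng.integers(3))]
    seq = "".join(bases)

    span = sum(int(n) for n, op in re.findall(r"(\d+)([MN])", cigar))
    ref_start = _project_ref(builds[founder], chrom, start)
    last = project_position(builds[founder].region_map, chrom, start + span - 1, "dst2src")
    ref_end = (last.left if isinstance(last, GapReport) else last) + 1

    placements: dict[int, tuple[int, int]] = {}
    if n_err <= budget:
        placements[founder] = (start, n_err)
    if not intron:
        rl = len(seq)
        for g in range(len(builds)):
            if g == founder:
                continue
            cand = _project_to_founder(builds[founder], builds[g], chrom, start)
            target = builds[g].sequences[chrom]
            if cand < 0 or cand + rl > len(target):
                continue
            window = target[cand : cand + rl]
            mism = sum(1 for a, b in zip(seq, window) if a != b)
            if mism <= budget:
                placements[g] = (cand, mism)
    return SimRead(
        name=name,
        end=end,
        founder=founder,
        chrom=chrom,
        seq=seq,
        is_reverse=is_reverse,
        true_start=start,
        true_cigar=cigar,
        ref_start=ref_start,
        ref_end=ref_end,
        n_errors=n_err,
        placements=placements,
    )


def evaluate_origin_labels(
    merged_path: str,
    truth_founders: Mapping[str, int],
    n_founders: int = 2,
    origin_tag: str = "po",
    filter_tag: str = "ft",
) -> dict:
    """Score the merged output against truth fragment origins.

    Returns a confusion matrix (truth founder × assigned category), the
    exclusive-mislabel rate (fraction of fragments assigned exclusively to a
    single wrong founder), per-founder exclusive counts, and the filter
    distribution.
    """
    assigned: dict[str, int] = {}
    filters: dict[str, str] = {}
    with pysam.AlignmentFile(merged_path, check_sq=False) as af:
        for rec in af:
            name = rec.query_name
            if name not in truth_founders:
                raise KeyError(f"read {name!r} in merged output missing from truth")
            if name not in assigned:
                assigned[name] = rec.get_tag(origin_tag)
                filters[name] = rec.get_tag(filter_tag)

    def category(flag: int) -> str:
        if flag.bit_count() > 1:
            return "both" if n_founders == 2 else "multiple"
        return f"founder_{flag.bit_length() - 1}"

    rows = []
    mislabeled = 0
    for name, truth in truth_founders.items():
        if name not in assigned:
            rows.append({"truth": f"founder_{truth}", "assigned": "unmapped"})
            continue
        flag = assigned[name]
        cat = category(flag)
        rows.append({"truth": f"founder_{truth}", "assigned": cat})
        if flag.bit_count() == 1 and flag != (1 << truth):
            mislabeled += 1
    frame = pd.DataFrame(rows)
    confusion = pd.crosstab(frame["truth"], frame["assigned"])
    n_total = len(truth_founders)
    filter_counts = pd.Series(filters).value_counts().to_dict() if filters else {}
    exclusive = {
        f"founder_{k}": int(
            sum(1 for f in assigned.values() if f == (1 << k))
        )
        for k in range(n_founders)
    }
    return {
        "confusion": confusion,
        "mislabel_rate": mislabeled / n_total if n_total else 0.0,
        "exclusive_counts": exclusive,
        "filter_counts": filter_counts,
        "n_fragments": n_total,
        "n_merged": len(assigned),
    }
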