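# Methods

## Edit-transcript model

A founder genome is modeled as the image of the reference under an ordered
list of atomic edits (a MOD file). Three instruction kinds suffice: `s`
(substitute one base), `d` (delete one base), `i` (insert a sequence after an
anchor position). Atomicity — no instruction references more than one source
position — makes the transcript trivially sortable and composable; the cost
is redundancy in multi-base deletions (a k-base deletion is k `d`
instructions), which gzip recovers. All positions are 0-based in the source
coordinate system; the VCF converter owns the 1→0 shift. An insertion before
the first base anchors at −1. At one position `s` and `d` are mutually
exclusive; `d` followed by `i` at the same anchor expresses a replacement and
is applied delete-then-insert; multiple `i` at one anchor concatenate in file
order. Instructions sort by `(chrom, pos, d<s<i)`.

Complex variants (inversions, translocations, tandem duplications) are
representable as coupled `d`/`i` sets but no dedicated converter is provided;
the VCF converter handles biallelic SNPs and anchored indels only, skipping
and counting everything else.

## Pseudogenome and region map

`build_pseudogenome` applies the sorted instructions in a single
left-to-right pass. In strict mode (default) the source base stated by each
`s`/`d` must match the reference — a silent mismatch would corrupt every
downstream liftover, so leniency is opt-in and counted.

The same scan yields the region map: maximal blocks
`(src_start, dst_start, length)` of 1:1 correspondence. Substitutions
preserve correspondence and do not break blocks; each `d` and `i` ends the
open block. Gap contents are implied by consecutive block coordinates
(deleted bases = src gap, inserted bases = dst gap), so the map is fully
described by the block list plus the two chromosome lengths, serialized as a
sidecar TSV next to the pseudogenome FASTA. Two conservation identities are
enforced on every build: `matched + deleted = len(src)` and
`matched + inserted = len(dst)`.

`project_position` is a `bisect` over block starts (the map is strictly
monotone in both systems). A position inside a gap returns a `GapReport`
carrying the flanking counterpart coordinates rather than a number, because
the caller — not the map — must decide an anchoring policy.

Pseudogenome chromosomes keep the reference names, so BAM headers stay
name-compatible across the pipeline; the destination identity lives in FASTA
header comments and the MOD checksum.

## Alignment liftover

`rewrite_cigar` walks the alignment's pseudogenome footprint left to right,
maintaining the current block index and the source coordinate just past the
last emitted reference-consuming op:

* footprint bases inside blocks keep their op (M, D, N);
* destination-only (inserted) bases under M become I — the read carries
  sequence the reference lacks — and vanish under D/N;
* when consecutive reference-consuming emissions are discontiguous in source
  space, the skipped reference-only (deleted) bases are spliced in as D, or
  as N when the crossing happens inside an intron gap. An intron's new
  length is therefore the source span of its destination span: deletions
  inside the intron lengthen the reference N, insertions shorten it.

Normalization then merges adjacent same-type ops, strips leading/trailing
D/N (adjusting the start), and converts edge I runs to soft clips. A read
starting inside inserted sequence is anchored to the first reference base at
or after the insertion with the overhanging bases soft-clipped — a policy
choice, preserved losslessly in the `op`/`oc` tags; a read lying entirely
within inserted sequence is returned unmapped with reason tag
`ur:Z:insertion`. Read-length conservation (ΣM+I+S invariant) holds by
construction and is asserted in tests.

The emitted record's NM is recomputed against the reference (mismatching M
bases + I bases + D bases); the pseudogenome-space CIGAR, edit distance and
0-based start are preserved as `oc`/`om`/`op`, with `og` recording which
pseudogenome the record came from. MAPQ, flags, sequence and qualities pass
through; the mate start of a paired record is projected through the map, and
TLEN passes through unchanged (the merge stage never consults it).

## Merging and the filter cascade

Inputs are N name-sorted remapped files, streamed through a k-way heap merge
keyed on read name (plain string order; each input is checked for
monotonicity). Within one file and name, properly-paired mates are linked
into paired units — pairs never span input files, so no cross-founder
chimeras — and orphaned proper flags are demoted to single ends.

Each unit's score is regenerated from the preserved tags: mismatches =
`om` − (I+D bases in `oc`); score = −6·mismatch − Σ(5 + 3·gap_length) over
I/D runs, i.e. a Bowtie2-like end-to-end scheme with a perfect match at 0.
All three penalties are configurable. Base qualities are deliberately not
consulted: after liftover only the CIGAR/NM summary of the original
alignment is available, and the comparison only needs to be consistent
across pseudogenomes, not absolutely calibrated.

Units identical on the five criteria (reference start, reference CIGAR,
pairing flag, fragment-end flag, score) collapse with origin flags OR-ed;
equal-coordinate units with different scores stay distinct — the score
difference is exactly the informative-allele signal. If any paired unit
exists all unpaired units are dropped; otherwise the two ends are filtered
independently. The cascade is:

* **Unique** — singleton set: output, label U.
* **Quality** — unique maximum regenerated score: output, label Q;
  non-maximal units are dropped, ties pass on.
* **Pileup** (optional, off by default, two-pass) — among tied units,
  strictly greatest mean depth over the unit's M/D reference span, computed
  from Unique+Quality decisions only; ties and all-zero depth fall through.
* **Random** — uniform choice, label R. The RNG is
  `default_rng([seed, crc32(name), end])`, so the decision is a pure
  function of the seed, the read name and the candidate identities —
  independent of input file order and of how many fragments were processed
  before (paired preference being absolute means a paired unit is never
  outscored by an unpaired one, by design).

One output unit per surviving set; tags `po` (origin bit-set, bit k ⇔
founder k) and `ft` (U/Q/P/R). The report counts fragment-set decisions per
(filter × origin) with percentages summing to 100.

## Single-reference baseline

The comparison arm reproduces the traditional annotation: from the founders'
`s` instructions build the diagnostic table (founder allele = its ALT, else
the reference base; positions where all founders agree are dropped since a
shared ALT separates founders from the reference but not from each other).
Only M-aligned bases are counted — no calls inside read insertions,
deletions skip positions — with no base-quality threshold by default. Each
read is labeled independently, pairs included, mirroring how allele-query
pipelines operate; multi-mapped (secondary) records are excluded by the CLI.

## Synthetic data: what it emulates and what it does not

The generator draws an i.i.d. uniform ACGT reference, then per-founder
variants by a per-base draw: SNP rate 0.007 (the order of divergence of
wild-derived mouse founder strains from the reference), insertion and
deletion rates 0.0007, indel lengths geometric with mean 3 (short indels
dominate real call sets). Reads are 100 bp, base error rate 0.002, coverage
a test-level choice (2–6× on 5–15 kb toy chromosomes keeps every suite and
the acceptance script in seconds on one CPU). F1 mode draws each fragment's
founder Bernoulli(1/2); inbred mode pins it — the negative-control design in
which any fragment merged exclusively to the other founder is a measured
mislabel.

Because running a real aligner is out of scope, each read carries its truth
alignment (all-M at its sampled pseudogenome locus; aM nN bM in intron mode)
and a *projected* candidate on each other founder: the truth locus is mapped
own-pseudogenome → reference → other pseudogenome, and the candidate is
emitted iff the read matches there within an end-to-end budget of
round(0.06·L) mismatches — mimicking an aligner's tolerance at the locus an
aligner would find. This exercises the merge logic faithfully but is not a
genome-wide search: spurious distant multi-mappings, mapping errors,
chimeras, quality-dependent errors and expression structure (isoforms,
coverage peaks) are not modeled. Passing tests therefore demonstrate
coordinate-arithmetic correctness and decision-logic correctness under known
truth, not performance on real libraries. All generators are byte-
deterministic per seed; every RNG stream is keyed off the single config
seed.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere internally; 1-based
  conversions happen only at VCF ingestion and inside htslib's text SAM
  rendering.
* All scores and distances are exact integers; no floating-point tolerances
  exist anywhere in the decision path. The only floating comparison
  (Pileup mean depth) uses exact sums over integer arrays.
* Zero-length blocks are never emitted; empty chromosomes yield empty block
  lists and reject all projections.
* Random-filter candidates are put in canonical key order before drawing, so
  ties break identically regardless of discovery order.
* `collect_fragment_sets` tolerates two read lengths per name (paired ends)
  and rejects more; duplicate candidates within one input collapse in the
  same identical-merge that handles cross-input duplicates.

## Known limitations

* MNPs, non-anchored complex indels and symbolic ALTs are skipped at VCF
  conversion (counted, warned), not decomposed.
* The liftover does not left-normalize indels; a read whose aligner chose a
  different gap placement than the MOD file may remap with an equivalent but
  differently-placed gap.
* TLEN is not recomputed after liftover.
* The Pileup filter buffers unresolved fragments in memory and allocates
  per-chromosome depth arrays; it targets desk-scale and gene-panel-scale
  data, not whole-genome BAMs.
* N-founder merging (N ≤ 30) is implemented and tested at N=3 for flag
  arithmetic, but the simulator's cross-placement model is pairwise.
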