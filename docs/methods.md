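# Methods

## Data model

Input is Illumina-style paired-end RNA-Seq: two Casava 1.8 FASTQ files
(Phred+33), mate 1 and mate 2 of each cDNA fragment in separate files,
sharing an identity code (the header token before the first space; the mate
number is the first Casava field after it, with a fallback to trailing
`/1`/`/2`). Reads are nucleotide strings over {A,C,G,T,N} with per-base
Phred scores Q = −10·log₁₀ p_error, clamped to [0, 60]. N is treated
conservatively throughout: it never matches, never mismatches, and never
votes.

Coordinates are 0-based half-open internally; all user-facing reports are
1-based inclusive.

## Grooming

Each read is trimmed to its longest contiguous run of positions with
Q ≥ `min_phred` (default 20, i.e. error probability < 1%) and kept only if
that run has ≥ `min_run` bases (default 80). Ties between equal-length runs
go to the 5'-most run. This trim-then-filter reading (rather than keeping
whole reads that merely contain a qualifying run) is what produces output
read lengths in the 80–100 range from 100-base input, and makes grooming
idempotent. Mates are groomed independently; the pairing stage tolerates
missing mates.

## Discovery

A match between a read and the heterologous template is a **maximal run of
contiguous identical bases** of length ≥ `min_contig_match` (default 18,
sensible range 15–20), in either orientation, ungapped, with no mismatches
inside the run. The contract is exact equivalence with a brute-force
all-offsets scan; the implementation uses a k-mer index of the template
(k = `min_contig_match`) with maximal extension purely as an optimization,
and the equivalence is enforced by test. Template intervals can be masked;
masked positions never seed or extend a run. When a read yields several
maximal runs, all are reported and downstream stages use the longest
(ties: smallest offset, forward first).

Coding-frame screening removes reads whose aligned span contains a stop
codon (TAA/TAG/TGA) in the template's reading frame, counting only complete
codons fully inside the span — a stop straddling the span edge or out of
frame does not reject a read.

Initial assembly is greedy perfect-overlap merging: repeatedly join the
pair of pieces with the longest exact suffix–prefix overlap ≥ `min_overlap`
(default 21; containment counts as an overlap of the contained length),
until no join is possible. Tie-breaks (earliest read identity, forward
orientation first) make the result deterministic. No mismatches and no
indels are ever tolerated at this stage.

## Walking

Walk parameters and defaults: `min_overlap` 30, `max_errors` 2,
`min_ragged` 5, `max_find` 50, `max_add` 50, direction 3'→5' first (so
that the second walk needs no coordinate shifting of previously matched
reads), optional `target_length`/`max_steps` caps.

Each step scans the complete groomed files for reads (either orientation)
that align ungapped to the growing end with ≥ `min_overlap` overlapping
bases, ≤ `max_errors` mismatches within the overlap, and ≥ 1 base of
extension beyond the end. For each read only its best placement is kept
(longest overlap, then fewest mismatches). Candidates are ranked by overlap
length descending, then mismatches ascending, then identity, truncated to
`max_find` and added up to `max_add`. The scan is implemented as a
vectorised per-diagonal comparison of all reads at once (reads are encoded
into a byte matrix once per walk); a 3'→5' step runs the same right-end
scan on the reverse-complemented consensus and maps placements back. The
ranking is a total order (identity+mate is unique), so the result is
independent of file order and of any internal batching — this determinism
contract replaces thread-level parallelism as an observable behavior, and
`--threads` never changes an output byte.

**Melding.** Extension proceeds outward one position at a time past the old
end. A position is called only while the number of covering reads (over all
retained matches, not just this step's) with a called base is ≥
`min_ragged`; the first failing position stops the step (the ragged-end
rule, read as position-by-position coverage gating). The called base is the
one with the greatest sum of Phred scores among covering reads; ties go to
the base covered by more reads, then alphabetical. The consensus quality at
a new position is min(40, round(winning Phred sum / covering reads)) — the
vote itself only needs weights proportional to Q, but a concrete output
quality requires a convention, and this one stays inside the Casava range.
Interior consensus positions are never modified during walking; melded
reads are retained in the DataSet with their alignment records.

A 3'→5' walk prepends; all placements and the cumulative **origin shift**
are updated. After both walks, the earlier walk's DataSet is shifted by the
origin shift and the sets are combined: duplicates (same identity and mate)
keep the lower-mismatch copy, and the full-length consensus is re-melded
position by position — terminal positions require ≥ `min_ragged` covering
reads, interior positions ≥ 1 (a zero-coverage interior position is written
as N). Every combined read is re-verified against the re-melded consensus;
a read whose mismatches exceed max(`max_errors`, 20% of its aligned span)
raises an integrity error naming it. The fraction bound, rather than
`max_errors` alone, is used because a read accepted during walking is
vetted only over its overlap span and can legitimately carry further
sequencing errors in its extension region, whereas a genuine coordinate
inconsistency disagrees at ~75% of positions.

After every step the full state — consensus record first, then every
contributing read with a `TW pos=<1-based placement> strand=<F|R> mm=<n>`
header annotation — is written to `step_<n>.tw.fastq`. Checkpoints are
sorted (placement, identity, mate) and therefore byte-reproducible; a walk
restarted from any checkpoint reproduces the same subsequent checkpoints.

## Pairs and fragment sizes

Duplicate removal keeps one match per (identity, mate) — fewest mismatches,
then smallest offset — and is idempotent. Missing mates are found by a
single pass through the groomed files (identity present, mate absent) and
placed with the discovery matcher followed by full-span verification at
the walk error tolerance; unplaceable mates are reported, not added. The
pair sort orders pairs by the primary mate's placement (the mate that
entered the DataSet first) with its partner adjacent. Fragment length is
the inclusive outer span of the two aligned reads, so two mates aligned to
the same window give fragment length = read length — the observed floor.
Pairs aligned in improper orientation (same strand, or facing outward) are
flagged but still counted in the statistics.

## Reporting

The pileup assigns each read's orientation-resolved aligned bases to the
consensus columns it covers (depth = Σ base counts, conserved against
Σ aligned spans). Variant calling reports any column whose second most
frequent called base has ≥ `min_minor_count` supporting reads (default 5,
matching the ragged minimum; the threshold is an absolute count, so calls
are monotone in it). Given a reading frame, the consequence of
substituting the minor base is classified silent/missense/nonsense by
direct codon translation. ORF finding scans the three forward frames (and
the reverse strand on request) for the longest complete ATG…stop interval,
ties to the 5'-most start; translation uses the standard genetic code with
`*` for stop. Alignment rendering is fixed-width text (consensus line
first, reads offset-aligned beneath, `.` for agreement, the read base for a
mismatch) or a stacked-digit depth histogram — the informational content of
the original pixel displays without a GUI.

## Simulator

The generator emulates the targeted use case so every stage can be scored
against ground truth:

- transcript: random sequence at the requested GC fraction with one
  embedded complete reading frame (default ~80% of the transcript, ATG …
  stop, no internal stops; an in-frame stop is planted immediately upstream
  of the ATG so the embedded frame is exactly the longest ORF);
- fragments: lengths truncated-normal with mean 219, sd 50, floored at 100
  (the floor reproduces the observed minimum fragment size, which equals
  the read length), uniform starts; mate 1 is the first 100 bases of the
  fragment, mate 2 the reverse complement of the last 100;
- qualities: flat `high_q` (default 37) with a small fraction of positions
  (default 0.005) at `low_q` (default 12). The low-quality fraction was set
  so that default datasets survive grooming at roughly the rate seen in
  real Illumina data of this vintage (~70–80% of reads); at 0.02 the
  80-contiguous-base rule would discard three quarters of all reads;
- errors: substitution-only, per base with probability 10^(−Q/10) —
  matching Phred semantics and the method's ungapped world;
- variants: biallelic sites mixed per fragment at a given allele fraction
  (default experiments use 0.5, emulating a heterozygous locus).

Everything derives from one integer seed (two independent child streams
for transcript and reads); identical parameters give byte-identical files.
The truth table records each read's origin, strand, allele and injected
error positions.

Not modelled — and therefore not exercised by passing tests: positional
quality decay, indel errors, adapter/contaminant sequence, expression
mixtures of multiple homologous transcripts, and splice variants. Real
data can also defeat the ungapped model in low-complexity or repetitive
regions; the method was never intended for those cases.

## Problem sizes and numerical choices

The test and acceptance workloads are sized to the method's behavior, not
to the paper's 9×10⁷-pair dataset: recovery experiments use 1,500–1,700
base transcripts at ~50× raw depth (several hundred fragments), which
exercises every code path — seed discovery, dozens of walk steps in both
directions, origin shifting, combination, mate recovery — in seconds per
replicate. The parameter-recovery suite runs 20 seeded replicates at flat
Q20 (1% per-base errors) and requires exact consensus/reference identity
over the covered interval wherever simulated depth ≥ 5. Completeness at
the extreme transcript ends is limited by *admissible* coverage, not raw
coverage: a position covered by exactly 5 reads is not guaranteed 5 reads
that each pass the ≤ 2-mismatch overlap test under a 1% error rate, so the
walk may stop a few bases short of the last depth-5 position while never
calling a wrong base; the recovery contract is therefore exactness over
the covered interval plus a span check (≥ 95% of the depth-≥5 region),
and the acceptance script reports recovery identity measured the same way.

Other conventions chosen where the design was open: weighted-vote ties go
to read count then alphabetical base; candidate ranking at the `max_find`
cap is overlap length, then mismatches, then identity; equal-length
grooming runs prefer the 5' run; discovery reports all maximal runs and
downstream uses the longest; the checkpoint annotation dialect
(`TW pos= strand= mm=`) is this package's own.
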