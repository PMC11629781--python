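# Methods

## Matching model

A degenerate primer denotes a set of concrete sequences: each IUPAC
symbol stands for its base set (W = {A,T}, Y = {C,T}, ...), and inosine
(I) for {A,C,G,T}. Position *p* of a primer matches template base *t*
iff the two symbols' sets intersect, so the mismatch total of a primer
against a concrete region equals the minimum Hamming distance between
the region and any expansion of the primer. The test suite verifies
this equivalence against brute-force enumeration for primers with up to
2^12 expansions.

Inosine pairs are not equally stable (I-C > I-A > I-T ≈ I-G), but we
adopt the conservative convention of scoring them all as matches: a
mismatch count is then a lower bound on duplex disruption. The
`InosinePolicy.RANKED` mode exposes the ordering as report metadata and
never changes a verdict. No thermodynamic (melting-temperature/nearest-
neighbour) modelling is attempted; counts and positions are the model.

Templates are case-folded and U→T mapped before matching (cDNA-derived
sequences). A template N (or any template ambiguity) intersects every
primer code and is therefore never counted as a mismatch; profiles flag
such positions as `ambiguous-template` so reports can exclude them.
This rule is our decision for user-supplied FASTA — the transcribed
reference tables contain concrete bases only.

## Coordinates, terminal window and risk

Primer positions are 1-based 5′→3′; region offsets are 0-based
half-open. The 3′-terminal window is the last `TERMINAL_WINDOW = 3`
positions (24–26 of a 26-nt primer, anchored on "the third nucleotide
from the 3′ end"); "internal" means positions 1..L−3. The window size
is configurable because the experimental literature it summarizes does
not use a single convention.

Risk levels (precedence top-down, each rationale citing its rule):

| level | trigger |
|---|---|
| failure_likely | ≥ 4 internal mismatches, or ≥ 3 total with a 3′-terminal hit |
| severe | any 3′-terminal mismatch, or ≥ 3 internal mismatches |
| reduced | 1–2 internal mismatches (~1/10 misdetection) |
| negligible | none |

The boundaries interpolate between separately published results
(1–2 internal ≈ 1/10; ≥3 with terminal > 1/1000; 5–6 internal ≈ 13–22×
and 79–108× fewer amplifications; ≥4 internal prevents amplification in
most cases); they are a classification aid, not a kinetic prediction,
and the classification is monotone: adding a mismatch never lowers the
level.

## Binding-site location

The locator scans every full-length window of the template on the
relevant strand and keeps the minimum-mismatch window, leftmost on
ties (deterministic output). Reverse primers are compared 5′→3′
against the reverse-complemented template. If the best window exceeds
`max_scan_mismatches` (default 10 for a 26-nt primer) the site is
reported as not found with the best score attached, rather than
guessed. The O(nL) scan is exact; at desk scale (hundreds of
sequences, L = 26) there is nothing to gain from a seeded heuristic.

## Lineage grouping

Variable positions are columns with more than one concrete base (N
contributes no variability). Sequences identical at all variable
positions form a lineage; per-lineage totals are computed on one
representative after asserting that members can only differ at the
supplied positions. Labels are roman numerals in first-seen order;
arbitrary inputs are first sorted by sequence id so that shuffling
relabels but never recounts, while fixture rows keep their documented
table order. Percent summaries round half-up to integers (43/247 →
17%). `p_distance` excludes non-concrete sites from its denominator.

## Transcribed datasets and conserved fill

The three reference datasets ship as variable-position state tables
(`src/minicoi/data/*.tsv`): each row lists the concrete bases at the
non-conserved positions of the 26-nt forward-primer region, plus
multiplicity (*O. similis*: 14 lineages summing to 247 sequences) or
accession/species (tunicates), plus the originally reported per-primer
mismatch totals, which the tests use purely as an oracle — the package
always recomputes them. Unlisted positions are conserved and filled
with the lexicographically smallest base in the intersection of both
forward primers' allowed sets at that position: arbitrary but
deterministic, and provably mismatch-neutral, so every recomputed
profile depends only on the transcribed states (property-tested as
fill-invariance). One transcription correction is documented in the
data file: the *O. albicans* single-primer G is placed at position 18,
the only placement consistent with both its published totals and its
single-primer markup.

The registry reserves `oithona_nana_partial` and
`microsetella_norvegica_partial` but ships no rows: their haplotype
bases were published only in supplementary figures that are not
transcribable here.

## Poly-T inserts

Appendicularian poly-T inserts are homopolymeric, intron-like runs in
the coding strand (poly-A on the other strand), excised at the mRNA
level; published lengths are tens to hundreds of nt, mean ≈ 140 and up
to ~500 nt in *O. dioica* (~1 500 nt in *O. vanhoeffeni*). Detection
reports all maximal runs of T with length ≥ `min_len`; the default
floor of 10 nt operationalizes "tens of consecutive Ts" and is our
stated convention — no published cutoff separates a biological insert
from ordinary AT-rich COI sequence. Raising the floor is monotone
(never adds runs). An optional mode also scans the complement for
poly-A, mapped back to coding-strand coordinates.

## Synthetic templates

`synthesize_fasta` embeds each binding region in a template shaped like
a real amplicon context: random flank (default 80 nt), forward region,
spacer (default 60 nt, split around an optional poly-T insert), an
exact concrete target of the chosen reverse primer, and a trailing
flank. Insert lengths are drawn as a shifted geometric — floor 10 nt,
untruncated mean equal to the configured 140 nt, truncated at 500 nt —
matching the published length scale while guaranteeing that a generated
insert is at least at the detector's default floor. Everything is
deterministic under the seed, and each record's layout is recorded in
its FASTA description.

What the generator does *not* emulate: sequencing error, indels in the
primer region, within-lineage variation outside the variable positions,
codon structure of the flanks, and the real-data failure of Sanger/
Illumina reads to span an insert. Passing tests therefore demonstrate
the correctness of the arithmetic and the pipeline plumbing on
faithfully reconstructed primer regions — not the recall of the locator
on noisy field data.

## Review outcome table

The packaged `study_outcomes.tsv` carries one row per study × taxon ×
basin for the 30 reviewed studies (fail / bias / NA / OK, with the
study's primer combination). Misperformance rows, study codes, taxa
and basins are transcribed from the review's synthesis tables; the
per-study combination membership uses every study-code superscript
printed with the per-combination summaries plus the row counts
(3/2/17/4/4). The remaining degrees of freedom — which unlisted
studies used Leray–Geller, which two of them scored *O. similis* OK,
the identity of the fourth Leray XT and Other studies, and basins of
studies without a misperformance entry — are fixed arbitrarily but
consistently with every published tally, and the file documents itself
as such. Distinct-study counting deduplicates by study code, so a
study observed in two basins is one study. Uniqueness is enforced on
(study, taxon, basin, combination) because the same study×taxon pair
legitimately occurs in two basins.

## Known limitations

- The risk categories order qualitative thresholds; they do not predict
  amplification efficiency.
- Lineage reconstruction realizes one region per lineage: any real
  within-lineage variation outside the variable positions is invisible
  (immaterial to the shipped statistics, relevant to user FASTA).
- Reverse-primer performance is covered by construction-based
  properties only; the public *O. similis* alignment leaves the
  reverse region almost entirely uncovered, and no per-sequence
  reverse-region table was published.
- The locator assumes substitution-only divergence in the binding
  region (no indels), which holds for the protein-coding COI primer
  sites it targets.
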