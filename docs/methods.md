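# Methods

This note documents the models and procedures implemented in `mibird`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make every result
deterministic.

## Primer binding model

A primer is compared to a binding site position by position, in primer
orientation. Two frames are supported and are related by complementation:

* **sense frame** (default): the site string is the reference subsequence
  read in primer orientation, so a Watson-Crick match is simple base
  equality. The G/T wobble rule becomes: primer `G` tolerates site `A`
  (whose annealing-template partner is `T`, giving a G:T pair) and primer
  `T` tolerates site `C` (template `G`).
* **template frame**: the site is the annealing-template strand aligned
  against the primer; a match is complementarity and the wobble pairs are
  the literal G:T and T:G.

Wobble acceptance is on by default, since primer/panel agreement statistics
are most informative under the pairing rule the primers were designed to
exploit; every comparison can be re-run with `wobble=False`. Ambiguity
codes in references count as a match when the required base is inside the
code's expansion (N matches everything); this "lenient" mode avoids
inflating mismatch counts on low-quality references and can be switched to
strict identity. The 3'-terminal mismatch flag inspects exactly the last
primer base by default (`terminal_window=1`), configurable because "the 3'
end" has no universally agreed width.

Mismatch histograms bin panel members at 0, 1, 2, 3, 4 and >=5 mismatches.
Panel members without a locatable site are reported separately rather than
forced into the >=5 bin (a flag restores the latter behaviour), because the
two conventions answer different questions and neither is canonical.

### Melting temperature

Tm is computed from nearest-neighbour thermodynamics: stack enthalpies and
entropies are summed with terminal initiation terms (unified duplex
parameters, SantaLucia 1998), the entropy is salt-corrected by
0.368 (N-1) ln[Na+], and

    Tm = 1000 dH / (dS + R ln(C_T / 4)) - 273.15

for a non-self-complementary oligo. Defaults: 50 mM monovalent salt,
0.5 uM total strand concentration. Both the parameter tables and the
conditions are injectable through `ThermoParams`, because published Tm
values for the same oligo differ by several degrees across parameter sets
and salt corrections; no claim is made that these defaults reproduce any
particular online calculator. The implementation is independent of
Biopython's `Tm_NN`, which the test suite uses as a cross-check (agreement
to < 0.01 degC under identical parameters).

## In-silico PCR

Primer sites are located by exhaustive substitution-only window scan:
every window of core length on the appropriate strand is scored (forward
primers on the sense strand, reverse primers on the reverse complement),
the window with the fewest mismatches wins, ties go to the leftmost window
on the scanned strand, and a site qualifies only within `max_mismatch`
(default 5). Exhaustive scanning is exact and cheap at desk scale (cores
<= 30 nt, references a few hundred bases to ~20 kb); no heuristic seeding
is needed. Indels inside a primer site are deliberately not modelled: a
site disrupted by indels or deleted outright simply fails to qualify, and
the record is excluded from insert analyses with an explicit reason —
matching the practice of dropping references whose primer regions are
deleted.

The insert is the region strictly *between* the two primer sites (primer
regions excluded); the expected insert length for the shipped primers is
about 171 bp, against a total amplicon of insert + 23 + 27 bp.

## Taxonomic resolution

Dissimilarity between two inserts is the Levenshtein edit distance
(minimum substitutions + insertions + deletions), computed with `edlib`;
the test suite checks it against an independent dynamic-programming
implementation and the metric axioms. The inter-species table covers all
C(n,2) unordered pairs of distinct species (duplicate species are collapsed
to the first record, with a warning). For the genus-level table the
literal definition — pairs of species belonging to different genera — is
the default; because published genus-level totals are sometimes computed
otherwise, two alternative statistics are exposed behind `genus_mode`
(congeneric pairs; per-genus-pair minimum distance) without any claim about
which convention a given publication used.

## Read pipeline

Stage order and defaults (all in `ProcessingParams`):

| stage | rule | default |
|---|---|---|
| quality trim | longest contiguous run with every base >= cutoff, ties leftmost | Q10 |
| merge | innie overlap minimising mismatch fraction, ties -> longest | min overlap 10 bp, max mismatch fraction 0.25 |
| filter | drop reads with N or out-of-window length | window = expected amplicon +/- 20% |
| primer removal | anchored, substitutions only, both ends | <= 3 mismatches per primer |
| dereplication | exact counts; representatives >= 10 reads; rescue at >= 99% identity | 10 reads, 0.99 |

Notes on the open choices:

* **Trimming rule.** Tail trimmers differ in their exact segment rule; the
  longest all-above-cutoff segment is deterministic, testable by
  enumeration, and equals the common behaviour on reads whose quality only
  decays at the tail. Q10 corresponds to a 10% per-base error ceiling.
* **Merging.** Only the 10 bp minimum overlap is a protocol constant; the
  0.25 mismatch-fraction ceiling is the conventional default of overlap
  mergers. Consensus takes the higher-quality base at each disagreeing
  position (forward wins ties) and retains the per-position maximum
  quality.
* **Length window.** "Unusual length" has no published bound; the window
  defaults to the expected amplicon length (primers + 171 bp insert)
  +/- 20% and is configurable.
* **Rescue identity.** Identity is 1 - d/max(|a|,|b|) with d the edit
  distance, so "one or two nucleotide differences" on a ~171 bp insert
  clears 99% exactly as intended; a substitution-only (Hamming) mode exists
  for equal-length variants. Rare sequences that rescue nowhere are
  discarded *but counted*, so read totals are conserved at every stage.
* **Random-base spacer.** Library constructs may carry a 6-base random
  spacer ahead of the forward primer; `leading_bases` (default 0, i.e.
  spacer already removed by the sequencer pipeline) allows an anchored
  match after up to that many extra bases at either end.

Dereplication output is invariant to input order: representatives are
ranked by (count, sequence) and rare variants join the representative with
the highest identity, ties broken by representative count then sequence.

## Assignment

Hits are collapsed to the best record per species, then ranked by bit
score, ties by reliability score L/(m+1), then accession. The top hit must
clear >= 97% identity and E <= 1e-5 or the query is unassigned. The ratio
score divides the top species' reliability by that of the best hit to a
*different* species (not the second record overall, which may be another
sequence of the same species). Exact ties between different species —
equal bit score and equal reliability — produce an `ambiguous` status
listing the candidates, an explicit extension for a case the thresholds
alone cannot resolve. No minimum ratio score is enforced by default (it is
an indicator, not a filter); `min_ratio_score` turns it into one.

The built-in aligner is an exact local (Smith-Waterman) alignment via
Biopython's `PairwiseAligner` on both strands with match +2 / mismatch -3,
gap open 5 / extend 2 — a desk-scale stand-in for a database search, exact
rather than heuristic. Its E-value uses the ungapped Karlin-Altschul
formula E = K m n exp(-lambda S): lambda is solved numerically from the
score matrix at uniform base composition; K defaults to 0.41 and is
configurable. These E-values are single-subject estimates adequate for
thresholding at 1e-5 (a 171 bp exact match scores far below 1e-50), not
database-calibrated statistics; E-values read from external tabular files
are taken as-is.

## Detection tables

Assigned reads accumulate into (sample, species) cells; unassigned and
ambiguous reads into a per-sample `non_target` bucket. Every
assigned-but-unexpected species keeps its own column *and* counts toward
the non-target fraction of the percentage:

    percent_target = 100 * reads of expected species / total reads,

with total = assigned + unassigned, reported to one decimal (raw fractions
retained internally). Samples with zero reads report a missing percentage
rather than 0/0. Control screening lists any species with nonzero counts
in a negative control; an empty list is a pass.

## The synthetic-data generator

`simulate_panel` builds mitogenome-like records — random padding (120 bp a
side), the forward primer site, a random insert (171 bp), the reverse
primer site, more padding — with planted per-record site plans: a chosen
number of substitutions (wobble-compatible or explicitly
wobble-incompatible) or outright deletion of a primer region. Inserts are
drawn i.i.d. and every pairwise edit distance is verified against the
configured minimum (default 6, the resolution margin the survey analyses
assume) before emission; offenders are redrawn. Each record is then
checked against the locator itself — planted sites must be found at the
planted interval with the planted mismatch count and deleted sites must
come back absent — with padding redrawn on the rare spurious match, so the
truth sidecar is guaranteed consistent with the analysis code paths.

`simulate_survey` emits 2 x 150 bp paired-end reads as the two ends of the
full amplicon (primer cores + insert), with i.i.d. substitution errors
(default rate 0.001, a MiSeq-like average), constant Phred 35 qualities and
a 5-base Q6 tail (so the Q10 trimmer has realistic work to do), and
exact per-species read counts by default (a stochastic mode sits behind the
same seed). Negative controls receive no biological reads.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: PCR amplification bias and chimeras, indel
sequencing errors (substitution-only by default, so identity arithmetic in
dereplication is exact), quality-dependent error rates, contamination and
tag-jumping, real phylogenetic correlation among inserts (random inserts
are far more divergent than congeneric 12S sequences, so real genus-level
resolution is harder than the simulated one), and reference-database
incompleteness — misidentification driven by missing references is outside
the simulator's world.

All randomness flows through `numpy.random.default_rng` with integer seeds
derived from the config seed, so identical configs give byte-identical
panels, reads and FASTQ files across platforms.

## Problem sizes

The test suite and the acceptance script run entirely on generated data at
desk scale, chosen as the smallest sizes that exercise each property:
panels of 12-80 records for unit tests, the full 407/410-record panel for
the pair-count and exclusion identities (82,621 pairwise distances compute
in under a second via edlib), and a 16-sample survey (12 single-species
cages, one mixed walk-through cage, three negative controls; 40 read pairs
per cage) for end-to-end recovery.

## Known limitations

* Substitution-only site location: a primer site with a single internal
  indel is reported absent rather than shifted.
* The built-in aligner is O(|q| x |s|) per pair — fine for hundreds of
  references, not for genome-scale databases; real surveys should feed
  external tabular hits into `parse_hit_table`.
* Tm values depend on the injected parameter set; cross-calculator
  agreement is not asserted.
* Multi-rank (e.g. lowest-common-ancestor) assignment is out of scope; the
  assigner calls species or nothing.
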