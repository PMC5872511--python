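# Methods

## Model of L1 amplification and decay

The package treats an L1 family as a set of genomic copies produced by a
highly homogeneous group of progenitor ("source") elements over an
amplification window. After insertion a copy evolves neutrally, so its
divergence from the family consensus measures its age along one lineage,
and the pairwise divergence between two copies accumulates along both
lineages since their insertions. This is what licenses the two clock
conversions used throughout:

* pairwise divergence *d* → family age `d / (2 r)`;
* divergence-from-consensus *d* → single-copy age `d / r`.

The per-lineage rate defaults to `r = 0.13 %/Myr`, the value calibrated on
the 56-Myr Hippomorpha/Ceratomorpha split; `CalibratedClock` also accepts a
`(calibration_divergence, t_cal)` anchor and derives
`r = 100·d_cal / (2 t_cal)` so that anchoring on `2 r t_cal` returns `r`
exactly.

Divergence estimation uses the Tamura–Nei (TN93) correction (closed form,
validated to 10 decimals against `ape::dist.dna`), restricted to a
~600 bp 3'-end window (end of ORF2 + 3'UTR) with two kinds of columns
masked on the consensus: CpG dinucleotides (both positions) and polypurine
runs of ≥5 consecutive A/G inside the 3'UTR. The run length is not pinned
down by prior work; 5 is the package default and is configurable. Masking
is a pure function of the consensus, hence idempotent. The SE of a family's
mean pairwise divergence is the standard error over pair distances (pairs
are not independent, so this is the usual first-order approximation).

## Forward simulator (`simgenome`)

The simulator is the source of ground truth for every stage, and its
defaults are the study conditions used by the tests:

* substitution process: single-parameter equal-rate (Jukes–Cantor-style)
  model applied per site with the closed-form probability
  `3/4·(1−exp(−4rt/3))`; optionally multiplied at CpG sites of the input
  sequence. Analytically checkable; no Gillespie machinery at these sizes.
* insertion times: uniform within the family's `[t_end, t_start]` window.
* truncation: 5'-only; truncated copies lose `100 + Geometric(mean
  truncation_scale − 100)` bp, capped so ≥200 bp of the 3' end survives.
  The 100-bp floor keeps "retains the very 5' end" equivalent to "full
  length", which the 5'UTR-based full-length copy-number estimator relies
  on (target-primed reverse transcription either completes or aborts well
  short of the 5' end). The geometric shape itself is a stand-in; no
  empirical truncation-length distribution was imposed.
* `p_full_length` defaults to 0.1 (the ~10% full-length fraction typical of
  successful families).
* placement: uniform over background positions, never nested or
  overlapping, so harvest ground truth is unambiguous. The background is a
  random sequence at 42% GC.
* `demo_scenario` builds multi-family scenarios from one ancestral element:
  family bodies at ~8% pairwise divergence (configurable), GC-rich ~2 kb
  promoters shared within a promoter type and non-homologous between types,
  staggered 4-Myr amplification windows 6 Myr apart, and a genome sized so
  elements make up about a third of it. Progenitor ORFs are kept stop-free
  (active elements encode functional proteins); the copies then decay
  freely.

What the simulator does **not** emulate: indels and internal deletions
after insertion, nesting of inserts, insertion-site preference, gene
conversion, segmental duplication, or assembly artifacts. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under clean neutral decay, not robustness to every property of
real assemblies.

## Harvest

The RT anchor is a ~250-aa protein query matched by seeded (4-mer word)
local Smith–Waterman under BLOSUM62 against all six reading frames;
overlapping hits merge keeping the best score. The default score threshold
is 35% of the query self-score, calibrated on simulation so that RT domains
~30% diverged at the DNA level are still found while 100-kb random genomes
yield nothing. Fragments of ±7000 bp are annotated by edit-distance infix
alignment of ORF1/ORF2/3'UTR exemplars, anchored around the RT hit so that
neighbouring inserts inside the fragment cannot be mis-assigned; ORF motifs
may match over a 3'-anchored 60% of the exemplar (near-full-length
elements). A candidate is an element iff ORF1, ORF2 and 3'UTR are present
in order. The 5'UTR is the sequence upstream of ORF1 capped at 2500 bp,
minus any upstream stretch matching a body/3'UTR motif in either
orientation (the tail of a neighbouring insert is not promoter). The
element's exact 5' boundary is unknowable without promoter homology; this
is inherent to the harvest design, and downstream promoter work accounts
for it.

Coordinates are 0-based half-open internally; human-readable tables print
1-based inclusive spans.

## Family classification

Promoter grouping is single linkage on a block identity: the homologous
block of the shorter 5'UTR is chained right-to-left from the ORF1 junction
(breaking at >100 bp homology gaps, so stray flank homology does not count)
and scored by edit identity as an infix of the longer; elements link at
identity ≥0.70 over ≥50% of the shorter 5'UTR. Heavily truncated elements
whose retained promoter falls below the coverage bar end up in singleton
classes and drop out — consistent with restricting family definition to
elements with identifiable promoters.

Within a class, families are cut from a neighbor-joining tree (vectorised
Studier–Keppler NJ, cross-checked against scikit-bio) of the 3'-terminus
region under TN93 distances, with column-resampled bootstrap support.
The cut selects maximal clades that are (a) supported at ≥70% and (b)
internally homogeneous — mean within-clade distance at most half the mean
distance to everything outside — then refines each chosen clade
recursively, because the mean-based ratio can let a union of two tight
families slip through. If nothing qualifies the class is one family.
Candidate families are re-checked on a 5'-promoter-region tree (flagged,
not dropped, when their members scatter), and clusters below 10 members
are dropped, mirroring the >10-copies rule for deriving reliable consensus
sequences. These thresholds are heuristic by necessity — the underlying
family concept is qualitative — and all are exposed as parameters.

Consensus sequences are stitched from two parts: the promoter consensus
uses only members whose promoter block covers ≥90% of the class's
promoter length (estimated as the second-largest block, so a member's
self-match cannot inflate it), and the body consensus (ORF1→3'UTR) uses
every member, column-majority with >50%-gap columns removed and ties
broken A<C<G<T. Feature spans are projected from a reference member.

Naming is a pure function of (genome label, promoter type, age rank):
shared families are "Perissodactyla", Roman numerals rank families of the
same label and promoter type by ascending age, ties broken by descending
copy number (logged).

## Recombination scanning

MaxChi: within every sequence triplet, sites where the triplet is variable
are split by a moving boundary; the 2×2 chi-square of
(match/mismatch)×(left/right) is maximized over boundaries with at least
`window` (default 50) variable sites and ≥300 columns (or L/4) on each
side — only large-segment events are considered. Significance comes from
permuting the variable-site order (default 1000 permutations, seeded) with
Bonferroni correction across all triplet-pair tests, which controls the
familywise error (measured ≤ α on recombination-free simulations). A
consequence worth knowing: with T tests an effect can only be declared if
`permutations > T/α`, so larger panels need more permutations (the
seven-consensus analyses here use 5000). The reported position is the
1-based column of the last variable site on the 5' side, with the equally
optimal plateau alongside, and is also projected into ORF2-local
coordinates; on a plateau wider than one column the true boundary is only
localized to that interval.

Bootscan: per sliding window (default 200 bp, step 20), column-resampled
bootstrap NJ trees; the curve is the fraction of replicates in which each
reference is the target's nearest neighbour by patristic distance.

Verification builds bootstrap-annotated NJ trees from the columns on each
side of a candidate breakpoint; the report is verified when one of the
implicated sequences has a different, ≥70%-supported sister group on the
two sides. NJ is used throughout (rather than mixing in likelihood
methods): it is fast, self-contained and adequate at the divergences
involved; sides shorter than 200 columns skip verification.

The recombination acceptance check runs on a synthetic consensus panel
(`synthetic_orf2_consensus_panel`) constructed with the published case's
lineage structure — two clades, an outgroup, and a chimera switching
parents at ORF2 position 2207 — because the real consensus set is
supplementary data of the original study and is not redistributed here.
The panel places informative sites immediately at the breakpoint, so exact
localization tests the machinery rather than the local density of
substitutions.

## Copy numbers and sequence features

Genomic fragments are found by 12-mer seed matching against each family
consensus (both strands), chained along diagonals (≥5 seeds, ≥100 bp span,
≥0.02 seeds/bp — the density floor kills single-shared-word decoys),
assigned to the single best family on >50% overlap (ties alphabetical,
logged) and merged within 50 bp on the same strand. Two full-length
estimates per family: `n_fl_utr` counts fragments reaching the consensus
5' end within 50 bp (a retained 5'UTR implies the insertion was complete);
`n_fl_complete` counts harvested elements whose own fragment reaches the
promoter head and whose 5'UTR region contains it — reconciling both
estimates through the same fragment table keeps the invariant
`n_fl_complete ≤ n_fl_utr ≤ n_total`, which is asserted on every run.

Tandem repeats in promoters are detected by a self-match periodicity scan
(match profile at each candidate period, smoothed over one period,
edge-trimmed to exact-match runs, harmonics suppressed) — a deliberately
simple scorer, since only unit length and copy number are consumed. The
LPR motif matrix scores each of the four short ORF1 motifs present when
≥80% of its ancestral columns are non-gap and ≥80% identical; an
all-gap region flags the family "unknown".

dN/dS is the counting estimate: per-codon synonymous/nonsynonymous site
fractions with mutations to stop codons excluded from the possible
changes, pathway-averaged difference counts (pathways through stops
skipped), Jukes–Cantor correction of pS and pN, averaged over all pairs.
The stop-exclusion convention is chosen deliberately: it is coherent with
coding sequence whose frames stay open, and neutral simulation under that
constraint gives ω = 1 in expectation. Biopython's implementation (which
counts stop mutations as nonsynonymous) serves as an independent oracle on
codons where the conventions provably coincide. Sequences with premature
stops are excluded with a warning by default; `on_stop="mask"` instead
skips offending codons pairwise, which suits consensus sequences whose
rare majority-call errors produce isolated stops. ω is undefined (None)
when ds = 0.

## Pipeline, determinism and problem sizes

The CLI stages communicate through plain files (FASTA/TSV/newick/JSON), so
`run-all` is byte-identical to running the subcommands in order, and a
fixed seed makes the whole pipeline byte-reproducible (every stochastic
stage derives its seed from the run seed). The manifest records the seed
and every threshold that affects output. An empty genome yields empty
tables and exit code 0.

Test and acceptance workloads use desk-scale problem sizes chosen to make
the statistical criteria decidable: 20 recovery scenarios of 2–6 families
× 14 members with 100 bootstrap replicates; age recovery at 60 members;
rate comparison at 500 loci per family × 2 families; 50 chimera and 100
null replicates at 1000 permutations; copy-number recovery at 1000 inserts
in a 12-Mb genome; 100 dN/dS replicates at 300 codons. Full-size analyses
(thousands of elements, 1000 bootstrap replicates) use the same code paths
with the corresponding parameters.

## Known limitations

* No indel evolution after insertion: the aligner stack (mafft for MSA,
  edit-distance projection onto consensus coordinates) is exercised only
  by boundary jitter, not by real indel patterns.
* Family cutting assumes families are tighter within than between; a
  continuously evolving single lineage (master-gene drift) violates this
  and would be over- or under-split depending on thresholds.
* The breakpoint position on sparse alignments is only localized to a
  plateau between informative sites.
* Copy-number scanning assumes ≤~25% divergence between insert and its
  family consensus (seed density floor); older fragments fall through and
  would need a sensitive-mode scan.
* Real-genome quantities that depend on the horse and rhinoceros
  assemblies (absolute family counts, Table-style copy numbers, real
  promoter GC ranges) are out of reach of the simulator and are not
  asserted anywhere; the tests cover recovery of known simulated truth
  plus the published values that are pure functions of printed inputs.
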