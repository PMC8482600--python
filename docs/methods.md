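# Methods

This note documents the models, thresholds and design choices behind
`spacerscope`, and what the synthetic benchmarks do and do not demonstrate.

## Matching and the two-step filter

The internal matcher is a seed-and-extend search: exact `seed_word`-mer
seeding (default 10 nt, both strands), candidate windows of the spacer
length plus a ±3 band around each seed diagonal, and gapped extension with
edlib in infix mode. `n_ident` is the number of identical aligned columns
of the best extension; `matched_fraction = n_ident / spacer_length` is the
single metric combining identity and coverage that all filtering uses.
Gaps count as non-identities. Overlapping hits (≥ 50%) of one spacer on one
subject collapse to the best one before "unique protospacer" counting. The
matcher does not compute e-values or bitscores and does not reproduce any
particular BLAST HSP set; pre-computed tabular hits can be ingested instead
(`read_hit_table`, requiring the `qlen` and `nident` extension columns).
A consequence of exact 10-mer seeding is that a target with substitutions
spaced closer than the word size is invisible — the same sensitivity floor
a word-size-10 BLAST search has.

Filtering order: spacers shorter than 27 nt are removed; hits inside CRISPR
arrays are removed; step 1 keeps matched fraction > 0.90; step 2 keeps
fraction > 0.80 on subjects with a step-1 hit from a *different* spacer of
the same genus. Step 2 therefore cannot introduce subjects absent from
step 1, and the kept set shrinks monotonically as the step-1 threshold
rises — both are asserted as properties in the tests.

### The array-hit test

A hit is in-array when the spacer's repeat aligns to either 23-nt flank
with **more than 13 identities**. We score this with a global alignment
(match +1, mismatch 0, gap open −3, gap extend −3) with **free end gaps**,
thresholding the net score (identities minus interior gap costs). Two
deliberate choices:

* *Free end gaps.* The repeat (~29 nt) is longer than the flank window
  (23 nt); with penalized end gaps and a zero mismatch score the optimizer
  buys spurious matches with gaps, and a *random* repeat/flank pair reaches
  a median of 12–13 "identities" — the 13 threshold would then discard
  roughly half of all genuine hits. With free end gaps and the net-score
  statistic, random pairs score ~9 (false-flag rate ≈ 0.7% measured over
  both repeat orientations) while a true repeat prefix in the flank scores
  ~23. This is the only reading under which the 13-identity threshold
  separates arrays from noise, and for the typical gapless optimum the
  score *is* the count of identical nucleotides.
* *Both orientations.* The repeat and its reverse complement are both
  tested, since arrays occur on either genomic strand.

## Repeat clustering and subtypes

Greedy incremental clustering: repeats sorted by descending abundance then
lexicographically; each joins the first cluster whose representative has
equal length and ≥ 90% global identity, else founds one. The canonical
ordering makes the partition independent of input order. Repeats are
clustered in their stored orientation; orientation correction happens
downstream, where a cluster called `reverse` has all its spacers, repeats
and flanks reverse-complemented before PAM calling. Subtype assignment
takes the best reference identity over both orientations with a 74% floor;
ties break toward the lexicographically smaller label.

`global_identity` is identities over alignment length of a global
alignment with the same scoring as above but *penalized* end gaps —
repeats compared for clustering are expected to correspond end-to-end.

## Flank profiles and GC-corrected information content

Each spacer contributes exactly one observation per flank position: its
consensus flank (plurality base over that spacer's kept hits; ties and
all-N positions give N, which is excluded from counting). Identical
consensus-flank pairs within a cluster collapse to one unique protospacer
— this deduplication guards against redundant database records inflating
one protospacer into many observations.

Conservation is relative entropy against a GC-derived background,
`ic_i = Σ_b f_b log2(f_b / p_b)` (0·log 0 ≡ 0), with
`p_A = p_T = (1−GC)/2` and `p_C = p_G = GC/2` where GC is the cluster's
mean spacer GC. Relative entropy was chosen over uniform-background
entropy differences because the correction is defined via expected
nucleotide occurrences; no small-sample correction is applied — the
median-ratio thresholds below already normalize against the noise floor,
which scales as ~3/(2·ln2·n) bits for n observations. The median pools
all 2 × 23 positions of both flanks, including eventual PAM positions.

Thresholds (all config fields):

| quantity | bits | median factor | extra gate |
|---|---|---|---|
| orientation qualifying position | > 0.3 | > 5× | ≥ 2 positions per side |
| PAM position | > 0.5 | > 10× | ≥ 2 positions, ≥ 10 unique protospacers |

Orientation: type I/IV/V PAMs are 5′ (upstream), type II 3′ (downstream);
the qualifying (or higher-scoring, if both qualify) side fixes forward vs
reverse. Type III and unassigned clusters pass through an externally
supplied orientation. Type V is treated as upstream for this purpose.
PAM motifs span from the most distal flagged position to the protospacer
edge; unflagged interior positions render N; flagged positions render the
smallest IUPAC set whose cumulative frequency reaches 0.8, filled in
descending frequency (a documented approximation — how partially conserved
positions map to degenerate codes is not uniquely determined by the data).

Repeat–PAM comparison aligns upstream PAM positions −k…−1 with the last k
repeat bases (downstream with the first k bases of the repeat on the other
side); a position matches when the repeat base lies within the PAM
character's IUPAC set. The crRNA-handle scan looks for ATTGAAAC within the
last 10 nt of the repeat, allowing one mismatch by default.

## Strand bias

One strand call per spacer, on its primary target: nucleotide-database
subjects are preferred over metagenomic ones, then the longest subject,
then the lexicographically smallest id. The protospacer must lie fully
inside exactly one ORF; overlapping-gene and intergenic cases are
undetermined rather than guessed. Strand semantics are anchored to base
pairing: with the array orientation resolved, the crRNA hybridizes the
complement of the strand its sequence matches; when that targeted strand
is the ORF's coding strand the crRNA can also base-pair the mRNA, so
"coding-strand targeting" is synonymous with RNA-targeting capability.
GFF CDS annotations override the internal six-frame scanner (one ORF per
stop, start ∈ {ATG, GTG, TTG}, ≥ 90 nt, bacterial code).

Group bias uses the exact two-sided binomial test at p₀ = 0.5 (the sum of
all outcome probabilities no larger than the observed one), delegated to
`scipy.stats.binomtest`; an exhaustive enumeration oracle in the tests
verifies agreement to 10⁻¹² for all n ≤ 25. Significance is α = 0.01.

## Co-occurrence categories

Arrays link to every cas cluster with edge-to-edge distance strictly below
25 kb on the same accession. "Same PAM" means exact motif equality after
stripping uninformative N at the motif edges; degenerate-code near-matches
never drive a category. Category 3 additionally requires that no *other*
array in the genome links to the cas clusters in question. A genome
satisfying several categories reports the most-shared one (3 > 2 > 1) with
all satisfied categories listed as evidence. Cas cluster intervals,
subtype labels and cas1–cas2 presence are inputs; cas gene detection is
out of scope.

## The synthetic universe

The generator plants the statistical structure the pipeline assumes, with
defaults chosen as the study conditions: 20 repeat clusters × 30 spacers,
32-nt spacers, 29-nt repeats (type I/III repeats end with the ATTGAAAC
handle), 3-nt PAMs at 90% adherence on the subtype's side, alternating
forward/reverse planted orientations, 50% coding fraction, substitution
rate 0.02 per protospacer copy, 1–3 hits per spacer, GC 0.5, 18 decoy
spacers and 12 array-embedded self-hits.

Protospacers are embedded inside stop-free ORFs such that the
spacer-identical strand is the template strand for coding-class spacers.
The 23-nt windows flanking each protospacer are i.i.d. at the target GC —
matching the noise model behind the GC correction — while the rest of the
ORF is stop-free codons at the same GC. The true ORF intervals are written
to GFF3 (planted protospacers may contain in-frame stops, so the internal
scanner is benchmarked on stop-free ORFs separately). Decoys are planted
with exactly 3 or 4 substitutions confined to the first 20 nt (leaving an
intact seed word), re-drawn until the planted matched fraction is realized
under the matcher's own alignment metric and no flank trips the array test
by chance — each decoy therefore exercises the fraction filter and nothing
else. Array-embedded hits place repeat–spacer–repeat cassettes on their
own contigs.

What passing these benchmarks does **not** show: real flanks have
dinucleotide and codon structure the i.i.d. model lacks; real databases
are redundant in ways the one-subject-per-hit layout only gestures at
(dedup is exercised, but not at realistic redundancy); repeat divergence
within real clusters is not limited to ≤ 1 substitution; and decoy hits in
nature are not guaranteed to carry clean seed words. Database-scale
figures (fractions of spacers with hits per genus/subtype, catalog sizes)
depend on CRISPRCasdb and multi-terabase external databases and are out of
scope.

## Numerical and degenerate-input choices

* Positions with no ACGT observation have ic = 0; a cluster with no kept
  hits yields no profile, an undetermined orientation and no PAM call.
* Consensus ties become N and are excluded from profile counts, shrinking
  per-position n rather than biasing frequencies.
* IUPAC input codes other than N are mapped to N on read, with a warning.
* `binomtest` handles the k = n/2 and k ∈ {0, n} edges exactly; p-values
  are never clipped.
* Benchmark problem sizes (200 clusters for PAM recovery, 600 for
  specificity, n = 400 per strand-bias group, 20 × 30 universes) were
  chosen to give the planted effects decisive power while keeping a full
  run in tens of seconds on one CPU. At n = 400 the planted coding
  fractions 0.55 and 0.43 sit near the α = 0.01 binomial power boundary,
  so their significance flag is sampling-dependent by construction; the
  acceptance check asserts recovery of the fraction and the bias
  direction for those two groups, and significance only where the planted
  effect is decisive (0.65 significant, 0.50 not).

## Known limitations

* The matcher is not a BLAST replacement: no e-values, no HSP statistics,
  word-size-10 sensitivity floor.
* PAM calls for type II systems are per repeat cluster by default; real
  type II PAMs can be strain-specific within a repeat cluster (profile
  building accepts any grouping of spacers, so per-genome grouping is
  possible, but Cas9 PID analysis is out of scope).
* The ORF scanner is deliberately simple (longest frame per stop); it is a
  fallback, not a Prodigal substitute, and GFF input takes precedence.
* Orientation and PAM calls for clusters below 10 unique protospacers are
  never attempted; external orientations are taken at face value.
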