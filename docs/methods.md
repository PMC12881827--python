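# Methods

This note documents the generative model, the defaults and the numerical
choices behind `motifgrammar`, in the spirit of the model documentation of
simulation packages like msprime: what is sampled from what, which knobs
matter, and what the package's own validation does and does not show.

## Sampling model

One simulated sequence is produced per *round*. Within a round, draws
happen in a fixed order, each from its own distribution:

1. **Background**: uniform with replacement from the background pool (the
   pool may be smaller than the number of requested sequences).
2. **Instance count** *k*: a fixed user value or Poisson(λ).
3. **Group chain** g₁…g_k: g₁ ~ group marginal; gᵢ₊₁ ~ conditional row of
   gᵢ. The chain is first-order; longer memory is out of scope.
4. **Motifs**: one per group, from the within-group distribution. A motif
   belonging to several groups is the same motif regardless of the path
   that selected it; co-occurrence accounting is by motif id.
5. **Instance strings**: letter *i* ~ PFM column *i*, independently.
6. **Orientation**: Bernoulli(p_forward) per instance; reverse instances
   are written as their reverse complement.
7. **Position**: center (⌊(L−w)/2⌋), integer-uniform over valid starts, or
   a rounded Gaussian centered on the middle placement with configurable
   offset and sd.

Implantation **replaces** background letters rather than splicing, so
sequence length is invariant and BED coordinates, per-position probability
tracks and fixed-length model inputs all stay aligned with the background.

**Overlaps.** Default policy `resample(max_tries=100)`: positions are
redrawn until the instance does not intersect an already-placed one; after
`max_tries` failures the instance is dropped with a warning and counted
(`dropped_instances` in the counts output — kept alongside the eight
entity tallies so no information is lost). The alternative `allow` places
regardless; later instances overwrite earlier letters and the earlier
record is flagged `occluded` — both records are kept, because a
benchmarking consumer may want to know a site was drawn even if partially
overwritten.

**Probability tracks.** Each sequence carries a (length × alphabet)
matrix: the background's generative distribution, overwritten at each
placement by the motif's columns (reversed and letter-complemented on the
minus strand). I.i.d. backgrounds use the analytic background frequencies;
imported, shuffled and Markov backgrounds use the one-hot encoding of
their realized letters, since the true generative distribution of a real
sequence is unknown.

**Seeding.** A single master seed spawns child streams
(`numpy.random.SeedSequence.spawn`): one for backgrounds, one for motifs,
one per round. Results are therefore independent of evaluation order and
bit-reproducible; text floats are printed with 6 significant digits and
the `.npz` writer is deterministic, giving byte-identical bundles for
identical config + seed.

## Motif simulation and information-content control

Motif lengths are integer-uniform on [len_min, len_max]; each PFM column
is an independent Dirichlet(α) draw. Per-position information content is
IC = log₂|Σ| − H(column) in bits with 0·log 0 := 0 (uniform reference);
small symmetric α gives sharp, high-IC columns, large α near-uniform ones.
There is no closed form for E[IC] under Dirichlet(α), so
`calibrate_concentration` bisects in log α on a Monte-Carlo estimate
(20,000 columns by default, fixed internal seed so the objective is a
deterministic monotone function; bracket α ∈ [10⁻⁴, 10⁴], default
tolerance 0.02 bits). Targets outside (0, log₂|Σ|) are rejected.

**Multimers** lay components on a shared axis, each starting where the
previous ended plus its spacing. Positions covered by exactly one
component copy that component's column (weights do not rescale a lone
column); gap positions take the alphabet background distribution, so gaps
are indistinguishable from background; overlapped positions (negative
spacings) take the weight-normalized convex combination of the covering
columns, and all-zero weight over an overlap is an error.

## Backgrounds

The order-*k* background model is a Markov chain fitted by counting
(k+1)-mers with an optional pseudocount: transition row of context *c* ∝
counts + pseudocount; initial context distribution = empirical first
*k*-mers of the training sequences; order 0 is the i.i.d. letter model.
Sampling an unseen context is an error at pseudocount 0 and a uniform draw
otherwise. Markov sample lengths always come from the configured
[len_min, len_max] bounds, not from the training-length distribution.
Imported FASTA is uppercased; soft-masking is not preserved; letters
outside the alphabet are rejected by default or optionally resampled from
the background frequencies. Higher-order shuffling is deliberately not
implemented — tools dedicated to that produce FASTA this package imports.

## Motif file formats

MEME-minimal and JASPAR parsing stand on Biopython. JASPAR counts are
normalized with pseudocount 0; a zero-sum column is an error rather than a
silent uniform. Written MEME files quantize each column to 10⁻⁶ units with
largest-remainder rounding so printed columns sum to exactly 1.000000 and
a write→read round trip reproduces columns to within 10⁻⁶. MEME files
carrying only log-odds matrices are converted to probabilities by softmax
against the declared background (pᵢ ∝ bᵢ·2^sᵢ); this is lossy because
printed log-odds are rounded, and imported PWMs are used only as PFMs for
instance sampling.

## Grammar co-occurrence tables

Four tables fully determine the soft grammar and are written as TSV:
the group conditional P(h|g); the first-draw motif marginal
m(a) = Σ_g P(g)·P(a|g); the consecutive-draw joint
J(a,b) = Σ_{g,h} P(g)·P(a|g)·P(h|g)·P(b|h); and the conditional
C(b|a) = J(a,b)/Σ_b J(a,b). The implementation is three matrix products;
tests check it against an exhaustive enumeration over all (g, a, h, b)
draw paths to 10⁻¹².

## Sequence modification

Edits use 0-based half-open coordinates (BED convention) and preserve
length. `shift_site` writes the site at the shifted interval — the site
wins where old and new intervals overlap — and fills vacated positions
with a fixed letter or background draws; this overwrite-and-fill semantics
is a documented design choice. Batches apply in instruction order;
disjoint-interval batches are order-independent.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` run, at these sizes:

* **Grammar experiment**: 50,000 i.i.d. uniform backgrounds of length 200;
  eight length-10 motifs (α = 1); groups {0,1,2}, {2,3,4,5}, {1,6,7};
  uniform group marginal and within-group tables (the detailed tables of
  the motivating experiment are not published, so uniform defaults are
  used and documented); group conditional 0.8 self / 0.1 each other;
  3 instances per sequence, p_forward 0.5, uniform positions. Checked:
  50,000 sequences out, all 8 motifs and 3 groups used, and every
  shared-group motif pair co-occurring in more sequences than every
  disjoint-group pair.
* **Distribution recovery**: 10,000 sequences; Poisson(λ=2) count mean and
  Bernoulli(0.3) strand fraction within 3 standard errors; uniform
  positions pass a chi-square test at p > 0.001; Gaussian positions
  (sd = 5 on length-200 sequences, where boundary resampling makes
  truncation negligible) recover mean and sd within 3 SE, allowing the
  1/12 variance added by integer rounding.
* **Oracles**: co-occurrence vs enumeration (10⁻¹²); all 24 permutations
  of "ACGT" with multinomial frequencies within 3 SE at n = 24,000;
  Markov fit→sample→fit transition recovery L∞ ≤ 0.02 at 10⁶ letters.
* **Round trips and determinism**: MEME 10⁻⁶; FASTA+BED re-slicing with
  strand; track rows sum to 1 within 10⁻⁶; byte-identical bundles.
* **IC control**: Monte-Carlo E[IC] strictly decreasing over
  α ∈ {0.1, 0.5, 1, 5, 50}; calibration to a 1.0-bit target within
  0.05 bits.

Runtime is linear in the number of sequences (checked qualitatively over
1k/2k/4k).

## What the synthetic data does and does not emulate

Backgrounds are exchangeable and, except in Markov mode, carry no local
composition structure (no CpG islands, repeats or chromatin context);
implanted instances are independent draws from the PFM, so no
instance-level dependencies within a site; the grammar captures
co-occurrence frequency but not distance preferences between
grammar-sampled sites (fixed spacing is modeled separately via multimers).
Passing recovery tests therefore demonstrates correctness of the sampling
machinery and bookkeeping, not realism of the sequences; realism depends
on user-supplied backgrounds and motifs.

## Known limitations

* True latent-state HMM backgrounds are not implemented; the order-*k*
  chain is the intended background model.
* Live motif-database retrieval is out of scope; import is file-based
  (MEME/JASPAR).
* No joint placement optimization: the resample overlap policy is greedy
  per instance and can drop instances in crowded sequences (counted and
  warned, never silent).
* Position tallies in `counts.json` are start coordinates on the output
  sequence; they are comparable across sequences only when lengths match.
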