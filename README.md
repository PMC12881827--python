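# motifgrammar

Lightweight end-to-end simulation of DNA regulatory sequences for
benchmarking motif-analysis and model-explainability tools.

Methods that decipher cis-regulatory grammar — *de novo* motif discovery,
TF-cooperativity analysis, attribution methods for sequence-based deep
learning models — are hard to evaluate on real genomes because the ground
truth is unknown. `motifgrammar` produces fully controlled datasets where
every implanted transcription factor binding site is known: it simulates or
imports binding motifs and background sequences, implants motif instances
following a probabilistic co-occurrence grammar, and writes a complete
ground-truth bundle (FASTA, BED, CSV, JSON counts, MEME motifs,
co-occurrence tables, per-position letter-probability arrays).

## The model

**Motifs.** A motif is a position frequency matrix (PFM): column *i* is a
probability vector **p**ᵢ over the alphabet. Simulated motifs draw each
column from a Dirichlet(α) distribution; the concentration α controls the
expected information content per position, IC = log₂|Σ| + Σₗ pₗ log₂ pₗ
(bits), which decreases monotonically in α. `calibrate_concentration`
inverts this map numerically, so you can ask for "motifs with 1.4 bits per
position" directly. Multimers model TF complexes: component motifs laid out
at fixed (possibly negative) spacings, with weights mixing overlapping
columns.

**Backgrounds.** I.i.d. sequences from configurable letter frequencies,
user FASTA as-is, mononucleotide shuffles, or sequences sampled from an
order-*k* Markov chain fitted to user sequences.

**Grammar.** Motifs belong to groups (possibly several). Per sequence, the
number of instances *k* is fixed or Poisson(λ); the first instance's group
is drawn from the group marginal distribution and each subsequent group
from a conditional distribution P(next group | previous group); the motif
is drawn within the group. Motifs sharing a group therefore co-occur in the
same sequence more often — a *soft* syntax, complementing the *hard*
fixed-spacing syntax of multimers. Orientation is Bernoulli(p_forward)
per instance; positions are center-fixed, uniform, or Gaussian. Insertion
replaces background letters, keeping coordinates and probability tracks
aligned.

**Modification.** Real sequences can be edited directly: mask intervals
(with Ns or any letter), substitute single nucleotides, shift a motif site,
or implant an instance at an exact position — the perturbations used in
model-explainability workflows such as in silico marginalization.

## Worked example

```bash
cat > demo.yaml <<'YAML'
n_sequences: 50
seed: 3
backgrounds: {mode: iid, n: 40, len_min: 100, len_max: 100}
motifs: {n_motifs: 4, len_min: 6, len_max: 8, alpha: 0.5}
grammar:
  groups:
    group_0: [motif_0, motif_1]
    group_1: [motif_1, motif_2, motif_3]
insertion:
  count: {dist: poisson, lam: 2}
  p_forward: 0.4
  position: {dist: uniform}
YAML
motifgrammar simulate --config demo.yaml --outdir out --seed 7
```

prints

```
simulated 50 sequences, 84 motif instances -> out
```

meaning 50 length-100 sequences were generated, with 84 instances of the
four simulated motifs implanted (Poisson(2) per sequence, 40% forward
strand, uniform positions). `out/` then contains `sequences.fasta`,
`instances.bed` (one interval per implanted site with strand),
`details.csv` (sequence, motif, group, instance string, coordinates,
strand, draw order per row), `counts.json` (tallies of every sampled
entity), `motifs.meme`, four `cooccurrence_*.tsv` tables implied by the
grammar, and two `.npz` archives with the per-position letter
probabilities of the final and background sequences. The first rows of
`details.csv`:

```
sequence_id,motif_id,group_id,instance,start,end,strand,draw_index,occluded
sequence_0,motif_2,group_1,TACTTGT,10,17,+,0,False
sequence_1,motif_2,group_1,TATTAAG,41,48,-,0,False
```

The same run with the same seed reproduces every file byte-for-byte.

The library mirrors the CLI (`simulate_motifs`, `simulate_iid`,
`build_grammar`, `run_simulation`, `write_bundle`, `mask_interval`,
`implant_at`, ...) and adds finer control, e.g. exact per-sequence
implantation positions.

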