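# Methods

This note documents the models and conventions implemented in
`repairscape`, the defaults chosen where the underlying analysis left a
choice open, and what the synthetic-data generator does and does not
emulate.

## Outcome representation and canonicalization

An editing outcome is a deletion interval `[del_start, del_end)` plus an
inserted sequence, applied to a stored target sequence (0-based half-open
coordinates; the Cas9 cut is a gap index, `pam_start − 3`, between the 17th
and 18th protospacer bases). Within repeated sequence the same edited
molecule admits several representations; all counting therefore uses a
canonical form.

For an edit with deletion size `L` and insertion size `k` producing edited
sequence `E`, a representation with start `s` is valid iff `E[:s] ==
seq[:s]` and the suffixes beyond the replaced block agree. Writing `p`/`q`
for the longest common prefix/suffix of `seq` and `E`, the valid starts are
exactly the contiguous interval

```
max(0, len(E) − k − q)  ≤  s  ≤  min(p, len(seq) − L),
```

so the canonical (left-most) representative and the full equivalence class
are computed in O(len) without enumeration. Canonicalization is idempotent,
and the left-most convention is the standard indel-normalization choice;
any fixed choice preserves all downstream statistics.

**Microhomology.** For a pure deletion, `microhomology_length` is the
number of equivalent same-size intervals minus one — equivalently the
length of the maximal exact repeat shared by the two deletion junctions.
Inside long repeat runs this raw junction repeat can exceed the deletion
size (deleting one base of `AAAAAA` has five representations); since end
joining cannot anneal more homology than was deleted, the annotation layer
used by classification-adjacent statistics and the generator caps the
MMEJ-usable microhomology at the deletion size. The raw definition remains
the contract of `microhomology_length` itself.

**Window attribution.** Outcomes are attributed to the cut when some
equivalent deletion interval contains one of the two cut-adjacent bases,
or some equivalent insertion gap lies within 3 nt of the cut. Outcomes
failing both tests raise `OutOfWindowError` rather than being silently
kept.

## Ten-way classification

Pure deletions split by size (1, 2, 3–9, 10+) and by microhomology at
threshold `mh_min = 2` bp: the exponential microhomology law is fit from
size 2 upward and 0–1 bp of junction homology is treated as incidental.
`mh_min` is a configuration knob throughout.

Pure 1–2 bp insertions whose equivalent gap set contains the cut are
compared with the `ins_size` bases immediately 5′ (PAM-distal template) and
3′ (PAM-proximal template) of the cut, each read contiguously from the cut;
a partial (1-of-2) dinucleotide match counts as no match. Insertions
matching both identical flanks are counted as PAM-distal by default (the
dominant templating mechanism) and are excluded from proximal-share
analyses, which only use targets with differing flanking nucleotides;
`both_as_distal=False` flips the convention.

Everything else — insertions longer than 2 bp, off-cut insertions,
untemplated cut insertions, mixed insertion-deletions — is `OTHER_I_MH`
when the inserted sequence shares an exact match of ≥ `mh_min` bp with the
target within 10 bp of the edit locus, else `OTHER_I_NOMH`.

## Directionality

Directionality of a pure deletion is `max(left_del, right_del) /
del_size`, where `left_del`/`right_del` count deleted bases 5′/3′ of the
cut. Because microhomology makes the interval ambiguous, the split is taken
from the equivalent representation whose midpoint is closest to the cut
(ties resolved left-most): this prevents representation choice from
inflating directionality. Single-base deletions are entirely on one side
and score exactly 1. The alternative definition `|left − right| / size` is
exposed as `abs_directionality`; both give 1 for 1 bp deletions.

## Synthetic-data generator

The generator emulates the statistical shape of a self-targeting screen so
that every stage can be verified at desk scale. Targets are random
79-mers with a fixed layout (13 nt context, 20 nt protospacer, NGG PAM;
cut at position 30, leaving exactly 30 bases 5′ of the cut for the 30 bp
deletion window), with cut-flanking dinucleotides cycled through all 16
pairs. Per (target, line) the exact outcome distribution over the
enumerated candidate set is constructed in frequency units:

- **Microhomology deletions** (usable MH ≥ 2) receive frequency
  `A_s·e^{B_s·d}` with `d = del_size − s`. Defaults:
  `A_s = min(0.05, 0.006·1.3^{s−2})`, `B_s = −0.18 + 0.008·(s−2)` — longer
  microhomologies are more likely and less distance-penalized.
- **Templated 1 bp insertions** at the cut receive a total frequency and
  PAM-proximal share set per flank pair. Defaults: distal T/A targets are
  3× more insertion-prone than G/C (0.29 vs 0.097 of mutated reads);
  default proximal share 0.15 with the extreme pairs T/G → 0.005 and
  G/T → 0.56; identical flanks collapse to a single both-matching outcome.
- **Untemplated and 2 bp insertions** get a small flat weight
  (2×10⁻⁴ each).
- **Non-microhomology deletions** absorb the remaining mass with a
  geometric size decay (ratio 0.85 per added base): no empirical law is
  asserted for these events, only monotone decay.

**Category multipliers.** A knockout line is defined by multipliers `m_c`
per outcome category. A category with `m_c ≠ 1` receives exactly `m_c`
times its control mass; the unmodified categories are rescaled to absorb
the remainder. The planted log2 fold change of a modified category is
therefore exactly `log2(m_c)` (plain renormalization would shift it by
`−log2` of the total modified mass). When the exact semantics are
infeasible (modified mass ≥ 1, or nothing left unmodified) the
distribution falls back to plain renormalization and is flagged. Presets
named after the screen's knockout lines transcribe the direction and rough
magnitude of the reported category effects; they are illustrative
documentation, not fitted values.

Reads are sampled per (target, line, replicate, timepoint) as a multinomial
draw with Poisson-jittered depth (expected `read_depth` mutated reads;
`fixed_depth` disables the jitter for exact expectations). At least two
replicates are required, so the per-sample coverage filter has teeth.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error and alignment artifacts, gRNA
efficiency differences, wild-type (uncut) reads, designed microhomology
cassettes (random 79-mers carry mostly 2–4 bp microhomologies, so the MH
deletion categories are smaller than in a designed library and long-MH
fits may be underdetermined), and any correlation structure between
replicates beyond shared truth.

## Profile pipeline

Targets with fewer than `min_reads = 100` mutated reads in **any**
observed (line, replicate, timepoint) sample — including samples where the
target is entirely absent — are dropped everywhere, keeping the target set
comparable across lines. Outcomes observed in exactly one read across all
samples are removed. Surviving counts are pooled over replicates and
timepoints; frequencies are fractions of pooled mutated reads (wild-type
reads never enter the denominators).

Log2 fold changes use `lfc = log2((f_ko + pc)/(f_ctrl + pc))` with
`pc = 0.001` (0.1% in frequency units) applied uniformly; the same
pseudocount stated for the deletion-grid analyses is reused for category
fold changes, configurably. Per-knockout summaries average per-target LFCs
over targets (rather than taking the LFC of averaged frequencies); the
absent-in-both convention emits 0 with a flag.

Insertion flank summaries report, per flank pair, the mean over targets of
(i) the absolute 1 bp-insertion frequency and (ii) the PAM-proximal share
`prox/(prox + dist)` of templated cut insertions, over targets with
differing flanks only. Confidence intervals are percentile bootstrap
(2.5/97.5) over targets with 1000 resamples, deterministic per seed; a
single target yields a degenerate interval.

## Microhomology regression

One observation per microhomology deletion outcome per (target, line):
size `s`, distance `d = del_size − s` (bases strictly between the repeat
copies; the start-to-start convention `d = del_size` differs by the
constant `s` and only rescales `A`), response `y` = outcome frequency. Raw
per-outcome points are fit without pooling across targets. `y = A·e^{B·d}`
is fit per (s, line) for s = 2..15 by Levenberg–Marquardt
(`scipy.optimize.curve_fit`) with initialization `A₀ = max(y)`,
`B₀ = −0.1`. Fewer than 3 observations or fewer than 2 distinct distances
produce an explicit no-fit record instead of silent NaNs. The fit is
scale-equivariant: scaling y scales A and leaves B unchanged.

## Knockout clustering

Rows of the LFC matrix are (target, outcome) pairs present in the control
line and in at least `min_lines = 10` knockout lines (both filters are
logged with the removed frequency mass); entries are pseudocounted LFCs
with absent frequencies taken as 0, so the matrix is complete. Rows are
embedded with UMAP (`n_neighbors = 50`, `min_dist = 0`, 2 components,
seeded; raw LFCs, unscaled — the columns share units) and grouped by
k-means on the embedding coordinates (default k = 7, 50 restarts, seeded).
k-means was chosen because the clustering algorithm itself was an open
choice and k-means gives a reproducible, total labeling; a density-based
alternative can be swapped in by clustering the coordinates differently.

Composition table E distributes each category over clusters (columns sum
to 100%), table F gives each cluster's category make-up (rows sum to
100%); both weight rows by control-line frequency by default (configurable
to unweighted), since the screen-level picture weights outcomes by
abundance. Knockout enrichment subtracts the per-column overall mean from
per-cluster means, so each column has size-weighted mean zero.
Directionality summaries restrict to non-homologous pure deletions
(`mh_len < mh_min`) and include a library-wide average row.

## Outcome predictor

Candidates per target: all deletions of 1–30 bp with some equivalent
interval touching the cut-adjacent bases, and all insertions of 1–2 nt at
gaps within 3 nt of the cut, canonicalized and deduplicated (no two
candidates yield the same edited sequence).

The feature registry (version `v1`, 235 binary features, hash-stamped into
every model) implements these families: outcome type; deletion size
one-hots and size classes; left/right deleted-base offsets; microhomology
one-hots and classes; inserted-sequence identity (1–2 nt) and gap offset;
outcome category; flank-match status; nucleotides flanking the deletion
junctions and the cut; single-sided deletion flags; and pairwise products
(insertion identity × flank base, size class × MH class, sidedness × size
class). The registry documents its own composition; no particular feature
count is targeted.

Training minimizes `Σ_t KL(measured̃_t ‖ softmax(X_t θ)) + λ‖θ‖²`, where
`measured̃` adds 0.5 reads to every enumerated outcome and renormalizes —
equivalently penalized multinomial maximum likelihood with the KL direction
`D(measured ‖ predicted)` and natural logarithms (both directions are
reported at evaluation). Measured outcomes outside the enumeration limits
are excluded from numerator and denominator with their mass logged. The
optimizer is L-BFGS with analytic gradients from `θ = 0` (deterministic;
relative-loss tolerance 1e−6), and the loss history is recorded — line
search makes it non-increasing, which the tests assert. Default
`λ = 0.01`; the objective is convex, so the start does not affect the
optimum. Non-convergence raises unless a partial model is explicitly
allowed.

Train/test splits are by target (10% held out) to prevent leakage between
outcomes of the same target. Evaluation reports per-target KL (forward and
symmetrized) and pooled Pearson correlations for individual outcome
frequencies, ten-category aggregates, and per-target in-frame fraction
(net length change divisible by 3), plus a replicate-vs-replicate KL floor
when replicates are available.

## Problem sizes and numerical conventions

The verification suite plants parameters and recovers them at desk scale:
category-LFC recovery uses 200 targets at 5×10⁴ reads per replicate × 2
replicates; microhomology-law recovery 200 targets at 2.5×10⁴ × 2;
archetype clustering 60 targets × 10 outcomes × 8 knockout lines with
within-group noise sd 0.3 across 5 seeds; predictor recovery 200 targets
from a registry-linear weight vector; bootstrap calibration 1000 simulated
40-target datasets with 1000 resamples each. Distribution sums are checked
to 1e−9; composition tables to 1e−6 of 100%. Ties in the directionality
split resolve left-most; k-means and UMAP seeds are explicit everywhere;
all randomness flows from named seeds (no stage reads global entropy).

## Known limitations

- Substitution (SNV) outcomes are out of scope; the outcome grammar is
  indel-only, and targets are stored protospacer-5′→3′ (no PAM-on-minus
  handling).
- The non-MH deletion size law is a modelling convenience (geometric
  decay), not an empirical claim.
- The clustering stage does not attempt to reproduce any particular
  cluster geometry obtained on real screen data; recovery guarantees apply
  to planted archetypes only.
- The exponential MH law is fit only over observed distances; no
  extrapolation or mixed-effects variants.
- With random synthetic targets, microhomology sizes above ~6 bp are too
  rare to constrain their fits; those rows are reported as no-fits rather
  than extrapolated.
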