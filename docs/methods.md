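# Methods

This note documents the models and procedures implemented in
`viromenet`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical choices that affect
results.

## Weighted read assignment

Reads from a virome are mapped against a genome database; a read
aligning equally well to several genomes ("ambiguous") cannot be counted
naively. Per sample, the module first counts unambiguous reads u_g per
genome, then allocates each ambiguous read over its candidate genomes
g_1..g_k with weights u_i / Σ_j u_j. When every candidate has u = 0 the
read is split 1/k; this keeps total assigned mass per sample equal to
the number of distinct reads, which we prefer over discarding such reads
because it preserves column sums (and hence relative abundances) under
any ambiguity level. The allocation is one-pass — unique counts are
computed once and ambiguous reads allocated once, with no EM iteration.
Accumulation is in float64, so "exact" conservation holds to ~1e-12
relative; tests assert 1e-9 absolute per sample.

Genome-length normalization is deliberately absent by default (counts
are the substrate of the correlation analysis, and SparCC's Dirichlet
resampling expects integers); `to_relative` provides per-sample closure
when relative abundances are needed. Detection for the prevalence filter
means strictly positive assigned weight. The default prevalence
threshold is 0.4: genomes seen in fewer than 40% of samples are excluded
before network inference because sparse counts yield spurious
correlations.

## Compositional correlation (SparCC)

Sequencing counts are compositional: per-sample totals are arbitrary, so
Pearson correlations of fractions are biased by closure. The module
works with log-ratio variances t_ij = Var_s(log x_is / x_js), which are
invariant to per-sample scaling. Under the sparsity assumption that most
pairs are uncorrelated,

    Σ_{j≠i} t_ij ≈ (d − 1) ω²_i + Σ_{j≠i} ω²_j,

a linear system solved for the basis variances ω²_i, from which
ρ_ij = (ω²_i + ω²_j − t_ij) / (2 ω_i ω_j).

Procedure and defaults:

- **Fractions.** Per sample, fractions are drawn from
  Dirichlet(counts + 1). The +1 pseudocount makes zero counts usable and
  is the standard flat-prior posterior. Counts must be integers; callers
  with weighted (fractional) counts round first (the CLI does this and
  says so).
- **Exclusion iterations (default 10).** The sparsity approximation
  fails for strongly correlated pairs, so the single strongest-|ρ| pair
  above a threshold (default 0.1) is removed from the linear system and
  the basis re-solved, up to 10 rounds. A pair is not excluded if doing
  so would leave a genome with fewer than two partners (the system would
  become singular); exclusion then stops with a log message.
- **Inference iterations (default 10).** The whole computation is
  repeated over independent Dirichlet draws and the element-wise median
  taken — robust to outlier draws.
- **Clamping.** Non-positive ω² solutions are clamped to 1e-8 and ρ to
  [−1, 1]; both can occur for small d because the system is approximate.
  At least 4 genomes are required.
- Sample variance uses ddof = 1; at least 3 samples are required.

The implementation is validated element-wise (tolerance 0.05) against an
independent loop-level reimplementation of the same equations on
5-genome × 200-sample data, and for compositional robustness by
rescaling a sample's counts.

## Network host prediction

Queries are genomes without host labels; references carry ranked host
lineages (domain → species, contiguous from domain). A query is assigned
the host of the reference with which it has the maximum correlation,
provided that maximum is ≥ the cutoff (default 0.6). Negative
correlations are never used for prediction. Ties at the maximum: if all
tied references agree at the requested rank the assignment is made,
otherwise the query abstains (logged) — abstention preserves measured
precision. If a reference lacks the requested rank, the deepest
available rank is used and flagged.

Calibration re-runs the rule on the reference-only subgraph,
leave-self-out: each reference is predicted from its strongest
positively correlated *other* reference and scored at the chosen rank.
Where nothing is predicted at a cutoff, accuracy is reported as
undefined (NaN), not 0 or 1. The default evaluation rank is phylum, with
genus available. The sign census counts same-host reference pairs with
ρ ≥ 0.3 and ρ ≤ −0.3; |ρ| < 0.3 is treated as too close to zero for a
reliable sign. Census, calibration and prediction all consume the same
ρ matrix.

## Alignment-evidence filters

Boundary semantics, fixed and documented per filter: identity
"above 80%" is strict (> 80); lengths and coverages are inclusive (≥).
"Best hit" is always max bitscore, ties broken by lower e-value then
lexicographic subject id, so outputs are deterministic and
order-insensitive.

- Genome homology: identity > 80% and alignment ≥ 1,000 nt; best
  qualifying hit defines the host.
- Contig taxonomy voting: per-protein best hits with e < 1e-5 and
  identity > 30% are summed per contig; totals below 1,000 are
  unclassified. Ranks are fixed domain → species while a single taxon
  holds ≥ 80% of the contig's post-filter total bitscore (the post-
  filter total is the denominator at every rank, so the per-rank share
  is non-increasing with depth). Viral/eukaryotic/unclassified-at-domain
  contigs never yield hosts. The environmental-contig homology strategy
  applies the genome-homology alignment filter against contigs labelled
  this way; thresholds are configurable.
- CRISPR: mismatches + gaps ≤ 2 and full spacer coverage
  (alignment ≥ spacer length − gaps). Spacers are ~20–30 nt, so partial
  matches are noise; the host is the spacer's source organism, multiple
  concordant spacers raise the support count, and conflicting phyla are
  all reported with a conflict flag.
- tRNA: best hit with identity ≥ 90% and tRNA coverage ≥ 0.9.

## Dice distance and BIONJ

All-vs-all translated-search hits are filtered (identity ≥ 30%, length
≥ 30 aa, e ≤ 0.01) and summed per ordered genome pair into S[A][B]. The
printed form of the distance, "1 − (2 × AB/AA+BB)", is parenthesized as
1 − 2·AB/(AA+BB): the only reading with D(A,A) = 0 and D ∈ [0, 1].
Because a translated search is not perfectly symmetric, AB is
symmetrized as (S[A][B] + S[B][A])/2, which reduces to AB when the
search is symmetric. Self-scores sum all qualifying self-hits. Genomes
without self-hits are dropped (their denominator is undefined); pairs
with no cross-hits sit at distance 1 and are retained rather than
dropped. D is clamped to [0, 1].

The tree is built by neighbour joining with the BIONJ reduction: pair
choice by the Q criterion, standard branch-length formulas, and reduced
distances d(u,k) = λ(d(i,k) − L_i) + (1−λ)(d(j,k) − L_j) with the
variance-minimizing weight

    λ = 1/2 + Σ_k (v(j,k) − v(i,k)) / (2 (r−2) v(i,j)),

clamped to [0, 1], where the variance matrix v is initialized to D and
reduced as v(u,k) = λ v(i,k) + (1−λ) v(j,k) − λ(1−λ) v(i,j). When
v(i,j) ≈ 0, λ = 1/2. Negative branch lengths are clamped to 0 with the
total deficit logged. On additive matrices the result coincides with
plain NJ in topology and path lengths (verified against an independent
NJ implementation); non-symmetric or NaN inputs are rejected.

Cluster extraction cuts the tree into maximal clades whose internal
leaf-to-leaf path diameter is ≤ a threshold. The tree is unrooted, so it
is first rerooted on its longest edge (the deepest split); rooting
anywhere on the between-group backbone makes well-separated groups
clades of the traversal, and the longest edge lies on that backbone
whenever separation is real. A rooting that fell inside a tight group
would split only that group.

## Functional profiles

profile[ko, s] = Σ_g copies(g, ko) × abundance(g, s) — "proportionally"
realized as copy-number weighting, matching the worked multiplication
rule (abundances 1, 5, 10 with one copy each → 16). Per-sample
renormalization to relative KO abundances is an option, not the default.
Best-hit annotation keeps, per protein, the maximum-bitscore hit with
e ≤ 1e-5 (ties: lower e-value, then lexicographic KO id).

## VHR and differential abundance

VHR(taxon, sample) = summed abundance of viruses assigned to the taxon /
the taxon's host abundance in the paired cellular metagenome. Records
with zero host abundance are flagged undefined and excluded from
correlations (never zero-imputed; the count is logged). Associations are
Spearman rank correlations of (host abundance, VHR), per taxon (≥ 5
defined records) and pooled; a negative pooled sign is the reduced-lysis
(Piggyback-the-Winner) signature.

Differential abundance uses the two-sided Mann–Whitney U test per
feature: exact enumeration when both groups have ≤ 8 tie-free samples,
otherwise the tie-corrected normal approximation. "False discovery rate"
is realized as Benjamini–Hochberg step-up; features with q < 0.05 are
significant. The enriched group is the one with the higher median
(ties: higher mean; still tied: flagged "tied" rather than guessed).
Both groups need ≥ 3 samples. scipy and statsmodels provide the test
and the correction; tests verify them against exhaustive-permutation
and brute-force step-up oracles and check null calibration.

## Synthetic data

`simulate_community` emulates the abundance coupling the co-occurrence
method relies on. Host log-abundances are i.i.d. normal per sample
(σ = 1 by default, configurable covariance), exponentiated and closed to
relative abundances — heavy-tailed dynamics of the kind marine
communities show. Each virus's latent abundance mixes its host's signal
with independent log-normal noise on the linear scale:
a_v = coupling·h + (1 − coupling)·ε, with dispersion σ_ε = 0.5 by
default. Virus counts are multinomial per sample at a fixed depth
(default 1e5 reads), matching fixed-depth read-count data better than
Poisson sampling. Defaults (20 hosts × 3 viruses, 120 samples,
coupling 0.95) are the standing study conditions of the recovery
analyses.

`simulate_read_alignments` draws a fraction of reads as ambiguous pairs
with probability proportional to the joint abundance p_i·p_j, the true
origin within the pair proportional to relative abundance — the regime
in which the unique-ratio reassignment is unbiased (flagging
origin-drawn reads instead would systematically favour abundant
genomes). The realized truth counts are returned alongside the table.
`simulate_homology_set` plants genome groups whose within-group summed
bitscores are a high fraction of the self-score and between-group a low
one, so Dice + BIONJ + cluster extraction can be scored against the
planted partition.

What the simulations do **not** emulate: sequence content (no reads or
alignments are generated, only tables), mapping error structure,
genome-length effects, uneven sample depths, temporal autocorrelation
between samples, and multi-host viruses. Passing the recovery tests
therefore shows the inference machinery is correct under its own model
assumptions, not that real viromes satisfy those assumptions.

## Problem sizes and determinism

The validation analyses run at desk scale by choice: SparCC oracle
comparisons at 5 genomes × 200 samples, host-prediction recovery over 20
simulated communities of 60 viruses × 120 samples, statistics checks on
1,000 random p-vectors and 50 null datasets. All randomness flows
through explicit seeds (`numpy.random.default_rng`); the same seed gives
byte-identical synthetic tables and correlation matrices.

## Known limitations

- The SparCC basis solution degrades below ~4 genomes and for densely
  correlated communities where sparsity fails; clamping keeps outputs
  legal but such ρ values are approximate.
- The network method cannot distinguish shared-host coupling from
  environmental co-variation; on real data its accuracy must be read
  from the reference calibration curve, not assumed.
- Host-prediction abstention on ties means coverage depends on the
  reference panel's redundancy.
- BIONJ assumes distance noise roughly proportional to branch length;
  Dice distances near 1 are saturated and carry little signal, so deep
  branches are poorly resolved (visible in the synthetic homology sets
  as long, arbitrary-length deep edges).
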