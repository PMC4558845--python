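# Methods

This document records the models, algorithms, parameter defaults, and
numerical choices implemented in `cytonuc`, together with the scope of the
synthetic-data generators and known limitations. Every empirical number
quoted here was computed by this package (the pytest suite or
`scripts/acceptance.py`).

## Substitution models and distances

**WAG.** The empirical amino-acid model is assembled from the published
exchangeability matrix and equilibrium frequencies (bundled as a
plain-text PAML-format file in `cytonuc/data/wag.dat`). The generator is
`Q_ij = s_ij π_j` (i≠j), rows summing to zero, scaled so the expected
rate at equilibrium is 1 substitution/site. Transition probabilities
`P(t) = exp(Qt)` are computed by symmetric eigendecomposition of
`Π^{1/2} Q Π^{-1/2}` (exact for a reversible Q, numerically stable), with
a clip-and-renormalize guard against negative round-off; the
decomposition is cached on the model object.

**Discrete-Γ rate heterogeneity.** k equiprobable categories with the
mean-of-quantile rates (computed via the incomplete-gamma identity),
normalized to mean 1. Defaults used in placement and profiling:
shape α = 1.0, k = 4. α = 1.0 is a neutral default expressing moderate
heterogeneity; the profiling pipeline accepts any α
(`--gamma-alpha`).

**K80 distance.** The pairwise ML distance has the closed form
`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` with P/Q the transition/
transversion difference proportions (pairwise deletion of gaps and
ambiguity). When a log argument is ≤ 0 the estimate is **flagged**
saturated (`distance = inf`, `saturated = True`) rather than raised, so
callers can apply their own exclusion policy. The closed form is verified
against an independent two-stage grid search over (t, κ) to within 1e-4.

**WAG distance.** No closed form exists; the pairwise log-likelihood
`Σ_ij n_ij log(π_i P_ij(t))` is maximized by bounded Brent search on
t ∈ [1e-8, 50], xatol 1e-6. Identical sequences return exactly 0;
estimates above 0.99·50 are flagged saturated. Verified against a dense
t-grid oracle (step 1e-4) and by simulation (mean over 100 replicates of
length 10,000 within 2% of truth for t ∈ {0.1, 0.5, 1.0}).

**Mean outgroup rate.** A family's rate is the mean pairwise distance
from the designated outgroup sequence to each ingroup sequence (averaging
over sequences, not species). Saturated pairs are excluded with a
warning; if every pair is saturated a `SaturationError` is raised — a
silent mean of infinities would be meaningless.

## Profile HMM search

Plan7-style lean profile: match columns are alignment columns with gap
fraction < `gap_threshold` (default 0.5). Emissions are Henikoff
position-based sequence weights plus background-proportional pseudocounts
with total mass 1 per column; transitions are weighted path counts with
Laplace smoothing. Local alignment uses uniform entry/exit (1/M).
Scores are log₂ odds against the background ("bits"): the forward score
sums over paths (reported as `bit_score`), the Viterbi traceback supplies
the `match_path` used to project hit residues into reference-alignment
columns (insert-state residues are dropped — they have no reference
column). Forward ≥ Viterbi is asserted property-based.

**E-values.** Bit scores of `n_decoys` i.i.d. background-sampled decoys
(defaults 200 decoys of length 150, fixed seed) are fitted with a Gumbel
law by maximum likelihood; `e_value(S) = N_db · (1 − GumbelCDF(S))`.
Calibration demands ≥ 100 decoys. The search cutoff default is
**e ≤ 1e-5**.

## Maximum-likelihood placement

Queries are attached at the **midpoint** of each reference-tree edge by a
new node with a pendant branch; topology, reference branch lengths, and
the WAG+Γ model are fixed, and only the pendant length is optimized
(bounded Brent on [1e-8, 5], xatol 1e-6). The engine precomputes, per
edge and per Γ category, the conditional likelihood of all reference data
below and above the midpoint (Felsenstein pruning with per-site
log-scaling), so each per-query likelihood evaluation is a single
20-state message. Per-site likelihoods mix Γ categories by an
equal-weight log-sum-exp mean. The best edge maximizes the attachment
log-likelihood (ties broken toward the lower edge number); likelihood
weight ratios are softmax weights over edges. Output follows **jplace
version 3** (edge numbers in `{braces}` on the tree string; fields
`edge_num, likelihood, like_weight_ratio, pendant_length`; top 7 edges
per query). The engine agrees with an independent naive full-tree
pruning recomputation to ~1e-12 log-likelihood units and 20/20 best-edge
agreement on the acceptance benchmark.

**Classification.** A placement is *eukaryote* iff the tip set subtended
by its edge (child side) is purely eukaryote-annotated; the stem edge of
the maximal eukaryote-only clade qualifies but is flagged
`low_confidence` (a fragment attaching there may as well be an outgroup).
The same rule on mitochondrial/cytosolic tip labels yields the lineage
call (`ambiguous` when the subtended eukaryote tips mix lineages).

## Two-round profiling

Round 1: build profile from the full (eukaryote+prokaryote) reference
alignment → search the species database (e ≤ 1e-5) → align hits into
reference coordinates via the Viterbi path → place on the annotated
reference tree → retain eukaryote-placed fragments. Round 2: rebuild the
profile from the **eukaryote-only subalignment** and repeat
search/align/place on the same database; the round-2 retained set is
final. `presence = retained set after round 2 non-empty`; the lineage
call is `mt`/`cy`/`both`/`single`/`absent` by the lineages of the
retained placements. Per-family/round decoy seeds derive
deterministically from the config seed and a CRC-32 of the family name.
Exposed on the command line as `cytonuc profile run2round`.

**Benchmark behavior.** On the generator defaults (100 eukaryote
fragments, 100 prokaryote contaminants, 200-column reference, divergence
0.1, fragment floor 30 aa), recall is 1.0 at every seed examined.
Contaminant leakage is seed-dependent: across five seed chains it was
{0.00, 0.00, 0.01, 0.06, 0.10}. The mechanism, verified by tracing one
leaked full-length contaminant: the round-2 *eukaryote-only* profile can
misalign a divergent prokaryote sequence (observed: 113/200 correctly
placed residues, 64 spurious gap columns), and the scrambled row then
places confidently inside the eukaryote clade. The procedure is
implemented exactly as specified (round-2 retention is not intersected
with round 1); intersecting the rounds would remove this failure mode but
would be a different method.

## Compensatory-substitution regression

`Y = β₀ + β₁·δmt + β₂·X + β₃·X·δmt + ε`, fitted by OLS (statsmodels)
with explicit rank and degrees-of-freedom checks. Nested comparisons use
`F = [(SSE_r − SSE_f)/Δdf] / [SSE_f/df_f]` with the p-value from the F
distribution; backward selection drops the interaction, then the slope,
at α = 0.05 (`cytonuc stats fit` / `stats compare`). The mt/cy rate
correlation is the Pearson r over specificities with both lineages
(≥ 3 pairs required; `stats correlate`). Verified: noiseless tables are
recovered to machine precision; with σ = 0.05 and 200 rows, each mean
coefficient over 500 replicates lies within 2 Monte-Carlo SE of truth;
the nested-F type-I error at α = 0.05 under β₃ = 0 was 0.05.

## Codon-reassignment scan

Each focal codon is mapped to its reference-alignment column through the
focal row's gaps (the target codon is rendered as `X` during translation
so an unknown code cannot bias the mapping; the focal row and reference
`X` residues are excluded from counts). Columns containing the target
codon are retained when reference Shannon **entropy < 1.0 nats** and
**gap fraction < 0.20** (both strict); each retained column votes for its
plurality reference residue, ties split fractionally. The report's call
is the residue with the largest aggregated fraction. CLI: `cytonuc
codescan --cds ... --alignments ... --codon TGA`.

## Synthetic-data generators

All generators are deterministic under a seed; a global seed expands to
per-component seeds via `numpy.random.SeedSequence([seed, index])`
(always < 2³¹). Defaults are the study conditions, fixed before any
outcome was observed:

- **Family trees**: 8 eukaryote tips (4 mitochondrial + 4 cytosolic
  paralogs, each lineage a clade) sister to 6 prokaryote tips; branch
  lengths Exponential(mean 0.15).
- **Alignments**: evolved gap-free along the tree; root from equilibrium;
  each site keeps one Γ category over the whole tree. No indel process —
  fragmentation below models truncation, not internal gaps.
- **Profiling databases**: fragments evolved 0.1 subs/site from random
  eukaryote (orthologs) or prokaryote (contaminants) tips; truncated-
  geometric lengths with floor 30 aa, mean extra 50. Truth labels
  support recall/leakage scoring.
- **Rate tables**: X ~ U(0.05, 0.8) shared by the mt and cy row of each
  specificity; Y on the model plane plus Normal(0, σ²) noise, default
  β = (0.10, 0.39, 0.38, 0.07), σ = 0.05. Negative Y values that noise
  occasionally produces are **not clipped**: truncation would bias OLS
  recovery, and the recovery criteria assume an unbiased generator.
- **Reassigned genomes**: 6 genes × 100 codons, target-codon density
  0.1, exactly `round(fraction · n_targets)` planted columns whose
  consensus is the reassigned residue, reference conservation 0.9, gap
  rate 0.05, translation table 4.

Note that the mt/cy Pearson correlation implied by these generator
defaults is ≈ 0.78–0.87 (both lineages share X with strong slopes), which
is a property of the synthetic design, not a target.

## Numerical choices

- Log-space dynamic programming throughout the HMM (`logaddexp`;
  the delete-chain recursion is vectorized with a cumulative-sum
  identity); per-site max-rescaling in the pruning recursions.
- Eigendecomposition-based `expm` for reversible generators (cached).
- Brent bounded scalar optimization for all 1-D ML problems (distance,
  pendant length), tolerances 1e-6.
- Seeds derived by `SeedSequence` spawning or CRC-32 of names — never
  Python's randomized `hash()`.

## Limitations

- The profile HMM is a lean reimplementation: no glocal/uni-local mode
  switching, no multi-hit scoring, no heuristic filters; e-value
  calibration is per-profile Monte-Carlo rather than analytic.
- Placement optimizes the pendant branch only; the attachment point is
  fixed at the edge midpoint (no along-edge optimization).
- Round-2 retention follows the specification exactly; as noted above, a
  eukaryote-only profile can misalign divergent contaminants, giving
  seed-dependent leakage up to ~10% on the benchmark generator.
- Alignments are simulated without indels; profile deletion/insertion
  states are exercised by fragmentation and by gapped reference columns
  only.
- The regression assumes homoskedastic independent errors; rates
  estimated from shared phylogenies violate independence in real data
  (no phylogenetic correction is implemented).
- Headline external-data estimates (regression coefficients on the real
  aaRS/tRNA rate tables; the 38% TGA→Ser and 80% ATA→Ile conserved-column
  fractions of specific mitochondrial genomes) require retrieving public
  sequence accessions and curated family alignments, so they are not
  desk-scale reproducible here. The command paths are: `cytonuc stats
  fit`/`stats compare`/`stats correlate` on a rate table assembled from
  real distances (`cytonuc.substitution.mean_outgroup_distance` +
  `cytonuc.regression.assemble_rate_table`); `cytonuc profile run2round`
  for the presence/absence matrices; `cytonuc codescan --codon TGA` and
  `--codon ATA` on the focal mtDNA CDS and per-gene reference alignments.
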