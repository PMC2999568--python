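# Methods

This note documents the models and procedures implemented in
`mat_alpha_trace`, the choices made where the design was genuinely open,
and what the synthetic-data tests do and do not establish about real
domain datasets.

## Problem setting

Fungal mating types in heterothallic Pezizomycotina are specified by two
dissimilar sequences (idiomorphs) at one locus: one encodes a MATA_HMG
DNA-binding protein, the other a protein with an α1 domain whose family
membership has been unclear. The package implements the computational
chain used to ask whether the α1 domain is a derived subclass of the
HMG-box superfamily: conserved-core profiling of the four domain classes
(α1, MATA_HMG, SOX, HMGB), consensus-versus-consensus similarity with
BLAST-style statistics, maximum-likelihood phylogenetics of the core
region under LG+Γ with resampling-based edge supports and topology
tests, marginal ancestral reconstruction of per-class ancestors, and a
scan for the conserved `Y-[LMIF]-x(3)-G-[WL]` motif downstream of the α1
domain.

## Core-region profiling

Domain sequences are aligned with a compact progressive aligner: a UPGMA
guide tree on fractional shared-k-mer distances (k = 3), then
profile–profile global alignment with affine gaps (BLOSUM62, gap open
−11, extend −1; a gap run of length L costs `open + (L−1)·extend`).
The aligner is plumbing, not a contribution: it makes the pipeline
self-contained, and externally aligned FASTA is accepted at every stage.
No claim is made of reproducing Muscle or Kalign output exactly.

The analysis then restricts to the ~40-column conserved core:

- `extract_core` keeps the columns spanned by a 1-based window in the
  ungapped coordinates of an anchor row (insertion columns inside the
  window are retained).
- `coverage_filter` removes rows whose non-gap residue count over the
  core is *less than* 80 % of the core length; a row at exactly 80 %
  is kept, because the rule removes rows *below* the threshold.
- `remove_gappy_columns` deletes columns whose gap fraction exceeds 0.5,
  the mechanism used for the minority insert block that occurs inside
  HMGB cores. The 0.5 default removes minority inserts while keeping
  consensus-bearing columns.

Column profiles use frequencies `(count + pseudocount) / (non-gap total +
20·pseudocount)`; `X` counts as missing, never as a 21st symbol.
Information content is `log2(20) − H` bits per column; an all-gap column
is flagged, reported uniform with 0 bits. The consensus takes the modal
residue per column (ties broken alphabetically, so the result is
deterministic and independent of row order); its per-position support is
the modal frequency. The pseudocount defaults to 0 for consensus
building (mirroring logo behaviour) — downstream likelihood-style uses
may pass 0.05 to avoid zeros.

## Consensus comparison

Two consensus (or ancestral) sequences are compared by optimal local
affine-gap alignment under BLOSUM62 (open −11 / extend −1 — the BLASTP
defaults). Identity is the fraction of aligned identical pairs over the
alignment length; positives are aligned pairs with a positive matrix
score (identical pairs included), matching the BLAST convention. The
expect value is Karlin–Altschul, `E = K·m·n·exp(−λS)`, with the standard
gapped BLOSUM62 constants λ = 0.267, K = 0.041 and the pairwise search
space m, n set to the two sequence lengths by default. With pairwise
search spaces these E-values are order-of-magnitude indicators, not
database-search statistics. Because the optimal local alignment need not
be unique, the comparison is computed in a canonical (lexicographic)
orientation so that swapping query and subject changes nothing.

## Substitution model

The LG replacement matrix (published exchangeabilities and stationary
frequencies, embedded as data) builds a reversible generator
`Q_ij = S_ij π_j`, normalized to one expected substitution per unit
branch length. Rate heterogeneity uses Yang's discrete gamma with k = 4
equal-probability categories by default; category rates are the bin
means of Gamma(α, 1/α) (not medians), renormalized to mean exactly 1.
An optional invariant-site proportion adds a rate-0 spike with weight
p_inv; the gamma weights become (1−p_inv)/k. Gamma rates are not
rescaled by 1/(1−p_inv): branch lengths under +I models are expected
substitutions per *variable* site. Transition matrices come from a
symmetric eigendecomposition reused across branches and categories.

Model selection (LG, LG+G, LG+I+G) maximizes each candidate's
likelihood over branch lengths plus α and/or p_inv and ranks by
AIC = 2p − 2lnL, counting one parameter per branch. α is optimized on a
log scale up to 10⁶ rather than the conventional ceiling of 100: at
α = 100 the four discrete rates still differ from uniform by ~10 %,
which would leave LG+G a few lnL units *below* LG on equal-rates data
and break the nesting property; near the 10⁶ bound the +G model is
numerically indistinguishable from LG. Each +G/+I candidate is also
restarted from a near-uniform-rates initialization, because the
alternating (α, branch-length) optimization can stall on a ridge.

## Likelihood machinery and tree search

`PruningEngine` implements Felsenstein pruning with per-category partial
vectors and per-(category, site) log-scaling (needed beyond ~200 taxa,
harmless below). Gaps and `X` are missing data (partial vectors of
ones); a fully missing column contributes exactly 0 to the lnL. The
engine also maintains outward ("up") partials so the likelihood
factorizes through any single edge, which makes three things cheap:

- branch-length optimization — Jacobi-style sweeps of per-edge Brent
  searches against the partials from the start of the sweep, with the
  total lnL re-checked after each sweep (a non-improving sweep is rolled
  back, so lnL is non-decreasing across rounds); bounds 1e-8 to 50;
- NNI screening — both rearrangements around an internal edge are
  evaluated from cached partials, re-optimizing only the central branch;
  the screened value is a lower bound on the candidate's fully
  optimized lnL, so accepting only screened improvements keeps the hill
  climb sound;
- marginal ancestral posteriors (below).

Tree search is NJ (on pairwise ML distances under the chosen model,
optimized per pair on a common log-spaced grid with local refinement,
saturated pairs capped at 10) followed by best-improvement NNI
hill-climbing with full branch re-optimization after each accepted move
and a final polish. No SPR/TBR and no bootstrap search, by design: edge
confidence comes from expected likelihood weights.

## Edge supports and topology tests

LR-ELW support of an internal edge compares the three topologies of the
edge's NNI neighbourhood by RELL: sites are resampled with replacement
(10,000 replicates by default, reducible), per-site lnL vectors are
re-summed without re-optimization, likelihood weights
`w_j = exp(lnL_j − max)/Σ` are averaged, and the support is 100× the
mean weight of the ML topology. The two alternative topologies get a
local branch-length re-optimization (the five edges around the
rearrangement) before their site-lnL vectors are taken. The three
weights sum to 100 by construction. This NNI-neighbourhood definition is
the closest published reading of "local rearrangement" ELW support; the
original implementation's exact algorithm is not public.

KH and SH tests are RELL-based: KH compares each topology against the
best with centred two-sided resampled differences; SH uses the
max-centred simultaneous comparison. The ML topology receives p = 1
under both by construction. All resampling flows from one explicit
seed; supports and p-values are bit-reproducible for a fixed seed and
replicate count.

Monophyly on an unrooted tree is the existence of an edge bipartition
separating exactly the queried taxa; single taxa and the full leaf set
are trivially monophyletic.

## Ancestral reconstruction

Marginal ML reconstruction at an internal node: per site, the posterior
over residues is proportional to π_s times the product of the partial
likelihoods of the subtrees hanging off the node, summed over rate
components with their per-site posterior weights (the invariant spike
participates only for constant-compatible sites). MAP ties break
alphabetically. For a single class with no outgroup, the class tree is
midpoint-rooted and the ancestor read at that root. This is standard
marginal reconstruction, not a re-implementation of Ancescon's
distance-weighting refinements — a deliberate method substitution, since
downstream conclusions only require defensible ancestors. Ancestors are
reconstructed on core columns only; indels are not reconstructed.

## Motif scanning

The PROSITE subset covers literals, `[sets]`, `{negated sets}`, `x`,
`x(n)` and `x(n,m)` — everything the downstream-motif analysis needs;
N/C anchors are not implemented because the patterns used need none.
Matching is greedy with backtracking; positions are 1-based
(ScanProsite convention); overlapping matches are reported by default.
`downstream_window` extracts the ~60 residues after a 1-based domain
end, shorter at the protein end and flagged when the protein stops at
the domain boundary (the *S. cerevisiae*-like case). The analytic
expected hit count multiplies per-position allowed-set probabilities
(wildcards contribute 1) by the number of windows; for the core pattern
under uniform frequencies this is (1/20)(4/20)(1/20)(2/20) = 5·10⁻⁵ per
window, and Monte-Carlo scans agree within binomial noise.

## Synthetic data

The generator emits the statistical structure the analysis assumes,
with full ground truth (true tree, true internal sequences, planted
motif positions). Defaults are the study conditions used throughout the
tests:

- 48 taxa: 6 α1-a, 6 α1-b, 12 MATA_HMG, 12 SOX, 12 HMGB; 40-column
  core; LG+G with α = 0.8, 4 categories.
- topology: the α1 clade (split α1-a/α1-b) attaches *between* the two
  MATA_HMG subclades, making MATA_HMG paraphyletic without α1; SOX and
  HMGB branch off successively earlier.
- branch lengths: within-class edges ~0.05 expected substitutions/site
  (jittered ±50 %), class stems 0.5, backbone edges 0.45. These were
  set so that the recovered class edges carry LR-ELW supports in the
  70–100 range — the regime the real domain classes show — and fixed
  thereafter.
- class truncations: terminal deletions of 2 (α1-a) and 4 (α1-b)
  residues from the core, mirroring the shorter α1 cores; the true
  alignment therefore pads α1 rows with end gaps.
- motif: one instance drawn uniformly from the language of
  `Y-[LMIF]-x(3)-G-[WL]`, planted 0–53 residues after the domain end in
  α1-class proteins only, inside random flanks drawn from the LG
  stationary frequencies.
- optionally, a fraction of HMGB rows receive a 6-residue interior
  insert block (off by default) to exercise the gappy-column filter.

Gamma rates are drawn once per site at the root and shared across
branches, matching the inference model. Indels beyond the fixed
truncations and the optional HMGB insert are not simulated — the
analysis operates on core columns, so a general indel process would add
nothing the pipeline consumes. Everything is deterministic given the
seed (byte-identical FASTA).

What passing the synthetic tests shows: the estimators are correct and
well-calibrated when the model is true (pruning matches brute-force
enumeration; ELW weights are uniform on a star tree and decisive on a
long edge; ancestors are recovered at the expected accuracy; the
planted history is recovered at the expected rate). What it does not
show: robustness to alignment error, model misspecification,
composition bias, or long-branch effects present in real domain
datasets — those require the real supplementary datasets, which the
package reads through the same FASTA/tabular interfaces.

## Problem sizes in the validation suite

The test suite and the acceptance script run at desk scale: 20 seeded
48-taxon replicates (1,000 RELL replicates per support) for topology
recovery, 10 seeds for ancestral recovery, 10⁶ residues for motif
calibration, and 8 replicates in the acceptance script's recovery
block. These sizes give stable pass/fail behaviour for the stated
thresholds while keeping a full run in the minutes range.

## Numerical choices and degenerate inputs

- Branch lengths clipped to [1e-8, 50]; pairwise distances capped at 10
  (pairs with no residue overlap are set to the cap and flagged).
- lnL convergence tolerances: 1e-4 per branch-length optimization,
  1e-3 for accepting an NNI move; ties in NNI improvement resolve to
  the first-encountered edge in deterministic postorder.
- Consensus/MAP ties break alphabetically everywhere.
- An empty local alignment (no positive-scoring pair) is returned
  flagged rather than raised.
- All randomness flows through explicitly passed
  `numpy.random.Generator` objects; there is no global RNG state.

## Known limitations

- The progressive aligner is intentionally simple (no iterative
  refinement); for publication-grade alignments use an external aligner
  and feed the aligned FASTA in.
- E-values depend on the chosen Karlin–Altschul constants and search
  space; they are configuration, not ground truth.
- NNI-only search can in principle be trapped by local optima that SPR
  would escape; the validation suite measures exactly this (recovery in
  ≥16/20 replicates under the study conditions).
- The ELW "local rearrangement" definition is an interpretation (see
  above); supports from other implementations may differ in detail.
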