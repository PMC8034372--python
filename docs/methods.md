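# Methods

## Range evolution model

States are non-empty subsets of an ordered area set (2–16 areas; the
default five-area system is A = Indian Subcontinent, B = Asia, C = East of
the Wallace Line, D = Americas, E = Africa). The allowed state space is
every subset of cardinality at most `max_range_size`, minus an explicit
exclusion list, plus an optional null (empty) range. Exclusions remove
exactly the listed subsets — supersets must be listed explicitly — and
excluded states are absent from the rate matrix entirely rather than
rate-zeroed, so they can never appear transiently on a branch. By default
`max_range_size` is the largest observed tip-range cardinality with a
floor of 2.

**Anagenesis.** The generator Q has `Q[S, S∪{a}] = d·|S|` (every occupied
area is an equally weighted source; no distance scaling) and
`Q[S, S∖{a}] = e`. Rates are per Ma, matching chronogram branch lengths;
no unit inference is attempted. The null range is absorbing and carries
zero probability at tips and the root.

**Cladogenesis.** Scenario sets per family:

| family      | singleton parent | wider parent |
|-------------|------------------|--------------|
| DEC         | sympatry-copy    | subset sympatry (2·\|S\| ordered outcomes) + vicariance with one singleton daughter |
| DIVALIKE    | sympatry-copy    | vicariance into any ordered disjoint bipartition |
| BAYAREALIKE | copy             | copy (both daughters inherit S) |

With +j, every parent adds jump outcomes (parent copied to one daughter,
a single unoccupied area to the other). Weights are 1 per non-jump
scenario and `j` per jump scenario, normalized per parent; `0 ≤ j ≤ 3`.
At `j = 0` the +j model reduces exactly to its base model (nesting is a
tested invariant at 1e-12).

**Likelihood.** Felsenstein pruning with a cladogenetic convolution at
each internal node. Per-branch transition matrices use an
eigendecomposition fast path (one decomposition of Q, two small matrix
products per branch), verified against `scipy.linalg.expm` at the longest
branch and falling back to dense `expm` when Q is defective. Partial
vectors are rescaled per node with accumulated log factors. The root
likelihood averages uniformly over allowed non-null states ("no
cladogenesis above the root"); conditioning the root on a single state is
available (`root_state=`) for degenerate checks and for users who prefer
that convention. Polytomies are accepted by the tree reader but rejected
by the likelihood engine, which assumes strict bifurcation.

**Survivorship conditioning.** Observed clades contain only surviving
lineages. `condition_survival=True` renormalizes every branch's transition
rows over non-null endpoints — because the null range is absorbing, a
non-null endpoint implies it was never visited, so this is the exact
likelihood of a process conditioned, branch by branch, on escape from
global extinction. The default remains the standard unconditioned DEC
likelihood (comparable to mainstream implementations); the conditioned
variant is what the parameter-recovery experiment uses, since the
synthetic-data generator necessarily produces survivor-conditioned data
and the unconditioned likelihood then drives the range-loss estimate to
zero on large trees.

**Fitting.** Bounded L-BFGS-B on log-transformed (d, e) and a
logistic-transformed j, from a fixed grid of five deterministic starts
(fewer may be requested); rates bounded in [1e-9, 10] per Ma. A fit in
which no start converges is returned flagged rather than raised. For the
six-model comparison, if the +j search lands below its base model's
optimum (possible only through optimizer noise, since j = 0 is feasible),
the base solution is substituted as the +j optimum.

**Marginal reconstruction.** Up-down pass: outside likelihoods are
propagated through the cladogenetic convolution and branch matrices, and
per-node marginals are `inside × outside`, normalized. Verified against
exhaustive enumeration over all internal-state assignments on ≤4-tip,
≤3-area instances (1e-8).

## Model comparison

AICc = −2 lnL + 2k + 2k(k+1)/(n−k−1) with k = 2 (d, e) or 3 (+j). The
sample size n is the number of coded tips; for the published six-model
table this is 29, a value derived from consistency with the printed AICc
column (the source never states it) and overridable on the CLI. Akaike
weights subtract the minimum AICc before exponentiation. The ±j test is a
likelihood-ratio test with one degree of freedom at α = 0.05; both the
LRT p-value and the AICc difference are reported, since either rule could
underlie a published significance flag.

## Bayesian binary MCMC

Each area is an independent presence/absence character under the
symmetric two-state model, P(same after t) = 1/2 + 1/2·e^(−2rt), with a
(1/2, 1/2) root prior. Per area and chain, the rate moves by a Metropolis
random walk on log r (step 0.6, log-uniform prior on [1e-5, 10] per Ma);
given the rate, node-state uncertainty is handled analytically: at each
sampling point the exact per-node conditional presence marginal is
accumulated (Rao-Blackwellization), which has the same expectation as
counting sampled states but much lower Monte Carlo variance — with a
fixed rate the estimates are exact. Defaults: 10 chains × 10,000
generations, sampling every 100, 10% burn-in (desk scale); a
`paper_scale` preset runs 1,000,000 generations. Convergence is flagged
when the first- and second-half chain pools disagree by more than 0.1 at
any node/area.

Composite node ranges multiply per-area marginals, restrict to the
allowed non-null states, and renormalize (the all-absent product mass is
redistributed proportionally). This composition rule is explicit here
because upstream GUI tools do not document theirs; numeric parity with
any particular tool's composite output is not claimed.

## Event counting

Stochastic mapping conditioned on the tip data: node states, cladogenetic
scenarios and daughter inheritances are drawn from their joint posterior
(root-to-tip sampling over the pruning partials), and anagenetic histories
along branches are drawn by uniformization (endpoint-conditioned CTMC
bridges; cached powers of the uniformized kernel). In a focal node's
window — its cladogenesis plus its subtending branch by default, the
split alone with `window="clado"` — range gains count as dispersal
(founder events included), losses as extinction, vicariant splits as
vicariance. Both modal counts (integer, mirroring published event
matrices) and posterior expectations over `n_maps` (default 500) maps are
reported. The uniformization sampler is validated against a
rejection-sampling oracle.

## Supermatrix filters

Robinson-Foulds distances are symmetric differences of non-trivial
bipartitions on unrooted topologies, branch lengths ignored, computed
after pruning both trees to their shared taxa; at least four shared taxa
are required. The congruence filter retains a gene tree iff RF to the
reference is strictly below the threshold (default 6, i.e. "RF ≥ 6
discarded"). Occupancy filtering keeps ortholog groups whose taxon set
covers every required taxon. Third-position stripping removes every third
alignment column of a codon-aligned matrix (columns 3, 6, 9, …), the
interpretation consistent with codon-aware alignment where columns come
in triplets. Concatenation fills missing taxon-gene blocks with `?`;
completeness counts only unambiguous A/C/G/T cells as present (N, `-`,
`?` are missing) — one defensible reading of a percent-complete report,
configurable in principle and stated here explicitly. Support-based edge
collapsing before RF is not applied.

## Synthetic data

`simulate_chronogram` draws a pure-birth tree (two lineages from the root
split; each splits at the birth rate; one further exponential wait after
the last split) and rescales to a requested root age, default 120 Ma to
match a basal-theraphosid time scale. `simulate_ranges` draws the root
uniformly from allowed singletons, simulates anagenesis exactly
(event-by-event Gillespie) and cladogenesis from the model's scenario
distribution, and records true node states, scenario categories and
per-branch gain/loss counts. Because every tip must be extant, a branch
history that reaches the absorbing null range is redrawn (counted in
`restarts`) — the standard survivorship device; whole-tree rejection has
acceptance probability near zero for deep many-tip trees at realistic
extinction rates. The study-emulation preset is 29 tips, five areas,
maximum range size 2, root age 120 Ma, DEC with d = 0.008, e = 0.004 per
Ma — rates chosen once to give realistic range variation (a handful of
widespread tips, all five areas occupied) at the study's time scale.

Gene-tree discordance applies random NNI moves (RF to the reference is
bounded by twice the move count) and random taxon deletion. Codon
alignments evolve under Jukes-Cantor with a third-position rate
multiplier, emulating synonymous-site saturation.

What the generator does *not* emulate: among-gene rate variation,
alignment error, missing data within retained genes, fossil-calibration
uncertainty (HPDs are consumed as metadata, never estimated), and any
geological time-stratification of dispersal. Passing tests therefore
demonstrate internal correctness of the inference machinery under the
stated models, not robustness to real-data violations of them.

## Experiment sizes and numerical choices

- Oracle comparisons run on all ≤4-tip, ≤3-area instances in the test
  grid (enumeration is exact there); tolerance 1e-8 for pruning vs
  enumeration, 1e-12 for +j nesting.
- Parameter recovery: 20 replicates of 300-tip trees under the five-area,
  max-range-2 study design at d = 0.02, e = 0.01 per Ma, root age 120 Ma,
  survival-conditioned ML with two starts. Median relative errors are
  well under 25% for d; for e they sit near 20%, reflecting the
  well-known weak identifiability of range loss (the median fluctuates by
  several points across seed sets).
- +j power: 15 replicates of 29-tip data at d = 0.005, e = 0.01, j = 1.5
  — founder-event-dominated evolution — tested by LRT at α = 0.05.
- BBM validation uses ≤5-tip instances at fixed rates (tolerance 0.02)
  and 10-chain seed-to-seed agreement at 0.02.
- Ultrametricity tolerance is relative (default 1e-6 × height), and the
  offending tip is reported against the majority root-to-tip depth.
- Matrix exponentials are dense; the state space tops out at 2^5 = 32
  states for five areas, so no sparse machinery is used.

## Known limitations

- No time-stratified or distance-scaled dispersal matrices.
- BBM assumes rate homogeneity across branches and areas' independence;
  an asymmetric-frequency (F81-like) variant is future work.
- The event-matrix "window" convention (cladogenesis + subtending branch)
  is one defensible reading of published per-node event tables; the
  alternative clado-only window is exposed but counts from different
  windows are not comparable across publications.
- DEC's e is weakly identified on survivor-conditioned data; treat
  absolute range-loss estimates with caution, especially without
  `condition_survival`.
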