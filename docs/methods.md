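# Methods

## Configuration space and encoding

Sites are ordered (N-1, N-2, N-3); a configuration is their joint occupancy.
The fixed index encoding is

    1=(1,1,1)  2=(0,1,1)  3=(1,0,1)  4=(1,1,0)
    5=(1,0,0)  6=(0,1,0)  7=(0,0,1)  8=(0,0,0)

The 32 reactions are the 12 assemblies and 12 disassemblies (the edges of
the occupancy 3-cube) plus 8 slides between adjacent sites with empty
destination (undirected pairs {2,3}, {3,4}, {5,6}, {6,7}). Matrix
convention: `Q[i,j]` is the rate of configuration *i* → *j*, rows sum to
zero, and the stationary distribution solves `pᵀQ = 0`. This is stated
prominently because the transpose is the classic source of silent bugs in
master-equation code; the master equation itself reads `dp/dt = s·Qᵀp`
with `s` the time scale in 1/h.

## Process hierarchy and governance

The catalog holds 46 processes: 2 mandatory global (A, D), 1 global slide,
6 site-specific assembly/disassembly, 5 site-specific slides, 32
configuration-specific. Within a model, each reaction is governed by the
most specific covering process (smallest governed set). Processes of equal
set size never overlap, so claiming reactions in ascending size order
resolves governance exactly and independently of insertion order. A model
in which some process governs no reactions after overruling is redundant
and excluded.

## Enumeration and duplicate identification

Candidates are all process sets containing A and D with at least one
regulated and one constitutive process and `3·|regulated| + |constitutive|
≤ 7` (70,270 raw candidates; a closed-form count cross-checks the
generator). Two retained models must not describe identical rate-matrix
families. The implemented duplicate rule: models whose resolved reaction
partition and regulated flags coincide are duplicates *iff they differ
only in their non-global sliding process composition* — such pairs are
pure relabelings of the same sliding rate slots (e.g. {S2\*, S21} versus
{S21, S23}). Signature-equal models that differ in assembly/disassembly
composition (e.g. {A, D, A1, A2} versus {A, D, A2, A3}) or in the use of
global sliding are counted as distinct model hypotheses: their parameters
attach to different named mechanisms even though the reachable matrix set
coincides. This rule yields 68,145 models and leaves all site-specific
assembly/disassembly occurrence frequencies exactly equal while slightly
depleting non-global sliding processes — the qualitative census the model
class is known for. Enumeration order is (parameter count, process ids,
regulated ids) in catalog order, so model indices are stable for this
implementation; they are deliberately not aligned with any external
numbering.

## Equilibrium detection

Detailed balance for all positive parameter values is decided by the
Kolmogorov cycle criterion: (a) any slide reaction covered in one direction
only forces a one-way edge and hence nonzero net flux; (b) otherwise, for
5 seeded generic rate draws in [0.1, 10], the sum of forward-minus-backward
log rates around every basis cycle of the reaction graph must vanish
(tolerance 1e-9). The cycle basis is cached per slide-coverage pattern (16
possibilities). The criterion is validated in the tests against a brute
force oracle (steady state via GTH, max |net flux| < 1e-10 over random
draws). The census over the full catalog is 194. Note the two categories
that generate these models — all-global models (8) and models free of
sliding and configuration-specific processes (188) — overlap in the two
simplest {A, D} models; quoting 8 + 188 = 196 double-counts that overlap.

## Steady states and derived quantities

Steady states use the Grassmann–Taksar–Heyman state-reduction algorithm
(subtraction-free, numerically stable for stiff generators); a dense
nullspace solve is kept as a test oracle only. Irreducibility is checked
via strongly connected components; reducible matrices raise an error that
fitting converts to a −∞ likelihood. Accessibility of a site is the summed
probability of configurations with that site empty. Net fluxes
`J_ij = p_i Q_ij − p_j Q_ji` are antisymmetric and conserve probability at
each configuration; site-centric aggregation reports net
assembly-minus-disassembly per site and net slide fluxes N-2→N-1 and
N-3→N-2, which balance per site at steady state. Site-centric fluxes are
reported per promoter (probability flux, 1/h after applying the time
scale). Effective opening/closing rates are `s·|Re λ₂|` of the activated/
repressed generator (the slowest nonzero relaxation rate after an
instantaneous regulation switch, an upper bound on switching speed); a
complex λ₂ is reported by its real part with a warning.

## Likelihoods

Stage 1 is the multinomial log10 likelihood of the configuration counts
under the model steady states, multinomial coefficient included (it cancels
in R1). The normalization slot — the activated-state global assembly rate —
is fixed to 1; it embodies the overall time-scale degree of freedom and is
counted as one of the model's parameters. Stage 2 is a Gaussian likelihood
(constants dropped; maximum 0) of the four accessibility fold-changes, with
model fold-changes computed from prefactor-modified activated matrices; the
printed SDs are squared to variances. The κ bounds [1/5, 5] cap the
representable change in apparent N-3 binding energy at ln 25 ≈ 3.2 k_BT.
Stage 3 adds two Gaussian terms: the Flag(N-1)/Flag(N-2) log2 ratio at one
time (variance from the two replicates, ddof = 1) and the mean-centered
log2 Flag/Myc series at N-1. Centering makes the covariance
`C = sd²(I − J/4)` singular; the likelihood uses its Moore–Penrose inverse
(rank tolerance 1e-10), equal to `(I − J/4)/sd²` because the centering
projector is idempotent. Centering makes the term invariant under adding a
constant to all model h values, which the tests assert through the
pseudoinverse path.

## Histone exchange model

The free-histone pool holds Myc at `αM/βM` and Flag rising after a lag
`t0` as `F(t) = αF/βF·(1 − e^{−βF(t−t0)})`; defaults αF = 50/min,
αM = 10/min, βF = 0.01/min, βM = 0.03/min, t0 = 15 min (pool parameters are
in 1/min and converted to hours at a single point). A new nucleosome is
Flag-tagged with probability `P+(t) = F/(F+M)`, rising from 0 to 0.9375.
Each configuration is refined by per-site tags (empty/Flag/Myc; 27
states). Assembly splits into Flag (`×P+`) and Myc (`×(1−P+)`) channels;
disassembly and slides move tags at unchanged rates, so marginalizing tags
recovers the 8-state generator exactly (lumpability, asserted entrywise
and on trajectories). The tagged master equation `dq/dt = s·Eᵀ(t)q` is
integrated with LSODA (rtol 1e-8, atol 1e-10), re-evaluating `P+(t)`
inside the right-hand side; `E(P+) = B + P+·Δ` is precomputed so only a
scalar and one matrix-vector product vary per call. Integration starts at
t = 0 from the repressed steady state with all nucleosomes Myc-tagged;
since `P+` vanishes before the lag this equals starting at t0. Observables
are `g = log2 Flag(N-1)/Flag(N-2)` and `h = log2 Flag/Myc at N-1`. By
default model observables are evaluated at the nominal measurement times
with the lag acting only inside `P+` (the convention under which the g
ratio is quoted at t′ = 2 h); a `lag_shift` option instead shifts the
evaluation times by t0, matching the convention in which data time axes
are displayed shifted by 0.25 h.

## Fitting

All fits run in log10 parameter space with box bounds (rates [1e−2, 1e2],
κ [1/5, 5], time scale [1e−3, 1e3] 1/h — the wide time-scale range plus
the sloppiness flag covers its weak identifiability) using L-BFGS-B with
numerically estimated gradients (ftol 1e-9) from multiple starts: the
default 100 starts draw initial rates log-uniformly over the bounds, κ
always starts at 1, and later stages warm-start from the previous stage's
optimum. Runs are reproducible bit-for-bit for a fixed seed. Models whose
converged optima differ in value beyond tolerance, or whose best optimum is
reached at distant parameter vectors, are flagged (`multiple_optima`,
`non_unique_params`), not discarded. The staged pipeline keeps models with
`R_k < Rmax` (default 6) after each stage; every stage refits all previous
data, so survivor sets shrink monotonically and the staging order is
immaterial.

Sensitivity analysis scans the joint negative log10 likelihood from the
optimum along each parameter axis, each Hessian eigenvector and the
gradient (nonzero when the optimum sits on a bound), in exponentially
growing steps, *ignoring bounds*, until the likelihood has dropped by 0.30
log10 units (≈50%). A parameter's error bar is the largest log10 deviation
at the drop level over all directions; directions that never cross within
3 decades set a `sloppy` flag.

## Synthetic data generator

The generator emulates the three measured data types from a fully
specified model: per-state multinomial configuration counts (default 150
molecules per state, the order of magnitude of single-molecule EM
datasets), Gaussian fold-change noise on the fold-change scale truncated
at zero (matching the stage-2 likelihood), and Gaussian noise (default SD
0.4) on g replicates and on h values before centering. The default ground
truth uses the best-supported model structure {A regulated; D, D1-4, S2\*,
S3-4} with plausible synthetic rates — regulated assembly decreasing
repressed → activated, sticky-mutant κ pattern a3 > 1, d3 < 1, s32 > 1,
s23 < 1 — chosen once for a mostly-occupied repressed and largely-open
activated promoter; they are not fitted values from any experiment. What
the generator does not emulate: EM measurement artifacts, methylation
footprint error models, or microarray normalization of exchange data —
passing recovery tests therefore demonstrates correctness of the
inference machinery, not robustness to those real-data distortions.

## External data availability

The three-state single-molecule configuration counts exist only as a
source-data spreadsheet of the original study and are not redistributed;
the package ships a clearly labelled synthetic stand-in
(`data/config_counts_synthetic.tsv`) plus loaders for a user-supplied
transcription (`data/config_counts_measured.tsv`). The exchange fixture's
four h measurement times are likewise not printed in the modelled summary;
the packaged file uses assumed times (0.5, 1, 2, 4 h) and documents that in
its header. Reference-value checks that need the measured counts fail with
an explanatory message rather than silently skipping.

## Problem sizes used in the test suite

The suite fits single models and a 7-model pipeline with 2–4 multi-starts,
uses 20 000-molecule counts for parameter recovery, and runs the full
68,145-model enumeration plus equilibrium census (a few seconds). These
sizes were chosen so the whole suite completes in about a minute while
still exercising every stage end to end; production pipeline runs over the
full catalog with 100 starts are embarrassingly parallel across models.

## Known limitations

* The duplicate-identification rule is a reconstruction (see above); the
  catalog size depends on it, and alternatives (pure signature collapse)
  give slightly smaller catalogs.
* Stage-3 fits inherit the time scale's weak identifiability; error bars
  from the sensitivity scan, not point estimates, are the meaningful
  output.
* The design is fixed to three sites; generalizing requires regenerating
  the configuration space, process catalog and κ placement (the extension
  point is `config_space.build_configuration_space`).
* Stochastic trajectory simulation is not a supported interface; all
  dynamics are solved at the distribution level.
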