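# Methods

This note documents the estimator, its defaults, the synthetic benchmark
generators, the numerical choices, and the limitations a user should know
before trusting a reconstructed causal network.

## State-space reconstruction

Each scalar series {x_t} is embedded as delay vectors
(x_t, x_{t−τ}, …, x_{t−(E−1)τ}); for generic observables of an autonomous
deterministic system the resulting shadow manifold is diffeomorphic to the
attractor, which is what licenses cross-map estimation between variables
of the same system.

* **E (embedding dimension)** — default 4.  Automatic selection uses the
  false-nearest-neighbour criterion with the classical defaults: ratio
  test r_tol = 10, absolute test a_tol = 2 standard deviations, false
  fraction cutoff 1%, searched up to E = 8.  The unfolding coordinate is
  the *next* sample x_{t+τ} beyond the reconstruction window: for
  noninvertible dynamics (a logistic map) the past is not a function of
  the present, and a past-looking test never unfolds.  A rounding-noise
  floor (10⁻⁹σ) on the ratio test keeps exactly periodic signals from
  being flagged on machine-epsilon distances.
* **τ (lag)** — default 1 (appropriate for maps).  Automatic selection
  takes the first local minimum of the delayed mutual information,
  estimated with marginally equiprobable bins (⌈√L⌉ of them).  When the
  DMI curve is essentially flat — its range below 25% of its maximum, as
  for white noise — no lag is preferable and the fallback τ = 1 is
  returned.  Both selector parameterisations are conventions; nothing in
  the estimator depends delicately on them.

## Cross mapping with delay optimisation

To score causation U → V, the E_v + 1 nearest neighbours of each point of
M_V (the minimal bounded simplex in E_v dimensions) are mapped to the
same-time points of M_U and averaged with weights w_i ∝ exp(−d_i/d_min);
the skill is ϱ = |Corr(u_t, û_t)| over the common support.  Exact
zero-distance matches take the whole weight mass (they are perfect
predictors).  Because influence propagates with a lag in discrete-time
systems, the effect series is translated over candidate delays
(default −5…5, both signs, since the favourable sign is not known a
priori) and the delay maximising the skill is kept.  Ties are broken
toward the smallest |delay|, preferring the negative one, so argmax
results are platform-independent.

Defaults chosen where the procedure is silent: Euclidean metric;
Theiler exclusion window 0 (only the query point is excluded — the
benchmark maps decorrelate in one step; an `exclusion` parameter exists
for flow-like data); minimum common support 20 points, below which a
pair errors rather than returning a correlation estimated from noise.

## The direct-causation index

For a pair (X, Y) conditioned on mediators Z¹…Zˢ the engine builds, per
mediator, the nested estimate X̂^{Ẑ^Y} (Z estimated from M_Y, then X
estimated from the manifold of that estimate — the information that flows
X → Z → Y), plus the plain X̂^Y, every link delay-optimised.  Then

    ϱ_C = |Corr(X, X̂^Y)|,
    ϱ_D = |Pcc(X, X̂^Y | {X̂^{Ẑ^Y}})|.

**Alignment.** Delay translation and nested estimation shrink supports,
so X, X̂^Y and all conditioning estimates are restricted to the
intersection of their supports before any correlation is taken; each
higher order is aligned with its own conditioning set.  The procedure
itself does not fix an alignment rule; intersection is the only choice
that uses every series unmodified.

**Partial correlation** is computed from least-squares regression
residuals (numerically stable for several conditioners); the defining
recursion is retained as an independent formulation and the two agree to
10⁻¹⁰ on well-conditioned data — that equivalence is asserted in the test
suite.  A conditioner with |Corr| > 1 − 10⁻¹⁰ against either argument
raises a zero-denominator error naming the pair.

**Higher orders.** ϱ_D2 … ϱ_Dn condition on estimates routed through
every *ordered* chain of n distinct mediators (s!/(s−n)! chains); a
configurable cap (default 64 chains) turns combinatorial explosions into
an explicit refusal rather than silent truncation.  The decision uses the
first order by default — higher orders are opt-in via `order=` — and the
proximity index γ = (∏ ϱ_Dn)/ϱ_C^s (= ϱ_D/ϱ_C when only order 1 is
computed) is reported so users can apply a closeness cut when both
indices hover near T.

**Decision rule.** direct if ϱ_D ≥ T; indirect if ϱ_C ≥ T > ϱ_D; none if
ϱ_C < T.  T = 0.5 by default.  The "much greater" in the indirect case is
operationalised as a single threshold crossing; γ carries the graded
information.

**Network strategies.** `all` conditions jointly on every other variable;
`top_score` keeps the q = 3 mediator candidates maximising
ϱ_C^{X→Z} + ϱ_C^{Z→Y} (high prior probability of an indirect route);
`sparse_min` conditions on each candidate singly and reports the minimum
ϱ_D — appropriate when the network is known to be sparse.  Per-pair
failures are recorded on the edge (`decision = "error"`) and never abort
the matrix.

**Significance.** Circular time-shift surrogates of the source series
(seeded random rotations) preserve autocorrelation while destroying
cross-dependence; the identical pipeline is re-scored and
p = (1 + #{surrogate ≥ observed})/(1 + N).  Across a network the
Benjamini–Hochberg adjustment is reported alongside.  The scheme is a
documented choice: the procedure calls for multiple-testing-corrected
significance without fixing the null generator.

## Benchmark generators

The generators *are* the study conditions; they are first-class, tested
code.  The n-node coupled logistic network iterates

    x^j_t = x^j_{t−1}(α_j − α_j x^j_{t−1} − Σ_i β_ji x^i_{t−1}) + ε_j,t

with independent Gaussian noise per node and step (sd 0.005 — "white
noise" read as Gaussian, the conventional choice) and ground truth
*derived from the coupling matrix* (edge i→j iff β_ji ≠ 0), so truth and
dynamics cannot drift apart.  The three-species system uses the growth
rates (3.6, 3.72, 3.68) for (X, Y, Z) and preset modes: direct (β_yx),
chain (β_zx, β_yz), loop (β_zx, β_yz, β_xy), plus fan-in, fan-out and
cascade motifs for recovery studies.  Coupling magnitudes for the modes
are not part of the printed system; 0.4 is the package default for every
active β, configurable.  Burn-in 1000 steps; initial states uniform on
(0.2, 0.8), seeded; trajectories leaving (−0.5, 1.5) raise a divergence
error naming the step (never triggered at the defaults — checked over
hundreds of seeds).  A noise-free causal-chain variant (X autonomous)
supports transitivity demonstrations, and a documented synthetic 8-node
ring-plus-chords network (10 edges, β = 0.2) stands in for a
network-scale topology.

The trial protocol draws aligned random segments (default 100 trials of
length 1000 from length-5000 runs) with one seeded offset per trial.  A
single user seed fans out to all stages through fixed integer-keyed
SeedSequence derivation, so adding trials never perturbs earlier ones and
every CLI run is byte-for-byte reproducible.

What the generators deliberately do **not** emulate: observational noise,
irregular sampling, missing data, nonstationarity, or continuous-time
dynamics.  Passing benchmarks therefore demonstrates correctness of the
estimator under its own assumptions, not robustness to real-data
pathologies.

## Problem sizes used by the shipped studies

The acceptance script runs the full 100-trial protocol per mode (about
half a minute total).  The test suite uses 30 trials for the three
headline modes (same verdicts as 100), 20 trials per motif for structure
recovery, and 200 repeats × 99 surrogates on length-300 segments at a
single delay for null calibration — sizes chosen so the whole suite runs
in a few minutes while keeping every comparison statistically meaningful.

## Known limitations

* **Near-synchronization.**  Strong unidirectional coupling partially
  enslaves the driven variable; its state becomes an approximate function
  of the driver's history, which creates *genuine* reverse-direction
  cross-map skill that no mediator conditioning can remove (there is no
  mediated path).  At the benchmark's β = 0.4 the spurious reverse index
  sits near 0.5 for the strongest links (independently confirmed by
  cross-validated k-NN regression of the driven state on driver history),
  so exact full-adjacency recovery at T = 0.5 fails for the chain and the
  common-driver motifs even though every mediated link is correctly
  suppressed.  Synchronized and strongly coupled regimes are outside the
  method's scope; larger embedding dimensions shrink (but do not
  eliminate) the artifact.
* The framework assumes autonomous deterministic dynamics observed
  through smooth functions; heavily forced or nonstationary records
  violate the embedding premise.
* Delay-scanning maximises over candidates and therefore inflates weak
  indices slightly (max of several noisy values); the surrogate test
  re-scores surrogates through the same maximisation, keeping p-values
  calibrated.
* Higher-order conditioning cost grows factorially; the cap makes this
  explicit rather than silently truncating.
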