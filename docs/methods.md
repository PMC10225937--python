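# Methods

## The model

A circuit of `n` genes is described by the protein concentrations
`ω = (ω_1, …, ω_n)` with thermodynamic (promoter-occupancy) kinetics

    dω_i/dt = p_i · N_i / D_i − d_i ω_i
    N_i = l_i + m_i q_i(S) + Σ_{j activates i} k ω_j²
    D_i = 1 + N_i + Σ_{j represses i} k ω_j²

where `q_i(S) = R_i S² / (K_i² + S²)` is the Hill response of the
signal-bound activating transcription factor (cooperativity 2), regulators
bind as dimers (exponent 2), a single rate constant `k` is shared by all
active regulatory edges, and `m_i` marks the genes receiving the signal
(genes U and V in the superstructure; gene W, when present, receives none).
The wiring is a signed integer matrix `y` with `y[i][j] ∈ {−1, 0, +1}`:
gene j represses, ignores, or activates gene i. Self-edges follow the same
rule (self-activation contributes to both `N_i` and `D_i`, self-repression
to `D_i` only). Two tying rules reduce the search dimension by default:
the leakiness of the two signal genes is shared (`l_v = l_u`) and the first
degradation rate is fixed to one (`d_u = 1`), which sets the time unit.

The bifurcation parameter is the signal concentration S. The diagram
classes of interest are the **mushroom** (four saddle-node points, two
disjoint bistable signal ranges, an intermediate "ON" branch available
only at intermediate signal) and the **isola** (a closed equilibrium branch
bounded by two saddle nodes, coexisting with a fold-free outer branch).

## Saddle-node detection

At an equilibrium, the extended Jacobian `Q = [D_ω f, D_S f]` (shape
N×(N+1)) has a one-dimensional null space spanned by the branch tangent β
(computed by SVD; the point is declared degenerate when the smallest
singular value falls below 1/gate² ≈ 1e−6 of the largest, as at a cusp).
A saddle node is exactly the condition `β_{N+1} = 0`, so the scalar

    J = β_{N+1}²

vanishes precisely at folds; the design objective is `Ψ = Σ_k J_k` over the
prescribed fold coordinates. State and signal Jacobians are analytic and
vectorized over batches; a central-finite-difference fallback serves
models that provide only a right-hand side.

## Diagram tracing

Isola branches are disconnected from every boundary equilibrium, so the
tracer is a dense root sweep rather than pseudo-arclength continuation:

1. All equilibria on a signal grid (default: geometric spacing at low
   signal, linear above — folds cluster at low S) from a Newton lattice of
   8 seeds per state axis, batched over the whole grid.
2. Neighbor-seeding refinement: roots found at each grid value seed the
   adjacent values, repeated until no new root appears. This recovers
   equilibria whose Newton basins are smaller than the lattice spacing and
   keeps per-slice counts consistent.
3. Branch linking by nearest-neighbor assignment (Hungarian matching,
   stability-consistent, relative distance gate 0.5).
4. Every equilibrium-count change is refined by bisection to 1e−6 of the
   grid span and polished by a Moore–Spence solve (`f = 0`, `Jφ = 0`,
   `|φ| = 1`, with S parametrized as exp σ to preserve positivity). Traced
   folds carry `J ≲ 1e−30` and equilibrium residuals ≤ 1e−9. Duplicate
   folds (re-detected in adjacent intervals) are merged at relative
   distance 1e−3 in S.
5. Branches are joined into components through their folds; a component is
   *closed* when none of its branches touches the signal window edge.

**Classification.** monostable: no folds, a unique branch. isola: a closed
two-fold component passing the curvature signature (below) plus a fold-free
open branch. mushroom: four folds bounding two disjoint interior bistable
ranges with a distinct intermediate branch in the gap between them;
*inverted* when that branch sits at lower expression (first state
coordinate) than the outer locus. bistable switch: two interior folds, one
bistable range, open branches. incomplete mushroom (left/right): a bistable
range truncated by the signal window (its edge is not anchored to a fold).
Anything ambiguous is labeled `other` rather than forced into a class.

**Isola curvature signature.** On an isola the two folds are the signal
extremes of one closed curve: the inverse-function curvature d²S/dω² is
positive at the low fold and negative at the high fold, and — the
operationally decisive part — the entire fold-bearing curve lies within
[S1, S2]. A bistable S-curve has the same local curvature signs at its own
folds (every fold bounding a bistable range from the left is a local
minimum of S along its branch), so local curvature alone cannot separate
the two classes; the containment criterion does, and is what the check
enforces together with the quadratic curvature fits (5 nearest branch
points per fold).

## Design search

The design problem is mixed-integer: find wiring `y`, kinetics `x` and fold
coordinates `(S_k, ω_k)` minimizing Ψ subject to `f(ω_k, x, y, S_k) = 0`,
bounds on `x` and `y`, and rectangular target boxes per fold. The search is
a seeded multistart hybrid with a global (diversification) and a local
(intensification) phase per start:

1. **Sample a wiring** uniformly within the integer bounds (unconnected
   wirings fail immediately).
2. **Diversification:** up to 40 log-uniform parameter draws (120 once
   interior multistability is seen) are scored by the fold transitions of a
   fast equilibrium-count profile over ~40 signal values; a log-space
   mutation hill climb (40 steps, step 0.4, 1–3 coordinates) intensifies
   from interior-bistable draws, since small moves often open the second
   bistable range.
3. **Fast path:** when the best draw's profile already shows the prescribed
   fold structure, its diagram is traced and verified directly.
4. **Local solve:** otherwise SLSQP minimizes Ψ over (log x, log S_k,
   box-normalized ω_k) with the equilibrium constraints normalized by
   promoter strength, fold ordering enforced with ≥10 % relative
   separation (raised-to 30 % between prescribed folds to steer away from
   coincident-fold cusp minima), restarted up to six times (the reset
   quasi-Newton model reliably finishes nearly-converged runs; runs
   stalling above Ψ = 0.05 or contracting by less than 3× per round are
   abandoned). Near-converged runs (Ψ < 0.05, feasibility ≤ 1e−3) are
   finished by per-fold Moore–Spence solves at fixed parameters.
5. **Verification:** success requires Ψ ≤ 1e−6 *and* a full trace whose
   label matches the target class with exactly the prescribed number of
   folds, each inside its box (2 % relative slack). Ψ alone can vanish at
   coincident folds; verification rejects those.

All child seeds derive deterministically from the master seed; a start is
bitwise reproducible from its seed.

**Default study conditions.** Parameter bounds: promoter strengths
[10, 2000], leakiness [1, 500], interaction k [1e−3, 1], TF totals
[50, 500], dissociation constants [1, 300], degradation rates [0.1, 10]
(all log-sampled; every printed reference value lies inside). Fold target
boxes (pairwise mode: the two low-signal folds share the first box):
S ∈ [0.1, 40] and S ∈ [2, 300] with expression ceilings (500, 1000) for
two genes, (500, 1000, 2000) for three. The boxes were fixed once by
tracing where the folds of mushroom-capable circuits drawn from the
default bounds actually fall; narrower boxes are the intended mechanism
for user-specific designs (e.g. enforcing a stricter expression range on
one gene, which breaks the mirror symmetry between wirings).

Isola design prescribes two folds with curvature conditions
`("curvature", "+-")` (the isola signature; `"-+"` targets a bistable
switch instead) and accepts only solutions verifying as isolas.

The ε-constraint scalarization turns a multi-objective problem (Ψ = 0 as a
constraint, plus e.g. protein burden Σ p_i) into a grid of single-objective
solves; infeasible levels are recorded and the non-dominated union is
returned.

## Reference circuits

The printed parameter sets used as regression fixtures are two-gene
circuits with the signal activating both genes. Their wirings are published
only graphically, so the package validated candidate signed wirings
computationally against all printed behaviors simultaneously: the
biosensor set (`fig5_A1`: p0=361, p1=p3=30, p2=411, k=9.04e−2, R1=143,
R2=300, d_u=1, d_v=1.38, K1=10, K2=137) must trace to a four-fold mushroom,
its p1=200 variant to an isola, and its p1=20 variant back to a (reopened)
mushroom. The unique wiring satisfying all three is mutual repression plus
self-repression on gene U (`[[−1,−1],[−1,0]]`); the phase-diagram base set
(`fig4_A3`: p0=230, p1=p3=50, p2=1000, R1=264, R2=275, K1=10, K2=133,
d_u=1) uses the mirror wiring (self-repression on V). The fig4 base point
(k=0.1, d_v=0.7) is a package default chosen by a coarse scan, since only
the sweep axes are published. Under these wirings the intermediate (ON)
branch carries high u and low v; ON/OFF labels are assigned by branch
identity, never by an expression threshold.

**Pinch direction.** For these circuits the mushroom neck pinches into an
isola and then collapses to monostability as d_v *decreases* (increasing
d_v instead widens the neck and pushes the bistable ranges out of the
window); the phase-map sweep and the pinch property test therefore run
along decreasing d_v.

## Robustness

Per topology, the verified solutions' parameter vectors are standardized
against the pooled solution set of all topologies, then scored by (i) the
natural log-determinant of the sample covariance (a hypervolume proxy;
singular covariance is an explicit error, never a silent −∞, so ranking
code must handle missing scores) and (ii) the sum over parameters of the
interquartile range (linear-interpolation quantiles). Bootstrap (default
1000 resamples, seeded) yields medians and quartiles; replicates with
singular covariance contribute only to the IQR statistics. The
robustness-versus-connections table feeds the Pareto front (maximize
robustness, minimize connections). Both the quantile method and log base
are recorded in every report.

## Dynamics

Deterministic runs use a stiff-capable adaptive integrator (LSODA, rtol
1e−8). Gaussian pulses follow `S(t) = S_min + (S_max − S_min)
exp(−((t−100)/τ)²/2)` with S_min = 10 and the printed center t = 100.
Noisy signals are a driftless random walk precomputed at dt = 0.01
(seeded), reflected at zero and held piecewise-constant; the diffusion
coefficient (default 1.5 concentration/√time) and the walk's start (the
midpoint of the configured range) are package defaults — the published
noisy-signal experiments specify neither. For noisy runs the integration
tolerance is relaxed to 1e−6 with step cap 0.5, since the signal noise
dominates the error budget.

The activation map starts the circuit on the outer (OFF) branch at the
baseline signal and records whether a pulse of given (τ, S_max) leaves it
on the intermediate (ON) branch; the horizon extends with τ
(center + max(6τ, 100) + 100) so slow pulses can settle. The isola memory
demonstration places the state on the isola by a reset override (leakiness
lowered to 20, which reopens the mushroom whose head deforms continuously
into the isola branch), integrates under the noisy signal, records each
onset of an excursion beyond the isola's fold range, and checks that after
an excursion (plus ~60 time units of relaxation in the tests) the isola
branch is never reoccupied. Paths whose first excursion happens too close
to the horizon are still in transit and classify as neither branch.

## Scale choices and what the tests show

The exhaustive screens are reported in the source material at 2000
(two-gene) and 10000 (three-gene) starts; the package's test suite and
acceptance script run desk-scale versions (500 and ~100 starts, seeded)
chosen so the full pipeline re-runs in minutes: at these scales the
two-gene screen typically recovers 4–7 of the mushroom wirings (a 500-start
run at seed 1 found all 7 distinct wirings, the cross-repression core most
frequent) and the three-gene screen a handful. The stochastic tests assert
structural properties (distinct-count growth, verification of every hit,
presence of the cross-repression core) rather than exact hit counts.
Synthetic robustness inputs are Gaussian/uniform clouds with known
covariance — they validate the scores' closed-form behavior, not the
distributional shape of real solution sets, whose spread is typically
heavier-tailed in log-parameter space.

## Known limitations

- Hopf bifurcations are not detected; oscillatory attractors, if present,
  would be reported as an absence of stable equilibria rather than
  classified.
- The tracer's resolution is bounded by the signal grid: bistable ranges
  narrower than a few grid steps at their location can be missed or
  reported with zero measured width.
- Stability is assessed by equilibrium eigenvalues only; basins and
  transient excitability are outside scope.
- Intrinsic gene-expression noise (Langevin/Gillespie) is not modeled;
  the noisy-signal demonstrations perturb the signal only.
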