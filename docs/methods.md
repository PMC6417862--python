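# Methods

`treadnet` models the dynamic steady state ("global treadmilling") of branched,
Arp2/3-nucleated actin networks grown in vitro from micro-printed nucleation
patterns: polymerization at a leading edge, ADF/Cofilin-driven fragmentation at
a trailing edge, and the feedbacks between them that select an equilibrium
network length. This note documents the models, their assumptions, the
numerical choices, and what the synthetic data do and do not emulate.

Canonical units everywhere: concentrations in µM, lengths in µm, times in s.
Literature values quoted per minute (e.g. a binding rate of 0.5/min/µM) are
converted at the boundary.

## 1. ADF/Cofilin transport and local depletion (`transport`)

Two depth-averaged 2D fields on the chamber plane: free cofilin `CF(x, y, t)`
diffusing in solution, and bound cofilin `CB(x, y, t)` riding on network
material that drifts away from the leading edge at the growth speed `V`:

    dCB/dt = -V dCB/dy + rB A CF - rU CB        (inside the network)
    dCF/dt =  D lap(CF) - rB A CF + rU CB

Assumptions: the chamber is thin, so 2D is adequate; actin disassembly is not
modeled here (the actin density `A` is prescribed, constant or tabulated
`A(y)`); binding is diffusion-limited and linear in `A·CF` (an optional
saturation factor `max(0, 1 - CB/(s_max·A))` exists but is off by default);
steric hindrance of diffusion inside the mesh is a few-percent effect, so the
`diffusion_correction` factor defaults to 1.

**Frame and geometry.** The nucleation line is stationary, so the leading edge
is fixed at a horizontal row; network material and its bound cofilin advect in
+y at `V`; the mask is a `W × L(t)` rectangle with `L(t) = V t` (plus an
optional `initial_length`), extended by whole grid rows. By default the
network's final extent is centred in the domain.

**Numerics.** First-order operator splitting per step: (i) conservative
first-order upwind advection of `CB` restricted to the mask, with zero inflow
at the leading edge and retained outflow at the trailing row (the trailing
edge recedes with the material, so nothing leaves); (ii) the linear two-state
binding/unbinding exchange solved *exactly* per cell (closed-form exponential
relaxation — unconditionally stable and mass-conserving); (iii) backward-Euler
diffusion of `CF` with a sparse operator factorized once (`scipy` `splu`) and
reused every step. Default spacing 1–2 µm (at least 10 cells across `W`),
default `dt = 2 s` capped by an advection CFL of 0.5. The leading-edge row is
treated as the `CB = 0` inflow boundary: material there has age zero, so
binding starts one row downstream. Boundary modes: `far-field` (Dirichlet
`CF = C0` on the domain edge, emulating the effectively infinite 20 × 20 mm
chamber) and `closed` (zero-flux; conserves total cofilin to direct-solver
round-off, used for the conservation tests). Negative concentrations beyond
1e-9 abort the run.

**Closed forms.** The no-depletion ("simple") model gives
`CB = kB C0 A y / V` and a critical-ratio equilibrium length
`L* = γ V / (kB C0)`. The quasi-steady estimate

    CF ≈ (C0 D + W L CB rU) / (D + A W L rB)

is an order-of-magnitude balance of diffusive supply against the binding sink.
Tested against the PDE it is good to a factor of two for depletion numbers
`rB A W L / D ≲ 2` and degrades beyond (ratio ≈ 2.5 at 5, ≈ 4 at 15), because
it carries no 2D geometry (no logarithmic supply factor). The property test
sweeps the moderate-depletion regime accordingly.

**Headline depletion run.** At the literature parameter set (V = 1.16 µm/min,
rB = 0.5/min/µM, rU = 0.31/min, A = 50 µM, C0 = 125 nM, W = 30 µm) on a
300 × 300 µm far-field domain, 40 min of growth depletes the free pool near
the network by ≈76% at the minimum (grid-converged from 3 µm to 1.5 µm
spacing and dt from 6 s to 1 s, and cross-checked with an independently coded
explicit scheme). The mean depletion over the network area is ≈63%. The
depletion deepens as the far-field boundary moves out (≈78% for a 600 µm
domain) and would only fall to ≈50% for a domain as small as ~60 µm, so the
value reported by `scripts/acceptance.py` reflects the declared geometry, not
a universal number: the quantity is geometry-sensitive and the in-chamber
truth depends on details (chamber-scale convection, measured `A(y)` inputs)
outside this model.

## 2. Stochastic fragmentation (`fragmentation`)

The network is a square lattice: nodes are effective crosslinking/branching
points, edges are filament arrays (not single filaments). Spacing defaults to
`a = 0.5 µm`. Nodes break independently at rate

    P = k_break · CB^β / A_local^α         (defaults β = 1, α = 2)

where `A_local` is a uniform-disc kernel average (radius `2a`) of intact
edges around the node, normalized so a fully intact lattice maps to `A0`
everywhere. Broken regions left behind by pruning stay visible to the kernel
(a margin of vacated rows is retained), so the trailing edge sees a locally
thinned mesh — the positive feedback that produces avalanche-like collapse.
Components disconnected from the leading-edge row are deleted
(`scipy.ndimage.label`), which is what makes disassembly *fragmentation*
(multi-node pieces) rather than erosion. Sampling is per-node Bernoulli with
`p = 1 − exp(−P dt)` (tau-leap style); the step must satisfy `dt·P ≤ 0.2`
for nodes above a density floor (default 20% of `A0`); below the floor a node
is effectively disconnected and may break within one step. By default `dt` is
chosen automatically from that contract and capped at one row-growth time.

`k_break` defaults to 0.25 µM/s, putting node-breaking events at the scale of
one per a few hundred seconds per micron of trailing edge at physiological
densities (tens of µM actin, a few µM bound cofilin).

**Measured length.** The trailing edge is the furthest row whose intact-node
occupancy is at least 10% of the columns. The strict any-node definition is
also available, but a single surviving node chain is invisible in a
fluorescence image, and the occupancy readout removes a constant
extreme-value offset of a few rows from the measured lengths.

**Transient diagnosis.** Equilibrium statistics are collected from twice the
time of the first macroscopic retreat (first drop of more than two rows below
the running maximum); runs that never retreat are flagged as not equilibrated.
Mean density profiles are averaged after rescaling each snapshot to its own
instantaneous length, so the sharp trailing-edge drop is not smeared by the
length fluctuations.

**Continuum approximation.** Material at distance `y` from the leading edge
has age `y/V`; its broken-node fraction obeys `V dq/dy = P(A0, CB)(1 − q)`,
`q(0) = 0`, and the network ends where `q` reaches a critical fraction
`q_c` (default 0.4), giving

    L = c · ln(1/(1 − q_c)) · V · A0^α / (k_break · CB^β)

with a calibration prefactor `c` fixed at one stochastic reference point.
The associated profile `A0 (1 − q(y))`, truncated at `L`, is near-flat before
the collapse. On its own simulations the package recovers log–log slopes of
about +1.8 in `A0` and −0.9 in `CB` (the stochastic avalanche renormalizes
the ideal +2/−1 slightly at these problem sizes: width 30 µm, lengths
5–70 µm, three seeds per point), and the calibrated continuum matches the
stochastic means to ≲13% over a 3 × 3 parameter sweep.

## 3. Equilibrium-length feedback system (`equilibrium`)

Combining disassembly with binding-with-depletion gives two `CB(L)` curves:

    CB = k1 A0² V / L                                        (disassembly)
    CB = k2 rB A0 C0 (L/V) · D / (rB A0 W L + D)             (binding)

The first falls, the second rises and saturates, so they intersect exactly
once: `(L*, CB*)` exists for every parameter combination. For α = 2, β = 1
the intersection is the positive root of a quadratic (used as the closed
form, cross-checked against a bracketing `brentq` search to 1e-10 relative).
Defaults: `k1 = 1 s/µM`, `k2 = 0.5`, `rB = 0.01/(s·µM)`, `D = 10 µm²/s`.
Generalized exponents are supported through the numeric path, with the
disassembly curve read as `CB = (k1 A0^α V / L)^(1/β)`.

Consequences carried by the solver and checked in tests: `L*` decreases with
`C0`, increases with `A0` and with `W` (wider networks deplete more, hence
live longer); the no-depletion limit is `L* → V sqrt(k1 A0/(k2 rB C0))`; the
strong-depletion limit is `L ≈ (k1/k2) A0² V² W/(D C0)` (the implementation
derives this from the two base relations; it is linear in `W` and quadratic
in `A0`) and matches the full solution to 10% when the depletion number
exceeds ~50. Phase maps over `(C0, A0)` or `(W, A0)` and the compensation
inversion (given a perturbed `A0` and a target length, solve for the `C0` or
`W` that restores it) are thin wrappers over the solver.

## 4. Elastic steering of heterogeneous networks (`steering`)

Two lanes of width `W` growing at `V1, V2` with elastic moduli `E1, E2`
(ratio `σ = E2/E1`) settle, in mechanical equilibrium, onto an arc of radius

    R = W [ (V1+V2)/(V1−V2) + (σ−1)(V1σ−V2) / (4σ(V1−V2)) ]

growing at

    Vh = (V1+V2)/2 − (V1−V2)(V1²σ²−V2²) / (2(V1²σ²+6V1V2σ+V2²)),

always turning toward the slower lane. Elasticity follows density as
`E ∝ A^τ` with τ = 2.5 by default (0.5 available; predictions are not very
sensitive). The beam force balance behind these closed forms is not
re-derived; the formulas are implemented and their limits tested (σ = 1
collapses R to `W(V1+V2)/(V1−V2)`; matched speeds grow straight; a very
sparse lane straightens the pair; an interior curvature maximum exists in σ;
`Vh` is invariant under swapping lanes with σ → 1/σ).

**Shared cofilin pool.** Two lanes compete for the same free pool, so their
equilibrium lengths are solved jointly with a shared depletion factor
`D/(rB(A1W1L1 + A2W2L2) + D)`. For α = 2, β = 1 this reduces to a scalar
quadratic (`L_i = K_i s`, `s² − b s − 1 = 0`), so joint ≥ isolated lengths
and the larger relative gain on the sparser lane follow analytically; the
closed form is cross-checked against the defining equations in tests.

**Shapes.** The centerline is integrated with pointwise curvature
`1/R(σ(y))`, where `σ(y) = (A2(y)/A1(y))^τ` from the lanes' density
profiles; beyond the shorter lane's trailing edge curvature is exactly zero
(the survivor grows straight; the transition is sharp by design). The
reported "mean curvature radius" is the inverse of the arclength-weighted
mean curvature over the *whole* centerline, straight tail included: that is
what makes the radius grow as rising cofilin shortens the curved sparse lane,
and it is stable for shapes mixing arcs and straight segments. For
cofilin-sweep comparisons the shape is evaluated over a fixed observed
arclength (the distance grown in a fixed time, default 30 min), not to the
longer lane's equilibrium length — otherwise the arc fraction would be
invariant, since both joint lengths scale with the same depletion factor.
Multi-lane mirror arrangements are exercised through the two-lane mirror
symmetry (swapping lanes mirrors the shape; no parameter set steers toward
the faster lane).

## 5. Synthetic data (`synthetic_data`)

Generators stand in for the imaging data so the inference stage is testable:

- **Kymographs** `CB(y, t)` along the network midline: `mode="pde"` runs the
  transport simulation (depletion included — later-starting material paths
  load more slowly); `mode="analytic"` is the no-depletion closed form, in
  which every material path is linear with slope `rB C0 A`. Beyond the
  growth frontier the analytic field continues with the frontier value so
  interpolated paths stay exactly linear. Additive Gaussian noise, clipped
  at zero.
- **Density profiles**: plateau at `A0` with a logistic collapse centred at
  `L − w/2` (width `w` defaulting to 10% of `L`, scale `w/8`), hard zero
  beyond `L`; multiplicative lognormal roughness.
- **Length tables**: records `(L, V, A0, CB)` over the experimental spans —
  cofilin 125–500 nM, widths 15/30/90 µm, density classes 30/50/80 µM with
  15% scatter; speed rises weakly with density (`V ∝ A0^0.3` around
  0.019 µm/s); `CB ≈ 10·C0` with 25% scatter; `L = c V A0^α / CB^β` times
  lognormal noise (default 10%).
- **Binding tables**: initial slopes `rB C0 A` with lognormal noise whose
  log-sd (0.78) is calibrated in closed form from the moment identity
  `R = sd(X)/sqrt(E[X²] e^{s²} − E[X]²)`, `X = C0·A`, so the Pearson
  correlation of slope with `C0·A` sits near 0.5 over repeated draws —
  the regime the correlation analysis operates in.

Noise models are additive Gaussian for image-like data and multiplicative
lognormal for strictly positive quantities. What the generators do *not*
emulate: intensity-to-concentration calibration (synthetic units are true
concentrations), microscope PSF/segmentation artefacts, and any correlation
structure between records beyond the condition design. Passing tests
therefore validate the estimators under the assumed noise laws, not under
raw-microscopy artefacts.

## 6. Inference (`inference`)

Initial binding slopes are OLS fits over the early window of each material
path (default: first 20% of the path, configurable in seconds; at least 3
samples), with optional mean-one normalization that makes slopes invariant
to intensity rescaling. The binding-rate test is a Pearson correlation of
slope against `C0·A`. Exponent fitting regresses `log(L/V)` on `log A0` and
`log CB` (the power law is linear in logs); `alpha_hat` is the `A0`
coefficient and `beta_hat` the negated `CB` coefficient, with OLS confidence
intervals, overall F-test p-value, and a standardized-predictor condition
number that rejects collinear designs. A fixed-exponent mode scores any
`(α, β)` pair by the R² of predicted vs observed log-lengths with a fitted
prefactor; on calibrated synthetic data the whole grid α ∈ [1,3] ×
β ∈ [0.5,1.2] stays above 0.7 when the truth is (2, 1). No multiple-testing
correction is applied: these are single planned tests.

## 7. Workbench and problem sizes

`workbench.RunConfig` (pydantic, unknown keys rejected, YAML round-trip)
drives named scenarios — depletion map, fragmentation run, phase maps,
steering sweep — each writing CSV/JSON plus a provenance sidecar (scenario,
parameters, seed, package version) that suffices to re-execute the run;
reruns byte-reproduce all CSVs. `compare_runs` diffs two bundles numerically
within tolerances. The `treadnet` CLI wraps the same functions.

Problem sizes used by the test suite and the acceptance script are chosen to
exercise every regime at laptop scale: transport tests use 60–300 µm domains
at 2–3 µm spacing; the headline depletion run in `scripts/acceptance.py`
uses the full 300 × 300 µm domain at 1 µm; fragmentation sweeps use width
30 µm, lengths 5–70 µm and three seeds per parameter point. All stochastic
components take explicit integer seeds and are bit-reproducible.

## Known limitations

- The transport model prescribes the actin density; it does not couple
  disassembly back into `A(y)` (that coupling lives in the feedback system
  at the mean-field level only).
- The fragmentation lattice has no mechanical stress propagation and no
  severing/debranching distinction; exponents near (2, 1) emerge as
  effective, not microscopic, parameters, and the recovered slopes on finite
  lattices are renormalized by ~10% below the ideal values.
- The quasi-steady estimate is only order-of-magnitude outside moderate
  depletion; use the PDE there.
- The beam model is 2D, static per arclength and torsion-free; viscoelastic
  relaxation is out of scope.
- Depth-averaging ignores the chamber's ~4.5 µm height and any difference
  between network thickness and chamber depth; the depletion magnitude is
  geometry-sensitive (see §1).
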