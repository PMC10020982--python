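# Methods

## Model

`hscniche` implements a deterministic compartment model of hematopoietic
stem cells (HSC) interacting with a bone-marrow niche of finite, constant
capacity `K`. Each clone `j` is tracked in three stem-cell states:

- `N_j` — niche-bound, quiescent;
- `A_j` — active, unbound: these cells divide or differentiate;
- `I_j` — inactive, unbound: post-division daughters that must reattach to
  the niche to remain stem cells, or are lost to differentiation.

With `E = K − Σ_k N_k` empty niche spaces, the dynamics are

```
dN_j/dt = b_j I_j E − u_j N_j
dA_j/dt = u_j N_j − (r_j + d_Aj) A_j
dI_j/dt = 2 r_j A_j − b_j I_j E − d_Ij I_j
```

Attachment is mass-action in empty niches and open only to inactive cells;
detachment activates cells at rate `u`; a division consumes one active cell
and yields two inactive daughters. The only sinks are the differentiation
terms `d_A A` and `d_I I`; these feed progenitor production, the flux
`φ_j = d_Aj A_j + d_Ij I_j` (cells/day). An optional lumped progenitor pool
`dD_j/dt = amp·φ_j − clear·D_j` is available but off by default: every
headline analysis uses the flux, which is fully determined by the stem-cell
states.

The separation of non-quiescent cells into active and inactive states is
what makes stem cells decay in the absence of a niche (`K = 0` or `b = 0`):
the unbound subsystem then has eigenvalues `−(r + d_A)` and `−d_I`, both
negative, regardless of how fast the cells divide.

## Equilibria and fitness

For a single persistent clone (`r > d_A`, `b > 0`) the positive equilibrium
is available in closed form:

```
E* = d_I (r + d_A) / (b (r − d_A))       N* = K − E*
A* = u N* / (r + d_A)                    I* = A* (r − d_A) / d_I
φ* = r A*
```

The clonal fitness `F = (b/d_I)(r − d_A)/(r + d_A)` satisfies `F = 1/E*`:
a clone's fitness can be read off the vacancies it leaves in monoclonal
homeostasis. `F` is independent of the detachment rate `u` and of `K`. In a
shared niche the clone with the highest `F` excludes all others and drives
the vacancy count to `1/F_max` — the analogue of the resource-competition
R* rule, with empty niches as the contested resource. Equal fitness means
neutral coexistence: any niche composition is then an equilibrium, and
composition is preserved from the initial condition.

Degenerate cases are reported as statuses rather than computed through:
`r ≤ d_A` or `b = 0` → no positive equilibrium; `u = 0` → a "frozen niche"
family (any occupancy with empty unbound pools is stationary).

Stability is assessed numerically — eigenvalues of a central-difference
Jacobian at the closed-form equilibrium, all real parts below `1e−8` — not
by re-deriving a symbolic proof.

Comparative statics (`comparative_statics`) re-evaluate the closed forms at
a 1%-perturbed parameter and report signs with a `1e−9` relative deadband
for declaring "0". The only conditional entry is the response of `A*` to
`r`: `dA*/dr > 0` iff `(d_I/b)(r + d_A)² > K(r − d_A)²`, i.e. only while
`r` is close to `d_A`.

## Numerical choices

- Integration uses `scipy.integrate.solve_ivp` with the implicit Radau
  method by default, `rtol = 1e−9`, `atol = 1e−12`. Interventions restart
  the integrator at each event time, so discontinuities are exact; the
  output grid is decoupled from internal steps, and a grid point that
  coincides with an event reports the post-event state.
- `simulate_to_steady_state` integrates in chunks sized from the slowest
  kinetic rate, growing geometrically, until the relative state change per
  chunk falls below `1e−10`.
- Competition runs start from the shared-niche quasi-equilibrium: the niche
  filled to the reference clone's monoclonal `N*`, split by the requested
  fractions, with unbound pools at their per-clone conditional equilibria.
  For neutral clones this lies exactly on the equilibrium manifold.
- Neutrality tolerance: relative fitness differences below `1e−9` are
  declared neutral. Any true difference wins eventually; how long depends
  on the parameters, so contest horizons are scaled inversely to the
  relative fitness gap.
- Exclusion time is the first crossing of a clone's niche fraction below a
  threshold (default 1%).

## Default parameterization

Raw rates are not uniquely identifiable from bulk count time series;
identifiable combinations are `F`, `E*`, `I*/A*` and `φ*`. The default
murine-like set (`homeostatic_murine_clone`) therefore pins identifiable
homeostatic properties rather than raw rates: vacancy `E*/K = 0.4%`
(the level reported for murine marrow), niche capacity `K = 10⁴` cells,
quiescent residence ≈ 100 days (`u = 0.01`/day), active-cell kinetics on
the scale of a day (`r = 1.0`, `d_A = 0.7`, `d_I = 0.3`/day, giving
`I*/A* = 1`), with `b` solved from the vacancy. The faster illustrative set
(`example_clone`: `b = 0.1`, `u = 0.2`, `r = 1.0`, `d_A = 0.5`,
`d_I = 1.0`, `K = 100`, `E* = 30`) keeps worked examples and tests short.

## Intervention scenarios

- **Mobilization** multiplies `u` of all niche-resident clones while the
  agent is available (agents are not clone-selective); no pharmacokinetics
  beyond the rectangular pulse.
- **Preconditioning** is an instantaneous fractional kill of every host
  compartment; the surviving fraction is the control variable, since no
  dose-response shape is modelled.
- **Transplantation** adds donor cells to the donor clone's inactive pool —
  the only pool from which attachment is possible, so grafted cells home
  through it. Doses may be split across days. Endpoints default to day 365.
- Reported endpoints: donor niche chimerism `N_donor/ΣN`, and the
  malignant (CSC) burden as total CSC stem cells plus their niche fraction.

These reproduce the qualitative clinical findings the model is built
around: dose splitting raises chimerism in unpreconditioned hosts because
host detachment vacates niches between doses (the advantage disappears at
host `u = 0` and shrinks with preconditioning); a short mobilization pulse
before HSCT reduces CSC burden only modestly (below 10% for the default
parameterization); multi-day mobilization without a graft *increases* the
malignant population, because detached CSC divide.

## Fitting

`simulated_annealing` minimizes the sum of squared residuals between an
observed `(time, clone, compartment, count)` table and the corresponding
model outputs. Proposals are independent multiplicative log-normal steps
(σ = 0.05 initially, adapted every 200 iterations toward a 30% acceptance
rate), which keep all rates positive and impose no upper bound; acceptance
is Metropolis under geometric cooling `T_k = T0·α^k` with `T0` set to the
starting cost and `α = 0.999`. Pairwise-equality constraints tie parameters
together throughout the search. Two safeguards are deliberate design
choices: failed simulations cost `+∞` (rejected), and an elitist restart
returns the walker to the best-ever point every 1000 iterations if it has
drifted more than 1.5× uphill — without it the pure Metropolis chain can
freeze in a poor basin on some random streams. Recovery is judged on the
identifiable quantities (`F`, `E*`, `I*/A*`, `φ*`), not raw rates.

## Synthetic data

The generator emulates the *structure* of the murine observations the
model class is fitted to — decline without a niche, recovery after partial
depletion, competition time courses — as samples of the model's own
trajectories with optional multiplicative log-normal noise (counts are
positive, so additive Gaussian noise was rejected). It does not emulate
specific assays (BrdU labelling, limiting dilution), measurement-process
biases, or inter-animal variability beyond i.i.d. noise; passing recovery
tests therefore demonstrate internal consistency of estimator and model,
not robustness to real-world misspecification.

## Known limitations

- Deterministic ODEs only: no demographic stochasticity, so very small
  clone sizes (single-cell extinction/engraftment) are outside scope.
- The niche is homogeneous; no perivascular/endosteal split, no turnover
  of niche cells, no delay terms.
- Mutations are parameter differences between clones fixed at `t = 0`; no
  mutation-arrival process.
- Mobilizing-agent and preconditioning effects are rectangular/instant
  simplifications of time-varying pharmacology.
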