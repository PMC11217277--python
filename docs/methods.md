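# Methods

## The constitutive model

`pennrheo` simulates and learns the steady-state rheology of colloidal
dispersions (emulsions, protein-stabilised droplets, paints) in which
primary particles aggregate into clusters that trap continuous phase.  The
viscosity is written in terms of an effective volume fraction

    eta(gamma_dot) = eta_f * (1 - phi_e / phi_m)^-2
    phi_e          = phi_p * (1 + C * S)
    S(gamma_dot)   = (S0 + theta * S_inf) / (1 + theta)

with `theta = gamma_dot_c * gamma_dot` the Peclet number,
`gamma_dot_c = 6 pi eta_f a^3 / (kB T)` its prefactor (`a` the primary
particle radius), `C = 1/varphi - 1` a compactness factor (`varphi` the
intra-cluster packing fraction), `S` the fraction of primary particles
bound in clusters, and `phi_m` the jamming fraction at which the viscosity
diverges.  Only the steady state is modelled; transient structural
kinetics (thixotropy) are out of scope.

Parameters, units and defaults:

| parameter     | meaning                               | default | unit  |
|---------------|---------------------------------------|---------|-------|
| `S0`          | structure parameter at zero shear     | 1.0     | —     |
| `S_inf`       | structure parameter at infinite shear | 0.0     | —     |
| `C`           | compactness factor                    | 2.0     | —     |
| `phi_m`       | maximum (jamming) volume fraction     | 0.64    | —     |
| `eta_f`       | continuous-phase viscosity            | 1e-3    | Pa s  |
| `gamma_dot_c` | Peclet prefactor                      | 0.58    | s     |

`phi_m = 0.64` is random close packing, the standard convention for
polydisperse hard-sphere-like dispersions; with `phi_p <= 0.2`, `C = 2`,
`S0 = 1` the effective volume fraction reaches at most 0.6, so the
simulated campaigns never jam.  `kB` is fixed at the exact 2019 SI value
1.380649e-23 J/K.

The default preset uses `a = 0.5 um` (`gamma_dot_c ~ 0.58 s`), which
places the shear-thinning transition inside the simulated window
`log10(gamma_dot) in [-5, 3]`.  A nanoparticle preset (`case1_literal`,
`a = 5 nm`, `gamma_dot_c ~ 5.8e-7 s`) is provided but produces essentially
flat flow curves over that window, since `theta` never exceeds ~6e-4; and
an `emulsion` preset uses `a = 1 um` (`gamma_dot_c ~ 4.7 s`), the scale of
protein-stabilised oil droplets.

All logarithms in the learning pipeline are base 10: the viscosity layer
`-2*log(1 - x*w) + b` reproduces the constitutive law exactly only when
`log = log10` and the network target is `log10(eta)`.

## Fitting measured flow curves

`QuemadaFlowCurveModel.fit` performs bounded least squares (SciPy
`least_squares`, 3 randomised starts because the model is mildly nonconvex
in `gamma_dot_c`) on log10-viscosity residuals.  The fit is parameterised
by the identifiable combinations `(gamma_dot_c, C*S0, C*S_inf, phi_m,
eta_f)`: a flow curve determines `C` and `S` only through their product.
A constant curve with both plateau products free is flagged as degenerate
rather than silently returning one of the infinitely many solutions.

## Synthetic datasets

The grid generator emulates a rheometer campaign: for each of `n_phi`
volume-fraction levels (equispaced over [0.01, 0.2], endpoints included),
`N_shear` equispaced values of `log10(gamma_dot)` over [-5, 3] — many
rates per sample, few samples.  Case 1 varies `(gamma_dot, phi_p)` only;
case 2 additionally varies two formulation surrogates `p1, p2 in [0, 1]`
(standing in for factors like pH, salt, protein history that shift the
structural plateaus), at 2 levels each, default {0.25, 0.75}.  The
surrogates set the plateaus through `S0 = p1`, `S_inf = p1*p2`, a mapping
chosen so that `0 <= S_inf <= S0 <= 1` holds on the whole unit square.

Rows are split 75/25 into train/holdout by a seeded permutation (holdout
count rounded half away from zero, so 900 rows split 675/225 and 3600
split 2700/900).  During training a further seeded 20% of the training
rows is reserved for validation.  The grid is seed-free; only splits and
the random test set consume seeds.

The 10^4-point random test set draws `(phi_p, log10 gamma_dot)` uniformly
over the stated ranges — it contains volume fractions never seen on the
grid, which is what separates genuine interpolation/extrapolation from
memorisation.  For case 2 the surrogates default to random draws from the
trained formulation levels (`p_sampling="levels"`): the campaign revisits
known formulations at new concentrations.  A `p_sampling="uniform"`
option draws `p1, p2` uniformly over [0, 1]^2 instead; note that with
only 2x2 trained levels this additionally measures the surrogate
network's extrapolation in formulation space, a much harder and
qualitatively different task that dominates the error of every model.

What the generator does *not* emulate: measurement noise (targets are
exact model evaluations), instrument artefacts (inertia, slip, shear
banding), non-monotone or thixotropic materials, and any mismatch between
the constitutive law and reality.  Passing benchmarks therefore show that
the physics-encoded architecture recovers and exploits the generating
physics from clean data — not that it fits arbitrary measured rheology.

## Architectures

Baselines are multilayer perceptrons (ReLU hidden layers, linear scalar
output) on the log-space inputs: 2-32-8-1 and 2-128-32-8-1 for case 1
(369 and 4 649 parameters), 4-32-8-1 and 4-128-32-8-1 for case 2.

The physics-encoded network (PeNN) replaces neural layers with the
constitutive relations, each carrying a trainable physical scalar:

* structure layer `S = 1/(10^x * w_S + 1)` (case 1) or
  `S = (x1 + 10^x3 * w_S * x2)/(10^x3 * w_S + 1)` (case 2),
  `w_S ~ gamma_dot_c`;
* effective-volume layer `phi_e = x1 * (x2 * w_C + 1)`, `w_C ~ C`
  (argument order fixed by requiring reduction to the constitutive law:
  x1 = phi_p, x2 = S);
* viscosity layer `log10 eta = -2*log10(1 - x*w_m) + b_f`,
  `w_m ~ 1/phi_m`, `b_f ~ log10 eta_f`.

The case-1 PeNN (2-1-1-1) is pure physics: 4 trainable scalars, and with
the generator's constants injected it is pointwise identical to the
generator.  The case-2 PeNN (4-6-2-1-1-1) prepends a dense 4-6-2 surrogate
(ReLU hidden layer, sigmoid 2-unit output so the plateau estimates stay in
(0,1)) whose outputs stand in for S0 and S_inf; phi_p and log10(gamma_dot)
bypass the surrogate into their physics layers.  48 parameters total.  No
ordering constraint S0_hat >= Sinf_hat is imposed.

Numerical choices: the viscosity layer's log argument is clipped at 1e-6
with zero gradient in the clipped (jammed) region, so early iterates that
overshoot `phi_e * w_m >= 1` cannot produce NaN; physical scalars
initialise at `w_S = w_C = w_m = 1, b_f = 0` (order-of-magnitude neutral
in log space); an optional log-parameterisation `w = 10^u` is available
for badly scaled targets such as the nanoparticle preset's
`gamma_dot_c ~ 6e-7`.  Dense weights use seeded Glorot-uniform init.

### Surrogate routing

By default the 4-6-2 surrogate is densely connected to all four inputs.
A `surrogate_inputs="p_only"` variant (2-6-2) feeds it only `(p1, p2)`,
so that shear-rate dependence can reach the output solely through the
structure layer; it is exposed for structural analysis (gradient-routing
diagnostics) but trains less reliably than the default and is not used
by the benchmark.

The case-2 loss surface is multimodal either way: the surrogate stack
and the structural weight `w_S` can partially trade roles, and a fraction
of random initializations converge to a visibly worse validation
plateau.  `TrainConfig(n_restarts=k)` therefore repeats training from
fresh seeded initializations and keeps the restart with the lowest
best-validation loss — the same multi-start principle the flow-curve
fitter applies to its nonconvex fit.  Selection uses validation loss
only; holdout and test sets play no role.

## Training protocol

Mean-squared-error loss on log10(viscosity); Adam (Nadam, AdamW and Lion
available) with learning rate 1e-3 and inverse-time decay
`lr_t = lr0/(1 + 5e-6 t)` per update step; 20% validation split; early
stopping with patience 500 epochs, restoring the best-validation weights
(without restoration the returned model would reflect 500 stale epochs);
epoch cap 20 000 (runs that hit it are flagged).  The default batch size
is 32, the convention of the deep-learning frameworks this protocol
mirrors; `batch_size="auto"` targets ~20 updates per epoch (batch
clipped to [8, 256]) so that cells of very different sizes receive
comparable optimization effort, and `batch_size=None` gives full-batch
training (the case-1 physics stack converges either way, but full batch
consumes most of the epoch cap because each epoch is a single update).
Training is deterministic given (seed, config, dataset): weight init,
validation split and batch shuffling all derive from explicit seeds.

Because the engine is plain NumPy (forward/backward passes of the dense
and physics layers are closed-form), runs are single-threaded,
reproducible and fast at these model sizes.

## Benchmark and statistics

The comparison protocol trains every model on every cell of the dataset
grid `n_phi in {3,5,7} x N_shear in {20,50,100,300,500}` (case 2, one
training seed per cell) and evaluates all of them on one shared
10^4-point test set.  Model differences are tested with a Friedman rank
test — blocks are the 15 datasets, treatments the 3 models, midranks on
ties, statistic `12/(n k (k+1)) * sum R_j^2 - 3 n (k+1)` referred to
chi-square with k-1 degrees of freedom — followed by pairwise two-sided
Wilcoxon signed-rank tests (zero differences dropped; exact null for
<= 25 pairs, normal approximation with continuity correction above).
Effect size is summarised as the per-cell ratio of baseline to PeNN
test-set mse (min/median/max per baseline).

Problem sizes: the headline single-cell comparison (n_phi=3, N_shear=300)
runs the full protocol above, with up to 3 validation-selected restarts
for the physics-encoded model (stopping at validation mse 1e-5).  The 15-cell sweep in the test suite runs a scaled
benchmark profile chosen so a single CPU sweeps all 45 trainings in
minutes while each model still reaches its plateau: `batch_size="auto"`
throughout; dense baselines with epoch cap 1 200 and patience 120 (their
validation loss plateaus well before the cap, which therefore binds
neither baseline); the PeNN with cap 3 000, patience 250 and up to 4
validation-selected restarts that stop as soon as one reaches a
validation mse of 1e-5 (most cells need a single run; the budget is
spent only where an initialization lands in a bad basin).  The
statistical assertions are unchanged by the profile.

## Known limitations

* The constitutive law is also the data generator, so the benchmark
  measures architecture quality under a correct physics prior; it cannot
  detect what happens when the encoded physics is wrong.
* With 2x2 formulation levels the case-2 surrogate is trained at four
  points of the unit square; its behaviour between/beyond them is
  unconstrained, which is why uniform-p test sets degrade every model
  (see dataset section).
* The case-2 PeNN loss landscape has rare bad basins (the surrogate and
  `w_S` can trade roles); a seed occasionally converges to a visibly
  worse validation plateau.  The benchmark mitigates this with
  validation-selected restarts; a single unlucky run remains possible.
* Measured-curve fitting assumes monotone shear-thinning data generated
  by a Quemada-type material; it reports, but cannot resolve, the
  `C`-vs-`S` product degeneracy.
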