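# Methods

This note documents the models implemented in `macsim`, the choices made
where the procedure was genuinely open, and what the synthetic data generator
does and does not emulate.

## Hybrid connectome construction

The construction synthesizes two data sources. Axonal tract-tracing gives a
*directed* binary topology (which connections exist and in which direction)
but, in whole-cortex collations, only categorical weights. Probabilistic
tractography gives continuous *fiber tract capacity* estimates — the fraction
of streamlines sent from a seed region that reach a target — but is
undirected and contaminated by false positives. The hybrid connectome uses
the tracer matrix as a mask and fills its nonzero entries with
tractography-derived weights.

Pipeline, per subject:

1. **Capacity weights.** `w_ij = counts_ij / total_sent_i`, diagonal zero.
   Entries can exceed 1 under distance correction, where each detected
   streamline is weighted by its path length.
2. **Symmetrization** by the mean of the two directions (tractography cannot
   resolve direction).
3. **Thresholding.** The weakest `floor(f * E)` nonzero undirected edges are
   discarded, `f` on the 5% lattice {0.00, 0.05, ..., 0.95}. The floor rule
   and the stable edge-index tie-break at the cutoff weight are our
   conventions; only the 5% increments are given.
4. **Parameter selection.** Steps 1–3 are run for every tracking condition
   (curvature threshold in {0.2, 0.4, 0.6, 0.8} x distance correction on/off)
   and every discard fraction — 160 candidates — and each candidate is scored
   by the AUC of its weights as a detector of tracer edge presence over
   undirected ROI pairs (midrank Mann-Whitney formulation, ties count 1/2).
   Ties at the maximum AUC resolve to the lowest discard fraction, then the
   lowest curvature, then distance correction off.
5. **Tract lengths.** Distance-corrected counting weights each streamline by
   its length, so the per-seed-voxel ratio of distance-corrected to plain
   counts estimates mean path length; the median over seed voxels (voxels
   with zero plain counts excluded) gives the pair's length in mm. Pairs with
   no valid voxel are marked missing (0) with a warning.
6. **Assembly.** Per-subject thresholded capacity matrices are averaged
   across subjects and masked by the directed tracer nonzeros; averaged
   lengths are symmetrized and masked by the symmetrized tracer support.
   Tracer edges with zero averaged tractography weight stay zero but are
   counted and logged.

The per-subject discard is applied *before* cross-subject averaging. Tracer
weights are used only as a binary mask; their ordinal categories are not
propagated.

## Network model

Each region is a reduced Wong-Wang dynamic mean-field node with an excitatory
(NMDA) and inhibitory (GABA) population, described by gating variables
`S_E, S_I` in [0, 1]:

    dS_E/dt = -S_E/tau_E + (1 - S_E) * gamma * r_E + sigma * xi(t)
    dS_I/dt = -S_I/tau_I + r_I                     + sigma * xi(t)

with firing rates `r = H(I) = (a*I - b) / (1 - exp(-d*(a*I - b)))` and input
currents

    I_E_i = W_E*I_0 + w_plus*J_NMDA*S_E_i
            + G*J_NMDA * sum_j C_ij * S_E_j(t - L_ij/v)  -  J_i * S_I_i
    I_I_i = W_I*I_0 + J_NMDA*S_E_i - S_I_i

Constants (`DMFConstants`): tau_E = 100 ms, tau_I = 10 ms, gamma = 0.641,
J_NMDA = 0.15 nA, w_plus = 1.4, I_0 = 0.382 nA, W_E = 1, W_I = 0.7,
a_E = 310 nC^-1, b_E = 125 Hz, d_E = 0.16 s, a_I = 615 nC^-1, b_I = 177 Hz,
d_I = 0.087 s. The removable singularity of H at a*I = b is evaluated by its
series limit (H -> 1/d), keeping the transfer function continuous.

The two free parameters are the global coupling `G` and the noise amplitude
`sigma`; the canonical search lattice is G in [0.1, 5] x 100 steps and sigma
in [0.01, 0.1] x 30 steps (3000 points). The connectome weights are
normalized to their maximum (never thresholded) before simulation.
Conduction velocity is 4 m/s, so inter-regional delays are `L_ij / v`
rounded to integration steps.

Numerical choices:

- Euler-Maruyama at dt = 0.1 ms (configurable). The ~100 ms gating time
  constants make this comfortably stable; the fixed point of the discrete
  map coincides with the ODE fixed point, which the tests verify against an
  independent root-finder to 1e-6 Hz.
- Noise enters both gating equations as independent Gaussian increments
  `sigma * sqrt(dt)` (dt in seconds); whether noise drives one or both
  populations is not constrained by the source material, and both-population
  injection is the symmetric choice.
- Gating variables are clamped to [0, 1] after each step.
- Delayed coupling uses a circular history buffer of `S_E`; delays round to
  the nearest step and are zero on the diagonal.
- Initial conditions: S_E = S_I = 0.1 plus a seeded uniform jitter of 0.01;
  the first 20 s (burn-in) are discarded before any BOLD or FC computation.
- State is recorded every 10 ms; the inner loop is numba-compiled and the
  noise stream is seeded inside the kernel, so trajectories are bitwise
  reproducible per seed.

## Feedback inhibition control (FIC)

The inhibitory-to-excitatory weight `J_i` is tuned per region so that each
excitatory population's time-averaged rate sits near the ~3 Hz biological
set point. The exact published update rule is not printed in the source
material, so we use a proportional controller on short noiseless
evaluations (1.5 s scored after a 0.5 s transient):

    J_i <- max(J_i + eta * (mean_rate_i - 3 Hz), 0)

with eta = 0.05 nA/Hz, per-iteration steps capped at +/-0.2 nA, up to 100
iterations, stopping when every region lies in the acceptance band
[2, 4] Hz. The gain was chosen from the local loop sensitivity
(dRate/dJ_i ~ -6 Hz/nA near the set point, giving ~0.3 loop gain); an order
of magnitude lower never converges within the iteration cap, an order higher
oscillates. Runs whose across-region mean rate is >= 10 Hz at termination
are flagged `rejected` — a reported state, excluded from fitting, never an
exception.

## Hemodynamics

BOLD is generated by the Balloon-Windkessel model driven by the excitatory
synaptic gating `S_E` (the total excitatory current is an equally defensible
drive; gating is the conventional choice and the one we adopt):

    ds/dt = z - kappa*s - gamma_f*(f - 1)
    df/dt = s
    tau_0 * dv/dt = f - v^(1/alpha)
    tau_0 * dq/dt = f*E(f, rho)/rho - v^(1/alpha) * q/v,   E = 1-(1-rho)^(1/f)

with kappa = 0.65 s^-1, gamma_f = 0.41 s^-1, tau_0 = 0.98 s, alpha = 0.32,
rho = 0.34, V_0 = 0.02, and percent-signal readout
`100 * V_0 * (k1*(1-q) + k2*(1-q/v) + k3*(1-v))`, k1 = 7*rho, k2 = 2,
k3 = 2*rho - 0.2. Integration is classic RK4 with the drive held piecewise
constant between neural samples (substeps keep h <= 10 ms); the pulse
response matches a stiff adaptive ODE solution to 1e-6. BOLD is sampled at
TR = 1 s; the canonical run is 10 min (600 volumes) after burn-in.

## Fitting and characterization

- FC is pairwise Pearson correlation over ROI time series; averaging (scans
  within subject, then subjects) happens in Fisher-z space. Both empirical
  and simulated FC are harmonized to z-space before comparison — whether the
  published comparison back-transformed to r is not stated; z is the
  consistent choice with z-space averaging and changes cosine similarity
  only marginally.
- Goodness of fit is the cosine similarity (uncentered correlation) between
  strict upper triangles. It is scale-invariant, so it scores the FC
  *pattern*, not its amplitude.
- Significance uses sign-aware degree-preserving rewiring of the empirical
  FC with the weight multiset preserved exactly and nodal strengths
  approximately: positive and negative edge classes are rewired by
  double-edge swaps sharing one occupancy set (degrees within each sign
  class are preserved exactly), then the original weights are re-assigned
  rank-matched to residual strength products in chunks of 2% of the
  remaining edges. On dense 82-node FC matrices the max nodal strength
  deviation is ~2% (the tests enforce <= 10%). p is the proportion of null
  cosine similarities >= the observed one, so complete ties give p = 1.
- PCA networks diagonalize the region-space covariance (not correlation) of
  the demeaned series; variance fractions over all components sum to 1.
- Nodal-strength comparison thresholds the empirical network at zero and the
  simulated one proportionally to the same undirected edge count (stable
  tie-break by edge index), then correlates row sums with a one-sided
  1000-shuffle permutation p.
- The weight-distance analysis bins edges into 8 equal-count tract-length
  bins (sizes differ by at most one), computes per-bin Pearson r between log
  weights, and reports the trend correlation between bin median lengths and
  bin r with a bootstrap-over-edges CI.

## Synthetic data generator

The generator produces the three inputs the pipeline needs, with the
statistical structure the method exploits:

- **Ground truth tracer network.** 82 ROIs in two Gaussian hemisphere
  clusters (SD 12 mm, centers 40 mm apart), 3389 directed edges drawn with
  probability decaying in distance (scale 30 mm) and a 25% interhemispheric
  fraction; log-weights Normal(-5.07, 1.92). Tract lengths are Euclidean
  distances times a lognormal detour factor (median 1.235, log-SD 0.2),
  reflecting that fiber paths exceed straight lines. These defaults place
  the intra/inter-hemispheric median lengths around the 33/51 mm split and
  the length-distance correlation in the strongly positive regime of real
  macaque data.
- **Tractography counts.** Per seed voxel, plain counts are
  Poisson(seeds * sensitivity(curvature) * w_ij * exp(-0.05/mm * d_ij));
  9 subjects, 20 voxels per ROI, 5000 seeds per voxel. A subject-fixed 90%
  of null pairs carry weak lognormal(-7.5, 1.5) false-positive intensity
  that does *not* scale with curvature sensitivity — false positives arise
  from noise and crossing fibers, not from the tract-following ability the
  curvature threshold controls — so conditions genuinely differ in
  true/false separation (AUC ~ 0.9, with the designated best condition the
  most sensitive one). The distance-corrected twin reweights the *same*
  detected streamlines by path length (with 5% per-voxel length jitter)
  rather than detecting new ones; this both exercises the length-ratio
  estimator and reproduces the empirical observation that distance
  correction lowers AUC by boosting long, disproportionately false edges.
  Sensitivities per curvature ({0.2: 0.3, 0.4: 1.0, 0.6: 0.55, 0.8: 0.4})
  and the false-positive parameters are free modelling choices — real
  per-condition false-positive rates are uncharacterized — and are
  documented, not claimed.
- **Surrogate empirical FC** runs the full simulator at a known (G, sigma),
  Fisher-z transforms the FC, and adds symmetric Gaussian noise, recording
  the generative parameters for recovery experiments.

What the generator does **not** emulate: voxel-level diffusion signal and
streamline geometry, spatially structured (gyral-bias) false positives,
inter-subject anatomical variability beyond independent count noise,
scanner/physiological confounds in FC, and hemodynamic variability across
regions. Passing tests therefore demonstrate the pipeline's correctness and
its recovery behavior under the stated statistical structure, not
performance on real diffusion or fMRI data.

## Problem sizes in the tests

The canonical study conditions (82 ROIs, 9 subjects, 600 s BOLD, 100 x 30
grid, 1000 nulls/permutations) are the package defaults. The test suite and
the acceptance script run the same code at reduced sizes chosen for quick,
repeatable runs: 8–30 node networks for simulator unit tests, 10–180 s
simulations, a 3 x 3 recovery grid on a 24-node network (G in {1, 2.5, 4},
sigma in {0.02, 0.05, 0.08}), 29 ROIs x 8 subjects for cohort recovery
(mirroring the 29-ROI optimization stage), and 10–100 nulls. Parameter
recovery at this scale localizes G exactly and sigma to within one grid
step; the FC pattern only becomes reproducible across noise realizations at
stronger coupling than the full-scale empirical optimum, which is why the
recovery experiment probes G >= 1.

## Known limitations

- The FIC controller stops anywhere inside the [2, 4] Hz band, so tuned
  mean rates sit near, not exactly at, 3 Hz (typically 3.1-3.4 Hz at
  moderate G).
- Strength preservation in the null model is approximate by construction
  (the weight multiset and degrees are exact).
- The AUC optimization and the hybrid assembly use the same synthetic tracer
  network as both optimization target and mask; the real procedure optimizes
  against an edge-complete single-hemisphere matrix and applies the result
  to a whole-cortex matrix. The synthetic shortcut exercises the same code
  paths with one network.
- Tract lengths for tracer edges never detected by tractography are missing
  (0), which shortens delay estimates for those edges; an optional fallback
  to Euclidean distance is available in the builder inputs but off by
  default.
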