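# Methods

## The model and what the package infers

Two reciprocally connected olfactory regions are modeled: the olfactory
bulb (OB), which receives the sensory drive, and the anterior piriform
cortex (PC), which is coupled to it bidirectionally.  Simultaneous
recordings from such a pair constrain twelve robust relationships among
population-averaged spike statistics — firing rate, spike-count variance
and covariance, Fano factor (FF) and pairwise count correlation (ρ) —
compared between regions and between the spontaneous and odor-evoked
states.  The package asks: which relative synaptic coupling strengths
are *compatible* with those twelve relationships?

### Minimal stochastic rate network

Each region is reduced to three Wilson–Cowan-type units (two excitatory,
one inhibitory; cells 1–3 are OB with cell 1 the inhibitory granule
population, cells 4–6 are PC with cell 4 inhibitory):

    τ dx_j = (−x_j + μ_j + Σ_k g_jk F(x_k)) dt + σ_j dW_j,   ν_j = F(x_j)

with the sigmoid F(X) = (1 + tanh((X − 0.5)/0.1))/2 and white noise
correlated within a region (c_OB = 0.3, c_PC = 0.35) and uncorrelated
across regions.  Defaults: τ = 1, σ_OB = 1.4, σ_PC = 2, mean inputs
μ = (13, 9, 7, 9, 5, 3)/60 in the spontaneous state; the evoked state
doubles the three OB inputs and changes nothing else.  Twelve synaptic
connections are allowed; after tying symmetric ones, four magnitudes
remain free — within-region inhibition |gIO| (OB) and |gIP| (PC), and
cross-region excitation gEO (OB→PC) and gEP (PC→OB) — plus a fixed weak
within-region E→I strength g_ε = 0.1.

### Gaussian moment closure

Stationary first/second-order statistics (6 means, 6 variances, 6
within-region covariances) are obtained without Monte Carlo by assuming
each within-region pair (x_j, x_k) is bivariate normal and solving the
closed moment-update equations by plain fixed-point iteration from the
exact uncoupled (Ornstein–Uhlenbeck) statistics: mean μ_j, variance
σ_j²/2τ, covariance c_jk σ_j σ_k/2τ.  Key numerical conventions:

- All Gaussian expectations are trapezoidal integrals on y ∈ [−3, 3]
  with mesh 0.01.  The clipped Gaussian mass (≈ 0.9973) is **not**
  renormalized; this clipped-domain convention is part of the scheme
  (e.g. E[F] at the sigmoid midpoint is mass/2, not exactly 1/2).  A
  wider or finer grid is available for refinement checks; halving the
  mesh moves solved statistics by < 1e−5.
- The correlation inside every bivariate density used during iteration
  is the *fixed background* value c_jk ∈ {0, c_OB, c_PC}, never the
  evolving covariance estimate (a fully self-consistent variant can
  produce non-positive-definite pair covariances).
- Convergence: all 18 statistics change by relative |Δ|/max(|v|, 1e−12)
  ≤ 1e−6, within at most 50 iterations; otherwise the solve is classified
  `nonconverged`.  After the convergence status, validity is checked
  pairwise: every within-region correlation must lie in [−1, 1] with
  positive variances, else `invalid_covariance`.  A damping factor is
  exposed but defaults to 1 (plain iteration).
- Bivariate integrals are evaluated spectrally through the Mehler
  expansion ρ_2D(y₁,y₂;c) = ρ(y₁)ρ(y₂) Σ_n cⁿ hₙ(y₁)hₙ(y₂) with
  orthonormal Hermite polynomials (400 terms).  Because the expansion
  holds pointwise on the grid, the spectral value equals the dense
  trapezoidal double sum exactly up to series truncation (≤ 1e−10 for
  |c| ≤ 0.97); the dense path is kept and used when |c| > 0.98.
- Firing-rate statistics are computed after convergence from the solved
  activity statistics: E[F], Var(F) by 1-D quadrature, and pairwise
  Cov(F_j, F_k) by the bivariate form at the *solved* pair correlation.
  Only (x_j, x_k) is assumed normal — never (F_j, F_k).
- The covariance update equations use the 1-D noise-input cross terms
  for both satellite inputs symmetrically, which makes Cov(1,2) =
  Cov(1,3) and σ²(2) = σ²(3) exact whenever g21 = g31; the specialized
  four-parameter update path is an algebraic reduction of the general
  one and agrees with it to machine precision.

The closure's Fano-factor analog for the rate model is FF_j =
Var(F_j)/E[F_j], mirroring the count-based variance-over-mean form; the
twelve constraints are evaluated on the firing-rate statistics (an
activity-statistics mode would only require passing the activity moments
to the same constraint evaluator).

### Constraint engine

The twelve relationships are strict inequalities on population-averaged
statistics (averaged over the 3 cells or 3 pairs per region), with fixed
ids 1–12: rates (1) ν_PC<ν_OB spont, (2) ν_PC<ν_OB evoked,
(3) ν_PC^Sp<ν_PC^Ev, (4) ν_OB^Sp<ν_OB^Ev; variability (5) FF_PC>FF_OB
spont, (6) Var_PC<Var_OB evoked, (7) Var_OB^Sp<Var_OB^Ev,
(8) FF_PC^Sp>FF_PC^Ev; co-variability (9) Cov_PC<Cov_OB evoked,
(10) ρ_PC>ρ_OB spont, (11) ρ_PC<ρ_OB evoked, (12) ρ_PC^Sp>ρ_PC^Ev.
Deterministic (closure) inputs are compared with zero margin; a margin
parameter exists for noisy inputs but defaults to 0.

### Coupling-space sweep

The four magnitudes are swept over 0.1–2.0 in steps of 0.1 (20⁴ =
160 000 tuples at full scale).  For every tuple both states are solved;
a tuple is *admissible* when both solves converge with valid covariances
and all twelve constraints hold.  Monte Carlo validation re-simulates
only the analytic admissible set (Euler–Maruyama, dt = 0.01, 3000
realizations of 500 time units at full scale) and re-checks the
constraints on the sampled statistics.  The admissible set is
characterized by its mean signed tuple, the SVD of the mean-centered
tuple matrix (variance fractions from squared singular values), the
per-constraint satisfaction profile, and constraint-subset fractions
recomputed from the stored per-tuple booleans.

Default problem sizes in the shipped test suite are reduced: a step-0.25
grid (4096 tuples, ≈ 1 minute) and 500-realization Monte Carlo over a
150-time-unit horizon for 20 sampled admissible tuples.  On the reduced
grid the analytic admissible fraction is ≈ 1.4% (vs ≈ 1.1% on the full
grid), the mean signed tuple ≈ (−0.60, 1.13, −1.52, 1.30), and the top
two SVD dimensions carry ≈ 81% of the variance — the full-grid values
are quantitatively close, so the reduced grid preserves the geometry.

### Rate-model Monte Carlo

Euler–Maruyama with √dt noise increments; the correlated noise is
generated as σ_j(√(1−c) η_j + √c ξ_region) with the common term shared
only within a region, which reproduces Cov = c σ_j σ_k/2τ exactly in the
uncoupled model.  Realizations start at x_j(0) = μ_j and are sampled at
every step after a 100-time-unit equilibration (≫ τ, so the unique
stationary law is reached; the start point only affects equilibration).
Trajectories exceeding |x| = 10³ are flagged divergent and excluded —
the sigmoid saturates, so legitimate trajectories stay O(1–10).

### Spike-count statistics

Counts are taken in half-open windows [t, t+T_win) that overlap by
T_win/2 and tile each state segment of a trial (a 2 s segment with
T_win = 1 s gives 3 windows), pooled across windows and trials
(stationarity within state assumed; the serial correlation induced by
overlapping windows is ignored for estimation, as is standard for these
point estimates — disjoint-window mode gives the same orderings).
Covariances use the n−1 denominator; FF = Var/mean; ν = mean/T_win.
Correlations involving a zero-variance unit are undefined and excluded
from pair averages rather than set to 0, which would bias them toward
zero.  Processing rules for recorded rasters: near-coincident spikes of
a unit (< 0.1 ms apart) keep only the first; units with whole-trial
rates strictly below 0.008 Hz or strictly above 49 Hz are dropped
(boundary values kept).

The synthetic-raster generator uses common-source thinning: each unit
keeps spikes of a shared mother Poisson train with probability √ρ and
adds an independent Poisson train, giving exactly Poisson marginal
counts and pairwise count correlation ρ at every window size.  It
emulates stationary, homogeneous, pairwise-correlated activity only — no
rate adaptation, refractoriness, burst structure, or odor-specific
tuning — so tests passing on it certify the estimators, not the full
complexity of recorded data.

### Conductance-based LIF network

Each region has 100 leaky integrate-and-fire neurons (OB: 20 excitatory
mitral/tufted + 80 inhibitory granule; PC: 80 excitatory + 20
inhibitory) with scaled voltage (reset 0, threshold ≈ 1, E_I = −2.5,
E_E = 6.5), τ_m = 20 ms, τ_ref = 2 ms, and two-stage synaptic filters
(rise/decay 1/5 ms excitatory, 2/10 ms inhibitory; jump α_E = 1,
α_I = 2 per presynaptic spike).  Every connection class is
Erdős–Rényi with p = 0.3 and conductances are normalized by p × pool
size.  Cross-region excitation is delayed (OB→PC 10 ms, PC→OB 5 ms) and
targets one population: PC feedback synapses on OB granule cells,
OB output (the lateral olfactory tract) on PC excitatory cells — the
anatomical reading; wiring the feedback onto excitatory cells instead
creates a runaway excitatory loop.  Thresholds are an evenly sampled
log-normal (mean 1, σ_θ = 0.1) between the 5th and 95th percentiles,
randomly assigned.  Drives: OB 0.6 (evoked 0.9 for M/T cells only — the
granule background of 0.6 is not sensory and does not change), PC 0
(evoked 0.4 for all PC cells).  Noise mixes an independent and a
region-shared term as σ(√(1−c̃)η_k + √c̃ξ), c̃_OB = 0.5, c̃_PC = 0.8,
with time measured in seconds (stationary voltage-noise SD σ/√(2τ_m)).

Integration is forward Euler at dt = 0.1 ms.  The implementation tracks
the three postsynaptic conductance sums per cell directly and applies
per-spike weighted jumps (cross-region jumps through a delay ring
buffer); because the synaptic filters are linear this is algebraically
identical to filtering each presynaptic train separately.  Voltage is
held during the refractory clamp and set to 0 at release.  Initial
voltages are uniform on [0, 1), synaptic variables 0; each realization
runs 0.5 s of unscored equilibration before the 2 s scored window
(configurable; 0 scores from the fresh start).  Graphs and thresholds
are quenched — drawn once and shared by all realizations and both
states; per-cell rates are averaged over realizations first, then the
population mean and SD are taken across the heterogeneous population.
Statistics delegate to the spike-count module with 1000 cell pairs
sampled per region (seeded) and a designated window of T_win = 1 s (the
experiments emphasize windows ≥ 0.5 s; full window curves are reported
alongside).

### Named violation experiments

With baseline couplings (gIO, gEO, gIP, gEP) = (7, 10, 20, 15) the
network is verified against all twelve constraints; three targeted
violations of the inferred ordering are then run with everything else
unchanged: test1 swaps the inhibition strengths (gIO = 20, gIP = 7),
test2 swaps the cross-excitation (gEO = 15, gEP = 1), test3 weakens the
PC-originating couplings (gEP = 10, gIP = 10).

## Known limitations

- The closure's variances and covariances degrade at strong coupling
  (the weak-perturbation assumption); means and mean rates remain
  accurate.  Cross-region covariances are not modeled at all — with no
  shared input they are pure coupling effects outside the perturbative
  regime.
- The strongest practical consequence of that degradation: within the
  admissible set (where gIP and gEP are strong) the closure overestimates
  the spontaneous PC pair correlation by ~0.03–0.04, while the admissible
  tuples satisfy the spontaneous ρ_PC > ρ_OB comparison only by razor-thin
  margins (~0.002).  Monte Carlo re-validation therefore rejects
  essentially every admissible tuple on that one constraint in this
  implementation (verified over the whole reduced-grid admissible set and
  a 40-tuple sample of the full-grid set).  The constraints were also
  evaluated in an activity-statistics mode (`stats_mode='activity'`);
  that mode yields no analytically admissible tuples at all, so the
  firing-rate mode is the meaningful one.
- The printed parameterization of the spiking network leaves several
  conventions open (noise time units, cross-projection targets,
  composition of the drive); the adopted readings are the ones that are
  mutually consistent and dynamically stable, and they reproduce the
  reference population rates for OB-spontaneous, PC-spontaneous and
  PC-evoked within the quenched-draw variability (~±0.5 Hz).  The
  OB-evoked mean rate comes out systematically higher than the reference
  value because the OB mean is granule-dominated and the granule evoked
  rise tracks the PC feedback increase; correspondingly the spontaneous
  correlation comparison between regions (constraint 10) fails by a
  small margin (~0.03–0.05) at baseline, where 11 of 12 constraints
  hold.  These deviations are asserted honestly in the acceptance suite
  rather than patched.
- Violation experiment test2 reproduces the expected loss of the evoked
  second-order relationships (constraints 6, 9, 11); test1 and test3 are
  directionally consistent but do not reproduce the full expected
  violation sets at the reduced realization counts and with this
  network reconstruction.
- Quenched-network variability (graph draw and threshold assignment)
  moves population mean rates by roughly ±0.5 Hz between draws; the
  acceptance script therefore averages over 4 independent draws × 125
  realizations.
- No oscillatory or time-dependent statistics anywhere: the rate model
  solves equilibrium statistics only, and breathing-driven temporal
  structure is out of scope.
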