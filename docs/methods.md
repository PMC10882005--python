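# Methods

## Cascade model

The proximal BCR network is reduced to three phosphorylation cycles in
series — pCD79a (X), pSYK (Y), pPLCγ2 (Z) — each with Michaelis–Menten
phosphorylation and dephosphorylation and totals scaled to 1. Extracellular
H₂O₂ (S) acts only by inactivating the phosphatases: the active-phosphatase
fraction P(S) = 1/(1 + (S/k_ros)^H_ros) multiplies every dephosphorylation
term. Each phosphorylated protein is the kinase of the next; SYK carries an
additional positive feedback term k_cat·(Y_T−Y)/(k_pos+Y_T−Y). As written
this term does not vanish at Y = 0 and therefore acts as a basal drive on
SYK; the `feedback_includes_yp` flag multiplies it by Y so that it behaves
as a true autocatalytic loop. The default is the unmodified form, and the
distinction matters for the ordering of population EC₅₀ values down the
cascade (see Limitations).

Assumptions: H₂O₂ is not degraded on the experimental time scale (patterns
hold their plateau); there is no receptor-level spatial organisation,
no LYN/BTK branch, no H₂O₂ transport or clearance kinetics; all cells start
fully unphosphorylated at t = 0 with no pre-equilibration of the basal
state (`simulate_cell` exposes the grid, so a caller can pre-equilibrate by
prepending a zero-stimulus segment if desired).

Default parameters (model units; concentrations numerically identified with
mM): k_f = 1, k_r = 10 min⁻¹; K_M1 = 2, K_M3 = 0.5, K_M5 = 0.125
(successively smaller forward Michaelis constants propagate and sharpen
sensitivity down the cascade), K_M2 = K_M4 = K_M6 = 1; k_cat = k_pos = 1;
k_ros = 0.5, H_ros = 1; totals 1. Variability scale s_x50 = 1.25.

## Population variability

Cell-to-cell variability enters through per-cell draws of the six Michaelis
constants and k_ros, each independently lognormal with arithmetic mean m
(the reference value) and arithmetic variance m·s²_x50, moment-matched to
the underlying normal (σ² = ln(1 + s²/m), μ = ln m − σ²/2). Because the
variance scales with m rather than m², the relative spread differs per
parameter (log-sd ≈ 0.76 for K_M1 up to ≈ 1.6 for K_M5). All draws are
seeded explicitly; there is no hidden global RNG state.

## Input patterns and pump schedules

Patterns are step, linear ramp, cubic ("exponential") ramp
c(t) = c_max·((t−t0)/T)³, or constant zero; ramps hold c_max after t0+T.
The cubic form is used for the exponential gradient because it satisfies
c(t0) = 0, c(t0+T) = c_max and has strictly increasing rate during the
gradient. Rates and cumulative exposures are exact closed forms.

Pump schedules realise a pattern in a stirred vessel dosed from
concentrated stock: on a uniform grid (default 1 s) the mass balance
d(CV)/dt = q·c_stock, dV/dt = q is inverted exactly per interval, so the
forward simulation reproduces the target at every grid point; sample
withdrawals are instantaneous and concentration-preserving. Decreasing
targets are rejected as infeasible (dosing only). A step at t = 0 is
necessarily realised over the first grid interval (the vessel starts
clean), so the target is matched from the second grid point onward.

## Dose–response fitting

R(S) = R₀ + R_max·S^H/(S^H + EC₅₀^H), fitted by trust-region-reflective
least squares with multi-start over H ∈ {0.5, 1, 2, 4} and EC₅₀ at the
quartiles of the positive doses; bounds EC₅₀ ∈ [min dose/10, max dose·10],
H ∈ (0, 10], R_max ≥ 0. Hill fits on poor data are multimodal; the
multi-start grid makes the recovery deterministic. Flat responses are
flagged degenerate rather than fitted.

## Bimodality

A heterogeneous population of Hill responders can be bimodal only when
H·σ_x50 > √2 (strict). The expected bimodal stimulus window is computed
operationally: n_virtual responders with per-cell EC₅₀ lognormal around the
fitted value (log-sd σ_x50) are evaluated on a stimulus grid; at each
stimulus the response density (Gaussian KDE, Silverman bandwidth) is
scanned for modes — local maxima above 5 % of the global maximum — and the
longest contiguous run with ≥ 2 modes is returned. The responders are
sampled by stratified inverse-CDF (one draw per equal-probability bin),
which leaves the distribution unchanged but removes Monte-Carlo flicker at
the window edges, so the result is seed-stable at n_virtual = 10⁴. The KDE
runs on the linear response scale: the virtual responses live on [0, 1],
where a log transform degenerates near the OFF state.

## Threshold-variability estimation (σ_x50)

If per-cell activation thresholds are lognormal with log-sd σ_x50 and
median m, the probability of a cell being ON at stimulus S is
Φ((ln S − ln m)/σ_x50). `estimate_sigma_x50` maximises the Bernoulli
likelihood of per-cell ON/OFF calls over (ln m, ln σ) by Nelder–Mead with
three spread initialisations. Zero-dose cells carry no threshold-location
information and are excluded; all-ON or all-OFF data are flagged not
identifiable. This estimator is an operationalisation — validated by
parameter recovery on synthetic threshold populations (σ̂ within 10 % at 9
doses × 2000 cells) — not a reimplementation of any published recipe.

## Cytometry pipeline conventions

Gating is a sequential chain of rectangular gates: debris removal
(FSC-A/SSC-A), singlet selection (FSC-H/FSC-W), live-cell selection (low
viability-channel signal, since dead/apoptotic cells stain high for cleaved
caspase-3/PARP). Gate bounds live in `GatingConfig` (YAML-serialisable);
the defaults are matched to the synthetic generator's subpopulations.
Samples with fewer than 5000 gated events are dropped (strict <). The ON
threshold per condition, replicate and channel is the 97.5th percentile
(linear-interpolation quantile) of the matched unstimulated control; events
are ON when strictly above it, so a control scores ≈ 2.5 % ON by
construction. MFI is the plain median; fold change divides by the matched
control's MFI. Compensation/spillover is out of scope; synthetic channels
are generated spillover-free.

## Synthetic data generator

The generator is the study-conditions stand-in for real flow data: model
populations (default 1000 cells) are resampled with replacement to the
requested number of events (default 10 000 per sample, mirroring typical
per-tube acquisition after gating losses) and mapped to fluorescence as
F = (α_c + β·level)·exp(ε), ε ~ N(0, 0.25²) per event. Debris (5 %),
doublets (3 %, summed donor intensities, high FSC-W) and dead cells (2 %,
high viability signal) are injected so gating is exercised. Static
experiments use the printed dose set {0, 0.25, 1, 2.5, 5, 10, 20} mM and
gradient experiments sample when the pattern reaches
{0, 1.25, …, 10} mM.

The per-channel autofluorescence offsets α = (290, 255, 460) are the one
deliberately calibrated quantity: they are solved (once, analytically,
against the model's basal level distributions) so that the control-derived
97.5th-percentile threshold coincides with the model's 30 %-of-maximum
activation level. Without this self-consistency the two ON conventions
measure different quantiles of the basal distribution and the pipeline
would systematically over-count ON events at low doses. Ground truth
(generating parameters, per-cell draws, per-sample true %ON) is always
carried alongside the events, sufficient to recompute every downstream
estimate exactly.

What the generator does *not* emulate: spectral spillover and
compensation residuals, instrument drift and acquisition-time effects,
non-lognormal detector noise at the low end, debris/doublet populations
with realistic morphology (they are placed only where the default gates
look), or any biological process outside the three-protein cascade. A
pipeline that passes the recovery tests here is validated for its
*statistical conventions*, not for robustness to real-instrument
artefacts.

## Numerical choices

ODE integration uses `scipy.integrate.solve_ivp` (RK45, rtol 1e-6,
atol 1e-9) on the stacked population system, split at pattern breakpoints
so the solver never steps across an input discontinuity; levels are clipped
to [0, totals] after solving (excursions are within solver tolerance).
Agreement with an independently coded fixed-step RK4 at dt = 1e-4 min is
within 1e-4 absolute over 25 min, and %ON values move < 0.5 percentage
points when tolerances are halved. The algebraic steady state (sequential
bracketing root-finds down the cascade) provides a second, solver-free
oracle. EC₅₀% uses first-crossing linear interpolation of %ON against
concentration reached and returns NaN when 50 % is never reached during the
gradient. Rate sweeps reuse one population draw across rates (variance
reduction), with the gradient sampled at 81 evenly spaced concentrations.

Problem sizes used by the test suite: populations of 1000 cells for
dose–response and rate-sweep behaviour (matching the study's population
size), 10 000 events/sample with 3 replicates and 3 seeds for the
end-to-end recovery checks, and smaller populations for unit-level
properties, which keeps the full suite in the ten-minute range on a single
core.

## Known limitations

- With the printed equations and variability convention, population %ON
  curves obey %ON(pSYK) ≥ %ON(pPLCγ2) at every dose (PLCγ2 is
  phosphorylated by SYK, so within a cell it always switches later), so
  Hill fits to %ON give EC₅₀(pSYK) < EC₅₀(pPLCγ2). The *level-based*
  (median-response) dose–response of the same simulations does show the
  strictly decreasing EC₅₀ / increasing H pattern down the cascade
  (5.4 / 4.7 / 4.0 and 1.4 / 1.5 / 3.0 for the deterministic cell).
- At s_x50 = 1.25 the induced per-cell threshold spread is large enough
  that even the upstream pCD79a distribution becomes bimodal at
  intermediate doses (its single-cell steepness ≈ 1.45 times a log-spread
  ≈ 1 exceeds √2); a spread nearer the experimentally estimated
  σ_x50 ≈ 0.6–1.0 keeps pCD79a unimodal while leaving pSYK/pPLCγ2 bimodal.
- The σ_x50 estimator convention (threshold-CDF ML on ON/OFF calls) and
  the per-replicate-average fit convention are this package's
  operationalisations; other conventions will shift absolute values.
- FCS ingestion is not implemented; events are read from CSV plus a
  samplesheet.
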