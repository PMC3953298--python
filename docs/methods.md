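# Methods

## The model

`gnrherk` implements a reduced kinetic model of gonadotropin-releasing
hormone (GnRH) signaling in which a square-wave hormone input drives, in
order: receptor occupancy, G-protein-mediated effector activation, MEK
activation, distributive dual phosphorylation of ERK with
nucleocytoplasmic shuttling, and an ERK-dependent transcription tier.  Ten
state variables are integrated (concentrations in uM, time in min):

    HR   hormone-bound receptor          E_n    unphosphorylated nuclear ERK
    GQ   free G protein                  ppE_n  active nuclear ERK
    E    active effector                 TF1    active transcription factor
    E_c  unphosphorylated cytosolic ERK  TF1DT  TF1-dependent transcript
    pE_c mono-phosphorylated cyt. ERK
    ppE_c active cytosolic ERK

with the right-hand side

    dHR/dt    = k1*G*(R0 - HR) - k_minus1*HR
    dGQ/dt    = -k2*HR*GQ + k_minus2*(GQ_tot - GQ)
    dE/dt     = k2*HR*GQ - k_minus3*E - k3*ppE_c*E
    dE_c/dt   = -v1 + v4 - k_imp*E_c + (k_exp/C_cn)*E_n
    dpE_c/dt  = v1 - v2 + v3 - v4
    dppE_c/dt = v2 - v3 - k_imp_act*ppE_c + (k_exp_act/C_cn)*ppE_n
    dE_n/dt   = C_cn*k_imp*E_c - k_exp*E_n + v5
    dppE_n/dt = C_cn*k_imp_act*ppE_c - k_exp_act*ppE_n - v5
    dTF1/dt   = k_TF1*ppE_n/(K_MM_TF1 + ppE_n) - d_TF1*TF1
    dTF1DT/dt = k_TF1DT*TF1/(K_MM_TF1DT + TF1) - d_TF1DT*TF1DT

where `G = gnrh_input(t)` is the square wave (amplitude p, period, width;
half-open pulse windows `[k*period, k*period + width)`), active MEK is the
algebraic quasi-steady-state hyperbola

    ppMEK = MEK_tot*(k_MEK_basal + k_mek*E) / (k_MEK_basal + k_mek*(K_MM_MEK + E)),

which at the default `k_MEK_basal = 0` reduces to `MEK_tot*E/(K_MM_MEK+E)`
(note that `k_mek` then cancels algebraically — see Limitations), and
v1..v5 are the distributive, competitively inhibited Michaelis-Menten
fluxes of two-step ERK (de)phosphorylation:

    v1 = kcat_1*ppMEK*E_c   / (km_1*(1 + pE_c/km_2) + E_c)
    v2 = kcat_2*ppMEK*pE_c  / (km_2*(1 + E_c/km_1) + pE_c)
    v3 = kcat_3*MKP_c*ppE_c / (km_3*(1 + pE_c/km_4 + E_c/km_5) + ppE_c)
    v4 = kcat_4*MKP_c*pE_c  / (km_4*(1 + ppE_c/km_3 + E_c/km_5) + pE_c)
    v5 = kcat_5*MKP_n*ppE_n / (kd_ppEn + ppE_n)

Phosphorylation occurs only in the cytoplasm; dephosphorylation occurs in
both compartments, with the nuclear step (v5) removing both phosphates at
once.  The mono-phosphorylated intermediate exists only in the cytoplasm
(no transport rates exist for it).  Negative feedback acts through active
cytosolic ERK on the effector (`k3*ppE_c*E`); a switch
(`feedback_target="ppE_n"`) retains the nuclear alternative.

### Compartment geometry and conservation

`C_cn = 3` is interpreted as the cytoplasm-to-nucleus volume ratio.
Concentrations are per-compartment; the transport terms carry the `C_cn`
and `1/C_cn` factors shown above so that ERK *amount* is conserved:

    (E_c + pE_c + ppE_c) + (E_n + ppE_n)/C_cn = ERK_tot = 0.9 uM.

This is exact at the resting state and is both analytically invariant under
the RHS (the transport and flux terms cancel; tested at random states) and
enforced numerically: `simulate` raises if the residual exceeds 1e-6
anywhere on a trajectory.  The resting state partitions unphosphorylated
ERK by the import/export balance `E_n/E_c = C_cn*k_imp/k_exp = 0.8`, which
is also the resting nuclear:cytoplasmic (N:C) ratio.

### Interventions

Two interventions terminate signaling mid-protocol.  *Washout* sets the
input to zero instantaneously and irreversibly (the experimental
counterpart is a series of rapid washes).  *MEK inhibition* leaves the
ligand and upstream species untouched but forces v1 = v2 = 0 from the
event time onward — an instantaneous, complete, irreversible blockade,
modeling a saturating dose of PD184352.

## Numerical integration

The square wave makes the RHS discontinuous at known times, so trajectories
are integrated segment by segment: the breakpoint set is all pulse edges
plus intervention times, the input and inhibition flag are frozen within
each segment, and the adaptive solver (LSODA, rtol 1e-8, atol 1e-10)
restarts at every breakpoint.  No event detection is needed because all
event times are known a priori.  These tolerances keep the ERK conservation
residual below 1e-6 over day-long horizons.  Output grids always include
every breakpoint.  Solver undershoot below zero is tolerated to -1e-8 in
the state (and clipped to zero only when computing observables); anything
larger is an error.

Two independent integrators cross-check this path:

* `oracle_simulate` — fixed-step classical RK4 over the same segments,
  used in tests (agreement to ~1e-8 per state component at step 0.001 min
  on pulse protocols; clean 4th-order self-convergence).
* `gnrherk._fast` — a numba-compiled fixed-step RK4 used only inside the
  fitting loop, where ~10^5 model evaluations are needed.  The receptor
  equation is linear for a segment-constant input and is advanced by its
  exact exponential solution inside each RK4 substep; this removes the
  fastest timescale (k1*G + k_minus1 ≈ 505/min during a maximal pulse)
  from the explicit step, so the remaining nine states integrate stably
  and accurately at dt = 0.02 min (absolute error ~2e-4 vs. the adaptive
  reference; ~0.6 ms per 30-min protocol after JIT compilation).

## Observables

* Whole-cell ppERK: volume-weighted mean concentration
  `(C_cn*ppE_c + ppE_n)/(C_cn + 1)` — what a lysate-based ppERK assay sees.
* N:C ERK: `(E_n + ppE_n)/(E_c + pE_c + ppE_c)` — the live-cell
  ERK2-GFP translocation readout.
* ppMEK: the algebraic MEK function of the current effector level.

## Integrated-response analyses

The comparison currency across protocols is the trapezoidal area under each
measure above its pre-stimulus resting baseline (signed, not clipped:
trajectories do not undershoot their baseline, and clipping would mask
bugs).  `frequency_response` varies the pulse interval at fixed width
(default grid: the constant-stimulation limit plus 15-240 min; horizon
480 min; frequency reported in pulses/h, normalization reference = the
highest-duty-cycle row, i.e. constant stimulation).  `width_response`
varies width at fixed interval.  `post_pulse_fraction` integrates
whole-cell ppERK before and after a single washout-terminated pulse.
`termination_ratio` compares transcript endpoints (default 360 min) after
MEK-inhibitor vs. washout termination.  `sensitivity_gradient_ratio` takes
central differences (±10% perturbations) of integrated measure vs.
integrated receptor occupancy along the varied-frequency and varied-width
axes around a base protocol (default 5-min pulses at 60-min intervals, the
crossing point of the two experimental axes).

## Genetic-algorithm fitting

Ten parameters are flagged as fitted (`R0, k2, k_minus2, k_exp_act, k_exp,
k_imp_act, k_imp, k_mek, K_MM_MEK, MEK_tot`).  Each generation: every
flagged parameter of every vector is multiplied by `(1 + 0.1*eps)`, eps
standard normal (positivity floor 1e-12); fitness is the weighted mean
squared error between model observables and objective records (solver
failures score +inf); the next population is resampled with replacement
with probability proportional to fitness rank, the best of N receiving
rank weight N.  Ties take adjacent ranks in stable input order.  One elite
— the best-ever vector — passes through each generation unmutated, making
best-so-far fitness non-increasing.  The stopping rule is a fixed
generation budget.  Everything is reproducible from a single integer seed.

## Synthetic data

The generators emulate the structure of the imaging measurements the model
was originally trained on, replacing them for testing:

* `generate_nc_traces`: per-cell N:C time courses under a protocol,
  i.i.d. Gaussian noise (default sd 0.05 in normalized units — symmetric
  noise at the magnitude typical of imaging ratios), each trace normalized
  to its t = 0 value.  All cells share the deterministic model signal: the
  model describes the single-cell average, so no cell-to-cell parameter
  variability is simulated.
* `generate_dose_response`: integrated N:C (or transcript endpoint as a
  reporter-gene proxy) across a GnRH dose range, normalized to the
  maximal-dose response.
* `standard_fit_objectives`: the recovery-experiment objective set — N:C
  traces for a 1-min pulse, a 10-min pulse, and constant stimulation at
  1e-7 M (60-min horizon, 3-min sampling) plus transcript endpoints for
  single 5-min pulses at five doses (1e-11 to 1e-7 M, 60-min horizon).
  Dose records are weighted by the inverse square of the maximal endpoint
  so both data types contribute at comparable scale.

Passing tests on these data show that the pipeline is self-consistent
(generation, fitting, and analysis agree with each other and with closed
forms); they do not show that the model matches any particular cell
system, and the noise model deliberately omits replicate-level and
between-experiment variance structure.

## Problem sizes

Default analysis horizons are 480 min for frequency/width responses,
30 min for single-pulse ppERK kinetics, and 360 min for termination
ratios.  The recovery experiment uses populations of 50 for 150
generations over 8 protocols with 60-min horizons; five seeds take a few
minutes on one CPU via the compiled integrator.

## Design choices where the design was open

* The printed equation set of the source model is not machine-readable, so
  the system above is a reconstruction from the prose description, the
  parameter table, and the canonical distributive-phosphorylation scheme;
  all structural choices are isolated behind `rhs`/`phospho_fluxes`.
* `k_minus2` is read as 1 min^-1 (the printed "1 s^-1" amid otherwise
  min-based units is taken as a unit typo) and assigned to recovery of the
  free G-protein pool rather than to effector decay, so that the effector
  decays slowly (k_minus3 = 0.05/min) after washout.  This is what lets
  ppERK keep rising after a short pulse ends — the package's central
  qualitative prediction — at the cost of making integrated effector
  responses more frequency-sensitive than width-sensitive (see
  Limitations).
* `GQ_tot` is not in the published table; default 1 uM (its magnitude
  trades off against k2).
* Elitism is added to the published selection scheme: without it,
  rank-proportional resampling can lose the best vector, and best-so-far
  fitness would not be monotone.
* The mutation update is read as multiplicative,
  `theta_new = theta_current*(1 + 0.1*eps)`.
* The sites/cell to concentration map is anchored at 80,000 sites/cell =
  0.1 uM (the default-expression condition carries the table value).

## Known limitations

* **Sloppiness / non-identifiability of the fitted subset.**  With
  `k_MEK_basal = 0`, `k_mek` cancels from the model exactly and cannot be
  recovered by any fit.  The pair (k2, K_MM_MEK) is nearly degenerate
  (scaling both rescales the effector and the MEK Michaelis constant
  together, leaving ppMEK almost unchanged except through G-protein
  depletion), and R0 trades off against k2.  The genetic algorithm drives
  the fit error to ~1e-6 on noiseless data while leaving these parameters
  at a multiple of their generating values; tests report this honestly
  rather than asserting full recovery.
* **Transcription-tier saturation.**  Under the reconstructed equations
  with the published constants, pulsed nuclear ppERK transients (~0.17 uM
  for a 1-min maximal pulse) sit well below K_MM_TF1 = 0.4 uM, so the
  transcription tier operates in its linear regime and integrated
  transcript output at 45-min pulse intervals reaches only ~9% of the
  constant-stimulation response.  Stronger downstream saturation would
  require substantially larger or longer nuclear ppERK excursions than
  this parameterization produces.
* The model is deterministic and single-compartment-pair; no receptor
  desensitization/internalization, no stochastic single-cell variability,
  no delay or spatial effects, and no calcium/NFAT arm.
* Inhibitor and washout semantics are idealized (instantaneous, complete,
  irreversible).
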