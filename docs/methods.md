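# Methods

`stepcal` implements a stepwise strategy for calibrating multiscale
mechanistic models against heterogeneous biological evidence, and ships a
complete worked example: a surrogate lung-adenocarcinoma (LUAD) growth
model calibrated in two steps against synthetic in vitro spheroid and
mouse-xenograft datasets.

## 1. Constraint scoring

Evidence enters the calibration as *computational constraints* of two
kinds, both scored on [0, 1] so that qualitatively different pieces of
evidence can be combined in one objective:

* **Binary knowledge rules** (`BinaryConstraint`): "the quantity stays
  above / below / between thresholds over a time window".  Score 1 if the
  rule holds at every trajectory sample in the window, else 0.
  Comparators are strict, so boundary equality scores 0 — a deterministic
  tie-break.
* **Continuous data fits** (`DataConstraint`): a measured series
  (time, mean, sd).  The model output is linearly interpolated onto the
  data times (the data times are the observables), and each point
  contributes

      phi(r) = 1          if r <= 1,        r = |y_model - mean| / (2 sd)
               exp(1 - r)  otherwise

  The score is the mean of phi over points.  The flat top means "within
  two standard deviations of every measurement" scores exactly 1 — the
  acceptance language used for growth-curve fits — with a smooth
  exponential penalty outside the band.  Any strictly monotone
  transformation of the misfit would preserve the argmax; this particular
  shape was chosen for its interpretable band semantics.  Missing or zero
  SDs fall back to 10% of the mean (1.0 absolute at mean zero),
  overridable per constraint.

The calibration objective is the weighted mean

    f(theta) = sum_k w_k s_k(y(theta)) / sum_k w_k  in [0, 1],

invariant under uniform weight rescaling and equal to 1 iff every
positively weighted constraint is satisfied.

## 2. CMA-ES maximizer

`stepcal.cmaes` is a from-scratch (mu/mu_w, lambda) Covariance Matrix
Adaptation Evolution Strategy configured for bounded calibration problems.

**Coordinates.** Each free parameter is mapped onto [0, 1] (through log
space when `log_scale` is set) so the covariance stays well conditioned
across parameters spanning different units and orders of magnitude.
Degenerate bounds (`lower == upper`) freeze a parameter out of the search.

**Initialization.** The mean is the vector of initial guesses; the
covariance is diagonal with sqrt(C_kk) equal to half the k-th search
interval width (overridable per parameter via `init_std`, e.g. the
benchmark's std of 0.5 raw units); sigma = 1.

**Population.** p = 4 + floor(3 ln d) by default (the rule recommended by
the reference implementations), overridable per step.

**Update equations** (standard Hansen formulation; d = dimension,
mu = floor(p/2), log weights w_i proportional to ln(mu + 1/2) - ln i,
mu_eff = 1 / sum w_i^2):

    y_i     = (x_{i:p} - m) / sigma                 sorted by objective, descending,
                                                    ties broken by candidate index
    y_w     = sum_i w_i y_i
    m      <- m + sigma y_w
    p_sigma <- (1 - c_sigma) p_sigma
               + sqrt(c_sigma (2 - c_sigma) mu_eff) C^{-1/2} y_w
    h_sigma  = [ ||p_sigma|| / sqrt(1 - (1 - c_sigma)^{2g}) < (1.4 + 2/(d+1)) E||N|| ]
    p_c     <- (1 - c_c) p_c + h_sigma sqrt(c_c (2 - c_c) mu_eff) y_w
    C      <- (1 - c_1 - c_mu) C
               + c_1 (p_c p_c^T + (1 - h_sigma) c_c (2 - c_c) C)
               + c_mu sum_i w_i y_i y_i^T
    sigma  <- sigma exp((c_sigma / d_sigma)(||p_sigma|| / E||N|| - 1))

with the usual default learning rates c_sigma = (mu_eff + 2)/(d + mu_eff + 5),
d_sigma = 1 + 2 max(0, sqrt((mu_eff - 1)/(d + 1)) - 1) + c_sigma,
c_c = (4 + mu_eff/d)/(d + 4 + 2 mu_eff/d), c_1 = 2/((d + 1.3)^2 + mu_eff),
c_mu = min(1 - c_1, 2(mu_eff - 2 + 1/mu_eff)/((d + 2)^2 + mu_eff)) and
E||N|| approximated by sqrt(d)(1 - 1/(4d) + 1/(21 d^2)).

**Numerical choices.** Out-of-bounds draws are resampled up to 100 times
and then clipped to the boundary (simple and deterministic).  The
covariance is symmetrized every update and repaired by flooring
eigenvalues at 1e-12 if it loses positive definiteness.  Non-finite
objective values, and candidates whose evaluation raises, are scored 0
(worst) and the run continues — an unstable parameter set is simply
unfit.  All randomness flows from one `numpy` generator seeded by the
`SearchSpec`; runs are bit-reproducible.

**Stopping.** Whichever comes first: the objective reaches a user
threshold (typically close to 1); the running best improves by less than
`stagnation_tol` (default 1e-6) over `stagnation_window` generations
(default 30); or a generation budget is hit.

## 3. Stepwise calibration engine

A plan is an ordered list of steps.  Each step maximizes one constraint
objective over its free parameters, then freezes the solved values, so
the plausible space shrinks monotonically.  Earlier constraints are
re-verified after every later step by re-simulating the earlier scenarios
with the merged parameter set; any score below the carry-over floor
(default 0.8, configurable) aborts the plan with a diagnostic.  The floor
is a package default — the methodology demands re-verification but
prescribes no tolerance.

A step may re-free an earlier parameter when the earlier data could not
identify it; the carry-over check then guards the earlier constraints
against the new value.  `narrow_ranges` offers the alternative "interval"
strategy (best +- 3 final-search-std, intersected with the original
bounds, multiplicative for log-scaled parameters; the multiplier k = 3 is
a package default).

Ordering guidance (best-documented phenomena first, lowest granularity
first, least connected submodels first) is carried as advisory metadata
on each step, not enforced logic.  Per-step CMA-ES seeds derive
deterministically from one master seed; each step runs `repeats`
independent CMA-ES runs (default 3) and keeps the best — the number of
runs behind a reported calibration is rarely stated in practice, so the
repeat count is explicit and reported.

## 4. Surrogate LUAD growth model

The original multiscale EGFR-pathway model this methodology was developed
for is proprietary and unpublished, so the package ships its own openly
specified surrogate: a Greenspan-style rim model — the minimal ODE system
exposing the five phenomena the calibration needs (proliferation, death,
neoangiogenesis, immune effect, treatment), the exact published geometry
formulas, and genotype-dependent treatment response.  Results obtained
with it characterize the calibration methodology, not the original model.

State: proliferating / quiescent / necrotic cell counts
(nb_pc, nb_qc, nb_nc) and a dimensionless vascular support A.  Geometry:

    tumor_volume = (nb_pc + nb_qc + nb_nc) / cancer_cd,   cancer_cd = 2.8e8 cells/cm^3
    tumor_radius = (3 tumor_volume / 4 pi)^(1/3)

(perfectly spherical tumor, constant packing density).  With
A_fac = 1 + a_ang A and shell fractions
g_q = ((R - L_p A_fac)_+ / R)^3, g_n = ((R - L_v A_fac)_+ / R)^3:

    nb_pc' = k_div drive (1 - I) nb_pc - k_q g_q nb_pc - e_imm nb_pc - k_kill I nb_pc
    nb_qc' = k_q g_q nb_pc - k_n g_n nb_qc - e_imm nb_qc
    nb_nc' = k_n g_n nb_qc - k_lys nb_nc
    A'     = k_ang nb_pc / (n_half + nb_pc) - d_ang A      (xenograft only)

In vitro mode is avascular and immune-free (A = 0, e_imm = 0).  Two
modelling decisions deserve emphasis because the observed growth
behaviours force them:

* **Vascularization stretches both rims.**  Angiogenic support relaxes
  the nutrient limitation of the proliferative rim (L_p) and of the
  viable rim (L_v) by the same factor A_fac.  An avascular spheroid
  plateaus near 0.5 mm; a vascularized xenograft grows linearly at tens
  of mm^3/day.  If only the necrosis threshold were stretched, a
  xenograft carrying the in vitro growth parameters could never exceed
  ~1 mm^3/day.
* **Treatment is cytostatic and cytotoxic.**  Gefitinib inhibition I
  both blocks division ((1 - I) on k_div) and kills cycling cells
  (k_kill I on nb_pc).  Quiescent cells are drug-tolerant persisters.
  A purely cytostatic drug (I <= 1) can stop growth but never shrink a
  tumor by ~8%/day; the persister pool is what makes the treated tumor
  plateau at a residual volume instead of vanishing.

Pharmacodynamics: I = i_max (1 - b_res) C / (C + Ki) with C a constant
effective exposure while dosed (no pharmacokinetic compartment is
modelled; the 25 mg/kg oral dose maps to the calibratable exposure
`c_gef`).

Genotype effects are parameterized from published constants, stored
verbatim in `LITERATURE_CONSTANTS`:

| constant | value | surrogate mapping |
|---|---|---|
| KRAS GTP-hydrolysis reduction | 98% | proliferation drive x (1 + 0.98) |
| EGFR ATP Km, wild type -> exon-19-del | 5.0 -> 129 uM | stored for inspection |
| gefitinib Ki, wild type -> mutant | 16.4 -> 0.833 nM | Ki in the inhibition law |
| gefitinib IC50 (mutant) | 6 nM | stored for inspection (the Ki derives from it) |
| PIK3CA PI3K activity fold | 2.7 | resistance b_res = min(1, fold - 1) = 1 |

The PIK3CA mapping reads the 2.7-fold constitutive PI3K activation as
exceeding the normal EGFR-driven level, so receptor inhibition is fully
bypassed (b_res capped at 1).  This reproduces the observed behaviour —
gefitinib has no effect on the doubly mutated line.  The doubly mutated
xenograft line also carries its own relative proliferative fitness
(`growth_pik`), since different patient-derived tumors grow at different
rates for reasons beyond the modelled pathway.

**Allometry.**  Rates (unit 1/day) are stored at the in vitro reference
mass of 2.63 g and rescaled to the scenario body mass (23 g for a mouse)
by Z(M) = Z_ref (M/M_ref)^b with b fixed by the physical dimension:
b = 3/4 for metabolic-type fluxes (Kleiber), -1/4 for rates, +1/4 for
times, 0 for dimensionless quantities.  The table is config-extensible;
only parameters flagged allometric are transformed.

**Integration.**  `scipy.integrate.solve_ivp` with LSODA
(stiffness-switching), rtol 1e-8, atol 1e-3 cells.  Fluxes use
non-negative clamped states; outputs are floored at zero.  A failed or
non-finite integration raises a `SimulationError` carrying the parameter
set (consumed by the factorial screening, and scored 0 by the optimizer).
Initial conditions partition the starting cell count into shells at the
starting radius; a xenograft starts at its saturated vascular support
k_ang/d_ang (an implanted, established tumor arrives vascularized).

## 5. Synthetic datasets

The original spheroid (radius) and xenograft (volume) measurement tables
are not publicly printed; the generator reproduces their *reported*
behaviours exactly in expectation:

| series | design |
|---|---|
| spheroid radius | 150 um at day 0, +12.5 um/day to 400 um at day 20, plateau toward 450 um; days 0..30 every 2 days; sd = 8% of mean |
| EGFR placebo | 200 mm^3, +20 mm^3/day (days 0-20), plateau toward 680 mm^3 |
| EGFR gefitinib | 200 mm^3, -16 mm^3/day (days 0-10), plateau toward 30 mm^3 |
| EGFR+PIK3CA placebo / gefitinib | 200 mm^3, +7.5 mm^3/day (days 0-20), plateau toward 380 mm^3; identical trends (no drug effect) |

Xenograft arms are sampled twice weekly (every 3.5 days) over 30 days
with sd = 10% of the mean.  Mean curves are piecewise: exactly linear on
the stated window, then a C^1 exponential approach to the plateau.
Seeded Gaussian noise with std sd/4 perturbs the means; different seeds
share the design and differ only in noise.  Initial sizes, plateau
levels, noise magnitudes and sampling grids are design choices (the
published statements fix only slopes, the day-20 radius and the plateau
onsets); they are echoed into each dataset manifest.

What passing calibration tests on these fixtures shows: that the
pipeline can recover parameter sets reproducing the reported growth
behaviours from noisy banded series plus knowledge rules.  What it does
not show: performance on the real measurement tables (unavailable),
identifiability of individual parameters (explicitly out of scope), or
transferability of the surrogate's mechanism to the original model.

## 6. The shipped two-step plan

* **Step 1 (in vitro, KRAS-mutant spheroid).**  Free: k_div, k_q, k_n,
  k_lys, L_p, L_v.  Constraints: the radius series (weight 3), binary
  milestones at days 10 and 20 (+-5% of the design trend — the printed
  "reaches 400 um by day 20" statement), and a viable-fraction rule
  (proliferative fraction in [0.02, 0.6] at day 30; placeholder bounds,
  since no numeric rim bounds are printed).  Population auto (= 9),
  <= 200 generations, best of 3 seeds; typically solved to objective 1.0
  in seconds.

  The radius series alone underdetermines (k_div, L_p): only their
  product (the linear radius velocity) is pinned, and a freeze-then-
  transfer plan inherits whichever representative the optimizer happened
  to find.  The search bounds therefore encode parameterization-style
  knowledge: k_div <= 0.25/day keeps the effective in vitro doubling
  time (with the ~2x KRAS drive) above ~33 h, and L_p >= 15 um is about
  one cell diameter.  Without these bounds, step 1 can return a
  fast-dividing/thin-rim solution that fits the spheroid perfectly but
  makes the downstream xenograft fit much harder.
* **Step 2 (xenograft, four arms simulated jointly).**  Free: k_ang,
  d_ang, a_ang, n_half, e_imm, i_max, c_gef, k_kill, growth_pik, and the
  re-freed k_lys (the spheroid never shrinks within the 30-day horizon,
  so step 1 cannot identify clearance; the carry-over check shows the
  in vitro fit is insensitive to it).  Constraints per arm: the volume
  series (weight 3; 5 for the gefitinib arm, which carries the drug
  response the model exists for) plus a soft trend anchor — the
  "approximately X mm^3/day" statements encoded as Gaussian bands of
  +-5% (+-10% for the fast-shrinking treated arm) at days 5/10/15/20
  (5/10 for the treated arm).  Soft anchors keep a nonzero gradient
  where hard binary milestones would create score plateaus that stall
  the optimizer.  Population 20, <= 500 generations, best of 3 runs with
  early exit at objective 0.92.  The step-2 landscape is multimodal —
  a basin where the vascular positive feedback (more proliferation ->
  more support -> wider rims) runs away fits the treated arm while the
  placebo arm explodes — so the repeated runs cycle through three
  vascularization starting regimes (conservative, rich, intermediate)
  rather than restarting from one point.

Step 2 typically converges within two minutes on one CPU at these
settings, a few minutes in the worst case (about 30,000 ODE integrations
at ~4 ms each when every repeat exhausts its budget); the step-1 problem
size (16-point series) and step-2 sizes (9-point series x 4 arms) are
the generator's designs.

## 7. Known limitations

* The growth model is a surrogate; its parameter values are not
  statements about the original pathway model.
* The flat-topped score gives no gradient inside the 2-SD band, so the
  calibrated trajectory sits somewhere inside the band rather than at
  its center; recovered slopes carry a few percent of shape bias (the
  rim model's gently convex volume curves fit linear data within the
  band but tilt the least-squares slope).
* Parameter identifiability and uncertainty quantification are out of
  scope by design; different seeds can land in different, equally
  well-scoring parameter basins.
* Human-scale extrapolation (e.g. 70 kg) is supported by the allometric
  math but ships without asserted targets.
* No pharmacokinetics: treatment exposure is a constant while dosed.
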