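# Methods

## Disposition models

Both models track drug *amounts* (nmol) in mouse tissue spaces after an
intravenous bolus; plasma concentration is `C = 1000 * A_p / V1` (nM).
Rate constants act on amounts (units 1/h); lymph transport is convective,
flow times concentration, hence first-order rates `L/V3` (ISF to lymph)
and `L/V4` (lymph to plasma).

Native protein (four drug states plus a degradation bookkeeping state):

```
dA_p/dt = -(k_up + k_pi) A_p + FR k_rc A_e + (L/V4) A_l
dA_e/dt = k_up (A_p + A_i) - (k_rc + k_e) A_e
dA_i/dt = k_pi A_p + (1 - FR) k_rc A_e - k_up A_i - (L/V3) A_i
dA_l/dt = (L/V3) A_i - (L/V4) A_l
```

Fc fusion: the endosomal pool splits into free drug `A_ef` and
FcRn-bound drug `A_eb`, and free receptor `R` (nM) is tracked explicitly,
making six states:

```
dA_p/dt  = -(k_up + k_pi) A_p + FR k_rc A_eb + (L/V4) A_l
dA_ef/dt = k_up (A_p + A_i) - k_e A_ef - k_on R A_ef + k_off A_eb
dA_eb/dt = k_on R A_ef - (k_off + k_rc) A_eb
dR/dt    = -k_on R C_ef + (k_off + k_rc) C_eb        (C = 1000 A / V2)
dA_i/dt  = k_pi A_p + (1 - FR) k_rc A_eb - k_up A_i - (L/V3) A_i
dA_l/dt  = (L/V3) A_i - (L/V4) A_l
```

Modeling assumptions, stated as the package's own commitments:

1. Pinocytosis into the endosome proceeds at the same protein-dependent
   rate `k_up` from plasma and from ISF.
2. Recycling from the endosome runs at the protein-independent rate
   `k_rc`; a protein-dependent fraction `FR` returns to plasma and
   `1 - FR` is secreted to ISF (transcytosis).
3. Only *unbound* endosomal drug transfers to the lysosome (`k_e`); the
   FcRn-bound complex is protected.
4. Recycling of the complex releases free drug (dissociation at
   extracellular pH is effectively instantaneous, since FcRn binding is
   micromolar-weak at pH 7.4) and returns the receptor to the free pool,
   which is why receptor conservation `R + 1000 A_eb / V2 = FcRn_total`
   holds identically.
5. Binding is bimolecular in the endosome: hazard `k_on * R` on free
   drug.  At study doses receptor occupancy stays below 0.1%, so the
   system is effectively linear in drug, exposures are dose-proportional
   and all percentage outputs are dose- and body-weight-invariant.

Not modeled, deliberately: target (vWF)-mediated disposition (the
observed dose-proportionality argues it is negligible), pH-dependent
switching of K_D between compartments, and competition by endogenous IgG
(absorbed into the fixed effective `FcRn_total`).

### Fixed parameters and units

Volumes `V1..V4` (0.85, 0.1, 4.35, 1.6 mL), lymph flow `L` (0.12 mL/h),
endosomal sorting rates `k_rc = 5.1975`, `k_e = 0.5396` 1/h, measured
affinity `K_D = 0.144` nM at pH 6.0, and effective `FcRn_total = 40` uM.
Time is in hours, concentrations in nM, `k_on` in 1/(nM h).

Body weight is not part of the fixed physiology tables; the package
defaults to 0.025 kg (a 7-week C57BL/6 consistent with the 0.85 mL plasma
volume) and exposes it everywhere as a parameter.  Absolute exposure
predictions scale with it; every ratio and percentage output does not.

### Numerics

Stiff integration (LSODA) at `rtol=1e-10`, `atol=1e-12` by default: the
binding hazard (~2.7 1/h) and the fitted `k_off` (~1e-5 1/h) span five
orders of magnitude.  Fitting uses `rtol=1e-8` for speed.  A cumulative
lysosomal-loss state turns mass balance into a testable invariant
(relative defect <= 1e-6 on every simulation).  Exposure is adaptive
quadrature on the integrator's dense output; AUC to infinity appends a
terminal tail `C(T)/lambda` with the log-slope computed from the ODE
right-hand side at the trace end.  An independent linear-algebra oracle
(`AUC_inf = 1000 [-M^-1 A(0)]_p / V1` with free receptor frozen at
`FcRn_total`) cross-checks the integrator to 0.1%.

## Parameter estimation (cluster Gauss-Newton)

Unknowns: `k_pi`, `k_up`, `FR` (native) plus `k_on` (fusion), fitted
jointly to both dose levels with one shared vector, against
`SSR = sum (log10 y_obs - log10 y_pred)^2` over pooled mean
concentrations.  Optimization runs in transformed coordinates (log10 for
rates, logit for `FR`), so the search is unconstrained; the sampling
ranges (`k_pi` 1e-3..100, `k_up` 5e-4..5, `k_on` 4.8e-4..4.87, `FR`
1e-4..0.9999) restrict only the initial draws.  The fitted `k_on`
deliberately demonstrates this by converging below its sampling range.

Each sweep approximates every iterate's residual Jacobian by weighted
linear regression of residual vectors on parameters across the whole
cloud (weights decay with inverse squared scaled distance), then takes a
regularized Gauss-Newton step accepted only on SSR decrease (damping
x10 on rejection, /10 on success), with steps trust-bounded at 3 units in
transformed space.  Because the cluster-regression Jacobian loses
transverse accuracy once the cloud has collapsed onto the solution
manifold, a per-iterate damped Gauss-Newton polish with forward-difference
Jacobians runs after the sweep (same accept-on-decrease rule, so SSR is
non-increasing along every retained trajectory).  The polish matters: the
four-parameter fusion problem is genuinely multimodal, with a broad ridge
minimum (`FR -> ~0.97`, compensating lower `k_on`) separated by a finite
SSR barrier from the narrow global basin at the true parameters, and only
iterates polished from a still-diverse cloud reliably reach the global
basin.

Acceptance screening: sort the final SSRs, take log10, normalize both
axes to [0,1], and cut at the point of maximum perpendicular distance
below the first-to-last chord (scale-invariant elbow rule); then apply
the one-sided Grubbs maximum test on log10 SSR iteratively at alpha=0.05
to drop stragglers.  Accepted sets are summarized per parameter as
rank-1 (lowest SSR), min, max and median, with the secondary
`k_off = K_D * k_on` appended.

Default run size is 1000 iterates x 100 iterations.  The test suite and
demo pipeline use scaled-down clouds (60-200 iterates, 8-30 sweeps plus
polish), which reproduce the same accepted-set structure for this
problem; the key convergence work is done by the polish stage, so the
sweep count mainly controls how well the iterate history covers parameter
space for the profile likelihood.

## Approximate profile likelihood

All points visited by all iterates over all iterations are binned by one
parameter's transformed value; the per-bin minimum SSR approximates the
profiled objective at near-zero extra cost.  A parameter is called
practically identifiable ("bounded") when the profile rises above the
acceptance cutoff on both sides of its minimum within the examined span.
On data generated at the reference estimates this classifies `k_up`, `FR`
(and `k_on` for the fusion) as bounded and `k_pi` of the native protein
as unbounded below ~1e-3: plasma-to-ISF leakage is too slow relative to
uptake to leave a signature in plasma data.

## Non-compartmental analysis

Naive pooling (mean of quantifiable replicates per time; all-BLQ times
dropped) reflects destructive sampling, where no animal contributes more
than one point.  `lambda_z` comes from log-linear regression over the
last 3..6 points chosen by best adjusted R^2 -- vendor software leaves
this selection manual, so an automatic rule is committed here.  AUC uses
the linear-up/log-down trapezoid (plain linear available), extrapolated
as `C_last/lambda_z`, with a warning above 20% extrapolated fraction.
`CL = dose/AUC_inf`, `MRT = AUMC_inf/AUC_inf`, `Vss = CL * MRT`; sparse-
data standard errors are out of scope.

## Binding kinetics and calibration

BLI sensorgrams follow the 1:1 Langmuir model (association toward the
Langmuir plateau at rate `k_on C + k_off`; mono-exponential dissociation)
fitted globally -- one `(k_on, k_off, R_max)` across the whole
concentration series, in log space, initialized from the dissociation
tail and the concentration dependence of observed rates.  Reference-tip
subtraction is pointwise with interpolation.  The ELISA standard curve is
the four-parameter logistic `y = d + (a-d)/(1+(x/c)^b)`; back-calculation
inverts the fitted curve, applies the dilution factor, and censors
readings outside the standards' response range (BLQ/ALQ flags, never
extrapolated numbers).  The assay LLOQ is lowest standard x minimum
dilution: 0.888 pM (fusion assay) and 9.77 pM (native assay).

## Synthetic study generator

Emulates the in vivo study design exactly: sampling at 0.083, 0.25, 0.5,
1, 2, 4, 8, 12, 24, 48, 72, 96, 168 h; four independent replicates per
time (destructive sampling, no within-animal correlation); doses
0.39/0.78 nmol/kg (native) and 0.0394/0.0788 nmol/kg (fusion); LLOQ
censoring to missing at the assay limits expressed in plasma units.
Replicate error is multiplicative lognormal with cv = 0.20 by default, a
typical ligand-binding-assay magnitude chosen once since replicate-level
variability is not tabulated in any source; the mean is bias-corrected so
pooled means are unbiased.  What the generator does *not* emulate:
between-animal kinetic differences (the truth is one parameter vector),
assay-plate effects, and correlated errors -- so passing recovery tests
demonstrates correctness of the estimation machinery under the stated
error model, not robustness to model misspecification in real animals.

## Soft diagnostics

Absolute model-predicted exposures (AUC over 0-24 h for the native
protein, 0-96 h for the fusion, at both study doses) are reported as
diagnostics only: they scale with the assumed 0.025 kg body weight, which
no table fixes.  At that default the native-protein values land within a
few percent of the observed naive-pooled exposures while the fusion runs
high by roughly a fifth; the package checks these values only for
positivity and exact dose-proportionality.

## Known limitations

* The two-dose design cannot identify `k_pi` for the native protein;
  conclusions about it are limited to an upper bound.
* The elbow rule and Grubbs screening are heuristics; the accepted-set
  spread is an uncertainty *indication*, not a posterior.
* The cluster sweep plus local polish is one member of the family of
  multi-start Gauss-Newton schemes; accepted-set counts and cutoffs
  depend on the run size and seed and are reported as descriptive, not
  inferential, quantities.
* In vitro BLI kinetics and the in vivo fitted `k_on` differ by about
  three orders of magnitude; the package treats both as valid
  measurements of different systems and never mixes them silently.
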