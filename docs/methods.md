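# Methods

`mcamorph` analyses middle cerebral artery (MCA) bifurcations: how far each
junction sits from the energetic optimum predicted by the principle of
minimum work, and how well morphometric and hemodynamic indices discriminate
aneurysmal from non-aneurysmal bifurcations in a case-control design.

## Geometry and derived indices

A bifurcation is the parent trunk (radius `r0`, cross-section `p0`) splitting
into a larger and a smaller branch (`r1 >= r2` by convention; on an exact tie
the input order is kept). Measured angles are `alpha` (between the branches)
and `beta`/`gamma` (trunk to larger/smaller branch); the observed branch
angles relative to the trunk *axis* are `Phi1 = 180 - beta`,
`Phi2 = 180 - gamma`. All angles are carried in degrees end to end, because
every quantity of interest is reported in degrees; any radian conversion is
an internal detail of the trigonometric calls.

Shape indices: asymmetry ratio `r2^2/r1^2` (1 = symmetric) and area ratio
`(r1^2 + r2^2)/r0^2` (>1 = combined branch lumen wider than the trunk).

**Junction exponent.** The exponent `n` solving `r0^n = r1^n + r2^n`
measures adherence to Murray's law; `n = 3` at the minimum-work optimum.
The solver works on `f(n) = (r1/r0)^n + (r2/r0)^n - 1`, which depends on the
radii only through their ratios (hence scale invariance) and is strictly
decreasing when `r0 > r1`, so the positive root is unique. It is bracketed
on `[1e-3, 20]` and solved by Brent's method to `|f| < 1e-10`. Two explicit
failure modes replace silent misbehaviour:

* `no_solution` when `r0 <= r1` — `f` never crosses zero; no positive
  exponent exists. Such junctions occur in measured and simulated data alike
  and are treated as missing in all downstream summaries.
* `capped` when the root exceeds `n_cap = 20` (trunk barely wider than the
  larger branch). The cap prevents numerically meaningless exponents from
  diverging as `r0 -> r1+`. Capped values are sentinels, not measurements,
  so they too enter group means, correlations and regressions as missing;
  the analysis report counts both categories.

## Optimal angles

Minimising junction cost `sum_i w_i * L_i` over the junction position
(weighted Fermat point) yields branch angles whose cosines follow the law of
cosines on the weight triple: weights `w = r` for the minimum-surface /
minimum-endothelial-drag rules, `w = r^2` for the minimum-volume /
minimum-pumping-power rules. The implementation evaluates the closed forms;
the optimal angles under the two families are the angles of the triangle
with sides `(r0, r1, r2)` and `(r0^2, r1^2, r2^2)` respectively, so the
predicted total always equals the sum of the two branch angles (checked to
1e-6 degrees).

A rule is *infeasible* when its weight triple violates the triangle
inequality (a cosine argument outside `[-1, 1]`). Infeasible rules are
flagged and their angles set to NaN rather than clamped: clamping would
fabricate a 0 or 180 degree optimum the theory does not support. Arguments
within 1e-12 of the boundary are accepted as exact boundary geometry. The
two families are flagged independently; the volume rule is infeasible
whenever the area ratio is below 1 (`r0^2 > r1^2 + r2^2`), which is common
in real cohorts, so volume-rule summaries routinely rest on fewer rows. The
degeneracy boundaries are `r0 -> r1 + r2` (surface-rule angles collapse to
zero) and `r0^2 -> r1^2 + r2^2` (volume-rule angles collapse to zero); the
volume-rule total passes 90 degrees where `r0^4 = r1^4 + r2^4`.

**Independent oracle.** `weighted_fermat_oracle` re-derives the angles from
first principles: it places three endpoints in the plane, minimises
`sum w_i |J - X_i|` by Weiszfeld iteration (started at the centroid, stopped
when the junction moves less than 1e-10), and measures the angles at the
optimum. An interior optimum exists only when each endpoint-triangle angle
is smaller than the corresponding force-balance angle of the weights — the
generalisation of the classical 120-degree Fermat condition — so endpoints
are drawn with triangle angles at random fractions (0.4–0.6, renormalised to
180) of those margins. The *returned* angles come solely from the converged
minimum; a defect in the closed forms would therefore surface as a mismatch
instead of being echoed. Agreement is within 0.1 degree (typically 1e-6)
over both families.

**Deviations.** Predicted minus observed: branch angles against `Phi1`,
`Phi2` and predicted totals against `alpha`. The volume-family rows are
differenced against the same observed angles as the surface family — there
is only one set of observations. Report deviations are averaged over the
rows where the rule is feasible, and the predicted/observed means in the
angle-comparison table use the same row subset, so the deviation table
equals the column difference exactly.

## Doppler indices

Pulsatility index `PI = (V_ps - V_ed)/V_m` (dimensionless) and volume flow
rate `VFR = V_m * p0` with `V_m` in cm/s, `p0` in mm² and VFR in cm³/s; the
mm²→cm² conversion (`p0/100`) happens in `volume_flow_rate` and nowhere
else. Velocities are taken as already angle-corrected.

## Synthetic cohort

Only group-level summaries (n, mean ± SD per parameter for the four groups:
aneurysmal `An` n=102, contralateral `nonAn` n=82, right/left controls `R`
n=88 / `L` n=87) are available, so the generator models each parameter as a
truncated normal with those moments — the minimal assumption recoverable
from the published summaries. Truncation sits at physiologic bounds (radii
> 0.3 mm, areas > 0.1 mm², angles in (5, 179) degrees, velocities > 5 cm/s,
PI in (0.05, 1.9) so that the synthesised velocity triple
`V_ps = V_m(1 + PI/2)`, `V_ed = V_m(1 - PI/2)` stays ordered).

* **marginal mode (default).** Every parameter drawn independently. The
  branch radii are relabelled so `r1 >= r2` row-wise, which makes the stored
  columns the max/min order statistics of the two draws (their exact target
  distribution, used by the recovery tests). The VFR column carries the
  marginally drawn flow rate: the published VFR mean exceeds the product of
  the `V_m` and `p0` means, implying a positive correlation the summaries do
  not quantify, so deriving VFR from independent `V_m` and `p0` draws would
  not reproduce the published marginal.
* **mechanistic mode.** Draws radii and `V_m` (optionally correlated with
  `r0`), derives `p = pi r^2` and `VFR = V_m p0/100`. It induces the
  cross-parameter correlations that marginal mode deliberately omits and is
  used to stress-test pipeline consistency (e.g. VFR–`p0` correlation
  ≈ 0.78 given the published `V_m` coefficient of variation ≈ 0.2).

Derived quantities — junction exponent, shape ratios, PI — are never drawn;
they are computed downstream exactly as for a measured cohort. One
consequence worth stating plainly: deriving the junction exponent from
*independent* radius marginals attenuates its group difference (simulated
means ≈ 2.6 vs ≈ 2.7 for cases vs controls, against 2.43 vs ≈ 2.83
published), because the published radii are correlated within a bifurcation
in a way the summaries do not quantify. The synthetic cohort therefore
reproduces the discrimination behaviour of directly drawn markers (total
angle, VFR) faithfully, but understates the junction exponent's predictive
value; its frequent absence from the selected multivariate set on synthetic
data is a property of the independence assumption, not of the method.
Roughly 18–20% of marginal-mode rows have `r0 <= r1` (no junction exponent),
consistent with drawing the trunk and larger-branch radii independently.

The replicated calibration protocol (`reproduce --replicates`,
`pipeline.replicate_markers`) works directly on the published marginal
summaries: per replicate it draws the marker for cases (n=102) and pooled
controls (n=88+87) from plain normal distributions with the printed moments
and computes the empirical AUC and the univariate logistic odds ratio. Plain
(untruncated) normals are the protocol's definition: the published AUCs are
properties of the printed moments, and the binormal mixture formula
`AUC = sum_g w_g * Phi((mu_case - mu_g)/sqrt(sd_case^2 + sd_g^2))` serves as
its closed-form oracle (agreement within 0.005 at 500 replicates). With the
angle bound at 179 degrees, truncation would shift the case mean by about
-1.1 degrees and the AUC by ≈ 0.008 — a generator artefact, not a property
of the published summaries, which is why cohort generation and the
calibration protocol are kept distinct.

Within-patient structure: `An`/`nonAn` rows share patient identifiers (and
`R`/`L` rows share control identifiers) so paired analyses are expressible,
but draws are independent — the real within-patient correlation is unknown.

## Inference stage

Nonparametric throughout, reflecting non-normal morphometric distributions:

* Mann–Whitney U for the five between-group contrasts (An–nonAn, An–R,
  An–L, nonAn–R, nonAn–L); exact enumeration when `n1 + n2 <= 12` without
  ties, otherwise the tie-corrected normal approximation with continuity
  correction (type-I error calibrates to 0.05 ± 0.01 at n=50 per group over
  10^4 null replicates).
* Wilcoxon signed-rank for paired predicted-vs-observed angle contrasts;
  zeros dropped, exact for n <= 12 without tied magnitudes.
* Pearson correlations, pairwise complete-case, for the predictor screen.
* Logistic regression by maximum likelihood; odds ratios per raw unit (per
  degree, per cm³/s, per exponent unit), Wald 95% CI as
  `exp(coef ± 1.96 SE)`. Non-convergence is flagged; (quasi-)separation is
  detected from perfect fitted classification and reported via a flag, with
  a faintly ridge-penalised Newton fit (lambda = 1e-6) supplying finite
  numbers when the unpenalised likelihood is unbounded.
* Selection rule: candidates with univariate p < 0.1 enter; within any
  retained pair with |r| > 0.5 the member with the larger univariate p is
  dropped (tie: the later in input order), each drop recorded in an audit
  log. The 0.5 default is a package choice — no threshold is published — and
  the audit log makes any alternative transparent.
* ROC: candidate thresholds at midpoints between consecutive sorted unique
  pooled scores, trapezoid AUC (equal to the Mann–Whitney U divided by
  `n1*n2`, ties counted half — asserted as an exact identity), Youden-optimal
  cut-off with ties resolved toward the smallest threshold. Protective
  markers (negative univariate slope: junction exponent, PI, shape ratios)
  are sign-flipped before the ROC so that higher always means case-like; the
  reported cut-off is mapped back to the original scale.

**Case definition.** Cases are aneurysmal bifurcations (`An`, n=102);
controls are the pooled control sides (`R` + `L`, n=175); the contralateral
`nonAn` group is excluded from the case-control fit. This pooling is a
package decision (configurable via `case_group`/`control_groups`): it
reproduces the published total-angle AUC almost exactly under the binormal
check (0.851 vs 0.848 printed), whereas alternative readings do not.
Bifurcations are treated as independent observations even when two rows
share a patient, matching the published unit of analysis. No
multiple-testing correction is applied; p-values are reported raw.

## Problem sizes and tolerances

Calibration runs use 500 replicates (Monte-Carlo SE of the mean AUC
≈ 0.001); generator recovery uses 10^4 rows per group (3-standard-error
moment checks); the rank-test calibration uses 10^4 null replicates. The
junction-exponent solver tolerance is 1e-10 on `f`; oracle agreement bands
are 0.1 degree (Fermat) and 2e-3 (logistic grid search at 1e-3 step).

## Limitations

* Truncated-normal marginals cannot express the skewness, within-bifurcation
  correlations, or within-patient pairing of real cohorts; passing
  calibration shows the pipeline recovers what the published summaries
  encode, not that it would reproduce every statistic of the raw data (the
  published VFR AUC of 0.667, for instance, reflects mild non-normality the
  generator cannot see; the synthetic value sits near 0.68).
* The junction-exponent attenuation described above means synthetic
  multivariate selections differ from the published final model.
* Tortuosity is a pass-through column: no published definition exists, so it
  is never computed, only summarised.
* No imaging, centerline, or CFD functionality; inputs are tabular
  morphometry and Doppler measurements.
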