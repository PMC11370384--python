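# Methods

`hippodev` re-creates, on fully synthetic data with known ground truth, a
surface-based analysis of hippocampal microstructure development: forward
biophysical diffusion models and their fitting, a Laplace coordinate system
over hippocampal gray matter, midthickness surface sampling with subfield
and long-axis parcellation, and the developmental statistics applied to the
resulting metric surfaces. This note records the models, the assumptions,
the numerically load-bearing choices, and the limits of what the synthetic
tests demonstrate.

## Signal models

All signals are normalised to the b = 0 volume; b-values are in ms/μm²,
diffusivities in μm²/ms, radii in μm, pulse timings in ms.

**DTI.** `S = S0 · exp(−⟨B, D⟩_F)` with the per-volume b-matrix
`B = b · g gᵀ`. The tensor is fitted by log-linear weighted least squares
on shells with b ≤ 1.2 (one OLS pass for the weights, one WLS pass), the
mono-exponential regime. FA is the normalised eigenvalue dispersion (FA of
an all-zero tensor is defined as 0); MD the eigenvalue mean.

**NODDI.** Three non-exchanging compartments:
Watson-dispersed sticks (intraneurite), an axially symmetric extraneurite
tensor with tortuosity `d_perp = d_par (1 − f_in)`, and isotropic CSF:

    S = (1 − f_iso) [ f_in · S_in + (1 − f_in) · S_en ] + f_iso · exp(−b d_iso)

with `d_par = 1.7` and `d_iso = 3.0` fixed, the standard convention.
Orientation dispersion is summarised by `ODI = (2/π) arctan(1/κ)`
(ODI(0) = 1 by continuity). The Watson–stick orientation convolution uses
the spherical convolution theorem over even Legendre orders l ≤ 30:
`S_in(g) = Σ_l (l + ½) Ã_l(κ) B_l(b d_par) P_l(μ·g)`, with normalised
Watson Legendre moments `Ã_l` computed by composite Gauss–Legendre
quadrature on panels geometrically refined towards the poles (stable to
κ ~ 10⁴) and stick-kernel moments `B_l` by a 64-node rule. Accuracy
against dense brute-force sphere integration: ≤ 5×10⁻⁷ for κ ≤ 1, ≤ 10⁻⁵
for κ ≤ 10, ≤ 8×10⁻⁵ at κ = 100 and ≤ 8×10⁻⁴ at κ = 1000 (the single-stick
limit). At κ = 0 the expansion reduces exactly to the stick spherical mean.
Fitting is multi-start bounded NLLS (fixed diffusivities; starts vary κ
plus one CSF-dominant start; mean orientation initialised from the tensor
eigenvector), with volumes canonically re-ordered so estimates are exactly
invariant to input volume order.

**SANDI.** Direction-averaged (spherical-mean) three-compartment model:

    S̄(b) = (1 − f_ec) [ f_in · S̄_stick(b, D_in) + (1 − f_in) · S̄_sphere(b, r_s) ]
            + f_ec · exp(−b D_ec)

with `S̄_stick = √(π/(4 b D)) erf(√(b D))`, the sphere modelled by the
Gaussian-phase-distribution (Murday–Cotts) attenuation with intrasoma
diffusivity fixed at 3.0, the first 50 roots of the spherical Bessel
derivative, and gradient strength recovered from
`b = (γG)² δ² (Δ − δ/3)`. Derived maps: `f_extracellular = f_ec`,
`f_neurite = (1 − f_ec) f_in`, `f_soma = (1 − f_ec)(1 − f_in)`; they sum
to one identically. Pulse timings default to δ = 7 ms, Δ = 24 ms
(plausible for an ultra-strong-gradient system); they are always explicit
in configs and sidecars. Soma radius estimates are timing-dependent, so
only recovery behaviour — not absolute radii — is meaningful.

### SANDI identifiability — the load-bearing analysis

Under the GPD approximation with fixed timings, the sphere's attenuation is
*exactly* exponential in b: `S̄_sphere(b, r_s) = exp(−b · D_eff(r_s))`,
with `D_eff` monotone in the radius (≈ 0.17 at 6 μm to 0.65 at 10 μm for
the default timings). The spherical-mean model is therefore a stick plus a
two-exponential mixture, with three consequences measured during
development:

1. **Label swap.** If `D_eff(r_s)` may equal `D_ec` within the fit bounds,
   soma and extracellular have an exact twin solution with swapped rates
   and relabelled fractions. The fitter enforces the ordering convention
   that the soma is the more restricted isotropic compartment
   (`D_eff(r_s) < D_ec`) and analytically relabels swapped solutions.
2. **Near-exact mimicry.** Distinct parameter sets can reproduce the five
   shell means to below double precision (sum-of-squares ~10⁻³²),
   particularly when the stick diffusivity drifts towards the exponential
   rates. No estimator can distinguish such sets. Estimation is well-posed
   only when the three decay rates are separated, which is the
   physiological gray-matter regime: `D_in` ∈ [1.6, 2.5],
   `D_ec` ∈ [0.5, 1.3], `r_s` ∈ [3, 11]; these are the default bounds.
3. **Noise amplification.** Even inside that regime the flat directions
   amplify shell-mean noise (~3×10⁻³ at SNR 50) into fraction spreads of
   ~0.2, and the box bounds turn that spread into bias for a pure
   maximum-likelihood fit (measured ≈ −0.16 on the neurite fraction,
   persisting at SNR 200). The default noisy-data estimator is therefore a
   MAP fit: residuals weighted by the per-shell standard error (noise sd
   estimated from the b = 0 repeats) plus a weak Gaussian prior centred on
   canonical gray-matter values (f_ec 0.3, f_in 0.5, r_s 8, D_in 2.0,
   D_ec 0.9) with sd equal to the physiological range divided by √12 —
   the same role the learned-regressor priors play in toolbox
   implementations. Without a noise estimate the objective is plain least
   squares and noiseless curves are recovered to machine precision.

The fit is initialised by a variable-projection grid search: for fixed
(r_s, D_in, D_ec) the model is linear in the fractions, so each cell of a
14³ rate grid reduces to a 2-variable least-squares problem clipped to the
fraction simplex; the best cell seeds the NLLS polish (plus two seeded
random starts). Rician bias is not corrected; at SNR 50 it raises the
highest-shell means by ~2×10⁻³ and is part of the characterised bias.

## Synthetic data

**Cohort.** 88 subjects, ages uniform on [8, 19] years, 42 males, both
hemispheres per subject. Uniform age sampling maximises slope-estimation
power; a triangular young-skewed mode is available.

**Protocol.** Six shells, b = 0 (14 volumes), 0.5 (30), 1.2 (30),
2.4 (60), 4.0 (60), 6.0 (60) ms/μm², 254 volumes; directions per shell by
electrostatic repulsion of antipodal pairs.

**Metric surfaces.** Per metric, vertex, hemisphere and subject:
baseline + age slope · (age − mean age) + extra male slope · (age − mean
age) + a fixed spatial pattern (uniform / AP-linear / PD-linear) + a
regional random offset drawn independently per (subfield × long-axis bin)
cell, hemisphere and subject + i.i.d. vertex noise, clamped to physical
ranges with a recorded clamp mask. Defaults encode the qualitative
developmental findings at plausible magnitudes: neurite fraction baseline
0.22, slope +0.008/yr (+0.008/yr extra in males); extracellular fraction
derived as 1 − f_neurite − f_soma, hence falling; MD 0.9 falling by
0.006/yr; soma radius 8 μm shrinking slightly; ODI and soma fraction flat
in age, ODI with a small sex-slope difference. The regional noise
component (sd 0.03 for fractions) is what gives parcel-level rows within a
subject independent residuals — the assumption the OLS F-tests make; a
shared subject intercept is available (`subject_sd`) but defaults to 0
because it induces within-subject row correlation those tests do not
model (measured: a 0.02 shared intercept drove the null family-wise
false-positive rate to ~0.3; the regional default gives 0.025 raw and a
clean-run fraction of 1.0 over 60 null runs).

**What the generator does not emulate.** Realistic subfield geometry and
contrast, partial voluming, preprocessing residuals (motion, eddy, Gibbs),
spatially correlated vertex noise within parcels, longitudinal structure,
or any nonlinear age trajectory. Passing tests demonstrate the machinery
is correct and calibrated under the stated generative model, not that the
empirical findings would replicate on new cohorts.

**Slab phantom.** An annular sector (inner radius 14 mm, outer 24 mm, arc
150°, height 20 mm, 1 mm voxels) whose three Laplace coordinates are
closed-form and mutually orthogonal: azimuth (AP), log-radius (IO), height
(PD). A straight-box variant has affine coordinates. Voxel centers sit at
integer multiples of the voxel size and planar region boundaries on voxel
faces, matching the solver's boundary convention exactly.

## Geometry numerics

The Laplace solver is red-black successive over-relaxation (ω = 1.9,
tolerance 10⁻⁶ on the largest update, max 10⁵ iterations) with Dirichlet
values imposed at the *face* between a boundary voxel and its in-mask
neighbour (half-spacing stencil, neighbour weight 2) and no-flux walls
elsewhere. Face-Dirichlet makes aligned planar boundaries exact and
reduces curved-boundary error to a zero-mean jag that decays within ~2
voxels; on the default phantom the worst off-rim error is ≈ 0.013 (AP
0.005, PD ~10⁻⁶). Disconnected mask components that touch neither
boundary raise an error naming the component.

Gradients use central differences inside the mask and one-sided stencils
at edges (units mm⁻¹); orientation maps take |cos θ| between normalised
vectors — diffusion peaks are antipodally symmetric, so the maps live in
[0, 1]. Surfaces are placed by inverting the voxelwise
(AP, PD, IO) → world map with piecewise-linear scattered interpolation;
vertices outside the sampled coordinate hull are flagged missing.
Enclosing-voxel sampling uses half-open voxel boxes with the documented
tie-break that a vertex exactly on a face belongs to the lower-index
voxel. Thickness is the Euclidean distance between inner and outer
surface positions linearly extrapolated from the sampled IO range to the
0 and 1 level sets; gyrification is native vertex area over unfolded
vertex area (unfolded coordinates scaled to the template's physical
extents); subfield volume is labelled-voxel count times voxel volume.
These are simplified, monotone proxies, named as such.

The standard template has exactly 7262 vertices per hemisphere: 61 rows
of 119 spanning the unfolded square plus a 3-vertex anterior apex row
standing in for the uncus tip, triangulated with a greedy ragged-strip
rule. Subfields occupy fixed PD bands (subiculum 0.22, CA1 0.30, CA2
0.10, CA3 0.18, DG/CA4 0.20) and the five long-axis bins fixed AP bands —
synthetic widths in anatomically plausible proportion, not a histological
atlas.

## Statistics

Pearson screening uses tiers 0.01 / 0.005 / 0.0005, the first being a
Bonferroni family of five (one metric across five subfields) at
family-wise 0.05. Nested F-tests compare a full OLS model (age, parcel,
group, age:parcel, group:parcel, plus the interaction of interest) with
the reduced model dropping that interaction;
`F = ((RSS_r − RSS_f)/(df_r − df_f)) / (RSS_f / df_f)`. With 88 subjects
and 5 subfields the age-by-sex denominator df is 424; with both
hemispheres and hemisphere in place of sex, 864; the age-by-parcel
numerator df is 4 — all pure functions of the design shape. Treatment
coding (references: subiculum, F, L); any full-rank coding gives the same
F, asserted by test. Benjamini–Hochberg FDR is applied within each test
family (e.g. the six microstructure age-by-sex tests).

Vertex-wise age contrasts fit `DV ~ age + sex + age:sex` per vertex on
hemisphere-averaged data and extract `t_age = β̂_age / SE(β̂_age)`
(residual df = n − 4); maps are correlated (absolute Pearson) with the
contrived AP and PD positional gradients, i.e. the unfolded coordinates
themselves.

The spin test correlates two surface maps against a null of rigid random
shifts of one map in the unfolded plane with toroidal wrap-around and
nearest-vertex resampling, 2500 permutations by default and the add-one
p-value `(1 + #{|R_null| ≥ |R_obs|}) / (n_perm + 1)`. Unfolded-plane
shifts are used because hippocampal maps live on a rectangle after
unfolding; a spherical-rotation null has no natural analogue there.
Calibration on independent Gaussian-filtered random fields gives a
fraction of p < 0.05 around 0.035 (slightly conservative) over 400+
replicates. Reference maps shipped with the pipeline are synthetic smooth
random fields standing in for histology/PET-derived surfaces — same
format, no biological content, and named `synthetic_*` accordingly.

## Problem sizes and defaults

The pipeline's demo configuration runs 30 subjects on a ~1000-vertex mesh
with 500 spin permutations; `full_scale=True` restores 88 subjects, 7262
vertices and 2500 permutations. Recovery and bias studies use 500
locations; calibration suites use 10⁴ Pearson replicates, 10³ F-test
replicates and 500 spin replicates at 250 permutations each. These sizes
were chosen so each study gives stable estimates while the whole battery
remains desk-scale.

## Known limitations

* The NODDI extraneurite tensor is not Watson-averaged (tortuosity only),
  a deliberate simplification of the original model's dispersion-coupled
  extracellular compartment.
* SANDI soma radii inherit the GPD approximation and the assumed timings;
  outside the physiological regime the model is provably non-identifiable
  from this protocol (see above), and estimates there reflect the prior.
* Macrostructure definitions are simplified proxies, not streamline-based
  thickness or atlas gyrification.
* The spin-test null assumes approximate stationarity of maps in unfolded
  space; strongly non-stationary maps may be mildly anticonservative.
* All statistical guarantees are under the generator's independence
  structure; real cohorts with shared within-subject variance would
  require mixed models, which are out of scope.
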