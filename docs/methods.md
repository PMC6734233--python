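# Methods

This note documents the models, defaults, and design choices behind
`migconn`, and what its synthetic validation does and does not establish.

## Analysis model

The pipeline treats each subject's brain activity as K network-node time
series and asks whether any node's weighted connectivity differs between
chronic (CM) and episodic (EM) migraine.

**Edges.** Partial correlation between node pairs, computed from the
ridge-stabilized inverse of the sample correlation matrix:
`P = (Σ + λ·c·I)⁻¹`, `r_ij = −P_ij/√(P_ii P_jj)`, with `c` the mean
diagonal of `Σ` so that λ is scale-free. Default `λ = 0.1`. At `λ = 0`
this is mathematically identical to correlating the residuals of each node
pair after regressing out all remaining nodes; the test suite verifies
that equivalence to 1e-10 against a brute-force implementation. The ridge
term trades a small bias for stability when T is modest relative to K.

**Soft threshold.** The power adjacency `w = |r|^β`, default `β = 6`,
unsigned. This down-weights weak edges smoothly instead of binarizing at a
hard cutoff, and is order-preserving on |r|. A signed variant
(`use_absolute_weights=False`) is available; a sigmoid adjacency was
considered and not implemented — the power form is the dominant convention
for weighted networks and one configurable exponent covers the practical
range.

**Node statistic.** Fisher's `z = arctanh(w)` (variance stabilization),
then degree centrality `DC_i = Σ_j z_ij`. The transform order — soft
threshold first, Fisher z second, DC on the z-stage weights — is fixed.

**Inference.** The group statistic is the difference of group means of DC
per node (the minimal statistic consistent with comparing a null
distribution of group assignments). Subjects are relabelled preserving
group sizes; p = (1 + #{|T_b| ≥ |T_obs|})/(B + 1) (add-one form, so p > 0),
two-sided, with a per-node null. B = 5000 by default; an exhaustive mode
enumerates all assignments for small cohorts and is used as the oracle in
tests. FDR is Benjamini–Hochberg across the node family at q = 0.05.
Covariate adjustment uses ordinary linear models of DC on the group
indicator plus nested covariate sets (age, sex, aura, allodynia,
depression, anxiety, disease duration, headache intensity, acute drug
use/month), with BH correction across nodes within each set; the
permutation and parametric routes agree on synthetic cohorts where the
covariates are independent of the planted effect, which the suite checks.

## Preprocessing

Framewise displacement is the Power backward-difference form:
`FD_t = Σ|Δtrans| + r·Σ|Δrot|` with head radius r = 50 mm. Frames with
FD > 0.5 mm are censored (the frame *into* which the high-FD transition
leads); the first 12 s (four volumes at TR = 3 s) are discarded first. The
scrub decision is a per-frame fact of the original trace, and the
operation returns the per-frame FD alongside its output, which makes
re-application a no-op (idempotence) — recomputing FD across censoring
gaps would spuriously re-flag step transitions.

Band-pass filtering is a 4th-order Butterworth applied forward-backward
(`sosfiltfilt`), i.e. zero phase, so no phase distortion enters the
correlation estimates; the contract (≥ 90% amplitude in-band, ≤ 10% one
octave outside, ≥ 80% of white-noise spectral mass inside 0.009–0.08 Hz)
is asserted in tests rather than assumed from the design. Intensity
normalization applies one global factor per run to reach an in-mask mean
of 10,000. Spatial smoothing uses a Gaussian kernel with
σ = FWHM/(2√(2 ln 2)) per axis, never across time. Motion correction,
registration, and nuisance-signal removal are treated as upstream: inputs
are assumed co-registered on a common grid.

## Group ICA

Runs are concatenated along time after per-subject voxelwise demeaning and
decomposed by spatial FastICA (voxels as samples, time points as
features), with a fixed, configured K instead of automatic dimensionality
estimation — a deliberate reproducibility choice at desk scale. Component
sign is fixed by requiring the peak-magnitude voxel to load positively, so
fits are bit-reproducible given the seed. Subject node time series come
from dual-regression stage 1: each frame's voxel vector is regressed on
the K group maps. Components are labelled signal/noise by maximum
absolute spatial correlation against reference templates with the 0.25
decision threshold; quantitative heuristics (boundary-ring loading
fraction, high-frequency time-course power fraction) are reported as
advisory only and never decide the label. On noiseless planted data the
recovered maps correlate with the truth at |r| ≈ 1 − 1e-4; the residual
is finite-voxel-sample estimation error in the unmixing, not a
convergence artifact, so exactness assertions use |r| > 0.999.

## Seed analysis

The hypothalamus (0, −4, −9), PAG (1, −31, −9) and DRN (1, −32, −17)
(MNI mm) are modelled as 3 mm spheres — small radii because these are
small diencephalic/brainstem structures, and sphere geometry because
hand-drawn or atlas masks are not distributable. Seed-to-network coupling
is the Fisher-z Pearson correlation between the seed's mean time series
and the target node's series, contrasted between groups with the same
permutation machinery, FDR-corrected across the three-ROI family.

## Synthetic cohorts

Node series are drawn from a zero-mean stationary Gaussian whose inverse
covariance is planted exactly, because partial correlation is a pure
function of the precision matrix. Optional AR(1) colouring
(`x_t = a·x_{t−1} + √(1−a²)·e_t`) adds temporal autocorrelation without
changing the stationary covariance; the default is white (a = 0) since the
analysis operates on correlations, not spectra.

The baseline precision uses a two-tier structure: the effect node's six
incident edges carry partial correlation 0.15; the remaining six nodes
form three disjoint pairs at partial correlation 0.45; all other entries
are zero. The group effect multiplies the effect node's incident precision
magnitudes by (1 + effect_size) in the CM group, leaving every non-incident
partial correlation untouched. The tier values were chosen by a power
analysis of the β = 6 adjacency: the strong pair edges give non-effect
nodes a high-variance degree term, which suppresses spillover
significance at those nodes, while the moderate incident edges keep the
planted contrast detectable at the study's group sizes (44/18) and run
length. A uniform-partial-correlation design is impossible here anyway
(uniform r must stay below 1/(K−1)) and has materially worse exclusive-
detection behaviour. Positive definiteness is verified on construction
and violations are rejected with a diagnostic.

Exclusive detection ("the effect node and no other") has a structural
ceiling under BH: once the effect node is almost surely discovered, the
rank-2 step-up threshold 2q/K ≈ 0.014 implies roughly
1 − (1 − 0.014)⁶ ≈ 8% familywise false-flag probability among the six
null nodes (less under positive dependence), so the achievable exclusive
rate is ≈ 0.92 regardless of effect size.

Motion traces are smooth sinusoidal drifts plus persistent 0.8 mm
translation steps at Bernoulli-sampled frames, so exactly the planted
frame exceeds the 0.5 mm FD threshold. The clinical table draws
demographics and questionnaire scores per group with realistic prevalences
(e.g. female 82%/61%, aura 9%/22%); depression and anxiety indicators are
derived from the drawn PHQ-9 ≥ 8 and HADS-A ≥ 8 cutoffs, and CM subjects
have ≥ 15 monthly headache days by construction. Covariates are
independent of the planted network effect, so adjusted and unadjusted
analyses agree on synthetic data.

What the generator does *not* emulate: physiological (cardiac/respiratory)
noise, scanner drift fields, rigid-body resampling of actual head motion,
spatial autocorrelation of BOLD noise, or hemodynamic temporal smoothing.
Passing tests therefore establish the statistical machinery's correctness
and calibration under the planted model, not robustness to every artifact
of real scanner data.

## Validation problem sizes

The suite's simulation studies use: 200 replicate study-sized cohorts
(44/18, T = 96, K = 7, B = 1000) for type-I calibration, judged against
the binomial 95% CI for 200 replicates applied to the mean per-node rate
(the seven per-node rates are positively dependent, so per-node CIs are
individually valid but jointly noisy); 50 replicates at effect size 0.5
and T = 100 for effect recovery; 6 random 8-subject instances at
B = 20,000 against exhaustive enumeration, with a Bonferroni-adjusted
simultaneous bound across the 18 comparisons; 20³-voxel, 8-subject
cohorts for ICA recovery; and 50 replicates for the three-seed contrast
structure. These sizes keep the full validation in the tens of seconds
while leaving each check statistically meaningful.

## Known limitations

- The imaging entry point assumes co-registered, nuisance-cleaned inputs;
  no registration or physiological denoising is provided.
- Fixed K replaces automatic ICA dimensionality selection.
- Degree centrality is the only graph metric; no betweenness, modularity
  or small-world statistics.
- Scrubbing can leave subjects with unequal frame counts; the seed
  analysis requires rectangular series and so expects either spike-free
  runs or upstream frame harmonization.
- The Mann–Whitney power of a 1 SD shift at n = 44/18 is ≈ 73% at
  p < 0.01 (AUC = Φ(1/√2) ≈ 0.76), so baseline continuous contrasts of
  that magnitude will not always reach significance at these group sizes.
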