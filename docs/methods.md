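# Methods

## The hemodynamic model

The solver treats the MRA-visible arterial tree as a resistive network in
steady state. Pulsatility, wall compliance and inertia are deliberately
absent: the model family averages temporal variation and asks only how mean
flow and pressure distribute over a patient's measured geometry.

**Branch law.** Each branch carries laminar Poiseuille flow,
Q = (P_in − P_out) / R with R = 8μL/(πr⁴). Internally the resistance is
integrated segmentwise along the centerline (per-segment radius = mean of
the two endpoint radii), which reduces exactly to the closed form for a
constant-radius branch and handles tapering without extra assumptions.

**Junctions.** Flow is conserved and pressure is single-valued at every
node. Together with the branch law this gives one sparse linear system in
the node pressures plus the total inflow.

**Inlet: the virtual branch.** All inflow roots (in clinical data, the
internal carotids and the basilar artery; in synthetic data, the generated
root) are joined by a virtual inlet: total inflow Q_tot splits across roots
proportional to cross-sectional area A_i = π r̄_i², and the area-weighted
mean of the root inlet pressures is set to MAP. With a single root this
reduces to a plain pressure condition P = MAP. A pure Dirichlet mode
(every root pinned at MAP) is available behind `inlet_mode="dirichlet"`;
the flow-split mode is the default because it honors both the MAP boundary
and the area-proportional distribution simultaneously when several roots
are present.

**Outlets: structured trees.** Every terminal node drains through the
lumped resistance of a self-similar binary tree: a segment of radius r has
length λ·r and Poiseuille resistance; its daughters at radii α·r and β·r
combine in parallel; growth stops when the segment diameter falls below
d_min, and such segments drain directly at the terminal pressure. Radii
live on the α^i β^j lattice, so the recursion is memoized exactly over
(i, j). The tree root radius is the outlet branch's mean inscribed-sphere
radius (the distance transform underestimates radii at the very tip of a
tube, so the distal-voxel value is not used).

**Cuff boundary.** MAP = DBP + (SBP − DBP)/3, the standard cuff estimate.

### Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| μ (blood viscosity) | 3.5×10⁻³ | Pa·s | typical whole blood |
| α, β (daughter ratios) | 0.9, 0.6 | – | classic structured-tree literature values |
| λ (length/radius) | 50 | – | same source |
| d_min (stop diameter) | 0.1 | mm | growth limit of the outlet trees |
| P_term | 10 | mmHg | venous-side reference |

All are config-exposed (`FluidParams` / `PipelineConfig`); none is fitted.
Units are SI internally and mmHg / mL·min⁻¹ at every reported surface
(1 mmHg = 133.322387415 Pa).

## Network extraction

Skeletonization uses 3-D thinning (scikit-image); skeleton voxels are
classified by 26-neighborhood degree (1 endpoint, 2 path, ≥3 junction).
Adjacent junction voxels are collapsed to a single node at their centroid,
since thinning can produce junction clusters. Per-point radii come from
the Euclidean distance transform of the mask with anisotropic spacing.
Numerical choices that matter:

- **Spur pruning** (default 2 mm): short free-ended branches are thinning
  artifacts; pruning never removes a branch whose endpoint carries an
  inflow seed, and pass-through nodes left at degree 2 are merged.
- **Endpoint extension**: thinning retracts a tube's skeleton from its
  rounded free end by roughly one local radius. Each degree-1 branch end
  is extended along its terminal direction while the distance transform
  stays flat (it only falls once past the end-cap center), restoring the
  true terminus. Without this, recovered lengths of thick short branches
  are biased low by up to ~2 radii.
- **Cycles** (e.g., an intact circle of Willis) are broken at the shortest
  cycle edge with a warning; the solver requires a forest rooted at the
  inflow branches, and closed loops with no junction are cut open into a
  path. Components unreachable from any inflow seed are dropped with a
  warning.
- **Seed snapping** (default 3 mm): inflow seeds attach to the nearest
  skeleton endpoint. When seeds are placed at the true vessel origin of a
  thick root (radius ≳ 1.5 mm), a snap distance of ~5 mm is appropriate
  because snapping happens before endpoint extension.

Morphometry per branch: length L (polyline arc length), tortuosity
τ = L/chord (undefined and flagged for closed branches), mean radius, and
diameter d = 2r̄. *Terminal arterial branches* are terminal-outlet branches
with d strictly below the mean diameter over all branches — the strict
inequality means a network of identical branches has none.

## Lesion analysis

Lesions are 26-connected components of the WMH mask; components under
5 voxels (config) are dropped as segmentation speckle. The
periventricular/deep split uses the minimum over lesion voxels of the
Euclidean distance to the ventricle mask; strictly greater than 10 mm is
deep. Distances here and in the ALTAB analysis are measured between voxel
centers of the two solid voxel sets — the minimum over full sets equals
the minimum over their boundaries, and is exactly 0 for overlapping sets.
Lesion volumes are natural-log transformed (base is a config choice;
volumes are heavily right-skewed).

The ALTAB threshold is the mean over lesions of the distance to the
nearest terminal branch; the comparison is inclusive (≤ T), so a branch at
exactly the threshold distance is an ALTAB. A sensitivity sweep over
6–20 mm in 1 mm steps is produced alongside every assignment; ALTAB counts
are monotone non-decreasing in T by construction. Vessel voxels are
partitioned to branches by nearest centerline point so that each branch
has a solid voxel set with a boundary to measure to.

## Statistics

OLS with Wald 95% CIs (t reference) and two-sided p values. Model tags:
bivariable; model 1 (age, sex); model 2 (age, sex, six cerebrovascular
risk factors). No multiplicity correction is applied to regression tables;
the Bonferroni 0.05/6 level applies only to the six ALTAB feature
comparisons (length, tortuosity, diameter, flow, mean pressure, pressure
drop). Subjects with zero WMH volume have no defined log volume and are
excluded from the models with a logged count — the conservative reading of
a log-transformed outcome. Rank-deficient designs raise an error naming
the aliased columns rather than silently dropping them.

The tenth-subsample procedure redraws `fraction` (default 0.1) of the
subjects without replacement `reps` times (default 10), refits, and
reports per-rep estimates plus sign consistency with the full-data fit;
`fraction = 1` reproduces the full fit exactly in every rep. Stratified
fits drop the stratifier from the covariate set inside each stratum (it is
constant there). Group comparisons use the classic equal-variance
two-sample t-test; degenerate inputs (groups under 2 observations, or two
identical zero-variance groups) return NaN or (t = 0, p = 1) respectively
instead of propagating numerical noise.

## The synthetic-data generator

**Trees** are full binary trees in continuous mm coordinates: daughter
radii are parent × (0.8, 0.7) by default, daughter lengths shrink by 0.75,
bifurcations deviate ±35° with the branching plane rotating 90° per
generation so branches splay into 3-D without colliding. Tortuosity is
injected as a sinusoidal waypoint displacement of amplitude `tortuosity_amp`
in a seeded random perpendicular direction, so arc/chord exceeds 1 exactly
when the amplitude is positive. Default root radius 1.5 mm and length
30 mm give length/radius ratios typical of second-order cerebral branches.
Exact morphometry (count, radii, lengths, tortuosity) is recorded
independently of any grid.

**Voxelization** marks a voxel foreground iff its center is within the
local branch radius of the centerline — the rasterized solid of one branch
is therefore a capsule (cylinder plus hemispherical caps), which is the
analytic volume the tests check against. Default vessel spacing is 0.4 mm
isotropic (near typical TOF in-plane resolution); lesion grids default to
1 mm. The grid origin is aligned so the root's start point lies on a voxel
center: an axis-aligned tube whose axis falls symmetrically between voxel
centers rasterizes to an even-sided cross-section with no medial column,
which 3-D thinning dissolves entirely.

**Lesions and ventricles** are rasterized ellipsoids and boxes with exact
analytic volumes and placements; overlap between lesions or with the
ventricle mask is a generation error. Grid-aligned placements make planted
boundary distances exact in the voxel-center metric used by the
classifiers.

**Cohorts** plant a log-linear model: log WMH volume = intercept +
β_flow·Q̄ + β_pressure·P̄ + β_drop·ΔP̄ + covariate terms + N(0, σ).
Defaults reproduce the observed cohort structure — n = 2631, age 68.5
(SD 11.1), the seven covariate prevalences, features Q̄ ~ N(7.86, 1.40)
mL/min, P̄ ~ N(82.4, 7.15) mmHg, ΔP̄ ~ N(0.51, 0.09) mmHg — with
bivariable effect sizes 0.13, 0.05 and 1.80 per unit. Covariates and
features are drawn independently, so planted coefficients are both the
marginal and adjusted truths; residual SD defaults to 1.3 and the
intercept is set so the mean log volume matches a 6.58 mL typical burden.

**What the generator does not emulate** — and what passing tests therefore
do not show about clinical data: realistic circle-of-Willis anatomy and
anastomoses (cycles are only exercised by a phantom fixture), MRA intensity
physics and flow-related enhancement, segmentation noise and dropout,
lesion texture or confluence, and correlated covariates/confounding (the
generator's independence is the simplest structure sufficient for
estimator-recovery tests; confounding scenarios require custom specs).

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately small
problems: depth-3 trees (~10⁴ foreground voxels at 0.4 mm), 20 random
trees up to depth 6 for solver cross-checks against a dense brute-force
assembly, 200 replicates for CI coverage and 1000 for type-I error at
n = 2000 / 200 subjects. Every random draw flows from an explicit seed
(`numpy.random.default_rng`); the pipeline writes a manifest with the
config hash and library versions, and two runs with the same inputs and
seed are byte-identical.

## Known limitations

- Steady 0-D flow only: no pulsatility, autoregulation, wall shear stress
  or compliance; pressure drops are meaningful relatively, not as absolute
  transmural pressures.
- Cycles are broken, not modelled; a dominant anastomotic pathway will be
  misrepresented.
- Radius from the inscribed sphere underestimates true lumen radius in
  non-circular cross-sections; diameter is 2× mean inscribed radius, not
  area-derived.
- The structured-tree parameters (α, β, λ, P_term) are literature defaults,
  not patient-calibrated; absolute flows scale accordingly.
- ALTABs are defined by spatial proximity only and need not be the true
  supplying arteries of a lesion.
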