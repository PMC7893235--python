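# Methods

This note documents the models and procedures implemented in `morphosig`,
the assumptions they make, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter for reproducing results.

## Data model

A *landmark scheme* fixes the ordered identities of `k` 3-D landmarks with
their annotations: type (fixed anatomical point, curve semilandmark,
surface semilandmark), module label, sagittal-midline flag, bilateral pair,
and ordered curve membership. Configurations are `k x 3` matrices in an
arbitrary specimen-local frame; partial specimens carry a presence mask,
and a module counts as present only when all of its landmarks are. The
long-form delimited table is the canonical file format because it has a
natural missing-value convention (absent rows); the TPS interchange format
is supported for complete specimens only.

## Superimposition

Centroid size is the root summed squared distance of the landmarks from
their centroid. Pairwise superimposition is the least-squares orthogonal
fit (SVD of the cross-covariance) over translation, proper rotation and,
optionally, uniform scale; reflections are never introduced implicitly —
anatomical chirality changes only through the explicit mirroring
operations. Generalized Procrustes analysis centers every configuration,
scales it to unit centroid size (partial Procrustes with scaling; original
sizes are retained separately because all downstream analyses treat size
and shape as distinct variables), and iterates rotation-to-consensus until
the change in summed squared residuals falls below `tol` (default 1e-10,
maximum 100 iterations; non-convergence is an error). The consensus is
initialized from the first specimen for determinism, and the converged
frame is canonicalized to the consensus principal axes with a
skewness-based sign convention, which makes the output invariant to input
order up to numerical tolerance.

**Reflection-augmented GPA.** Specimens of different widths can pull a
plain Procrustes alignment off the sagittal midline. Each configuration is
therefore doubled with its reflection across its own total-least-squares
midline plane (estimated from the midline landmarks; at least three
non-collinear ones are required), the 2k-landmark configurations are
aligned, and the mirrored half is dropped. The kept coordinates stay in
the frame of the augmented alignment: re-centering or re-scaling each half
separately would reintroduce exactly the midline drift the protocol
removes, so the per-configuration centroid/unit-size invariants are
asserted only for plain GPA output (an `augmented` flag records which
frame a dataset is in).

**Retrodeformation.** Mild asymmetric (shear-like) taphonomic deformation
is undone at the landmark level by bilateral symmetrization: each landmark
is averaged with its reflected, pair-relabelled counterpart across the
estimated sagittal plane. The result is exactly mirror-symmetric and the
operation is idempotent. The sagittal obliquity — the angle between the
midline-plane normal and the mean bilateral-pair axis — gates the
operation: above 10° (configurable) the specimen is refused as not
retrodeformable, matching the practice of excluding strongly deformed
material rather than inventing it. This is a landmark-level operation; it
does not reconstruct mesh-based retrodeformation protocols and cannot undo
non-affine (bending/torsional) deformation.

## Semilandmark sliding

The 3-D thin-plate-spline bending-energy matrix is the upper-left block of
the inverted TPS system; the kernel is taken as U(r) = −r so that the
quadratic form is positive semidefinite (the sign is a convention; the
form annihilates every affine image of the reference either way). Sliding
displaces each curve semilandmark along the 1-D tangent estimated by
central differences along its stated curve order (one-sided at the ends),
and each surface semilandmark within the 2-D tangent plane of its local
cloud (the two leading principal directions of the 8 nearest neighbours,
with neighbourhoods fixed by reference-shape proximity so they are stable
across specimens and iterations). Because the bending energy is quadratic
and the constraints are linear, the optimal tangent displacements have a
closed form; with displacement directions supported on single landmarks
the normal equations reduce to `(B[o,o'] (v·v')) t = −(v·(BW))`, which
keeps the cost low even at high landmark counts. Each of the (default 3)
iterations re-runs GPA, recomputes the consensus and its bending-energy
matrix, slides every specimen, and maps the result back into the
specimen's original frame; the per-iteration pre/post energies are logged
and the slide step never increases the energy it minimizes. Sliding is
tangent-displacement only — there are no meshes in scope to re-project
onto — and the minimized-Procrustes-distance variant is not implemented.

## Allometry

`ShapeAllometry` regresses the mean-centered aligned coordinates
(`n x 3k`) on centered natural-log centroid size. Natural log is used
everywhere; the base affects neither log–log slopes nor p-values. R² is
the explained fraction of total coordinate variance; its significance is
assessed by permuting the size labels (default 999 permutations, seeded,
with `(b+1)/(m+1)` smoothing). The unit-normalized coefficient vector is
the common allometric component; projecting specimens onto it gives the
standardized shape scores of the regression, and the slope of those scores
on ln CS equals the coefficient norm.

Two kinds of residual components are exposed, differing in one projection:

* `rsc_scores` — principal directions of the regression residual matrix
  after additionally partialling the CAC-score vector out of every column,
  so RSC scores are *exactly* uncorrelated with CAC scores (the model's
  orthogonality contract).
* `residual_component_scores()` — principal components of the
  allometry-corrected data themselves, exactly orthogonal to size but not
  partialled against the CAC score. The dimorphism scan uses these: when
  the CAC is estimated from a weak size signal (module-restricted fits can
  have R² ≈ 0.05) the estimated direction aligns with whatever dominates
  the residual variance, and partialling it out would absorb genuine
  non-allometric structure — including a real dimorphic offset.

Allometry correction returns the per-specimen regression residuals with
the consensus added back; refitting shape on size on corrected data gives
R² = 0 identically. Module-level ontogeny is assessed two ways: the OLS
slope of ln module CS on ln whole CS (1 = isometry), and the slope of each
globally-aligned module's CAC score on ln whole CS (0 = no shape change;
the CAC sign is fixed so slopes are non-negative). Slopes are compared
pairwise by the interaction F-test of `y ~ x + group + x:group`, built
directly from least-squares design matrices (the nested-model F with
`scipy.stats.f`); pairwise comparison matches how individual module
contrasts are usually reported. Intercepts are always estimated — forcing
them through zero would bias slopes — and fitted models can project the
landmark configuration at any size (the consensus exactly at the mean log
size).

## Modularity

The landmark congruence matrix holds, for every landmark pair, the
correlation-like similarity of their 3-D deviation vectors across
specimens (centered cross-products normalized by the deviation norms).
The maximum-likelihood comparison treats the absolute values of the
`k(k−1)/2` off-diagonal coefficients as data: a module hypothesis
partitions pairs into classes — one per within-module set, plus either a
single pooled between-module class or one class per module pair (both
variants are evaluated for every hypothesis) — each class's estimate is
its mean absolute coefficient, and the log-likelihood is normal on the
Fisher-z scale with variance 1/(n−3) (coefficients are clamped to
0.999999 before the transform; n ≤ 3 is an error). Models are ranked by
AICc with parameter count = number of classes + 1 and sample size = number
of pairs, and summarized with Akaike weights. A single-module null is
always evaluated. The hypothesis set is user-configurable; the default is
a nested scan from the scheme's full anatomical partition down to two
modules, since dense landmarking favours many-module models and the
interesting question is how far pooling can go.

Because dense semilandmark coverage inflates support for many modules, the
AICc-best partition is post-processed once (not iteratively refitted) with
the merge rule: any module pair whose between-module estimate comes within
0.1 of the lowest within-module estimate is mergeable, and mergeable pairs
are united transitively.

The covariance ratio uses the `3k x 3k` specimen covariance matrix. For a
module pair, CR² is the summed squared between-module covariances over the
geometric mean of the summed squared within-module covariances; the
overall CR is the mean over pairs, with CR < 1 indicating modularity. Each
landmark's own 3×3 covariance block is excluded entirely from the within
sums: removing only the variance diagonal would leave within-landmark
covariances that rotate with the coordinate frame and break the
invariance of CR to global rotations of the aligned data. The permutation
test reassigns whole landmarks (keeping x, y, z together) to modules,
preserving module sizes, and reports `p = (1 + #{CR_perm ≤ CR_obs}) /
(1 + n_perm)`; ties count against significance.

## Disparity

The Procrustes variance of a landmark is its mean squared 3-D deviation
from the mean aligned position, with sample divisor n−1 (the consensus
used for variances is the arithmetic mean of the aligned coordinates, so
per-landmark variances sum exactly to the total Procrustes variance).
Module variances are sums over their landmarks and are divided by the
landmark count so modules of different landmark density are comparable.
Raw variances use the aligned data; corrected variances use the
allometry-corrected residuals. The covariate test is an ordinary
least-squares fit of per-module disparity on a per-module covariate
(growth-rate slope, or the within-module correlation estimate from the ML
fit) with a two-sided slope t-test — with five modules this has little
power and is reported as the descriptive check it is.

## Dimorphism

The dip statistic is the smallest sup-norm distance between the empirical
CDF and any unimodal CDF (convex, then concave, an atom at the mode
allowed). It is computed by the classical greatest-convex-minorant /
least-concave-majorant iteration in count units and was validated to
1e-14 against an exact linear-programming oracle (minimization over
piecewise-linear unimodal CDFs with knots at the data; a mode strictly
inside a gap is dominated by an atom-carrying mode at an adjacent knot, so
scanning knot modes is exhaustive) for samples up to n = 45. Known
anchors: dip({0,1}) = 1/4; 1/(2n) ≤ dip ≤ 1/4; affine invariance.

The test's null distribution is Monte Carlo from uniform(0,1) samples (the
asymptotically least-favourable unimodal distribution), seeded, with
`(b+1)/(m+1)` smoothing; null dips are cached per sample size, so a scan
of many components costs one null simulation. The scan applies the test to
the first eight residual shape components of allometry-corrected data —
whole-skull and per module, the latter both in the global alignment and
separately aligned (where partial specimens join) — and repeats everything
with the smallest specimens removed. No multiplicity correction is applied
to individual p-values; instead the scan reports the expected false-flag
count (`n_tests × α`) alongside. In practice the uniform null is
conservative for near-Gaussian component scores, so unimodal data flag
less often than α would suggest.

'Juveniles' are identified by a deterministic rule replacing a by-eye
reading of the allometry plot: sort log centroid sizes, find the largest
gap, and flag everything below it when that gap exceeds twice the median
of the remaining gaps. The rule is configurable and logged; the pipeline
additionally requires the adult subset to be a majority of at least eight
specimens before running the reduced variant, since a spurious gap high in
a uniform size distribution would otherwise discard most of the sample.

## Synthetic data

The generator plants every effect the analyses are designed to detect, on
a bilaterally symmetric consensus (midline landmarks exactly on x = 0,
pairs exactly mirrored, modules clustered in space, curves smooth):

* **Modular covariance** — one latent factor per module (coherent
  displacement fields) plus one shared global factor, with amplitudes
  calibrated by least squares so the *population* congruence matrix
  implied by the planted fields matches the within-/between-module
  targets (defaults 0.7 / 0.3); unsatisfiable targets (within ≤ between)
  are an error. All planted fields are projected onto the orthogonal
  complement of the similarity group's tangent space at the consensus, so
  Procrustes alignment preserves them to first order.
* **Module-specific growth** — module internal geometry scales as
  `exp((β_m − 1) a)` with `a` the centered log size (defaults 1.4, 1.1,
  1.0, 1.0, 0.9 with the frill-analog steepest); module-centroid offsets
  scale with a compensating exponent chosen so whole centroid size tracks
  the size variable. Each module also carries an allometric *shape*
  direction with planted amplitude (frill-analog 3× the others).
* **Allometric variance share** — residual amplitudes are rescaled so the
  planted share of shape variance explained by size (default 0.5) holds
  exactly in the drawn sample: latent scores are centered, mutually
  orthogonalized and variance-normalized in-sample. Planted quantities are
  thus properties of the sample, not just the population, which keeps
  recovery tests sharp at n = 30.
* **Dimorphism** (off by default) — sexes, balanced across the size range,
  are displaced by ±δ along a planted within-module direction, with δ =
  `dimorphism_multiple` × the within-sex SD along that direction (so the
  between-sex separation is 2δ). The direction carries its own latent
  within-sex factor at module-factor scale, and both factor and offset
  ride the module's size factor, so the mixture is homoscedastic in
  module-normalized shape space.
* **Taphonomy** — a symmetric dorsoventral compression ('dilation') factor
  per specimen, with its variance share calibrated to a target fraction of
  shape variance (the study-like preset uses 5%, the magnitude a leading
  principal component would visibly carry); `apply_taphonomy` additionally
  offers a small sagittal shear for exercising retrodeformation.
* **Partial specimens** — extra specimens keeping only the frill-analog
  module plus one other, masked at the landmark level.

Finally every specimen is scaled to its drawn size (log-uniform over
±0.7, optionally bimodal with a planted juvenile cluster) and given a
random proper rotation and translation, so alignment is non-trivial. Same
seeds give bit-identical data.

What the generator does **not** emulate: digitization error correlated
along curves, mesh-level taphonomy (plastic flow, cracks), phylogenetic or
ontogenetic-stage structure beyond size, non-affine asymmetric
deformation, and measurement error in module assignment. Passing recovery
tests therefore demonstrates that the pipeline's inferences are correct
when its own statistical assumptions hold — not that those assumptions
hold for any particular fossil sample.

## Scale of the shipped analyses

The study-scale landmark count (821 over five modules, with 30 complete
plus 14 partial specimens) is available via `paper_like_truth(
full_scale=True)`. The test suite and the acceptance script run the same
preset at a desk-scale 80-landmark version of identical structure, chosen
so the full pipeline, permutation tests and repeated-simulation recovery
studies execute in seconds while every rank, rate and calibration property
being tested is unchanged.

## Known limitations

* The ML modularity likelihood treats landmark pairs as independent
  observations; as in the method it follows, AICc values are comparative
  indices, not calibrated probabilities.
* The dip test is conservative for near-Gaussian scores under the uniform
  null and has limited power below a between-mode separation of about six
  within-group SDs at n ≈ 44; the scan's multiple variants mitigate but do
  not remove this.
* Retrodeformation by symmetrization can only restore the asymmetric
  (shear) component of deformation; symmetric compression is confounded
  with biology and is handled only by inspecting leading shape components.
* The juvenile rule keys on size gaps alone; genuinely continuous size
  distributions with a sparse middle can trigger it, hence the pipeline's
  majority guard.
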