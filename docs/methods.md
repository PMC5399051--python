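# Methods

This note records the statistical model behind `wingid`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not demonstrate.

## Data model

The unit of analysis is one specimen's wing *shape*: an ordered set of
k = 15 homologous 2-D landmarks (vein junctions and termini). Landmark
order is semantic — index i is the same anatomical point in every
configuration — so readers never reorder points and reject records whose
landmark count differs from the dataset's. Configurations with fewer than
three landmarks, or with all landmarks collinear, are rejected outright:
the optimal rotation is underdetermined for them. Missing landmarks are not
imputed; a wing is usable only if every landmark can be placed.

Coordinates are used as read (an image-convention y-down axis is fine,
since only relative geometry survives superimposition); a `--flip-y`
ingestion flag is provided for mixed-convention datasets. A TPS `SCALE`
line multiplies coordinates on input; absent scale means unit scale. This
only affects stored centroid sizes — shape analysis is scale-free.

## Bilateral merging

Both wings of a specimen are measured where available and averaged into one
analysis shape. Left wings are first mirrored about the y axis so that both
sides share right-wing orientation (chirality is otherwise a genuine shape
difference). The two wings are then reduced to preshape (centred, unit
centroid size), one is optimally rotated onto the other, and the
landmark-wise mean is renormalized. This symmetric construction was chosen
over "fit side A onto side B, then average" because it makes the merged
shape provably independent of which side is taken as reference: swapping
the roles changes the mean only by a rotation. With a single wing present
that wing is used alone and a warning is logged. Averaging two wings with
independent digitization noise halves the shape variance around the
specimen's true shape; the test suite verifies the halving by Monte Carlo.

## Superimposition

Generalized Procrustes analysis in its orthogonal least-squares form:

- every configuration is centred and scaled to unit centroid size once
  (a *partial* fit — there is no per-iteration rescaling against the
  consensus, keeping "shape only" semantics explicit);
- the consensus is initialized as the first configuration (the optimum is
  insensitive to initialization for wing-like data, and a fixed rule makes
  runs reproducible);
- iterations alternate rotating every configuration onto the consensus with
  re-estimating the consensus as the re-centred, renormalized landmark-wise
  mean. Both half-steps are exact minimizers, so the objective (summed
  squared deviation from the consensus) is non-increasing; this is asserted
  every iteration.

Convergence: objective decrease below 1e-10, at most 100 iterations;
non-convergence returns a flagged result with a warning, never silently.
Proper rotations only — reflections inside the alignment would mask
digitization errors (e.g. an unmirrored left wing), so mirroring exists
only as an explicit I/O operation.

Aligned 2-D shapes of k landmarks span 2k − 4 dimensions (two translations,
one scale and one rotation are removed); for 15 landmarks that is 26. An
optional orthogonal projection onto the tangent space at the consensus
(`x − (x·c − 1)c` on flattened unit vectors) linearizes the shape manifold
before multivariate statistics. It is OFF by default: for wing data the
shapes sit so close to the consensus that the projection changes
coordinates by under 0.2% in norm and leaves leave-one-out confusion
matrices unchanged (both verified in the suite), and whether the original
tool chain applied it is not documented.

## Rank handling

The pooled within-group covariance of aligned coordinates is singular in
the raw 2k coordinate space (translation directions are exactly null; the
scale and rotation directions carry only second-order variance). All
discriminant statistics therefore operate on the principal subspace of the
pooled covariance: components with eigenvalue above 1e-10 of the largest
are kept, capped at min(n − g, 2k − 4). The cap matters — the second-order
directions are tiny but nonzero and would otherwise explode Mahalanobis
distances. MANOVA and CVA consume the identical reduction, which yields the
algebraic identity Λ = Π 1/(1 + λᵢ) over the canonical eigenvalues
(checked to 1e-8 in the suite).

## Discrimination

- **Wilks' Λ** is computed through the generalized between/within
  eigenvalues in log space (robust when Λ underflows; the result object
  carries `log_wilks_lambda` as well). Rao's F approximation supplies the
  p-value and is exact for g = 2 or p = 1; the univariate two-group case is
  verified against the t distribution.
- **CVA** solves **B**v = λ**W**v in the reduced subspace (where **W** is
  diagonal, so the problem whitens into an ordinary symmetric
  eigenproblem). Axes are scaled to unit pooled within-group variance of
  training scores; between-class scatter is diagonal in canonical space.
- **Classification** is Mahalanobis nearest class mean under the pooled
  covariance — a linear discriminant with *equal priors*, because
  identification is taxon assignment, not prevalence-weighted prediction;
  training class sizes deliberately do not bias assignment. Ties go to the
  first class in training-label order and are logged.
- **Typicality** of a specimen for a class is the upper-tail χ²
  probability of its squared Mahalanobis distance with df equal to the
  pooled covariance rank. Flags: `ambiguous` when max p < 0.01 (resembles
  no taxon) or at least two classes have p > 0.05 (resembles several);
  both thresholds are configuration options, since no canonical cutoffs
  exist — flagged specimens should be checked against identification keys.
  Under the null (queries drawn from a class's own distribution) the
  typicality for that class is uniform on (0, 1); the suite checks this
  with 2000 draws. The χ² reference treats the trained covariance as known,
  which is adequate when n − g is large relative to the rank (the reference
  study's regime); for very small training sets the probabilities are
  slightly anti-conservative.

A trained model (consensus, subspace basis, canonical axes, class means,
counts) serializes to a versioned JSON reference set; arrays are stored at
full precision and kept C-contiguous so a save/load round trip reproduces
every classification bit-for-bit.

## Validation

Leave-one-out cross-validation refits the CVA model for every held-out
specimen. The superimposition itself is computed **once** on the full
sample by default, mirroring the usual morphometric tool chain (alignment
in one program, cross-validated classification on exported coordinates);
per-fold re-superimposition is available behind
`PipelineConfig.loo_resuperimpose` and changes synthetic-benchmark accuracy
by at most one specimen (asserted in the suite). Confusion matrices follow
the published convention: rows true, columns predicted. Percentages are
rounded to one decimal, halves away from zero, matching the reference
tables; the unrounded values are retained and satisfy
"overall = class-size-weighted mean of per-class percents" to 1e-9.

The shipped reference tables reproduce the published counts. Recomputing
the genus-level overall percentage from the table counts gives
788/790 = 99.7% where the source text prints 99.8%, and *H. similis*
2/52 = 3.8% where it prints 3.9%; the package reports the recomputed
values and does not silently reconcile the discrepancy. The ambiguous
trailing figure in the eight-species table's last row is transcribed as
50/52 correct for *H. similis*.

## Synthetic generator

`SyntheticSpec` defaults describe the reference study design: 13 taxa with
class sizes (14, 40, 17, 35, 318, 46, 163, 14, 30, 45, 8, 32, 28) — 790
specimens — with bilateral wing pairs. Geometry is parameterized on the
preshape scale:

- `within_sd = 0.003` per tangent dimension (Procrustes units): total
  within-taxon dispersion ≈ √26 × 0.003 ≈ 0.015, a realistic magnitude for
  within-species wing-shape scatter in flies.
- `separation = 6` within-SD units per taxon mean (scalar or per-taxon;
  small values create closely related clusters). Six units reproduce the
  near-perfect but not guaranteed-perfect identification regime of the
  genus-level data.
- nuisance transforms: rotation uniform over ±180°, translation ±0.5 cm,
  scale 0.9–1.1, applied to raw coordinates and removed again by the
  pipeline.
- `digitization_sd = 0.0004` cm, about one pixel at the 2841 px/cm imaging
  resolution the wing template's ~0.9 cm length implies.

Taxon means are the stylized 15-landmark wing template plus a random unit
direction in the 2k − 4 tangent subspace times `separation × within_sd`;
within-taxon noise is Gaussian in the tangent space at the taxon mean
(keeping samples valid shapes), optionally with a full covariance. A
heuristic warns when a mean shift rivals the smallest landmark spacing, as
the implied wing outline may self-intersect. All randomness flows from one
seeded generator; identical spec + seed yields byte-identical TPS output.

The template is a hand-laid stylized wing, synthetic by construction — only
its topology (15 well-spread landmarks on a wing-like outline) matters to
the statistics. What the generator does **not** emulate: allometric
size–shape correlation, phylogenetic covariance between taxon means,
non-Gaussian digitization error, or measurement failure/missing landmarks.
Passing benchmarks on this generator therefore demonstrates the
correctness and calibration of the statistical machinery under the model's
own assumptions — not identification accuracy on real wings, which the
shipped published tables document instead.

## Problem sizes in the suite

The acceptance layer runs the 13-taxon, 790-specimen MANOVA, 8-taxon × 40
leave-one-out benchmarks at separations 6 and 0, and a 2000-draw typicality
calibration; oracle comparisons (dense generalized eigensolve,
pseudo-inverse Mahalanobis, naive per-fold refit, million-angle rotation
grid, 10⁴ random GPA restarts) use small instances where exactness is
well-defined. These sizes keep the whole suite within a few minutes on one
CPU while exercising the same code paths as a full-scale analysis.

## Known limitations

- 2-D landmarks only; no semilandmarks, no sliding, no image handling.
- Linear (pooled-covariance) discrimination only — no quadratic or kernel
  variants; genus-then-species identification is a convenience composing
  two reference sets, not a hierarchical model.
- The χ² typicality reference ignores covariance-estimation uncertainty.
- The TPS reader supports the LM=/ID=/IMAGE=/SCALE= dialect (2-D, no curve
  records); bit-exact compatibility with any particular desktop package's
  file quirks is out of scope.
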