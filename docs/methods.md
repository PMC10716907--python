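# Methods

## Scope and model

`qtdg` is a toolkit for deriving, fitting and re-sampling torsion-angle
preferences of small molecules. The workflow it supports is the one used when
torsion priors for conformer generation are harvested from a large body of
3D structures (computed conformer ensembles or crystallographic geometries):

1. every conformer is matched against a hierarchical library of dihedral
   SMARTS patterns and one torsion observation is recorded per central bond;
2. per-pattern observations are binned into 5° circular histograms and
   optionally smoothed with a wrapped-kernel KDE;
3. each distribution is fitted either with an ETKDG-style cosine series in
   energy space or with a wrapped-Gaussian mixture in probability space;
4. fitted densities are converted to inverse-CDF sampling tables so that a
   uniform random quantile yields a correctly distributed torsion angle,
   which can then be applied to a molecule by rigid torsion driving.

The toolkit consumes conformers and energies produced elsewhere (CREST,
GFN2-xTB, ETKDG, DFT); it never runs those engines.

## Torsion patterns and matching

A pattern is a SMARTS with four mapped atoms; the central bond is the 2–3
pair. Within each kind (`acyclic`, `ring`) file order is the specificity
hierarchy, and for every matched central bond exactly one observation is
emitted: the lowest-rank matching pattern wins, and among that pattern's
matches on the bond the lexicographically smallest atom-index quadruple is
the representative. One observation per central bond mirrors how distance-
geometry conformer generators attach one torsion potential per rotatable
bond, and keeps histograms free of multiplicity inflation from symmetric
matches. Ring patterns apply only to ring bonds and acyclic patterns only to
acyclic bonds.

The bundled library (`data/torsion_smarts_synthetic_v1.json`) is a synthetic
stand-in hierarchy, generated by `scripts/make_pattern_library.py`. It
reproduces the size and central-bond composition of the hierarchical
ETKDG-style pattern set — 387 acyclic patterns (C–C 168, C–O 56, C–S 16,
N–C 131, N–S 4, S–S 1, 11 others) and 105 ring patterns — with
systematically enumerated, RDKit-validated atom environments. It is intended
for testing the machinery and as a format template; substitute a curated
library via `load_pattern_library(path)` for production torsion statistics.

Dihedrals are measured with the atan2 convention (`n1·n2`,
`(n1×n2)·b̂2`) and stored in degrees on [0, 360); folding to [0, 180] is a
display concern only. The convention is pinned by the quadruple
(0,1,0),(0,0,0),(1,0,0),(1,0,1) → 90°.

## Distributions

Histograms use half-open bins [b·step, (b+1)·step) with a 5° default step
(72 bins). The KDE is circular: each observation contributes a Gaussian
kernel (default bandwidth 5°, matching the bin width) summed over ±3
periodic images, and profiles are normalized so the periodic trapezoidal
integral over [0, 360) is 1 ± 1e-6. Distribution similarity is the squared
Pearson correlation of two densities on a shared 1° grid — scale-free, so
relative peak structure rather than absolute magnitude drives the score.

## Energy transform and cosine-series fits

Bin probabilities p̂ᵢ = max(countᵢ/n, floor) are Boltzmann-inverted to
relative energies Eᵢ = −ln(p̂ᵢ/max p̂) in kT units; the floor (default 1e-4,
configurable) keeps empty bins finite and the subtraction pins min E = 0.

The cosine model is E(θ) = Σₙ Kₙ[1 + cos(nθ − dₙ)] + c with integer orders
n = 1..6, force constants Kₙ (kT) and phases dₙ. `fixed_phase` mode
restricts dₙ ∈ {0, π} (the ETKDG convention); `free_phase` fits the phases.
Because Kcos d and Ksin d enter linearly, both modes are solved exactly by
linear least squares on a cosine/sine design matrix — the global optimum of
the equivalent nonlinear problem, obtained deterministically with no
starting-point sensitivity. A consequence used as a test invariant: the
fixed-phase parameter set is a linear subspace of the free-phase set, so the
free-phase residual never exceeds the fixed-phase residual. Energy fits are
scored against histograms by converting to density ∝ exp(−E), normalized on
the evaluation grid.

Published fixed-phase parameter sets can be imported directly by
constructing a `CosineFit` and scoring it with `cosine_to_density` +
`fit_quality_r2`, as an alternative to refitting.

## Wrapped-Gaussian mixture fits

The probability-space model is a uniform baseline plus up to six wrapped
Gaussian peaks. Fitting choices that matter:

* **Bin integrals, not midpoints.** The model predicts each bin's mass as
  exact wrapped-normal CDF differences over the bin edges. At 5° resolution
  the midpoint approximation leaves a curvature-shaped systematic residual
  (and biases σ upward by ≈ step²/24σ), which a likelihood-based peak-count
  selection would otherwise absorb into spurious peaks.
* **Inverse-variance weighting.** Residuals are weighted by
  1/√max(p̂ᵢ, 1/n), the multinomial standard deviation of a bin proportion
  (floored at one count). Unweighted fitting over-serves tall bins and
  misfits tails in relative terms.
* **Peak-count selection.** k runs from 1 to 6; each k is scored with a
  multinomial BIC, −2Σᵢ countᵢ ln qᵢ + (3k+1) ln n, and the smallest k whose
  BIC is within 2 of the minimum is kept (parsimony within the evidence
  tie).
* **Starts.** Each k gets a peak-picking start (local maxima of the
  circularly smoothed histogram), a greedy incremental start (the best
  (k−1)-peak solution plus one peak at the largest positive residual), and
  seeded jittered variants; the best of the converged starts wins, so the
  result is deterministic given the seed.
* **Bounds.** Amplitudes and baseline ≥ 0; σ ∈ [1°, 120°]; means are
  unconstrained during optimization and wrapped into [0, 360) afterwards, so
  peaks straddling the 0/360 seam are recovered without artifacts.

Results report peak weights (mass fractions including the baseline),
approximate standard errors from the Gauss–Newton covariance, the per-k BIC
trace, and the Pearson r² against the source histogram.

## Sampling tables and torsion driving

A density becomes a sampling table by cumulative (trapezoidal) summation
over [0, 360] at 0.5° resolution, normalization to [0, 1], and monotone
linear-interpolation inversion; flat CDF stretches are tilted by ~1e-12 so
the inverse is single-valued. Torsion driving rotates the atoms on the
distal side of an acyclic central bond rigidly about the bond axis, so all
bond lengths, angles and intra-side distances are preserved exactly and the
requested dihedral is met to 1e-6°. Ring torsions are never driven: ring
angles are strongly coupled within the ring, so ring tables are only emitted
for downstream distance-geometry use. Molecules are driven bond by bond in
ascending central-bond index order with no clash resolution.

## Synthetic data and the fit battery

The generator draws from wrapped-normal mixtures — the same family as the
fit model, so parameter recovery is well-posed — with a closed-form CDF
(image sum, widened automatically for very broad components) as the oracle
for sampling tests. The standard battery is 50 seeded mixtures with 1–4
components, weights ≥ 0.1, σ ∈ [8°, 20°], and means ≥ 40° apart on the
circle, at n = 10⁴ angles per mixture: widths and multimodality typical of
real torsion histograms, at a problem size that keeps the full battery in a
few minutes on one CPU. What the battery does *not* emulate: correlated
torsions, ring-pucker coupling, crystal-packing effects, heavy-tailed or
skewed peaks, and the very uneven per-pattern support of real corpora — so
passing it demonstrates the correctness of the machinery, not the field
accuracy of any particular torsion library.

On this battery the median fit quality orders Gaussian ≥ free-phase cosine ≥
fixed-phase cosine (the free-phase fit is never worse than fixed-phase by
construction; the mixture family is the generator's own, so it tops the
ordering), and Gaussian fits recover component means within 2° and weights
within 0.05 in ≥ 95% of mixtures. Overlapping low-weight components at the
battery's minimum separation are the residual hard cases.

Toy molecules (butane; an amine/chloride salt pair; 2,2'-dimethylbiphenyl,
whose ortho-methyl clash forces a ≈ 90° inter-ring twist) are built in code
with seeded embedding and MMFF relaxation.

## Geometry statistics

Ensemble-vs-reference RMSD uses heavy atoms after Kabsch superposition with
canonical atom-order correspondence by default; a graph-automorphism-aware
minimum RMSD is available behind a flag (`symmetry=True`) since symmetric
molecules can otherwise overstate RMSD. Radius of gyration is heavy-atom and
unit-weight (√(Σ‖rᵢ − r̄‖²/N)); mass weighting is deliberately not used so
the statistic is a pure shape measure. Rotatable bonds are acyclic single
bonds between heavy atoms that each have ≥ 2 heavy neighbours, excluding
amide C–N bonds. Conformer energies (kcal/mol) are read from an SDF property
tag (default `energy_kcal`) or a two-column sidecar CSV; the energy-window
filter (default 6 kcal/mol) always retains the minimum-energy conformer.

## Numerical conventions and degenerate inputs

* Angles in degrees on [0, 360) everywhere; phases of cosine terms in
  radians.
* Collinear quadruples raise rather than returning an arbitrary dihedral.
* Empty histograms, zero-mass densities, constant profiles (undefined
  Pearson correlation), missing energies and ring central bonds raise
  `ValueError` with a describing message.
* Ties: fragment stripping breaks by heavy atoms → total atoms → canonical
  SMILES; lowest-energy conformer by label order; pattern matches by rank →
  smallest quadruple.
* All stochastic code paths (generators, mixture-fit starts, sampling) take
  explicit integer seeds and are reproducible bit-for-bit.
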