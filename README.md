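# qtdg — quantum-torsion distribution toolkit

`qtdg` is a Python toolkit for deriving, fitting and re-sampling small-molecule
torsion-angle preferences. It is aimed at cheminformatics developers who build
or evaluate conformer generators: people who harvest dihedral statistics from
large collections of 3D structures (computed conformer ensembles or
crystallographic geometries) and turn them into torsion priors for
distance-geometry methods such as ETKDG, or its quantum-derived counterpart
QTDG.

What it does:

* **Extract** — match molecules against a hierarchical dihedral SMARTS
  library (one observation per central bond, highest-priority pattern wins)
  and measure dihedrals on conformers.
* **Compare geometries** — smallest heavy-atom RMSD (Kabsch) between an
  ensemble and a reference, radius of gyration and its ratio, rotatable-bond
  counts, RMSD-vs-rotors regression and threshold summaries.
* **Distributions** — 5°-binned circular histograms, wrapped-Gaussian KDE
  smoothing, and Pearson r² between density profiles.
* **Fit** — Boltzmann inversion E = −ln(p/p_max) followed by an ETKDG-style
  cosine series E(θ) = Σₙ Kₙ[1 + cos(nθ − dₙ)] + c with fixed (dₙ ∈ {0, π})
  or free phases, or a wrapped-Gaussian mixture (up to six peaks, BIC-selected)
  fitted directly to bin probabilities.
* **Sample** — invert a fitted density's cumulative sum into an inverse-CDF
  table, draw seeded torsion angles through it, and apply them by rigid
  torsion driving of acyclic bonds.
* **Synthesize** — wrapped-normal mixture generators with a closed-form CDF
  oracle and built-in toy molecules, so the whole pipeline is testable
  without external data.

The bundled pattern library is a synthetic stand-in hierarchy matching the
published size and central-bond composition of the ETKDG-style set
(387 acyclic + 105 ring patterns); swap in a curated library with
`load_pattern_library(path)` for production statistics. The toolkit consumes
conformers and energies produced elsewhere (CREST/GFN2, ETKDG, DFT) — it
never runs those engines. See `docs/methods.md` for the models, numerical
choices and limitations.

## Worked example

Fit a bimodal torsion distribution and re-sample it:

```python
import numpy as np
import qtdg

spec = qtdg.MixtureSpec(components=((0.6, 65.0, 10.0), (0.4, 185.0, 14.0)), seed=11)
angles = qtdg.generate_mixture_angles(spec, 10_000)
hist = qtdg.build_histogram(angles)          # 72 bins at 5 degrees
result = qtdg.fit_gaussian_mixture(hist, seed=0)
print(result.summary())

table = qtdg.build_sampling_table(result.density())
draws = qtdg.sample_angles(table, 100_000, seed=1)
print(f"r2(sampled histogram, fitted density) = "
      f"{qtdg.fit_quality_r2(result.density(), qtdg.build_histogram(draws)):.4f}")
```

Output:

```
Wrapped Gaussian mixture fit
====================================================
peaks selected:   2 (BIC 58428.5)
observations:     10000
Pearson r^2:      0.9974
baseline:         2.395e-21 /deg
seed:             0
----------------------------------------------------
peak   weight  mean (deg)  sigma (deg)
   1    0.605       64.97         9.85
   2    0.395      184.76        13.83
r2(sampled histogram, fitted density) = 0.9999
```

The fit selects two peaks and recovers the generating means (65°, 185°),
widths and weights from the binned sample; the r² of 0.9974 is the squared
Pearson correlation between the fitted density at the bin centers and the
bin probabilities. Pushing 10⁵ uniform quantiles through the inverse-CDF
table reproduces the fitted density essentially exactly.

The same steps are available from the shell via `qtdg extract`, `qtdg
compare`, `qtdg hist`, `qtdg corr`, `qtdg fit`, `qtdg sample` and `qtdg
synth` — run `qtdg --help` for options.

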