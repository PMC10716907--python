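"""Synthetic data generators.

Provides wrapped-Gaussian-mixture torsion populations with known parameters
(the test-side mirror of the Gaussian fit family, so parameter recovery is
well-posed), their closed-form CDF as an oracle for sampling tests, small toy
molecule fixtures built in code, and a seeded battery of mixture specs used
to exercise the fitting and sampling pipeline end to end.

What these emulate — and what they do not: the mixtures reproduce the
multimodal, periodic shape of real torsion histograms, but not correlated
torsions, crystal-packing effects, or conformer-ensemble energetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.stats import norm

__all__ = [
    "MixtureSpec",
    "generate_mixture_angles",
    "analytic_mixture_cdf",
    "make_toy_molecule",
    "mixture_battery",
]

N_WRAP = 3


@dataclass(frozen=True)
class MixtureSpec:
    """A wrapped-normal mixture on the torsion circle.

    ``components``: tuple of (weight, mean_deg, sigma_deg); weights sum to 1.
    """

    components: tuple
    seed: int = 0

    def __post_init__(self):
        if not 1 <= len(self.components) <= 6:
            raise ValueError("1-6 components required")
        w = np.array([c[0] for c in self.components], dtype=float)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be positive and sum to 1")
        if any(c[2] <= 0 for c in self.components):
            raise ValueError("sigmas must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] % 360.0 for c in self.components])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])


def generate_mixture_angles(spec: MixtureSpec, n: int) -> np.ndarray:
    """Draw ``n`` seeded i.i.d. angles (degrees in [0, 360)) from the mixture.

    Component chosen by weight, angle by a normal draw wrapped into [0, 360).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    comp = rng.choice(len(spec.components), size=n, p=spec.weights)
    draws = rng.normal(spec.means[comp], spec.sigmas[comp])
    return draws % 360.0


def analytic_mixture_cdf(spec: MixtureSpec, angle) -> np.ndarray | float:
    """Closed-form CDF of the wrapped mixture on [0, 360).

    F(a) = sum_j w_j sum_k [Phi((a - mu_j + 360k)/s_j) - Phi((-mu_j + 360k)/s_j)],
    with the image sum truncated at +-3 wraps (widened automatically for very
    broad components), so F(0) = 0 and F(360-) -> 1.
    """
    a = np.asarray(angle, dtype=float)
    out = np.zeros_like(a)
    for w, mu, sg in spec.components:
        acc = np.zeros_like(a)
        # widen the image sum for very broad components (uniform limit)
        n_wrap = max(N_WRAP, int(np.ceil(4.0 * sg / 360.0)))
        for k in range(-n_wrap, n_wrap + 1):
            acc += norm.cdf((a - mu + 360.0 * k) / sg) - norm.cdf((-mu + 360.0 * k) / sg)
        out += w * acc
    return float(out) if np.isscalar(angle) else out


def expected_histogram(spec: MixtureSpec, n: int, step: float = 5.0):
    """Noise-free binned histogram: expected counts under the mixture.

    Bin masses are exact CDF differences (no sampling noise), scaled to n
    observations and rounded.  Useful as the idealized large-n input for
    fitting and sampling-fidelity checks.
    """
    from .distributions import TorsionHistogram

    edges = np.arange(0.0, 360.0 + step, step)
    cdf = analytic_mixture_cdf(spec, edges)
    probs = np.diff(cdf)
    counts = np.rint(probs * n).astype(int)
    return TorsionHistogram(counts=counts, step=step)


def mixture_battery(n_specs: int = 50, seed: int = 0) -> list[MixtureSpec]:
    """Seeded battery of random 1-4 component mixtures.

    Conditions are chosen to resemble real torsion preferences: peak widths
    of 8-20 degrees, component weights of at least 0.1, and peak means kept
    at least 40 degrees apart on the circle so components are resolvable.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_specs):
        k = int(rng.integers(1, 5))
        # rejection-sample means with minimum circular separation 40 deg
        while True:
            means = rng.uniform(0.0, 360.0, k)
            if k == 1:
                break
            sep = np.abs(means[:, None] - means[None, :])
            sep = np.minimum(sep, 360.0 - sep)
            if np.all(sep[np.triu_indices(k, 1)] >= 40.0):
                break
        w = rng.uniform(0.1, 1.0, k)
        w /= w.sum()
        while np.any(w < 0.1):  # renormalization can undershoot the floor
            w = np.maximum(w, 0.1)
            w /= w.sum()
        sig = rng.uniform(8.0, 20.0, k)
        comps = tuple((float(wi), float(mi), float(si)) for wi, mi, si in zip(w, means, sig))
        specs.append(MixtureSpec(components=comps, seed=int(rng.integers(0, 2**31 - 1))))
    return specs


def _embedded(smiles: str, seed: int = 0xF00D % 1000) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    AllChem.MMFFOptimizeMolecule(mol)
    return mol


def make_toy_molecule(name: str) -> Chem.Mol:
    """Deterministic small molecule fixtures with a 3D conformer.

    ``butane``: one rotatable bond (C2-C3).
    ``salt_pair``: an 8-heavy-atom amine plus a single-atom chloride
    counterion, for fragment-stripping tests.
    ``bimodal_biaryl``: 2,2'-dimethylbiphenyl — ortho methyls sterically
    force the inter-ring torsion to ~90 degrees.
    """
    recipes = {
        "butane": "CCCC",
        "salt_pair": "CCCCCCC[NH3+].[Cl-]",
        "bimodal_biaryl": "Cc1ccccc1-c1ccccc1C",
    }
    if name not in recipes:
        raise ValueError(f"unknown fixture {name!r}; options: {sorted(recipes)}")
    mol = _embedded(recipes[name])
    mol.SetProp("_Name", name)
    return mol
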