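"""Inverse-CDF torsion sampling and torsion driving.

A fitted density becomes a sampling table by taking the cumulative sum of the
density across all angles from 0 to 360 degrees, normalizing it to [0, 1] and
inverting it by monotone interpolation, so a uniform random quantile maps to
an appropriately distributed torsion angle.  Sampled angles are applied to
molecules by rigid rotation of one side of an acyclic central bond (torsion
driving); ring torsions are never driven here, since ring angles are strongly
coupled to the other torsions of the ring and belong to distance-geometry
refinement instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .distributions import DensityProfile
from .patterns import TorsionPattern, match_torsions, measure_dihedral

__all__ = [
    "SamplingTable",
    "build_sampling_table",
    "sample_angles",
    "set_dihedral",
    "drive_molecule",
]


@dataclass(frozen=True)
class SamplingTable:
    """Inverted, normalized cumulative torsion distribution.

    ``quantile_grid`` is strictly increasing from 0 to 1;
    ``angle_at_quantile`` is nondecreasing in [0, 360).
    """

    quantile_grid: np.ndarray
    angle_at_quantile: np.ndarray
    pattern_id: int = -1

    def __call__(self, u) -> np.ndarray | float:
        """Map uniform quantiles u in [0, 1] to torsion angles (degrees)."""
        out = np.interp(u, self.quantile_grid, self.angle_at_quantile)
        return float(out) if np.isscalar(u) else out


def build_sampling_table(
    density: DensityProfile, resolution: float = 0.5, pattern_id: int = -1,
) -> SamplingTable:
    """Build an inverse-CDF table from a density at the given angular resolution.

    The CDF is the cumulative sum of the (interpolated) density over
    [0, 360) at ``resolution`` degrees, normalized to end at 1.  Flat
    stretches are made strictly increasing by an epsilon tilt so the inverse
    interpolation is well defined.
    """
    if np.any(density.density < 0):
        raise ValueError("density must be nonnegative")
    grid = np.arange(0.0, 360.0 + resolution, resolution)
    dens = density.at(grid % 360.0)
    # trapezoid cumulative sum from 0 to 360
    seg = 0.5 * (dens[1:] + dens[:-1]) * resolution
    cdf = np.r_[0.0, np.cumsum(seg)]
    if cdf[-1] <= 0:
        raise ValueError("zero total mass")
    cdf /= cdf[-1]
    cdf = np.maximum.accumulate(cdf)
    eps = np.arange(cdf.size) * 1e-12
    q = (cdf + eps) / (1.0 + eps[-1])
    q[0], q[-1] = 0.0, 1.0
    return SamplingTable(quantile_grid=q, angle_at_quantile=grid, pattern_id=pattern_id)


def sample_angles(table: SamplingTable, n: int, seed: int = 0) -> np.ndarray:
    """Draw n i.i.d. torsion angles by pushing uniform quantiles through the table."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return np.asarray(table(rng.uniform(0.0, 1.0, n))) % 360.0


def _distal_atoms(mol: Chem.Mol, a2: int, a3: int) -> set[int]:
    """Atoms on the a3 side of the a2-a3 bond (a3 included)."""
    seen = {a2, a3}
    stack = [a3]
    while stack:
        cur = stack.pop()
        for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
            i = nb.GetIdx()
            if i not in seen:
                seen.add(i)
                stack.append(i)
    seen.discard(a2)
    return seen


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(axis, axis)


def set_dihedral(mol: Chem.Mol, quadruple, target: float, conf_id: int = -1) -> Chem.Mol:
    """Rotate the distal side of an acyclic central bond to the target dihedral.

    The atoms reachable from atom 3 without crossing the 2-3 bond are rotated
    rigidly about the bond axis, so all bond lengths and angles are
    preserved; afterwards :func:`qtdg.patterns.measure_dihedral` returns
    ``target`` (mod 360) to within 1e-6 degrees.  Operates in place on the
    given conformer and returns the molecule.

    Raises
    ------
    ValueError
        If the central bond is in a ring (torsion driving undefined) or the
        quadruple is not bonded 2-3.
    """
    a1, a2, a3, a4 = quadruple
    bond = mol.GetBondBetweenAtoms(a2, a3)
    if bond is None:
        raise ValueError("central pair is not bonded")
    if bond.IsInRing():
        raise ValueError("cannot drive a ring torsion")
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()
    current = measure_dihedral(pos[a1], pos[a2], pos[a3], pos[a4])
    delta = np.radians((target - current) % 360.0)
    axis = pos[a3] - pos[a2]
    moving = sorted(_distal_atoms(mol, a2, a3))
    for sign in (1.0, -1.0):
        rot = _rotation_matrix(axis, sign * delta)
        new = pos.copy()
        new[moving] = (pos[moving] - pos[a2]) @ rot.T + pos[a2]
        got = measure_dihedral(new[a1], new[a2], new[a3], new[a4])
        if abs((got - target + 180.0) % 360.0 - 180.0) < 1e-6:
            for i in moving:
                conf.SetAtomPosition(i, new[i].tolist())
            return mol
    raise RuntimeError("dihedral rotation failed to reach target")  # pragma: no cover


def drive_molecule(
    mol: Chem.Mol,
    tables: dict[int, SamplingTable],
    library: list[TorsionPattern],
    seed: int = 0,
    molecule_id: str = "",
) -> Chem.Mol:
    """Set every matched acyclic torsion to an angle sampled from its table.

    Bonds are driven sequentially in ascending central-bond atom-index order.
    A matched pattern without a table falls back to a uniform draw on
    [0, 360).  Ring torsions are left untouched.  Returns a driven copy.
    """
    out = Chem.Mol(mol)
    obs = match_torsions(out, library, molecule_id=molecule_id)
    acyclic_ids = {p.id for p in library if p.kind == "acyclic"}
    rng = np.random.default_rng(seed)
    for ob in sorted(obs, key=lambda o: tuple(sorted(o.atoms[1:3]))):
        if ob.pattern_id not in acyclic_ids:
            continue
        table = tables.get(ob.pattern_id)
        u = rng.uniform()
        angle = float(table(u)) if table is not None else 360.0 * u
        set_dihedral(out, ob.atoms, angle)
    return out
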