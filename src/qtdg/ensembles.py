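"""Conformer-ensemble I/O, preprocessing and geometry-comparison statistics.

An ensemble is a single molecule (fixed connectivity) with many conformers
and, optionally, one energy per conformer in kcal/mol.  Conformer generators
(CREST, ETKDG, ...) produce such ensembles; this module consumes them.
Preprocessing follows the usual crystal-data hygiene: keep the largest
substructure (drop solvent/counterions), exclude molecules whose output
connectivity no longer matches the input (InChI identity), restrict to a
low-energy window, and pick the lowest-energy conformer for single-geometry
analysis.

The comparison statistics are the standard ensemble-vs-reference measures:
smallest heavy-atom RMSD after Kabsch superposition, heavy-atom radius of
gyration (unit-weighted) and its conformer/reference ratio, rotatable-bond
counts, and RMSD-vs-rotors least-squares trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy import stats

__all__ = [
    "ConformerEnsemble",
    "ComparisonRecord",
    "strip_to_largest_fragment",
    "identity_check",
    "energy_window_filter",
    "lowest_energy_conformer",
    "kabsch_rmsd",
    "min_heavy_rmsd",
    "heavy_coordinates",
    "radius_of_gyration",
    "rg_ratio",
    "rotatable_bond_count",
    "rmsd_vs_rotors_regression",
    "rmsd_summary",
    "compare_ensemble",
]

DEFAULT_ENERGY_TAG = "energy_kcal"


@dataclass
class ConformerEnsemble:
    """A molecule with conformers and optional per-conformer energies (kcal/mol)."""

    mol: Chem.Mol
    energies: np.ndarray | None = None
    labels: list[str] | None = None
    molecule_id: str = ""

    def __post_init__(self):
        n = self.mol.GetNumConformers()
        if self.labels is None:
            self.labels = [str(i) for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("one label per conformer required")
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
            if self.energies.shape != (n,):
                raise ValueError("energies must match conformer count (all or none)")
            if not np.all(np.isfinite(self.energies)):
                raise ValueError("energies must be finite")

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    def coordinates(self, i: int) -> np.ndarray:
        return self.mol.GetConformers()[i].GetPositions()

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_sdf(cls, path, energy_tag: str = DEFAULT_ENERGY_TAG,
                 energy_csv=None, molecule_id: str = "") -> "ConformerEnsemble":
        """Read a multi-record SDF where each record is one conformer.

        Energies come from the named SDF property tag when present on every
        record, else from a two-column (label, energy) sidecar CSV, else are
        absent.
        """
        supp = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mols = [m for m in supp if m is not None]
        if not mols:
            raise ValueError(f"no molecules in {path}")
        base = Chem.Mol(mols[0])
        base.RemoveAllConformers()
        energies, labels = [], []
        for i, m in enumerate(mols):
            if m.GetNumAtoms() != base.GetNumAtoms():
                raise ValueError("conformer records differ in atom count")
            conf = Chem.Conformer(m.GetConformer())
            conf.SetId(i)
            base.AddConformer(conf, assignId=False)
            labels.append(m.GetProp("_Name") if m.HasProp("_Name") and m.GetProp("_Name") else str(i))
            if m.HasProp(energy_tag):
                energies.append(float(m.GetProp(energy_tag)))
        if len(energies) not in (0, len(mols)):
            raise ValueError(f"energy tag {energy_tag!r} present on only some records")
        energy_arr = np.array(energies) if energies else None
        if energy_arr is None and energy_csv is not None:
            import pandas as pd

            tbl = pd.read_csv(energy_csv)
            lookup = dict(zip(tbl.iloc[:, 0].astype(str), tbl.iloc[:, 1].astype(float)))
            energy_arr = np.array([lookup[lab] for lab in labels])
        mid = molecule_id or (mols[0].GetProp("_Name") if mols[0].HasProp("_Name") else "")
        return cls(mol=base, energies=energy_arr, labels=labels, molecule_id=mid)

    def to_sdf(self, path, energy_tag: str = DEFAULT_ENERGY_TAG) -> None:
        writer = Chem.SDWriter(str(path))
        try:
            for i, conf in enumerate(self.mol.GetConformers()):
                m = Chem.Mol(self.mol, confId=conf.GetId())
                m.SetProp("_Name", self.labels[i])
                if self.energies is not None:
                    m.SetProp(energy_tag, f"{self.energies[i]:.6f}")
                writer.write(m, confId=conf.GetId())
        finally:
            writer.close()

    @classmethod
    def from_xyz(cls, path, molecule_id: str = "", charge: int = 0) -> "ConformerEnsemble":
        """Read a multi-frame XYZ file; connectivity is perceived on frame 1."""
        from rdkit.Chem import rdDetermineBonds

        frames = _parse_xyz_frames(path)
        if not frames:
            raise ValueError(f"no frames in {path}")
        symbols0, coords0, _ = frames[0]
        block = _xyz_block(symbols0, coords0)
        mol = Chem.MolFromXYZBlock(block)
        rdDetermineBonds.DetermineBonds(mol, charge=charge)
        labels = []
        for j, (symbols, coords, comment) in enumerate(frames):
            if symbols != symbols0:
                raise ValueError(f"frame {j}: atom list differs from frame 0")
            if j > 0:
                conf = Chem.Conformer(mol.GetNumAtoms())
                for i, xyz in enumerate(coords):
                    conf.SetAtomPosition(i, xyz.tolist())
                conf.SetId(j)
                mol.AddConformer(conf, assignId=False)
            labels.append(comment or str(j))
        return cls(mol=mol, energies=None, labels=labels, molecule_id=molecule_id)


def _parse_xyz_frames(path):
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        nat = int(lines[i].strip())
        comment = lines[i + 1].strip()
        symbols, coords = [], []
        for line in lines[i + 2:i + 2 + nat]:
            parts = line.split()
            symbols.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        frames.append((symbols, np.array(coords), comment))
        i += 2 + nat
    return frames


def _xyz_block(symbols, coords) -> str:
    lines = [str(len(symbols)), ""]
    for s, (x, y, z) in zip(symbols, coords):
        lines.append(f"{s} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def strip_to_largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the disconnected component with the most heavy atoms.

    Ties break by total atom count, then by canonical SMILES order, so the
    result is deterministic.
    """
    if mol.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    def key(f):
        heavy = sum(a.GetAtomicNum() > 1 for a in f.GetAtoms())
        return (-heavy, -f.GetNumAtoms(), Chem.MolToSmiles(f))
    return sorted(frags, key=key)[0]


def identity_check(input_mol: Chem.Mol, output_mol: Chem.Mol) -> bool:
    """True iff the two molecules share an InChI identifier (connectivity-level)."""
    inchis = []
    for m in (input_mol, output_mol):
        s = Chem.MolToInchi(Chem.RemoveHs(Chem.Mol(m)), treatWarningAsError=False)
        if not s:
            raise ValueError("InChI generation failed")
        inchis.append(s)
    return inchis[0] == inchis[1]


def energy_window_filter(ens: ConformerEnsemble, window: float = 6.0) -> ConformerEnsemble:
    """Keep conformers within ``window`` kcal/mol of the ensemble minimum."""
    if ens.energies is None:
        raise ValueError("ensemble has no energies")
    keep = np.flatnonzero(ens.energies - ens.energies.min() <= window)
    mol = Chem.Mol(ens.mol)
    mol.RemoveAllConformers()
    confs = ens.mol.GetConformers()
    for j, i in enumerate(keep):
        conf = Chem.Conformer(confs[int(i)])
        conf.SetId(j)
        mol.AddConformer(conf, assignId=False)
    return ConformerEnsemble(
        mol=mol,
        energies=ens.energies[keep],
        labels=[ens.labels[int(i)] for i in keep],
        molecule_id=ens.molecule_id,
    )


def lowest_energy_conformer(ens: ConformerEnsemble) -> int:
    """Index of the minimum-energy conformer; ties break by label order."""
    if ens.n_conformers == 0:
        raise ValueError("empty ensemble")
    if ens.energies is None:
        raise ValueError("ensemble has no energies")
    winners = np.flatnonzero(ens.energies == ens.energies.min())
    return int(min(winners, key=lambda i: (ens.labels[int(i)], int(i))))


# ---------------------------------------------------------------------------
# geometry statistics
# ---------------------------------------------------------------------------

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of paired point sets after optimal rigid superposition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate shapes differ")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(ac.T @ bc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = ac @ rot - bc
    return float(np.sqrt((diff ** 2).sum() / a.shape[0]))


def heavy_coordinates(mol: Chem.Mol, conf_id: int = -1) -> np.ndarray:
    mask = np.array([a.GetAtomicNum() > 1 for a in mol.GetAtoms()])
    return mol.GetConformer(conf_id).GetPositions()[mask]


def min_heavy_rmsd(
    ens: ConformerEnsemble, reference: np.ndarray, symmetry: bool = False,
    reference_mol: Chem.Mol | None = None,
) -> float:
    """Smallest heavy-atom RMSD between the reference and any conformer.

    Default correspondence is canonical atom order (positional).  With
    ``symmetry=True`` and a ``reference_mol``, RDKit's graph-automorphism
    best-RMS search is used instead.
    """
    if symmetry:
        if reference_mol is None:
            raise ValueError("symmetry-aware RMSD needs reference_mol")
        ref = Chem.RemoveHs(Chem.Mol(reference_mol))
        probe = Chem.RemoveHs(Chem.Mol(ens.mol))
        return float(min(
            AllChem.GetBestRMS(probe, ref, prbId=conf.GetId())
            for conf in probe.GetConformers()
        ))
    mask = np.array([a.GetAtomicNum() > 1 for a in ens.mol.GetAtoms()])
    reference = np.asarray(reference, float)
    if reference.shape[0] == mask.size:
        reference = reference[mask]
    if reference.shape[0] != int(mask.sum()):
        raise ValueError("reference atom count does not match ensemble")
    best = np.inf
    for conf in ens.mol.GetConformers():
        coords = conf.GetPositions()[mask]
        best = min(best, kabsch_rmsd(coords, reference))
    return float(best)


def radius_of_gyration(coordinates: np.ndarray) -> float:
    """Unit-weight radius of gyration: sqrt(mean squared centroid distance)."""
    coords = np.atleast_2d(np.asarray(coordinates, float))
    if coords.size == 0:
        raise ValueError("no coordinates")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum() / coords.shape[0]))


def rg_ratio(conformer_coords: np.ndarray, reference_coords: np.ndarray) -> float:
    """Ratio Rg(conformer) / Rg(reference)."""
    ref = radius_of_gyration(reference_coords)
    if ref == 0.0:
        raise ValueError("reference radius of gyration is zero")
    return radius_of_gyration(conformer_coords) / ref


_AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])-[NX3]")


def rotatable_bond_count(mol: Chem.Mol) -> int:
    """Acyclic single bonds between two non-terminal heavy atoms, amides excluded.

    Non-terminal means at least two heavy-atom neighbours.  Amide C-N single
    bonds (C(=O)-N) are excluded per the usual rotor convention.
    """
    amide_bonds = set()
    for match in mol.GetSubstructMatches(_AMIDE):
        amide_bonds.add(frozenset((match[0], match[2])))
    heavy_deg = {
        a.GetIdx(): sum(nb.GetAtomicNum() > 1 for nb in a.GetNeighbors())
        for a in mol.GetAtoms()
    }
    count = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        ai, aj = bond.GetBeginAtom(), bond.GetEndAtom()
        if ai.GetAtomicNum() <= 1 or aj.GetAtomicNum() <= 1:
            continue
        if heavy_deg[i] < 2 or heavy_deg[j] < 2:
            continue
        if frozenset((i, j)) in amide_bonds:
            continue
        count += 1
    return count


@dataclass(frozen=True)
class ComparisonRecord:
    """One molecule's ensemble-vs-reference comparison statistics."""

    molecule_id: str
    n_rotatable_bonds: int
    min_rmsd: float
    rg_conformer: float
    rg_reference: float

    @property
    def rg_ratio(self) -> float:
        return self.rg_conformer / self.rg_reference


def compare_ensemble(
    ens: ConformerEnsemble, reference_coords: np.ndarray,
    conformer_index: int | None = None,
) -> ComparisonRecord:
    """Full comparison record for one ensemble against a reference geometry.

    Rg is taken on the lowest-energy conformer when energies are present
    (or the given ``conformer_index``), matching how single-geometry
    compactness is usually reported.
    """
    if conformer_index is None:
        conformer_index = lowest_energy_conformer(ens) if ens.energies is not None else 0
    mask = np.array([a.GetAtomicNum() > 1 for a in ens.mol.GetAtoms()])
    ref = np.asarray(reference_coords, float)
    ref_heavy = ref[mask] if ref.shape[0] == mask.size else ref
    return ComparisonRecord(
        molecule_id=ens.molecule_id,
        n_rotatable_bonds=rotatable_bond_count(ens.mol),
        min_rmsd=min_heavy_rmsd(ens, reference_coords),
        rg_conformer=radius_of_gyration(ens.coordinates(conformer_index)[mask]),
        rg_reference=radius_of_gyration(ref_heavy),
    )


def rmsd_vs_rotors_regression(records) -> tuple[float, float]:
    """OLS best-fit (slope, intercept) of min RMSD on rotatable-bond count."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two records")
    x = np.array([r.n_rotatable_bonds for r in records], float)
    y = np.array([r.min_rmsd for r in records], float)
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate design: all rotor counts equal")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def rmsd_summary(records, thresholds=(0.2, 0.5, 1.0)) -> dict:
    """Median/mean min-RMSD and the fraction of molecules within each threshold."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    r = np.array([rec.min_rmsd for rec in records], float)
    out = {"median": float(np.median(r)), "mean": float(r.mean())}
    for t in thresholds:
        out[f"fraction_le_{t}"] = float((r <= t).mean())
    return out
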