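"""Hierarchical torsion SMARTS library: loading, classification, and matching.

A torsion pattern is a SMARTS query with four mapped atoms ``[..:1][..:2][..:3][..:4]``
defining a dihedral; the central bond is 2-3.  Patterns are organised as a
specificity hierarchy: within each kind (``acyclic`` / ``ring``), file order is
priority order, and for every central bond matched by at least one pattern a
single observation is emitted for the highest-priority match.  This per-bond
assignment mirrors how ETKDG attaches one torsion preference per rotatable
bond and keeps histograms free of multiplicity inflation.

Angles are stored in degrees on [0, 360) throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem

__all__ = [
    "TorsionPattern",
    "TorsionObservation",
    "load_pattern_library",
    "classify_central_bond",
    "match_torsions",
    "measure_dihedral",
]

_BUNDLED = "torsion_smarts_synthetic_v1.json"
_BUNDLED_COUNTS = {"acyclic": 387, "ring": 105}

# Central-bond labels distinguished in the library taxonomy; any other element
# pair maps to "other".  Pairs are unordered.
_BOND_LABELS = {
    frozenset({"C"}): "C-C",
    frozenset({"C", "O"}): "C-O",
    frozenset({"C", "S"}): "C-S",
    frozenset({"N", "C"}): "N-C",
    frozenset({"N", "S"}): "N-S",
    frozenset({"S"}): "S-S",
}


@dataclass(frozen=True)
class TorsionPattern:
    """One SMARTS rule of the torsion hierarchy.

    Parameters
    ----------
    id : int
        Index in file order across the whole library.
    smarts : str
        SMARTS with atom maps 1-4 marking the dihedral quadruple.
    kind : {"acyclic", "ring"}
    central_bond : str
        Unordered element-pair label of the two central atoms
        ("C-C", "C-O", "C-S", "N-C", "N-S", "S-S" or "other").
    rank : int
        Priority within ``kind`` (position in file order; lower wins).
    name : str
        Optional human-readable tag.
    """

    id: int
    smarts: str
    kind: str
    central_bond: str
    rank: int
    name: str = ""

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:  # pragma: no cover - guarded at load
            raise ValueError(f"unparsable SMARTS: {self.smarts}")
        return q


@dataclass(frozen=True)
class TorsionObservation:
    """A matched dihedral quadruple measured on one conformer."""

    molecule_id: str
    conformer_id: str
    pattern_id: int
    atoms: tuple[int, int, int, int]
    angle: float  # degrees in [0, 360)


def _mapped_quadruple(query: Chem.Mol) -> tuple[int, int, int, int]:
    """Query-atom indices of map numbers 1..4, in map order."""
    by_map = {a.GetAtomMapNum(): a.GetIdx() for a in query.GetAtoms() if a.GetAtomMapNum()}
    if sorted(by_map) != [1, 2, 3, 4]:
        raise ValueError("pattern must carry exactly four mapped atoms 1-4")
    return by_map[1], by_map[2], by_map[3], by_map[4]


def classify_central_bond(pattern: TorsionPattern) -> str:
    """Label the unordered element pair of the two central mapped atoms."""
    q = pattern.query()
    _, i2, i3, _ = _mapped_quadruple(q)
    e2 = q.GetAtomWithIdx(i2).GetSymbol().capitalize()
    e3 = q.GetAtomWithIdx(i3).GetSymbol().capitalize()
    return _BOND_LABELS.get(frozenset({e2, e3}), "other")


def load_pattern_library(path=None) -> list[TorsionPattern]:
    """Load a torsion SMARTS library from a JSON file.

    With ``path=None`` the bundled library is loaded and its published size
    (387 acyclic, 105 ring) is asserted.  Records appear in file order;
    ``rank`` is the position within each kind.

    Raises
    ------
    ValueError
        On an empty library, an unparsable SMARTS (the offending record is
        named), or a record without four mapped atoms.
    """
    if path is None:
        text = resources.files("qtdg.data").joinpath(_BUNDLED).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    records = doc["patterns"] if isinstance(doc, dict) else doc
    if not records:
        raise ValueError("empty pattern library")

    patterns: list[TorsionPattern] = []
    rank_within = {"acyclic": 0, "ring": 0}
    for i, rec in enumerate(records):
        smarts = rec["smarts"]
        kind = rec["kind"]
        if kind not in rank_within:
            raise ValueError(f"record {i}: unknown kind {kind!r}")
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            raise ValueError(f"record {i}: unparsable SMARTS {smarts!r}")
        probe = TorsionPattern(
            id=i, smarts=smarts, kind=kind, central_bond="", rank=rank_within[kind],
            name=rec.get("name", ""),
        )
        _mapped_quadruple(q)  # validates the four maps
        patterns.append(
            TorsionPattern(
                id=i, smarts=smarts, kind=kind,
                central_bond=classify_central_bond(probe),
                rank=rank_within[kind], name=rec.get("name", ""),
            )
        )
        rank_within[kind] += 1

    if path is None:
        counts = {k: sum(p.kind == k for p in patterns) for k in _BUNDLED_COUNTS}
        if counts != _BUNDLED_COUNTS:
            raise ValueError(f"bundled library size mismatch: {counts}")
    return patterns


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral of four points, mapped to degrees in [0, 360).

    Uses the atan2 convention: with b1=p2-p1, b2=p3-p2, b3=p4-p3 and plane
    normals n1=b1xb2, n2=b2xb3, the angle is atan2(((n1xn2)·b2hat), n1·n2).
    Under this sign convention (0,1,0),(0,0,0),(1,0,0),(1,0,1) measures 90
    degrees.  Negative angles are wrapped by adding 360.

    Raises
    ------
    ValueError
        If either bonded vector pair is collinear (dihedral undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0 or np.linalg.norm(n1) < 1e-10 * nb2 * np.linalg.norm(b1) \
            or np.linalg.norm(n2) < 1e-10 * nb2 * np.linalg.norm(b3):
        raise ValueError("collinear points: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    ang = np.degrees(np.arctan2(y, x))
    return float(ang % 360.0)


def match_torsions(
    mol: Chem.Mol,
    library: list[TorsionPattern],
    molecule_id: str = "",
    conf_id: int = -1,
) -> list[TorsionObservation]:
    """Match the pattern hierarchy against one conformer.

    For every central bond with at least one matching pattern of the
    appropriate kind (ring patterns for ring bonds, acyclic otherwise),
    exactly one observation is produced: the lowest-rank matching pattern
    wins, and among that pattern's matches on the bond the lexicographically
    smallest atom-index quadruple is the representative.

    Raises
    ------
    ValueError
        If the molecule has no conformer.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D coordinates")
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()

    # bond key -> (rank, quadruple, pattern_id); unordered central pair
    best: dict[frozenset, tuple[int, tuple, int]] = {}
    for pat in sorted(library, key=lambda p: (p.kind, p.rank)):
        q = pat.query()
        m1, m2, m3, m4 = _mapped_quadruple(q)
        for match in mol.GetSubstructMatches(q, uniquify=False):
            quad = (match[m1], match[m2], match[m3], match[m4])
            bond = mol.GetBondBetweenAtoms(quad[1], quad[2])
            if bond is None:
                continue
            if bond.IsInRing() != (pat.kind == "ring"):
                continue
            key = frozenset((quad[1], quad[2]))
            incumbent = best.get(key)
            cand = (pat.rank, quad, pat.id)
            if incumbent is None or cand < incumbent:
                best[key] = cand

    obs = []
    for rank, quad, pid in sorted(best.values(), key=lambda t: t[1]):
        ang = measure_dihedral(pos[quad[0]], pos[quad[1]], pos[quad[2]], pos[quad[3]])
        obs.append(
            TorsionObservation(
                molecule_id=molecule_id,
                conformer_id=str(conf.GetId()),
                pattern_id=pid,
                atoms=quad,
                angle=ang,
            )
        )
    return obs
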