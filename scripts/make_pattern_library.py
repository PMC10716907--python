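"""Generate the bundled synthetic torsion-SMARTS hierarchy fixture.

The library mirrors the size and central-bond composition of the hierarchical
ETKDG-style dihedral pattern set (387 acyclic + 105 ring patterns; acyclic
central bonds: C-C 168, C-O 56, C-S 16, N-C 131, N-S 4, S-S 1, remainder
"other").  The individual SMARTS are synthetic stand-ins: systematically
enumerated, chemically plausible four-atom dihedral queries, most specific
first within each kind.  Every pattern is validated with RDKit before writing.

Usage:  python scripts/make_pattern_library.py
Writes: src/qtdg/data/torsion_smarts_synthetic_v1.json
"""

from __future__ import annotations

import itertools
import json
import pathlib

from rdkit import Chem

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "qtdg" / "data" / "torsion_smarts_synthetic_v1.json"

# Outer-atom environments, roughly most specific first so that file order is a
# usable specificity hierarchy.
OUTER = [
    "CX4H3", "CX4H2", "CX4", "CX3", "c", "NX3", "NX2", "n", "OX2", "o",
    "SX2", "F", "Cl", "Br", "I", "#15", "#6",
]

ACYCLIC_CENTRALS = {
    "C-C": (168, [("CX4", "CX4"), ("CX4", "CX3"), ("CX3", "CX3")]),
    "C-O": (56, [("CX4", "OX2"), ("CX3", "OX2")]),
    "C-S": (16, [("CX4", "SX2"), ("CX3", "SX2")]),
    "N-C": (131, [("NX3", "CX4"), ("NX3", "CX3"), ("NX2", "CX3")]),
    "N-S": (4, [("NX3", "SX2")]),
    "S-S": (1, [("SX2", "SX2")]),
    "other": (11, [("OX2", "OX2"), ("OX2", "SX2"), ("#15", "CX4")]),
}

RING_CENTRALS = [
    ("C", "C"), ("c", "c"), ("C", "N"), ("C", "O"), ("C", "S"), ("c", "n"),
]
N_RING = 105


def _validate(smarts: str) -> None:
    q = Chem.MolFromSmarts(smarts)
    assert q is not None, smarts
    maps = sorted(a.GetAtomMapNum() for a in q.GetAtoms() if a.GetAtomMapNum())
    assert maps == [1, 2, 3, 4], smarts


def acyclic_patterns():
    out = []
    for label, (count, centrals) in ACYCLIC_CENTRALS.items():
        made = 0
        pairs = itertools.cycle(centrals)
        outer_iter = itertools.product(OUTER, OUTER)
        for (o1, o4), (c2, c3) in zip(outer_iter, pairs):
            if made >= count:
                break
            s = f"[{o1}:1][{c2}:2]-!@[{c3}:3][{o4}:4]"
            _validate(s)
            out.append({"smarts": s, "kind": "acyclic", "name": f"acyclic_{label}_{made}"})
            made += 1
        assert made == count, (label, made)
    return out


def ring_patterns():
    out = []
    outer_iter = itertools.product(OUTER, OUTER)
    centrals = itertools.cycle(RING_CENTRALS)
    for (o1, o4), (c2, c3) in zip(outer_iter, centrals):
        if len(out) >= N_RING:
            break
        s = f"[{o1}:1][{c2};R:2]@[{c3};R:3][{o4}:4]"
        _validate(s)
        out.append({"smarts": s, "kind": "ring", "name": f"ring_{len(out)}"})
    return out


def main():
    patterns = acyclic_patterns() + ring_patterns()
    smarts = [p["smarts"] for p in patterns]
    assert len(set(smarts)) == len(smarts), "duplicate SMARTS"
    doc = {
        "version": "synthetic-v1",
        "description": (
            "Synthetic stand-in torsion SMARTS hierarchy matching the size and "
            "central-bond composition of the ETKDG-style dihedral pattern set "
            "(387 acyclic + 105 ring). Generated by scripts/make_pattern_library.py."
        ),
        "patterns": patterns,
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(doc, indent=1))
    print(f"wrote {len(patterns)} patterns to {OUT}")


if __name__ == "__main__":
    main()
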