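"""Named whole-molecule feature counts used by count-rule fingerprint bits.

Dictionary bits of kind ``feature_count_at_least`` reference these features by
name (e.g. ``element:N``, ``ring_size:6``, ``aromatic_ring``) instead of a
SMARTS pattern; the bit fires when the count meets the bit's threshold.  This
covers the sections of substructure-key systems that are defined as counts
(element tallies, ring census, hydrogen counts) rather than as patterns.
"""

from __future__ import annotations

from rdkit import Chem


class FeatureError(ValueError):
    """Unknown feature name."""


def _ring_bonds(mol: Chem.Mol, ring: tuple[int, ...]) -> list[Chem.Bond]:
    bonds = []
    n = len(ring)
    for i in range(n):
        bonds.append(mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % n]))
    return bonds


def count_feature(mol: Chem.Mol, name: str) -> int:
    """Count a named molecular feature on an RDKit molecule.

    Supported names: ``H`` (total hydrogens, implicit + explicit),
    ``element:<symbol>`` (heavy-atom tally; ``element:H`` = total hydrogens),
    ``heavy_atom``, ``ring_any``, ``ring_size:<k>``, ``aromatic_ring``,
    ``hetero_ring``, ``carbocycle``, ``saturated_ring``, ``fragment``,
    ``isotope``.  Ring features use the SSSR ring census.
    """
    if name == "H" or name == "element:H":
        return sum(a.GetTotalNumHs() for a in mol.GetAtoms()) + sum(
            1 for a in mol.GetAtoms() if a.GetAtomicNum() == 1
        )
    if name.startswith("element:"):
        symbol = name.split(":", 1)[1]
        if Chem.GetPeriodicTable().GetAtomicNumber(symbol) == 0 and symbol != "*":
            raise FeatureError(f"unknown element symbol in feature {name!r}")
        return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol)
    if name == "heavy_atom":
        return mol.GetNumHeavyAtoms()
    if name == "fragment":
        return len(Chem.GetMolFrags(mol))
    if name == "isotope":
        return sum(1 for a in mol.GetAtoms() if a.GetIsotope() != 0)

    ri = mol.GetRingInfo()
    rings = ri.AtomRings()
    if name == "ring_any":
        return len(rings)
    if name.startswith("ring_size:"):
        k = int(name.split(":", 1)[1])
        return sum(1 for r in rings if len(r) == k)
    if name == "aromatic_ring":
        return sum(1 for r in rings if all(b.GetIsAromatic() for b in _ring_bonds(mol, r)))
    if name == "hetero_ring":
        return sum(
            1 for r in rings if any(mol.GetAtomWithIdx(i).GetAtomicNum() != 6 for i in r)
        )
    if name == "carbocycle":
        return sum(
            1 for r in rings if all(mol.GetAtomWithIdx(i).GetAtomicNum() == 6 for i in r)
        )
    if name == "saturated_ring":
        return sum(
            1
            for r in rings
            if all(
                b.GetBondType() == Chem.BondType.SINGLE and not b.GetIsAromatic()
                for b in _ring_bonds(mol, r)
            )
        )
    raise FeatureError(f"unknown feature name {name!r}")


def is_known_feature(name: str) -> bool:
    try:
        probe = Chem.MolFromSmiles("C")
        count_feature(probe, name)
        return True
    except (FeatureError, ValueError):
        return False
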