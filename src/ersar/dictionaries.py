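"""Built-in fingerprint dictionary families.

Four interpretable families are shipped, with the conventional cardinalities
of the dictionary-fingerprint literature: PubChem-style (881 bits),
Substructure (307), MACCS (166) and Klekota-Roth-style (4,860).

Provenance differs by family and is stated per bit in the description column:

* ``maccs`` is genuine — built at runtime from RDKit's public MACCS key
  SMARTS table, so bits carry their standard meanings.
* ``pubchem``, ``substructure`` and ``klekota_roth`` are SYNTHETIC stand-ins:
  the authentic bit-definition lists are not redistributable here, so these
  dictionaries are generated programmatically with the correct cardinality,
  rule-kind mix (count rules for element/ring census sections, SMARTS for
  substructure sections) and overall spirit.  The ``substructure`` family
  opens with a curated block of genuine functional-group SMARTS (amides,
  amines, phenols, sulfonyls, ...) so that models built on it remain
  chemically interpretable.

Every generated SMARTS is compile-validated at build time; dictionaries are
cached per process and can be serialized/reloaded through the TSV format in
:mod:`ersar.fingerprints`.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Iterable, Iterator

from rdkit import Chem

from .fingerprints import BitDefinition, DictionaryError, FingerprintDictionary

#: Family name -> expected bit count.
BUILTIN_FAMILIES = {
    "pubchem": 881,
    "substructure": 307,
    "maccs": 166,
    "klekota_roth": 4860,
}

_ALIASES = {
    "klekota-roth": "klekota_roth",
    "klekotaroth": "klekota_roth",
    "kr": "klekota_roth",
}

#: Para-alkyl phenol (4-methylphenol-like) motif: shipped in the substructure
#: family and used as the default planted signal of the synthetic benchmark.
PARA_ALKYL_PHENOL_SMARTS = "[OX2H]c1ccc(cc1)[#6;A]"


def canonical_family(name: str) -> str:
    key = name.strip().lower().replace(" ", "_")
    key = _ALIASES.get(key, key)
    if key not in BUILTIN_FAMILIES:
        raise DictionaryError(
            f"unknown fingerprint family {name!r}; available: {sorted(BUILTIN_FAMILIES)}"
        )
    return key


# ---------------------------------------------------------------------------
# shared SMARTS pool (deterministic generator for the synthetic sections)
# ---------------------------------------------------------------------------

_CORES = (
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccsc1", "c1ccoc1", "c1cc[nH]c1",
    "c1cnc[nH]1", "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "C1CCCC1",
    "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1", "c1ccc2ncccc2c1", "c1ccc2occc2c1",
)
_DECORATIONS = (
    "", "C", "N", "O", "CC", "OC", "NC", "F", "Cl", "Br", "S", "CO", "CN",
    "CCC", "OCC", "NCC", "C(C)C", "CC(C)C", "N(C)C", "C(=O)", "C(=O)N",
    "C(=O)O", "S(=O)(=O)",
)
_CHAIN_ATOMS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "c", "n", "o", "s")


def _smarts_pool() -> Iterator[tuple[str, str]]:
    """Yield (smarts, description) pairs: decorated ring cores first, then
    atom chains of growing length.  Deterministic; duplicates removed and
    non-compiling candidates skipped by the consumer."""
    for dec, core in itertools.product(_DECORATIONS, _CORES):
        yield f"{dec}{core}", f"synthetic: {dec or 'bare'} + ring core {core}"
    for length in (2, 3, 4):
        for combo in itertools.product(_CHAIN_ATOMS, repeat=length):
            yield "".join(combo), f"synthetic: atom chain {'-'.join(combo)}"


def _take_smarts(pool: Iterator[tuple[str, str]], n: int, seen: set[str]) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    for smarts, desc in pool:
        if len(out) == n:
            break
        if smarts in seen or Chem.MolFromSmarts(smarts) is None:
            continue
        seen.add(smarts)
        out.append((smarts, desc))
    if len(out) < n:
        raise DictionaryError(f"SMARTS pool exhausted: wanted {n}, got {len(out)}")
    return out


def _finalize(name: str, raw: list[tuple[str, str, int, str]]) -> FingerprintDictionary:
    entries = [
        BitDefinition(index=i, rule_kind=kind, pattern=pattern, threshold=thr, description=desc)
        for i, (kind, pattern, thr, desc) in enumerate(raw)
    ]
    d = FingerprintDictionary(name=name, entries=entries)
    expected = BUILTIN_FAMILIES[canonical_family(name)]
    if d.n_bits != expected:
        raise DictionaryError(f"{name}: built {d.n_bits} bits, expected {expected}")
    return d


# ---------------------------------------------------------------------------
# MACCS (genuine, from RDKit's key table)
# ---------------------------------------------------------------------------

#: RDKit leaves three MACCS keys without a SMARTS ('?'); they have documented
#: meanings and are expressed here as feature-count rules.
_MACCS_SPECIALS = {
    1: ("feature_count_at_least", "isotope", 1, "isotope present"),
    125: ("feature_count_at_least", "aromatic_ring", 2, "more than one aromatic ring"),
    166: ("feature_count_at_least", "fragment", 2, "more than one fragment"),
}


def _build_maccs() -> FingerprintDictionary:
    from rdkit.Chem import MACCSkeys

    raw: list[tuple[str, str, int, str]] = []
    for key in sorted(MACCSkeys.smartsPatts):
        smarts, count = MACCSkeys.smartsPatts[key]
        if smarts == "?":
            if key not in _MACCS_SPECIALS:
                raise DictionaryError(f"MACCS key {key} has no SMARTS and no fallback rule")
            raw.append(_MACCS_SPECIALS[key])
        elif count == 0:
            raw.append(("smarts_presence", smarts, 1, f"MACCS key {key}"))
        else:
            # table semantics: bit set when matches exceed `count`
            raw.append(("smarts_count_at_least", smarts, count + 1, f"MACCS key {key} (> {count} matches)"))
    return _finalize("maccs", raw)


# ---------------------------------------------------------------------------
# PubChem-style hybrid (synthetic): element census + ring census + atom pairs
# + substructure SMARTS
# ---------------------------------------------------------------------------

_PUBCHEM_MULTI_ELEMENTS = (
    ("H", (4, 8, 16, 32)), ("Li", (1, 2)), ("B", (1, 2, 4)),
    ("C", (2, 4, 8, 16, 32)), ("N", (1, 2, 4, 8)), ("O", (1, 2, 4, 8, 16)),
    ("F", (1, 2, 4)), ("Na", (1, 2)), ("Si", (1, 2)), ("P", (1, 2, 4)),
    ("S", (1, 2, 4, 8)), ("Cl", (1, 2, 4, 8)), ("K", (1, 2)),
    ("Br", (1, 2, 4)), ("I", (1, 2, 4)),
)
_PUBCHEM_SINGLE_ELEMENTS = (
    "Be", "Mg", "Al", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni",
    "Cu", "Zn", "Ga", "Ge", "As", "Se", "Rb", "Sr", "Y", "Zr", "Nb", "Mo",
    "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn", "Sb", "Te", "Cs", "Ba",
    "La", "Ce", "Pr", "Nd", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm",
    "Yb", "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl",
    "Pb", "Bi", "Th", "U",
)
_PUBCHEM_ELEMENT_PAD = (("N", 16), ("O", 32), ("C", 64), ("S", 16), ("Cl", 16))
_N_ELEMENT_SECTION = 115
_N_RING_SECTION = 60
_N_PAIR_SECTION = 64

_PAIR_ELEMENTS = ("Li", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "As", "Se", "Br", "I")


def _element_section() -> list[tuple[str, str, int, str]]:
    rules: list[tuple[str, str, int, str]] = []
    for symbol, thresholds in _PUBCHEM_MULTI_ELEMENTS:
        for t in thresholds:
            rules.append(("feature_count_at_least", f"element:{symbol}", t, f">= {t} {symbol}"))
    for symbol in _PUBCHEM_SINGLE_ELEMENTS:
        rules.append(("feature_count_at_least", f"element:{symbol}", 1, f">= 1 {symbol}"))
    for symbol, t in _PUBCHEM_ELEMENT_PAD:
        if len(rules) == _N_ELEMENT_SECTION:
            break
        rules.append(("feature_count_at_least", f"element:{symbol}", t, f">= {t} {symbol}"))
    if len(rules) != _N_ELEMENT_SECTION:
        raise DictionaryError(f"element section has {len(rules)} rules, expected {_N_ELEMENT_SECTION}")
    return rules


def _ring_section() -> list[tuple[str, str, int, str]]:
    rules: list[tuple[str, str, int, str]] = []
    for k in range(3, 11):
        for t in range(1, 6):
            rules.append(("feature_count_at_least", f"ring_size:{k}", t, f">= {t} ring(s) of size {k}"))
    for feat in ("aromatic_ring", "hetero_ring", "saturated_ring", "ring_any"):
        for t in range(1, 6):
            rules.append(("feature_count_at_least", feat, t, f">= {t} {feat.replace('_', ' ')}(s)"))
    assert len(rules) == _N_RING_SECTION
    return rules


def _pair_section() -> list[tuple[str, str, int, str]]:
    table = Chem.GetPeriodicTable()
    rules: list[tuple[str, str, int, str]] = []
    for a, b in itertools.combinations_with_replacement(_PAIR_ELEMENTS, 2):
        if len(rules) == _N_PAIR_SECTION:
            break
        smarts = f"[#{table.GetAtomicNumber(a)}]~[#{table.GetAtomicNumber(b)}]"
        rules.append(("smarts_presence", smarts, 1, f"{a}~{b} bond"))
    assert len(rules) == _N_PAIR_SECTION
    return rules


def _build_pubchem() -> FingerprintDictionary:
    raw = _element_section() + _ring_section() + _pair_section()
    n_smarts = BUILTIN_FAMILIES["pubchem"] - len(raw)
    seen: set[str] = set()
    raw += [("smarts_presence", s, 1, d) for s, d in _take_smarts(_smarts_pool(), n_smarts, seen)]
    return _finalize("pubchem", raw)


# ---------------------------------------------------------------------------
# Substructure family (synthetic; curated functional-group head)
# ---------------------------------------------------------------------------

_FUNCTIONAL_GROUPS: tuple[tuple[str, str], ...] = (
    ("[OX2H]c1ccccc1", "phenol"),
    (PARA_ALKYL_PHENOL_SMARTS, "para-alkyl phenol (4-methylphenol-like)"),
    ("[CX3](=O)[OX2H1]", "carboxylic acid"),
    ("[CX3](=O)[OX2H0][#6]", "ester"),
    ("[CX3](=O)[NX3]", "amide"),
    ("[NX3][CX3](=[OX1])[NX3]", "urea"),
    ("[NX3][CX3](=[OX1])[OX2]", "carbamate"),
    ("[NX3][CX3]=[NX2]", "amidine/guanidine core"),
    ("[#6][CX3](=O)[#6]", "ketone"),
    ("[CX3H1](=O)[#6]", "aldehyde"),
    ("[NX3H2][CX4]", "primary aliphatic amine"),
    ("[NX3H1]([CX4])[CX4]", "secondary aliphatic amine"),
    ("[NX3]([CX4])([CX4])[CX4]", "tertiary aliphatic amine"),
    ("[NX3H2]c1ccccc1", "aniline"),
    ("[NX3;!$(N=O)]c", "arylamine nitrogen"),
    ("[CX3]=[NX2]", "imine"),
    ("[NX1]#[CX2]", "nitrile"),
    ("[$([NX3](=O)=O),$([NX3+](=O)[O-])]", "nitro group"),
    ("[OX2H][CX4]", "aliphatic hydroxyl"),
    ("[OD2]([#6])[#6]", "ether"),
    ("[OD2](c)[CX4]", "aryl alkyl ether"),
    ("COc1ccccc1", "anisole fragment"),
    ("[SX2H]", "thiol"),
    ("[SX2]([#6])[#6]", "thioether"),
    ("[#16X3]=[OX1]", "sulfoxide"),
    ("[#16X4](=[OX1])=[OX1]", "sulfone"),
    ("[SX4](=[OX1])(=[OX1])[NX3]", "sulfonamide"),
    ("[SX4](=[OX1])(=[OX1])[OX2H]", "sulfonic acid"),
    ("[SX4](=[OX1])(=[OX1])c1ccccc1", "aryl sulfonyl"),
    ("Oc1ccc(cc1)S(=O)(=O)", "sulfonyl phenol"),
    ("[PX4](=[OX1])", "phosphoryl"),
    ("C(F)(F)F", "trifluoromethyl"),
    ("[#6][F]", "C-F"),
    ("[#6][Cl]", "C-Cl"),
    ("[#6][Br]", "C-Br"),
    ("[#6][I]", "C-I"),
    ("C=C", "alkene"),
    ("C#C", "alkyne"),
    ("C=C-C=C", "conjugated diene"),
    ("[CX4H3]", "methyl"),
    ("[CX4H2][CX4H2][CX4H2][CX4H2]", "butylene chain"),
    ("CCCCCCCC", "octyl chain"),
    ("[CX4]([CX4])([CX4])[CX4]", "branched quaternary-neighbour carbon"),
    ("c1ccccc1", "benzene ring"),
    ("c1ccncc1", "pyridine ring"),
    ("c1cncnc1", "pyrimidine ring"),
    ("c1cc[nH]c1", "pyrrole ring"),
    ("c1cnc[nH]1", "imidazole ring"),
    ("c1ccoc1", "furan ring"),
    ("c1ccsc1", "thiophene ring"),
    ("c1ccc2ccccc2c1", "naphthalene"),
    ("c1ccc2[nH]ccc2c1", "indole"),
    ("c1ccc2ncccc2c1", "quinoline"),
    ("c1ccc2occc2c1", "benzofuran"),
    ("c1ccc2sccc2c1", "benzothiophene"),
    ("c1ccc(cc1)-c1ccccc1", "biphenyl"),
    ("c1ccc(cc1)C=C", "styrene fragment"),
    ("[cX3](:[cX3]):[cX3]", "aromatic CCC path"),
    ("[nX2]", "basic aromatic nitrogen"),
    ("[nX3H]", "pyrrole-type NH"),
    ("[oX2]", "aromatic oxygen"),
    ("[sX2]", "aromatic sulfur"),
    ("NC(=O)c1ccccc1", "benzamide fragment"),
    ("OC(=O)c1ccccc1", "benzoic acid fragment"),
    ("O=C1CCCCC1", "cyclohexanone"),
    ("C1CCNCC1", "piperidine ring"),
    ("C1CCOCC1", "tetrahydropyran ring"),
    ("C1CNCCN1", "piperazine ring"),
    ("C1CCNC1", "pyrrolidine ring"),
    ("O1CCOCC1", "dioxane ring"),
    ("[OX2H]c1ccc2ccccc2c1", "naphthol"),
    ("Oc1ccc(O)cc1", "hydroquinone"),
    ("Oc1ccccc1O", "catechol"),
    ("N(C)C", "dimethylamino"),
    ("CCN(CC)", "diethylamino"),
    ("NCCN", "ethylenediamine fragment"),
    ("OCCO", "glycol fragment"),
    ("OCCN", "aminoethanol fragment"),
    ("C=O", "carbonyl"),
    ("[CX3](=[OX1])([#6])[#7]", "C-acyl amide"),
)


def _build_substructure() -> FingerprintDictionary:
    raw: list[tuple[str, str, int, str]] = []
    seen: set[str] = set()
    for smarts, desc in _FUNCTIONAL_GROUPS:
        if Chem.MolFromSmarts(smarts) is None:
            raise DictionaryError(f"curated functional group does not compile: {smarts!r}")
        if smarts in seen:
            raise DictionaryError(f"duplicate curated functional group: {smarts!r}")
        seen.add(smarts)
        raw.append(("smarts_presence", smarts, 1, desc))
    n_pad = BUILTIN_FAMILIES["substructure"] - len(raw)
    raw += [("smarts_presence", s, 1, d) for s, d in _take_smarts(_smarts_pool(), n_pad, seen)]
    return _finalize("substructure", raw)


# ---------------------------------------------------------------------------
# Klekota-Roth-style family (synthetic)
# ---------------------------------------------------------------------------

def _build_klekota_roth() -> FingerprintDictionary:
    seen: set[str] = set()
    raw = [
        ("smarts_presence", s, 1, d)
        for s, d in _take_smarts(_smarts_pool(), BUILTIN_FAMILIES["klekota_roth"], seen)
    ]
    return _finalize("klekota_roth", raw)


_BUILDERS = {
    "maccs": _build_maccs,
    "pubchem": _build_pubchem,
    "substructure": _build_substructure,
    "klekota_roth": _build_klekota_roth,
}


@lru_cache(maxsize=None)
def builtin_dictionary(name: str) -> FingerprintDictionary:
    """Return a cached built-in family by (case/alias-insensitive) name."""
    return _BUILDERS[canonical_family(name)]()
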