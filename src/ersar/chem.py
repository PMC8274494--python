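"""Structure parsing, standardization and activity-table I/O.

Every downstream stage (curation, fingerprints, property profiles, the
predictor) consumes the standardized molecules and activity records produced
here.  Standardization follows the conventional QSAR preprocessing recipe:
strip salts and solvents down to the largest organic fragment, canonicalize
the tautomer with one fixed rule set, and emit canonical SMILES so that a
compound's representation is independent of how it was drawn.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

# RDKit writes parse failures to the C++ log; errors surface as exceptions here.
RDLogger.DisableLog("rdApp.*")

#: Tautomer canon in use; recorded in model artifacts so prediction-time
#: featurization provably replays the training-time rules.
TAUTOMER_RULESET = "rdkit-MolStandardize-default"

#: Required activity-table columns (ChEMBL-export-like).
REQUIRED_COLUMNS = (
    "compound_id",
    "smiles",
    "standard_type",
    "standard_value",
    "standard_units",
)

#: Recognized concentration units, normalized spelling.
UNIT_TO_MOLAR = {"nM": 1e-9, "µM": 1e-6, "M": 1.0}
_UNIT_ALIASES = {
    "nm": "nM",
    "um": "µM",
    "µm": "µM",
    "μm": "µM",
    "m": "M",
}


class ChemError(ValueError):
    """Base class for structure/table handling failures."""


class ParseError(ChemError):
    """SMILES text could not be parsed."""


class StandardizationError(ChemError):
    """Molecule vanished or broke during salt stripping / tautomer canon."""


class SchemaError(ChemError):
    """Activity table is missing a required column."""


@dataclass(frozen=True)
class Molecule:
    """A standardized structure.

    ``atom_count`` counts heavy (hydrogen-suppressed) atoms of the
    standardized parent; ``fragment_count_input`` counts fragments in the raw
    input, before salt stripping (the standardized molecule always has one).
    """

    id: str
    smiles_input: str
    smiles_canonical: str
    atom_count: int
    fragment_count_input: int

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles_canonical)
        if mol is None:  # pragma: no cover - canonical SMILES always parse
            raise ParseError(f"stored canonical SMILES failed to parse: {self.smiles_canonical!r}")
        return mol


@dataclass
class ActivityRecord:
    """One compound-assay measurement.

    ``pic50`` / ``label`` start unset and are filled in by curation.
    """

    compound_id: str
    smiles: str
    activity_type: str
    value: float
    units: str
    pic50: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.value > 0) or not math.isfinite(self.value):
            raise ChemError(f"{self.compound_id}: activity value must be a positive finite number, got {self.value!r}")
        self.units = normalize_units(self.units)


@dataclass
class ActivityTable:
    """Parsed activity table plus a per-reason drop report."""

    records: list[ActivityRecord]
    n_rows: int
    n_dropped: int
    drop_reasons: Counter = field(default_factory=Counter)


def normalize_units(units: str) -> str:
    """Normalize unit spelling; raise on anything unrecognized."""
    key = str(units).strip()
    if key in UNIT_TO_MOLAR:
        return key
    norm = _UNIT_ALIASES.get(key.lower())
    if norm is None:
        raise ChemError(f"unrecognized concentration units {units!r} (expected nM, µM or M)")
    return norm


def _syntax_error_position(smiles: str) -> tuple[int, str] | None:
    """Best-effort localization of a SMILES syntax error.

    RDKit reports failures without a usable position, so a lightweight scan
    pinpoints the common cases: unbalanced brackets/parentheses and unclosed
    ring-bond digits.
    """
    paren: list[int] = []
    bracket: Optional[int] = None
    ring_open: dict[str, int] = {}
    i = 0
    while i < len(smiles):
        ch = smiles[i]
        if bracket is not None:
            if ch == "]":
                bracket = None
            i += 1
            continue
        if ch == "[":
            bracket = i
        elif ch == "]":
            return i, "unmatched ']'"
        elif ch == "(":
            paren.append(i)
        elif ch == ")":
            if not paren:
                return i, "unmatched ')'"
            paren.pop()
        elif ch.isdigit():
            ring_open.pop(ch, None) if ch in ring_open else ring_open.setdefault(ch, i)
        elif ch == "%" and i + 2 < len(smiles):
            num = smiles[i + 1 : i + 3]
            ring_open.pop(num, None) if num in ring_open else ring_open.setdefault(num, i)
            i += 2
        i += 1
    if bracket is not None:
        return bracket, "unclosed '['"
    if paren:
        return paren[0], "unclosed '('"
    if ring_open:
        pos = min(ring_open.values())
        return pos, "unclosed ring bond"
    return None


def _largest_organic_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, int]:
    """Salt stripping: keep the fragment with the most heavy atoms.

    Fragments containing carbon outrank carbon-free ones; ties break by
    molecular weight, then by lexicographically smallest canonical SMILES, so
    the choice is a pure function of the structure.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if not frags:
        raise StandardizationError("molecule has no fragments")
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    pool = organic if organic else list(frags)

    def sort_key(f: Chem.Mol):
        return (-f.GetNumAtoms(), -Descriptors.MolWt(f), Chem.MolToSmiles(f))

    chosen = sorted(pool, key=sort_key)[0]
    if chosen.GetNumAtoms() == 0:
        raise StandardizationError("empty fragment after salt stripping")
    return chosen, len(frags)


_tautomer_enumerator: Optional[rdMolStandardize.TautomerEnumerator] = None


def _get_tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    global _tautomer_enumerator
    if _tautomer_enumerator is None:
        _tautomer_enumerator = rdMolStandardize.TautomerEnumerator()
    return _tautomer_enumerator


def parse_and_standardize(smiles: str, mol_id: Optional[str] = None) -> Molecule:
    """Parse SMILES and standardize to a single canonical-tautomer parent.

    Steps: parse -> largest organic fragment -> functional-group cleanup ->
    charge neutralization -> tautomer canonicalization (one fixed rule set,
    :data:`TAUTOMER_RULESET`) -> canonical SMILES.  Stereochemistry is preserved in the canonical form
    (the shipped fingerprint dictionaries are constitution-only and ignore it).

    Raises :class:`ParseError` for invalid notation and
    :class:`StandardizationError` when nothing survives salt stripping.
    """
    text = (smiles or "").strip()
    if not text:
        raise ParseError("empty SMILES")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        located = _syntax_error_position(text)
        if located is not None:
            pos, why = located
            raise ParseError(f"cannot parse SMILES {text!r}: {why} at position {pos}")
        raise ParseError(f"cannot parse SMILES {text!r}")
    parent, n_frags = _largest_organic_fragment(mol)
    parent = rdMolStandardize.Cleanup(parent)
    if parent is None or parent.GetNumAtoms() == 0:
        raise StandardizationError(f"{text!r}: empty after standardization")
    parent = rdMolStandardize.Uncharger().uncharge(parent)
    parent = _get_tautomer_enumerator().Canonicalize(parent)
    canonical = Chem.MolToSmiles(parent)
    if not canonical:
        raise StandardizationError(f"{text!r}: could not emit canonical SMILES")
    return Molecule(
        id=mol_id if mol_id is not None else canonical,
        smiles_input=smiles,
        smiles_canonical=canonical,
        atom_count=parent.GetNumAtoms(),
        fragment_count_input=n_frags,
    )


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_activity_table(path: str | Path) -> ActivityTable:
    """Read a delimited activity table into :class:`ActivityRecord` rows.

    Rows with missing SMILES, non-positive/non-numeric values, or
    unrecognized units are dropped and tallied per reason in the returned
    report; a missing required column raises :class:`SchemaError`.
    """
    path = Path(path)
    df = _read_delimited(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    records: list[ActivityRecord] = []
    reasons: Counter = Counter()
    for row in df.itertuples(index=False):
        smiles = getattr(row, "smiles").strip()
        raw_value = getattr(row, "standard_value").strip()
        units = getattr(row, "standard_units").strip()
        if not smiles:
            reasons["missing_smiles"] += 1
            continue
        if not raw_value:
            reasons["missing_value"] += 1
            continue
        if not units:
            reasons["missing_units"] += 1
            continue
        try:
            value = float(raw_value)
        except ValueError:
            reasons["non_numeric_value"] += 1
            continue
        try:
            records.append(
                ActivityRecord(
                    compound_id=getattr(row, "compound_id").strip(),
                    smiles=smiles,
                    activity_type=getattr(row, "standard_type").strip(),
                    value=value,
                    units=units,
                )
            )
        except ChemError:
            reasons["invalid_value_or_units"] += 1
    return ActivityTable(
        records=records,
        n_rows=len(df),
        n_dropped=int(sum(reasons.values())),
        drop_reasons=reasons,
    )


def write_activity_table(records: Iterable[ActivityRecord], path: str | Path) -> None:
    """Serialize records back to the standard five-column table (+ pIC50/label if set)."""
    path = Path(path)
    rows = []
    for r in records:
        row = {
            "compound_id": r.compound_id,
            "smiles": r.smiles,
            "standard_type": r.activity_type,
            "standard_value": r.value,
            "standard_units": r.units,
        }
        if r.pic50 is not None:
            row["pic50"] = r.pic50
        if r.label is not None:
            row["label"] = r.label
        rows.append(row)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a ``.smi`` file: one ``SMILES[<ws>id]`` per line, ``#`` comments allowed.

    Returns ``(smiles, id)`` pairs; missing ids default to ``mol<lineno>``.
    """
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
        pairs.append((smiles, mol_id))
    return pairs
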