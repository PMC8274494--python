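"""Dictionary-based substructure fingerprints.

A fingerprint dictionary is an ordered list of bit definitions; each bit is
either a SMARTS pattern (presence, or presence-of-at-least-k embeddings) or a
named whole-molecule feature count with a threshold (see
:mod:`ersar.features`).  Bit order is part of the contract: the vector layout
is exactly the dictionary order, so matrices computed at training and
prediction time are directly comparable.

Matching semantics: SMARTS embedding counts are symmetry-deduplicated (unique
atom *sets*, not raw match enumerations), so the count for ``C-C`` on octane
is 7, one per bond, not 14.  Fingerprints are computed on standardized
molecules, hence invariant to the input SMILES spelling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .chem import Molecule
from .dataset import FeatureMatrix
from .features import count_feature, is_known_feature

RULE_KINDS = ("smarts_presence", "smarts_count_at_least", "feature_count_at_least")

#: Cap on substructure match enumeration; far above anything a drug-like
#: molecule produces for dictionary-sized patterns.
_MAX_MATCHES = 100_000


class DictionaryError(ValueError):
    """Malformed dictionary file or bit definition."""


@dataclass
class BitDefinition:
    index: int
    rule_kind: str
    pattern: str
    threshold: int = 1
    description: str = ""
    _query: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.rule_kind not in RULE_KINDS:
            raise DictionaryError(f"bit {self.index}: unknown rule_kind {self.rule_kind!r}")
        if self.threshold < 1:
            raise DictionaryError(f"bit {self.index}: threshold must be >= 1, got {self.threshold}")
        if self.rule_kind.startswith("smarts"):
            self._query = Chem.MolFromSmarts(self.pattern)
            if self._query is None:
                raise DictionaryError(
                    f"bit {self.index}: SMARTS pattern does not compile: {self.pattern!r}"
                )
        else:
            if not is_known_feature(self.pattern):
                raise DictionaryError(f"bit {self.index}: unknown feature name {self.pattern!r}")

    def raw_count(self, mol: Chem.Mol) -> int:
        """Symmetry-deduplicated embedding count (SMARTS) or feature count."""
        if self._query is not None:
            return len(mol.GetSubstructMatches(self._query, uniquify=True, maxMatches=_MAX_MATCHES))
        return count_feature(mol, self.pattern)

    def is_set(self, mol: Chem.Mol) -> bool:
        return self.raw_count(mol) >= self.threshold


@dataclass
class FingerprintDictionary:
    """Ordered bit definitions; indices must be 0..n-1 contiguous."""

    name: str
    entries: list[BitDefinition]

    def __post_init__(self) -> None:
        indices = [e.index for e in self.entries]
        dupes = {i for i in indices if indices.count(i) > 1} if len(set(indices)) != len(indices) else set()
        if dupes:
            raise DictionaryError(f"dictionary {self.name!r}: duplicate bit index {sorted(dupes)[0]}")
        if indices != list(range(len(self.entries))):
            raise DictionaryError(
                f"dictionary {self.name!r}: bit indices must be contiguous 0..{len(self.entries) - 1}"
            )

    @property
    def n_bits(self) -> int:
        return len(self.entries)

    def bit_names(self) -> list[str]:
        return [f"{self.name}FP{e.index}" for e in self.entries]


@dataclass
class FingerprintVector:
    dictionary_name: str
    mode: str  # presence | count
    values: np.ndarray


def load_dictionary(path: str | Path, name: str | None = None) -> FingerprintDictionary:
    """Load a dictionary from TSV (columns: index, rule_kind, pattern,
    threshold, description).  Uncompilable SMARTS or a duplicate index raise
    :class:`DictionaryError` naming the offending bit."""
    path = Path(path)
    entries: list[BitDefinition] = []
    seen: set[int] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"index", "rule_kind", "pattern", "threshold", "description"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise DictionaryError(f"{path}: dictionary TSV must have columns {sorted(required)}")
        for row in reader:
            idx = int(row["index"])
            if idx in seen:
                raise DictionaryError(f"{path}: duplicate bit index {idx}")
            seen.add(idx)
            entries.append(
                BitDefinition(
                    index=idx,
                    rule_kind=row["rule_kind"].strip(),
                    pattern=row["pattern"],
                    threshold=int(row["threshold"] or 1),
                    description=row["description"],
                )
            )
    entries.sort(key=lambda e: e.index)
    return FingerprintDictionary(name=name or path.stem, entries=entries)


def save_dictionary(dictionary: FingerprintDictionary, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["index", "rule_kind", "pattern", "threshold", "description"])
        for e in dictionary.entries:
            writer.writerow([e.index, e.rule_kind, e.pattern, e.threshold, e.description])


def _as_rdkit(mol: Molecule | Chem.Mol) -> Chem.Mol:
    return mol.to_rdkit() if isinstance(mol, Molecule) else mol


def compute_fingerprint(
    mol: Molecule | Chem.Mol,
    dictionary: FingerprintDictionary,
    mode: str = "presence",
) -> FingerprintVector:
    """Compute one fingerprint vector.

    ``presence`` mode yields 0/1 per bit (1 iff the bit's rule is satisfied).
    ``count`` mode yields the raw deduplicated count when the rule is
    satisfied and 0 otherwise, so a positive count always coincides with the
    presence bit being set and count >= presence element-wise.
    """
    if mode not in {"presence", "count"}:
        raise DictionaryError(f"unknown fingerprint mode {mode!r}")
    rdmol = _as_rdkit(mol)
    values = np.zeros(dictionary.n_bits, dtype=np.int64)
    for e in dictionary.entries:
        c = e.raw_count(rdmol)
        if c >= e.threshold:
            values[e.index] = 1 if mode == "presence" else c
    return FingerprintVector(dictionary_name=dictionary.name, mode=mode, values=values)


def compute_matrix(
    mols: Sequence[Molecule],
    dictionary: FingerprintDictionary,
    mode: str = "presence",
) -> FeatureMatrix:
    """Fingerprint a list of standardized molecules into a FeatureMatrix.

    Row order follows input order; column order follows bit order.  A failure
    on any molecule is re-raised with the row id attached.
    """
    if not mols:
        raise DictionaryError("no molecules to fingerprint")
    rows = []
    for m in mols:
        try:
            rows.append(compute_fingerprint(m, dictionary, mode).values)
        except Exception as exc:  # noqa: BLE001 - annotate row provenance
            raise DictionaryError(f"fingerprinting failed for compound {m.id!r}: {exc}") from exc
    ids = [m.id for m in mols]
    return FeatureMatrix(
        ids=ids,
        feature_names=dictionary.bit_names(),
        values=np.vstack(rows),
        provenance={"dictionary": dictionary.name, "mode": mode},
    )
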