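"""Synthetic benchmark generation with a planted, recoverable signal.

The generator emulates a curated ChEMBL-style IC50 table: every "active"
compound carries a planted substructure motif (by default a para-alkyl
phenol, a classic estrogen-receptor pharmacophore element) and draws its
pIC50 from a clearly-active distribution (mean 7.0), while "inactives" are
built on motif-free scaffolds with clearly-inactive potencies (mean 4.0).
Class means sit one log unit clear of the 6/5 labeling thresholds so that at
zero label noise the labels are unambiguous and the motif presence bit
perfectly separates the classes — which is what makes end-to-end pipeline
recovery checkable.  ``label_noise`` decouples structure from class: with
probability ``label_noise`` an active is built motif-free (and an inactive
motif-bearing), degrading the learnable signal in a controlled way.

All emitted SMILES are validated by the standardizer at generation time, so a
downstream failure always implicates the pipeline, not the fixtures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem import ActivityRecord, parse_and_standardize, write_activity_table
from .dictionaries import PARA_ALKYL_PHENOL_SMARTS
from .fingerprints import FingerprintDictionary


class BenchmarkError(ValueError):
    pass


@dataclass(frozen=True)
class BenchmarkSpec:
    n_active: int = 150
    n_inactive: int = 150
    planted_smarts: str = PARA_ALKYL_PHENOL_SMARTS
    label_noise: float = 0.0
    pic50_active_mean: float = 7.0
    pic50_active_sd: float = 0.4
    pic50_inactive_mean: float = 4.0
    pic50_inactive_sd: float = 0.4
    active_threshold: float = 6.0
    inactive_threshold: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_inactive < 1:
            raise BenchmarkError("class counts must be >= 1")
        if not (0.0 <= self.label_noise < 0.5):
            raise BenchmarkError("label_noise must be in [0, 0.5)")
        if Chem.MolFromSmarts(self.planted_smarts) is None:
            raise BenchmarkError(f"planted SMARTS does not compile: {self.planted_smarts!r}")


# Scaffold grammar.  Motif-bearing templates place a free phenolic OH para to
# the decoration point; motif-free templates carry no aromatic hydroxyl at
# all, so the planted para-alkyl-phenol SMARTS can never match them.
_MOTIF_TEMPLATES = (
    "Oc1ccc({R})cc1",
    "Oc1ccc({R})c(C)c1",
    "Oc1ccc({R})c(F)c1",
    "Oc1ccc({R})c(Cl)c1",
    "Oc1cc(C)c({R})cc1",
)
_PLAIN_TEMPLATES = (
    "c1ccc({R})cc1",
    "c1ccnc({R})c1",
    "c1ncnc({R})c1",
    "c1csc({R})c1",
    "C1CCC({R})CC1",
    "c1ccc2cc({R})ccc2c1",
    "C1CCN({R})CC1",
    "c1ccn({R})c1",
    "COc1ccc({R})cc1",
)
_TERMINALS = ("", "N", "O", "N(C)C", "OC", "C#N", "Cl", "F", "CC")


def _random_chain(rng: np.random.Generator) -> str:
    """Random aliphatic decoration starting with carbon: C{0-5 more}[branch][terminal]."""
    n = int(rng.integers(1, 7))
    chain = "C" * n
    if n >= 2 and rng.random() < 0.4:
        cut = int(rng.integers(1, n))
        chain = chain[:cut] + "(C)" + chain[cut:]
    return chain + str(rng.choice(_TERMINALS))


def _generate_structure(rng: np.random.Generator, with_motif: bool) -> str:
    template = str(rng.choice(_MOTIF_TEMPLATES if with_motif else _PLAIN_TEMPLATES))
    return template.format(R=_random_chain(rng))


def _sample_pic50(rng: np.random.Generator, mean: float, sd: float,
                  lo: float | None, hi: float | None) -> float:
    """Draw from N(mean, sd) restricted to the class's potency region."""
    for _ in range(1000):
        x = float(rng.normal(mean, sd))
        if (lo is None or x > lo) and (hi is None or x < hi):
            return x
    raise BenchmarkError("pIC50 rejection sampling failed; check mean/sd vs thresholds")


def generate_benchmark(
    spec: BenchmarkSpec,
    table_path: str | Path | None = None,
    manifest_path: str | Path | None = None,
    id_prefix: str = "CMPD",
) -> tuple[list[ActivityRecord], dict]:
    """Generate an activity table plus its truth manifest.

    Deterministic in ``spec.seed`` (fixed seed -> byte-identical files).  The
    manifest records, per compound, the planted-motif membership, true class
    and drawn pIC50; IC50 values are back-transformed to nM.
    """
    rng = np.random.default_rng(spec.seed)
    query = Chem.MolFromSmarts(spec.planted_smarts)
    records: list[ActivityRecord] = []
    manifest_compounds: dict[str, dict] = {}
    seen: set[str] = set()
    plan = [("active", i) for i in range(spec.n_active)] + [
        ("inactive", i) for i in range(spec.n_inactive)
    ]
    for k, (cls, _) in enumerate(plan):
        wants_motif = (cls == "active") != (rng.random() < spec.label_noise)
        for _ in range(200):
            smiles = _generate_structure(rng, wants_motif)
            mol = parse_and_standardize(smiles)
            has_motif = mol.to_rdkit().HasSubstructMatch(query)
            if has_motif != wants_motif:
                continue  # decoration happened to (not) form the motif
            if mol.smiles_canonical in seen:
                continue
            seen.add(mol.smiles_canonical)
            break
        else:
            raise BenchmarkError("could not generate a fresh structure; grammar exhausted")
        if cls == "active":
            pic50 = _sample_pic50(rng, spec.pic50_active_mean, spec.pic50_active_sd,
                                  lo=spec.active_threshold, hi=None)
        else:
            pic50 = _sample_pic50(rng, spec.pic50_inactive_mean, spec.pic50_inactive_sd,
                                  lo=None, hi=spec.inactive_threshold)
        ic50_nm = 10.0 ** (9.0 - pic50)
        cid = f"{id_prefix}{k:04d}"
        records.append(
            ActivityRecord(
                compound_id=cid,
                smiles=smiles,
                activity_type="IC50",
                value=round(ic50_nm, 6),
                units="nM",
            )
        )
        manifest_compounds[cid] = {
            "smiles": smiles,
            "smiles_canonical": mol.smiles_canonical,
            "has_motif": bool(has_motif),
            "true_class": cls,
            "pic50": pic50,
        }
    manifest = {
        "spec": asdict(spec),
        "planted_smarts": spec.planted_smarts,
        "compounds": manifest_compounds,
    }
    if table_path is not None:
        write_activity_table(records, table_path)
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return records, manifest


def generate_duplicates_and_salts(
    records: Sequence[ActivityRecord],
    rate: float,
    seed: int = 0,
    kinds: Sequence[str] = ("unit_swap", "salt", "jitter"),
) -> tuple[list[ActivityRecord], list[dict]]:
    """Inject replicate rows with known ground truth to exercise curation.

    For each original row, with probability ``rate`` one extra replicate is
    appended: ``unit_swap`` re-expresses the same measurement in µM,
    ``salt`` appends a counter-ion to the SMILES (same measurement),
    ``jitter`` perturbs the value by a factor of 10**±0.05, and ``conflict``
    plants a measurement in the opposite potency region (which curation must
    drop as contradictory).  Returns the perturbed table and the injection
    log; rate 0 returns the table unchanged.
    """
    if not (0.0 <= rate <= 1.0):
        raise BenchmarkError("rate must be in [0, 1]")
    unknown = set(kinds) - {"unit_swap", "salt", "jitter", "conflict"}
    if unknown:
        raise BenchmarkError(f"unknown injection kinds {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = list(records)
    log: list[dict] = []
    for rec in records:
        if rng.random() >= rate:
            continue
        kind = str(rng.choice(list(kinds)))
        if kind == "unit_swap" and rec.units == "nM":
            twin = ActivityRecord(rec.compound_id + "_dup", rec.smiles, rec.activity_type,
                                  rec.value / 1000.0, "µM")
        elif kind == "salt":
            twin = ActivityRecord(rec.compound_id + "_salt", rec.smiles + ".Cl",
                                  rec.activity_type, rec.value, rec.units)
        elif kind == "jitter":
            factor = 10.0 ** float(rng.choice([-0.05, 0.05]))
            twin = ActivityRecord(rec.compound_id + "_jit", rec.smiles, rec.activity_type,
                                  rec.value * factor, rec.units)
        elif kind == "conflict":
            pic50 = -math.log10(rec.value * 1e-9) if rec.units == "nM" else None
            target = 4.0 if (pic50 or 0.0) > 5.5 else 7.0
            twin = ActivityRecord(rec.compound_id + "_conf", rec.smiles, rec.activity_type,
                                  10.0 ** (9.0 - target), "nM")
        else:
            continue
        out.append(twin)
        log.append({"compound_id": rec.compound_id, "kind": kind})
    return out, log


def motif_bit_names(dictionary: FingerprintDictionary, planted_smarts: str) -> list[str]:
    """Names of dictionary bits whose pattern is exactly the planted SMARTS."""
    return [
        f"{dictionary.name}FP{e.index}"
        for e in dictionary.entries
        if e.rule_kind.startswith("smarts") and e.pattern == planted_smarts
    ]
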