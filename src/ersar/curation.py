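"""Bioactivity curation: IC50 -> pIC50, replicate resolution, class labels.

Potency thresholds follow the common two-sided convention: IC50 below 1 µM
(pIC50 > 6) is active, above 10 µM (pIC50 < 5) is inactive, and the band in
between is an intermediate zone that is excluded from classification so the
two classes are well separated.  Both inequalities are strict, so pIC50 of
exactly 5 or 6 falls in the intermediate zone.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable, Sequence

from .chem import ActivityRecord, ChemError, UNIT_TO_MOLAR, normalize_units, parse_and_standardize

ACTIVE = "active"
INACTIVE = "inactive"
INTERMEDIATE = "intermediate"


class CurationError(ValueError):
    """Raised for unusable curation inputs (e.g. an empty record list)."""


@dataclass(frozen=True)
class CurationConfig:
    active_threshold_pic50: float = 6.0
    inactive_threshold_pic50: float = 5.0
    duplicate_rule: str = "median"  # median | mean | drop_conflicting

    def __post_init__(self) -> None:
        if not self.active_threshold_pic50 > self.inactive_threshold_pic50:
            raise CurationError("active threshold must exceed inactive threshold")
        if self.duplicate_rule not in {"median", "mean", "drop_conflicting"}:
            raise CurationError(f"unknown duplicate_rule {self.duplicate_rule!r}")


@dataclass
class CuratedDataset:
    """Deduplicated, labeled records plus bookkeeping counts."""

    records: list[ActivityRecord]
    n_active: int
    n_inactive: int
    n_dropped_intermediate: int
    n_dropped_conflict: int

    def summary(self) -> dict:
        return {
            "n_records": len(self.records),
            "n_active": self.n_active,
            "n_inactive": self.n_inactive,
            "n_dropped_intermediate": self.n_dropped_intermediate,
            "n_dropped_conflict": self.n_dropped_conflict,
        }


def to_pic50(value: float, units: str) -> float:
    """pIC50 = -log10(IC50 in molar); e.g. 1 µM -> 6, 10 µM -> 5, 1 nM -> 9."""
    if not (value > 0) or not math.isfinite(value):
        raise CurationError(f"IC50 must be positive and finite, got {value!r}")
    molar = value * UNIT_TO_MOLAR[normalize_units(units)]
    return -math.log10(molar)


def label_activity(pic50: float, config: CurationConfig = CurationConfig()) -> str:
    """Classify a pIC50: strictly above the active cut -> active, strictly
    below the inactive cut -> inactive, otherwise intermediate."""
    if not math.isfinite(pic50):
        raise CurationError(f"pIC50 must be finite, got {pic50!r}")
    if pic50 > config.active_threshold_pic50:
        return ACTIVE
    if pic50 < config.inactive_threshold_pic50:
        return INACTIVE
    return INTERMEDIATE


def curate(
    records: Sequence[ActivityRecord],
    config: CurationConfig = CurationConfig(),
    activity_type: str | None = "IC50",
) -> CuratedDataset:
    """Standardize, deduplicate and label activity records.

    Compound identity is the standardized canonical SMILES, so salt forms and
    alternative drawings of one parent collapse to a single compound.
    Replicates are aggregated by the configured rule (median pIC50 by
    default); replicate sets whose individual labels span both the active and
    inactive regions are contradictory and dropped rather than averaged
    (averaging could fabricate an intermediate).  Aggregated compounds whose
    summary pIC50 lands in the intermediate band are dropped and counted.

    ``activity_type`` restricts the endpoint (case-insensitive); pass None to
    accept all records as-is.  Unparseable SMILES rows are skipped.
    The result is independent of input row order apart from which replicate's
    compound id names the merged record (first in input order).
    """
    if not records:
        raise CurationError("no activity records to curate")
    groups: dict[str, list[tuple[int, ActivityRecord, float]]] = defaultdict(list)
    for pos, rec in enumerate(records):
        if activity_type is not None and rec.activity_type.upper() != activity_type.upper():
            continue
        try:
            mol = parse_and_standardize(rec.smiles)
        except ChemError:
            continue
        groups[mol.smiles_canonical].append((pos, rec, to_pic50(rec.value, rec.units)))

    curated: list[tuple[int, ActivityRecord]] = []
    n_intermediate = 0
    n_conflict = 0
    seen_ids: dict[str, int] = {}
    for members in groups.values():
        members.sort(key=lambda t: t[0])
    for canonical, members in sorted(groups.items(), key=lambda kv: kv[1][0][0]):
        pics = [p for _, _, p in members]
        labels = {label_activity(p, config) for p in pics}
        if ACTIVE in labels and INACTIVE in labels:
            n_conflict += 1
            continue
        if config.duplicate_rule == "drop_conflicting" and len(labels) > 1:
            n_conflict += 1
            continue
        agg = median(pics) if config.duplicate_rule != "mean" else sum(pics) / len(pics)
        label = label_activity(agg, config)
        if label == INTERMEDIATE:
            n_intermediate += 1
            continue
        first_pos, first_rec, _ = members[0]
        cid = first_rec.compound_id
        if cid in seen_ids:  # distinct structures sharing an id stay distinguishable
            seen_ids[cid] += 1
            cid = f"{cid}__{seen_ids[first_rec.compound_id]}"
        else:
            seen_ids[cid] = 1
        merged = replace(first_rec, compound_id=cid, smiles=canonical, pic50=agg, label=label)
        curated.append((first_pos, merged))

    curated.sort(key=lambda t: t[0])
    out = [rec for _, rec in curated]
    return CuratedDataset(
        records=out,
        n_active=sum(1 for r in out if r.label == ACTIVE),
        n_inactive=sum(1 for r in out if r.label == INACTIVE),
        n_dropped_intermediate=n_intermediate,
        n_dropped_conflict=n_conflict,
    )
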