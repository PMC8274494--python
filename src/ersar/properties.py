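"""Drug-likeness descriptors and class-comparison statistics.

Implements the chemical-space analysis layer: Lipinski rule-of-five profiles
per compound, six-parameter descriptive summaries (min, Q1, median, mean, Q3,
max) per descriptor and activity class, and Mann-Whitney U comparisons
between classes.  The U test is exact (full rank-split enumeration with
mid-rank ties) for small samples and switches to the tie-corrected normal
approximation for larger ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from scipy import stats

from .chem import Molecule

#: Largest pooled sample for which the exact U distribution is enumerated.
EXACT_ENUMERATION_LIMIT = 12

#: Lipinski cutoffs: a violation is mw >= 500, logp >= 5, HBA >= 10, HBD >= 5.
RO5_CUTOFFS = {"mw": 500.0, "alogp": 5.0, "n_hba": 10, "n_hbd": 5}


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class Ro5Profile:
    """Rule-of-five descriptors with classic Lipinski counting.

    ``alogp`` is the Crippen atom-additive octanol-water partition
    coefficient (the scheme is recorded in reports as ``crippen-alogp``);
    ``n_hbd`` counts O-H/N-H hydrogens, ``n_hba`` counts N and O atoms.
    """

    mw: float
    alogp: float
    n_hbd: int
    n_hba: int

    @property
    def n_violations(self) -> int:
        return (
            int(self.mw >= RO5_CUTOFFS["mw"])
            + int(self.alogp >= RO5_CUTOFFS["alogp"])
            + int(self.n_hba >= RO5_CUTOFFS["n_hba"])
            + int(self.n_hbd >= RO5_CUTOFFS["n_hbd"])
        )


@dataclass(frozen=True)
class DescriptorSummary:
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    n: int
    sd: float  # spread accompanying the mean; standard deviation (n-1)


@dataclass(frozen=True)
class GroupComparison:
    u_statistic: float
    p_value: float
    method: str  # exact | normal_approx
    n_a: int
    n_b: int


def ro5_profile(mol: Molecule | Chem.Mol) -> Ro5Profile:
    rdmol = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    return Ro5Profile(
        mw=float(Descriptors.MolWt(rdmol)),
        alogp=float(Crippen.MolLogP(rdmol)),
        n_hbd=int(Lipinski.NHOHCount(rdmol)),
        n_hba=int(Lipinski.NOCount(rdmol)),
    )


def summarize(values: Sequence[float]) -> DescriptorSummary:
    """Six-parameter summary; quartiles use linear interpolation (the common
    box-plot default)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise StatsError("cannot summarize an empty value list")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return DescriptorSummary(
        min=float(arr.min()),
        q1=float(q1),
        median=float(med),
        mean=float(arr.mean()),
        q3=float(q3),
        max=float(arr.max()),
        n=int(arr.size),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a via mid-ranks: U_a = R_a - n_a(n_a+1)/2."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks on ties
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def _exact_p_two_sided(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating every assignment of the pooled values
    to group a (all C(n, n_a) rank splits equally likely under H0)."""
    pooled = np.concatenate([a, b])
    n = pooled.size
    n_a = a.size
    ranks = stats.rankdata(pooled)
    us = []
    offset = n_a * (n_a + 1) / 2.0
    for combo in itertools.combinations(range(n), n_a):
        us.append(ranks[list(combo)].sum() - offset)
    us = np.asarray(us)
    total = us.size
    eps = 1e-9
    lower = np.count_nonzero(us <= u_obs + eps) / total
    upper = np.count_nonzero(us >= u_obs - eps) / total
    return min(1.0, 2.0 * min(lower, upper))


def compare_groups(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Mann-Whitney U comparison of two samples.

    Exact enumeration when the pooled size is at most
    :data:`EXACT_ENUMERATION_LIMIT`; otherwise the tie-corrected,
    continuity-corrected normal approximation.  The reported U is for the
    first sample, so U(a, b) + U(b, a) = n_a * n_b.
    """
    arr_a = np.asarray(list(a), dtype=float)
    arr_b = np.asarray(list(b), dtype=float)
    if arr_a.size == 0 or arr_b.size == 0:
        raise StatsError("both groups must be non-empty")
    u = _u_statistic(arr_a, arr_b)
    if arr_a.size + arr_b.size <= EXACT_ENUMERATION_LIMIT:
        p = _exact_p_two_sided(arr_a, arr_b, u)
        method = "exact"
    else:
        res = stats.mannwhitneyu(arr_a, arr_b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal_approx"
    return GroupComparison(u_statistic=u, p_value=float(p), method=method,
                           n_a=int(arr_a.size), n_b=int(arr_b.size))


RO5_DESCRIPTORS = ("MW", "ALogP", "nHBDon", "nHBAcc")


def class_comparison_report(
    profiles: Sequence[Ro5Profile],
    labels: Sequence[str],
    positive: str = "active",
    negative: str = "inactive",
) -> pd.DataFrame:
    """Per-descriptor, per-class six-parameter summaries plus U and p.

    One row per (descriptor, class); U/p compare the positive class against
    the negative class for that descriptor.  The logP scheme in use is
    recorded in the ``alogp_scheme`` column.
    """
    if len(profiles) != len(labels):
        raise StatsError("profiles and labels length mismatch")
    columns = {
        "MW": [p.mw for p in profiles],
        "ALogP": [p.alogp for p in profiles],
        "nHBDon": [float(p.n_hbd) for p in profiles],
        "nHBAcc": [float(p.n_hba) for p in profiles],
    }
    labels = list(labels)
    rows = []
    for desc, values in columns.items():
        by_class = {
            cls: [v for v, lab in zip(values, labels) if lab == cls]
            for cls in (positive, negative)
        }
        if not by_class[positive] or not by_class[negative]:
            raise StatsError(f"both classes must be represented (descriptor {desc})")
        comp = compare_groups(by_class[positive], by_class[negative])
        for cls in (positive, negative):
            s = summarize(by_class[cls])
            rows.append(
                {
                    "descriptor": desc,
                    "group": cls,
                    "n": s.n,
                    "min": s.min,
                    "q1": s.q1,
                    "median": s.median,
                    "mean": s.mean,
                    "sd": s.sd,
                    "q3": s.q3,
                    "max": s.max,
                    "u_statistic": comp.u_statistic,
                    "p_value": comp.p_value,
                    "method": comp.method,
                    "alogp_scheme": "crippen-alogp",
                }
            )
    return pd.DataFrame(rows)
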