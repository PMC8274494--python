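"""IC50 -> pIC50 conversion, labeling thresholds, replicate resolution."""

from __future__ import annotations

import pytest
from hypothesis import given, strategies as st

from ersar.chem import ActivityRecord
from ersar.curation import (
    ACTIVE,
    INACTIVE,
    INTERMEDIATE,
    CurationConfig,
    CurationError,
    curate,
    label_activity,
    to_pic50,
)
from ersar.synth import generate_duplicates_and_salts


def rec(cid, smiles, value, units="nM"):
    return ActivityRecord(cid, smiles, "IC50", value, units)


class TestToPic50:
    @pytest.mark.parametrize(
        "value,units,expected",
        [(1, "µM", 6.0), (10, "µM", 5.0), (1, "nM", 9.0), (1, "M", 0.0)],
    )
    def test_threshold_transforms(self, value, units, expected):
        assert to_pic50(value, units) == pytest.approx(expected)

    def test_non_positive_value_is_domain_error(self):
        with pytest.raises(CurationError):
            to_pic50(0.0, "nM")

    @given(st.floats(min_value=1e-3, max_value=1e6), st.floats(min_value=1.01, max_value=100))
    def test_strictly_decreasing_in_value(self, x, factor):
        assert to_pic50(x, "µM") > to_pic50(x * factor, "µM")

    @given(st.floats(min_value=1e-3, max_value=1e6))
    def test_unit_consistency(self, x):
        assert to_pic50(x, "µM") == pytest.approx(to_pic50(1000 * x, "nM"))


class TestLabeling:
    @pytest.mark.parametrize(
        "pic50,expected",
        [
            (6.5, ACTIVE),
            (4.2, INACTIVE),
            (5.5, INTERMEDIATE),
            (6.0, INTERMEDIATE),  # strict inequality at both boundaries
            (5.0, INTERMEDIATE),
        ],
    )
    def test_thresholds(self, pic50, expected):
        assert label_activity(pic50) == expected

    def test_config_invariant(self):
        with pytest.raises(CurationError):
            CurationConfig(active_threshold_pic50=5.0, inactive_threshold_pic50=6.0)


class TestCurate:
    def test_replicates_aggregate_by_median(self):
        # pIC50 6.2 and 6.4 <-> 630.96 nM and 398.11 nM
        out = curate([rec("a", "CCO", 10 ** (9 - 6.2)), rec("a2", "OCC", 10 ** (9 - 6.4))])
        assert len(out.records) == 1
        assert out.records[0].pic50 == pytest.approx(6.3)
        assert out.records[0].label == ACTIVE

    def test_conflicting_replicates_dropped(self):
        out = curate(
            [rec("a", "CCO", 10 ** (9 - 6.5)), rec("a2", "OCC", 10 ** (9 - 4.0)),
             rec("b", "CCN", 10 ** (9 - 7.0))]
        )
        assert out.n_dropped_conflict == 1
        assert [r.label for r in out.records] == [ACTIVE]

    def test_intermediates_dropped_and_counted(self):
        out = curate(
            [rec("a", "CCO", 10 ** (9 - 7.0)), rec("b", "CCN", 10 ** (9 - 4.0)),
             rec("c", "CCC", 10 ** (9 - 5.5))]
        )
        assert len(out.records) == 2
        assert out.n_dropped_intermediate == 1
        assert out.n_active == 1 and out.n_inactive == 1

    def test_empty_input_is_error(self):
        with pytest.raises(CurationError):
            curate([])

    def test_permutation_invariance(self):
        records = [
            rec("a", "CCO", 50), rec("b", "CCN", 10 ** (9 - 4.0)),
            rec("a2", "OCC", 80), rec("c", "CCCN", 10 ** (9 - 7.0)),
        ]
        fwd = curate(records)
        rev = curate(records[::-1])
        assert {(r.smiles, round(r.pic50, 9), r.label) for r in fwd.records} == {
            (r.smiles, round(r.pic50, 9), r.label) for r in rev.records
        }

    def test_salt_form_collapses_with_parent(self):
        out = curate([rec("a", "CCN", 50), rec("a_hcl", "CCN.Cl", 50)])
        assert len(out.records) == 1
        assert out.records[0].pic50 == pytest.approx(to_pic50(50, "nM"))


class TestInjectedPerturbations:
    def test_unit_swap_pair_collapses_with_unchanged_pic50(self):
        base = [rec("a", "Oc1ccc(CC)cc1", 100.0)]
        perturbed, log = generate_duplicates_and_salts(base, rate=1.0, seed=3, kinds=["unit_swap"])
        assert log and log[0]["kind"] == "unit_swap"
        out = curate(perturbed)
        assert len(out.records) == 1
        assert out.records[0].pic50 == pytest.approx(to_pic50(100.0, "nM"))

    def test_conflict_pair_is_dropped(self):
        base = [rec("a", "Oc1ccc(CC)cc1", 10 ** (9 - 7.0))]
        perturbed, _ = generate_duplicates_and_salts(base, rate=1.0, seed=3, kinds=["conflict"])
        out_conflicted = curate(perturbed)
        assert out_conflicted.n_dropped_conflict == 1
        assert not out_conflicted.records

    def test_rate_zero_is_identity(self):
        base = [rec("a", "CCO", 100.0), rec("b", "CCN", 200.0)]
        perturbed, log = generate_duplicates_and_salts(base, rate=0.0, seed=3)
        assert perturbed == base
        assert log == []
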