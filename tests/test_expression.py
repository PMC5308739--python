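"""Replicate averaging, median normalization and the concordance screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mirnetkit as mk
from mirnetkit.config import SAMPLES
from mirnetkit.expression import NoEligibleProbesError


def matrix(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(SAMPLES)).rename_axis("mirna_id")


class TestAverageReplicates:
    def test_mean_of_two_replicates(self):
        m = pd.DataFrame(
            [[100.0, 1, 1, 1], [200.0, 1, 1, 1]],
            index=pd.Index(["miR-a", "miR-a"], name="mirna_id"),
            columns=list(SAMPLES),
        )
        out = mk.average_replicates(m)
        assert out.loc["miR-a", SAMPLES[0]] == 150.0

    def test_mean_of_three_replicates(self):
        m = pd.DataFrame(
            [[30.0, 1, 1, 1]] * 2 + [[90.0, 1, 1, 1]],
            index=pd.Index(["miR-a"] * 3, name="mirna_id"),
            columns=list(SAMPLES),
        )
        assert mk.average_replicates(m).loc["miR-a", SAMPLES[0]] == 50.0

    def test_identity_without_duplicates(self):
        m = matrix({"miR-a": [1, 2, 3, 4], "miR-b": [5, 6, 7, 8]})
        pd.testing.assert_frame_equal(mk.average_replicates(m), m.astype(float))

    def test_empty_input_passes_through(self):
        m = pd.DataFrame(columns=list(SAMPLES)).rename_axis("mirna_id")
        assert mk.average_replicates(m).empty


class TestNormalization:
    def test_identical_samples_equal_factors(self):
        m = matrix({"a": [100] * 4, "b": [40] * 4, "c": [75] * 4})
        factors = mk.normalization_factors(m)
        assert factors.nunique() == 1

    def test_factor_scales_linearly_with_sample(self):
        base = np.array([50.0, 100.0, 200.0])
        m = matrix({k: [v, 2 * v, v, v] for k, v in zip("abc", base)})
        factors = mk.normalization_factors(m)
        assert factors[SAMPLES[1]] == pytest.approx(2 * factors[SAMPLES[0]])

    def test_subfloor_probe_excluded_from_eligibility(self):
        m = matrix({"low": [25, 1000, 1000, 1000], "hi": [100] * 4, "hi2": [200] * 4})
        factors = mk.normalization_factors(m)
        # median over {hi, hi2} only: (100+200)/2 in every sample
        assert factors[SAMPLES[0]] == 150.0

    def test_no_eligible_probes_raises(self):
        m = matrix({"a": [5, 5, 5, 5]})
        with pytest.raises(NoEligibleProbesError):
            mk.normalization_factors(m)

    def test_normalize_equalizes_eligible_medians(self, bundle):
        averaged = mk.average_replicates(bundle.raw)
        normalized = mk.median_normalize(averaged)
        eligible = (averaged >= mk.ELIGIBILITY_FLOOR).all(axis=1)
        medians = normalized.loc[eligible].median(axis=0)
        assert np.allclose(medians, medians.iloc[0], rtol=1e-9)

    def test_idempotent_on_normalized_matrix(self):
        m = matrix({"a": [100] * 4, "b": [40] * 4, "c": [400] * 4})
        once = mk.median_normalize(m)
        twice = mk.median_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_prescaled_sample_equals_unscaled_twin(self):
        """A sample that is another sample times 3 becomes identical to it."""
        rng = np.random.default_rng(0)
        col = rng.lognormal(6, 1, size=51) + 30
        m = pd.DataFrame(
            {SAMPLES[0]: col, SAMPLES[1]: 3.0 * col, SAMPLES[2]: col, SAMPLES[3]: col}
        ).rename_axis("mirna_id")
        normalized = mk.median_normalize(m)
        np.testing.assert_allclose(
            normalized[SAMPLES[1]], normalized[SAMPLES[0]], rtol=1e-12
        )


class TestFoldChanges:
    def test_unchanged_is_none(self):
        m = matrix({"a": [50, 50, 80, 80]})
        fc = mk.fold_changes(m, "PANC-1")
        assert fc.loc[0, "fold_change"] == 1.0 and fc.loc[0, "direction"] == "none"

    def test_doubling_is_up(self):
        m = matrix({"a": [60, 30, 1, 1]})
        fc = mk.fold_changes(m, "PANC-1")
        assert fc.loc[0, "fold_change"] == 2.0 and fc.loc[0, "direction"] == "up"

    def test_threshold_is_inclusive_both_sides(self):
        m = matrix({"a": [45, 30, 1, 1], "b": [30, 45, 1, 1]})
        fc = mk.fold_changes(m, "PANC-1").set_index("mirna_id")
        assert fc.loc["a", "direction"] == "up"
        assert fc.loc["b", "direction"] == "down"

    def test_zero_control_flagged_undefined(self):
        m = matrix({"a": [60, 0, 1, 1], "b": [60, 30, 1, 1]})
        fc = mk.fold_changes(m, "PANC-1").set_index("mirna_id")
        assert fc.loc["a", "direction"] == "undefined"
        assert np.isnan(fc.loc["a", "fold_change"])

    @given(
        treated=st.floats(1e-3, 1e6, allow_nan=False),
        control=st.floats(1e-3, 1e6, allow_nan=False),
    )
    def test_reciprocity(self, treated, control):
        """f(treated, control) * f(control, treated) == 1."""
        m = matrix({"a": [treated, control, 1, 1]})
        swapped = matrix({"a": [control, treated, 1, 1]})
        f = mk.fold_changes(m, "PANC-1").loc[0, "fold_change"]
        g = mk.fold_changes(swapped, "PANC-1").loc[0, "fold_change"]
        assert f * g == pytest.approx(1.0)


class TestConcordance:
    def fc(self, mapping, line):
        return pd.DataFrame(
            {
                "mirna_id": list(mapping),
                "cell_line": line,
                "fold_change": [v[0] for v in mapping.values()],
                "direction": [v[1] for v in mapping.values()],
            }
        )

    def test_up_in_both_lines_included(self):
        a = self.fc({"m1": (2.0, "up")}, "PANC-1")
        b = self.fc({"m1": (1.7, "up")}, "BxPC-3")
        out = mk.concordant_differential(a, b)
        assert list(out["mirna_id"]) == ["m1"] and out.loc[0, "direction"] == "up"

    def test_up_and_none_excluded(self):
        a = self.fc({"m1": (2.0, "up")}, "PANC-1")
        b = self.fc({"m1": (1.2, "none")}, "BxPC-3")
        assert mk.concordant_differential(a, b).empty

    def test_discordant_directions_excluded(self):
        a = self.fc({"m1": (2.0, "up")}, "PANC-1")
        b = self.fc({"m1": (0.4, "down")}, "BxPC-3")
        assert mk.concordant_differential(a, b).empty

    def test_mirna_in_one_list_only_excluded(self):
        a = self.fc({"m1": (2.0, "up"), "m2": (2.0, "up")}, "PANC-1")
        b = self.fc({"m1": (2.0, "up")}, "BxPC-3")
        assert list(mk.concordant_differential(a, b)["mirna_id"]) == ["m1"]

    def test_default_fixture_recovers_planted_truth(self, bundle):
        got = dict(zip(bundle.differential["mirna_id"], bundle.differential["direction"]))
        assert got == bundle.truth.expected_directions()


class TestScreenProperties:
    def test_rescaling_any_sample_leaves_differential_set_unchanged(self, bundle):
        for sample, c in [(SAMPLES[0], 0.5), (SAMPLES[3], 3.0)]:
            rescaled = bundle.raw.copy()
            rescaled[sample] *= c
            diff = mk.screen(rescaled, mk.CELL_LINES)
            pd.testing.assert_frame_equal(
                diff[["mirna_id", "direction"]],
                bundle.differential[["mirna_id", "direction"]],
            )

    def test_threshold_monotonicity(self, bundle):
        """The differential set at a stricter threshold is a subset."""
        normalized = mk.median_normalize(mk.average_replicates(bundle.raw))
        sets = {}
        for tau in (1.5, 1.8, 2.5):
            fc1 = mk.fold_changes(normalized, mk.CELL_LINES[0], tau=tau)
            fc2 = mk.fold_changes(normalized, mk.CELL_LINES[1], tau=tau)
            sets[tau] = set(mk.concordant_differential(fc1, fc2)["mirna_id"])
        assert sets[2.5] <= sets[1.8] <= sets[1.5]
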