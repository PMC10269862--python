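"""CFU conversion, vial filters, and phenotype statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flymgwa import assay
from flymgwa.assay import (
    FlyCfuRecord,
    colonies_to_cfu,
    dunn_posthoc,
    filter_vials,
    kruskal_wallis,
    pairwise_vs_control,
    sex_comparison,
)


class TestColoniesToCfu:
    def test_too_dense_plate_is_censored_at_128000(self):
        assert colonies_to_cfu(0, True) == 128_000
        assert colonies_to_cfu(500, True) == 128_000

    @pytest.mark.parametrize("count,expected", [(0, 0), (1, 800), (159, 127_200)])
    def test_countable_plates_scale_by_800(self, count, expected):
        assert colonies_to_cfu(count, False) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            colonies_to_cfu(-1)

    def test_record_log_cfu(self):
        record = FlyCfuRecord("AF", colony_count=0, too_dense=True)
        assert record.cfu_per_fly() == 128_000
        assert record.log_cfu() == pytest.approx(np.log2(128_001))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(0, 200), min_size=2, max_size=20))
    def test_monotone_and_bounded_by_censoring_point(self, counts):
        counts = sorted(counts)
        cfu = colonies_to_cfu(np.array(counts), np.zeros(len(counts), bool))
        assert (np.diff(cfu) >= 0).all()
        dense = colonies_to_cfu(np.array(counts), np.ones(len(counts), bool))
        assert (dense == 128_000).all()
        # censored value is the maximum attainable for countable plates
        assert (cfu[np.array(counts) <= 160] <= 128_000).all()


def _vial_frame(rows):
    base = {
        "fly": 1,
        "sex": "female",
        "colony_count": 10,
        "too_dense": False,
        "contaminated_vial": False,
    }
    return pd.DataFrame([{**base, **row} for row in rows])


class TestFilterVials:
    def test_density_boundary(self):
        df = _vial_frame(
            [
                {"strain": "A", "experiment": "E1", "vial": "V1",
                 "vial_density": 29, "unexpected_colony_count": 0},
                {"strain": "A", "experiment": "E1", "vial": "V2",
                 "vial_density": 30, "unexpected_colony_count": 0},
            ]
        )
        retained, log = filter_vials(df)
        assert list(retained["vial"]) == ["V2"]
        assert list(log["reason"]) == ["density"]

    def test_contamination_boundary(self):
        df = _vial_frame(
            [
                {"strain": "A", "experiment": "E1", "vial": "V1",
                 "vial_density": 40, "unexpected_colony_count": 5},
                {"strain": "A", "experiment": "E1", "vial": "V2",
                 "vial_density": 40, "unexpected_colony_count": 6},
            ]
        )
        retained, log = filter_vials(df)
        assert list(retained["vial"]) == ["V1"]  # exactly 5 unexpected CFU passes
        assert list(log["reason"]) == ["contamination"]

    def test_partition_into_retained_and_excluded(self, small_sim):
        *_, records = small_sim
        retained, log = filter_vials(records)
        vials_per_key = records.groupby(["strain", "experiment", "vial"]).size()
        dropped = records.merge(log[["strain", "experiment", "vial"]])
        assert len(retained) + len(dropped) == len(records)
        assert vials_per_key.size >= len(log)


class TestKruskalWallis:
    def test_hand_computed_h(self):
        # H = (12/(6*7)) * (6^2/3 + 15^2/3) - 3*7 = 3.857...
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.statistic == pytest.approx(27 / 7)
        assert res.df == 1
        # the two-group exact p: the 2 most extreme of C(6,3)=20 assignments
        assert res.p == pytest.approx(0.1)

    def test_identical_groups(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.statistic == 0.0 and res.p == 1.0

    def test_fourteen_groups_have_df_13(self, rng):
        groups = {f"g{i:02d}": rng.normal(i, 1, 10) for i in range(14)}
        assert kruskal_wallis(groups).df == 13

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1, 2]})


class TestDunnPosthoc:
    def test_all_identical_share_one_letter(self):
        table, letters = dunn_posthoc(
            {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}
        )
        assert set(letters.values()) == {"a"}

    def test_two_separated_groups_get_distinct_letters(self):
        groups = {"lo": list(range(10)), "hi": list(range(100, 110))}
        table, letters = dunn_posthoc(groups, alpha=0.05)
        assert letters["lo"] != letters["hi"]
        assert table["p_adj"].iloc[0] < 0.05

    def test_outlier_group_pattern_a_b_b(self, rng):
        groups = {
            "A": rng.normal(0, 0.5, 12),
            "B": rng.normal(10, 0.5, 12),
            "C": rng.normal(10, 0.5, 12),
        }
        _, letters = dunn_posthoc(groups)
        assert letters["B"] == letters["C"] != letters["A"]

    def test_bonferroni_adjustment_not_smaller_than_bh(self, rng):
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abcd")}
        bh, _ = dunn_posthoc(groups, adjust="bh")
        bonf, _ = dunn_posthoc(groups, adjust="bonferroni")
        assert (bonf["p_adj"].to_numpy() >= bh["p_adj"].to_numpy() - 1e-12).all()


class TestPairwiseVsControl:
    def test_identical_mutant_not_flagged(self):
        out = pairwise_vs_control(
            {"AF": [1.0, 2.0, 3.0], "mut": [1.0, 2.0, 3.0]}, "AF"
        )
        assert out.loc[0, "p"] == 1.0
        assert not out.loc[0, "significant"]

    def test_zero_cfu_mutant_flagged_lower(self, rng):
        control = rng.uniform(10, 15, 20)
        out = pairwise_vs_control({"AF": control, "mut": np.zeros(20)}, "AF")
        row = out.set_index("group").loc["mut"]
        assert row["significant"] and row["direction"] == "lower"

    def test_one_test_per_noncontrol_group(self, rng):
        groups = {f"m{i}": rng.normal(size=5) for i in range(8)}
        groups["AF"] = rng.normal(size=5)
        assert len(pairwise_vs_control(groups, "AF")) == 8

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            pairwise_vs_control({"a": [1]}, "AF")


class TestSexComparison:
    @staticmethod
    def _records(female, male, strain="S1"):
        rows = [
            {"strain": strain, "sex": "female", "log_cfu": v} for v in female
        ] + [{"strain": strain, "sex": "male", "log_cfu": v} for v in male]
        return pd.DataFrame(rows)

    def test_identical_distributions_p_one(self):
        out = sex_comparison(self._records([1, 2, 3, 4], [1, 2, 3, 4]))
        assert out.loc[0, "p"] == 1.0

    def test_disjoint_sexes_exact_p(self):
        # all females above all males, n=4 each: 2 of C(8,4)=70 assignments
        out = sex_comparison(self._records([10, 11, 12, 13], [1, 2, 3, 4]))
        assert out.loc[0, "p"] == pytest.approx(2 / 70)

    def test_missing_sex_skipped_with_warning(self):
        records = pd.DataFrame(
            [{"strain": "S1", "sex": "female", "log_cfu": 1.0}] * 3
        )
        with pytest.warns(UserWarning):
            out = sex_comparison(records)
        assert out.empty


def test_phenotype_by_strain_tracks_planted_truth(small_sim):
    config, _, _, truth, records = small_sim
    phenotype = assay.phenotype_by_strain(records)
    assert set(phenotype.index) <= set(truth.strain_means)
    # colony quantization (1 colony = 800 CFU) and censoring distort
    # absolute values, but the strain ordering must track the truth
    truth_values = np.array([truth.strain_means[s] for s in phenotype.index])
    from scipy.stats import spearmanr

    rho, _ = spearmanr(phenotype.to_numpy(), truth_values)
    assert rho > 0.8


def test_cfu_tsv_round_trip(small_sim, tmp_path):
    *_, records = small_sim
    path = tmp_path / "cfu.tsv"
    assay.write_cfu_tsv(records, path)
    back = assay.read_cfu_tsv(path)
    pd.testing.assert_frame_equal(back, records[assay.CFU_COLUMNS])
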