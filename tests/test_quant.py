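"""Protein rollup: peptide ratios, median quantities, geometric-mean combination, t-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from plexquant.errors import DataError
from plexquant.ingest import assign_uniqueness
from plexquant.quant import (
    ContrastSpec,
    combine_fold_changes,
    peptide_ratios,
    protein_pvalue,
    protein_quantity,
    quantify_contrast,
)
from conftest import make_psm_table

MS49_VS_DU49 = ContrastSpec("MSD49_vs_DUD49", "MSD49", "DUD49")


def ratios_frame(values, protein="P1"):
    return pd.DataFrame(
        {
            "protein_id": protein,
            "peptide_sequence": [f"PEP{i}" for i in range(len(values))],
            "ratio": values,
            "pool_id": "pool1",
        }
    )


class TestPeptideRatios:
    def test_simple_ratio(self):
        t = assign_uniqueness(make_psm_table([("AAAK", ["P1"], 1, 200, 100, 1)]))
        out = peptide_ratios(t, MS49_VS_DU49)
        assert out["ratio"].tolist() == [2.0]

    def test_uses_channels_from_channel_map(self):
        """MSD49 vs DUD49 must read channels 128 and 129."""
        t = assign_uniqueness(make_psm_table([("AAAK", ["P1"], 999, 300, 150, 999)]))
        out = peptide_ratios(t, MS49_VS_DU49)
        assert out["ratio"].tolist() == [300 / 150]

    def test_zero_control_channel_skipped(self):
        t = assign_uniqueness(
            make_psm_table([("AAAK", ["P1"], 1, 200, 0, 1), ("CCCK", ["P2"], 1, 50, 25, 1)])
        )
        out = peptide_ratios(t, MS49_VS_DU49)
        assert out["protein_id"].tolist() == ["P2"]

    def test_non_unique_peptides_excluded(self):
        t = assign_uniqueness(
            make_psm_table([("AAAK", ["P1", "P2"], 1, 200, 100, 1), ("CCCK", ["P2"], 1, 60, 30, 1)])
        )
        out = peptide_ratios(t, MS49_VS_DU49)
        assert out["protein_id"].tolist() == ["P2"]

    def test_requires_uniqueness_annotation(self):
        t = make_psm_table([("AAAK", ["P1"], 1, 1, 1, 1)])
        with pytest.raises(DataError, match="uniqueness"):
            peptide_ratios(t, MS49_VS_DU49)


class TestProteinQuantity:
    def test_odd_count_median(self):
        assert protein_quantity(ratios_frame([1.0, 2.0, 4.0]))["P1"] == 2.0

    def test_even_count_midpoint(self):
        assert protein_quantity(ratios_frame([1.0, 3.0]))["P1"] == 2.0

    @given(
        st.lists(st.floats(0.01, 100.0, allow_nan=False), min_size=1, max_size=25)
    )
    def test_matches_sort_and_pick_oracle(self, values):
        got = protein_quantity(ratios_frame(values))["P1"]
        s = sorted(values)
        n = len(s)
        expected = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert got == expected


class TestCombineFoldChanges:
    def test_reciprocal_pair_is_exactly_one(self):
        assert combine_fold_changes([2.0, 0.5]) == 1.0

    def test_idempotent_on_equal_values(self):
        assert combine_fold_changes([1.3, 1.3]) == pytest.approx(1.3, rel=1e-15)

    def test_two_and_eight_give_exactly_four(self):
        assert combine_fold_changes([2.0, 8.0]) == 4.0

    def test_missing_pool_undefined(self):
        assert np.isnan(combine_fold_changes([2.0, float("nan")]))


class TestProteinPvalue:
    def test_all_zero_log_ratios_give_p_one(self):
        assert protein_pvalue([0.0, 0.0, 0.0]) == 1.0

    def test_zero_variance_nonzero_mean_gives_p_zero(self):
        assert protein_pvalue([1.0, 1.0, 1.0, 1.0]) == 0.0

    def test_single_measurement_undefined(self):
        assert np.isnan(protein_pvalue([0.5]))

    def test_matches_textbook_t_distribution(self):
        """{0.8, 1.1, 0.9, 1.2}: t = mean / (sd/sqrt(4)) with df = 3."""
        x = np.array([0.8, 1.1, 0.9, 1.2])
        t = x.mean() / (x.std(ddof=1) / 2.0)
        expected = 2.0 * stats.t.sf(t, df=3)
        assert protein_pvalue(x) == pytest.approx(expected, rel=1e-12)


class TestQuantifyContrast:
    def make_two_pool_tables(self, case_scale=1.0):
        rows1 = [
            ("AAAK", ["P1"], 1, 100 * case_scale, 50, 1),
            ("CCCK", ["P1"], 1, 120 * case_scale, 40, 1),
            ("DDDK", ["P1"], 1, 90 * case_scale, 45, 1),
        ]
        rows2 = [
            ("AAAK", ["P1"], 1, 110 * case_scale, 55, 1),
            ("CCCK", ["P1"], 1, 130 * case_scale, 50, 1),
        ]
        t1 = make_psm_table(rows1, pool_id="pool1")
        t2 = make_psm_table(rows2, pool_id="pool2")
        return assign_uniqueness([t1, t2])

    def test_geomean_is_product_root_of_pool_medians(self):
        tables = self.make_two_pool_tables()
        q = quantify_contrast(tables, MS49_VS_DU49).set_index("protein_id")
        fc1, fc2 = q.loc["P1", "fc_pool1"], q.loc["P1", "fc_pool2"]
        assert fc1 == 2.0  # median of {2.0, 3.0, 2.0}
        assert q.loc["P1", "fc_geomean"] == (fc1 * fc2) ** 0.5
        assert q.loc["P1", "n_peptides"] == 5

    def test_scale_equivariance(self):
        base = quantify_contrast(self.make_two_pool_tables(), MS49_VS_DU49)
        scaled = quantify_contrast(self.make_two_pool_tables(case_scale=3.0), MS49_VS_DU49)
        assert scaled["fc_geomean"].iloc[0] == pytest.approx(
            3.0 * base["fc_geomean"].iloc[0], rel=1e-12
        )

    def test_permutation_invariance(self):
        tables = self.make_two_pool_tables()
        shuffled = [t for t in tables]
        shuffled[0] = type(tables[0])(
            df=tables[0].df.sample(frac=1.0, random_state=4).reset_index(drop=True),
            pool_id=tables[0].pool_id,
            channel_map=tables[0].channel_map,
        )
        a = quantify_contrast(tables, MS49_VS_DU49)
        b = quantify_contrast(shuffled, MS49_VS_DU49)
        pd.testing.assert_frame_equal(a, b)

    def test_antisymmetry_for_odd_counts(self):
        tables = [self.make_two_pool_tables()[0]]  # pool1 only, 3 peptides
        fwd = quantify_contrast(tables, MS49_VS_DU49)["fc_geomean"].iloc[0]
        rev = quantify_contrast(
            tables, ContrastSpec("rev", "DUD49", "MSD49")
        )["fc_geomean"].iloc[0]
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_protein_missing_in_one_pool_has_no_combined_fc(self):
        t1 = make_psm_table([("AAAK", ["P1"], 1, 100, 50, 1)], pool_id="pool1")
        t2 = make_psm_table([("CCCK", ["P2"], 1, 100, 50, 1)], pool_id="pool2")
        q = quantify_contrast(assign_uniqueness([t1, t2]), MS49_VS_DU49).set_index("protein_id")
        assert not q.loc["P1", "quantified_in_all_pools"]
        assert np.isnan(q.loc["P1", "fc_geomean"])

    def test_noise_free_recovery_equals_truth(self, prepared_noise_free):
        """With zero reporter noise the combined FC equals the spiked truth."""
        tables, _, truth = prepared_noise_free
        contrast = MS49_VS_DU49
        q = quantify_contrast(tables, contrast).set_index("protein_id")
        tfc = truth.true_fc(contrast.case_group, contrast.control_group)
        for pid, fc in tfc.items():
            assert q.loc[pid, "fc_geomean"] == pytest.approx(fc, rel=1e-12)
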