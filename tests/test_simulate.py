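"""Synthetic-data generator: determinism, noise-free exactness, structure, fixtures."""

import numpy as np
import pandas as pd
import pytest

from plexquant.concordance import fetal_loss_rate, wb_relative_expression
from plexquant.errors import ConfigError, DataError
from plexquant.ingest import assign_uniqueness, filter_psms
from plexquant.quant import ContrastSpec, quantify_contrast
from plexquant.simulate import (
    SimulationConfig,
    fixture_fetal_counts,
    generate_densitometry,
    generate_experiment,
)


def test_same_seed_gives_byte_identical_tables():
    cfg = SimulationConfig(n_proteins=50, frac_spiked=0.2, seed=7)
    t1, a1, _ = generate_experiment(cfg)
    t2, a2, _ = generate_experiment(cfg)
    for x, y in zip(t1, t2):
        assert x.df.to_csv() == y.df.to_csv()
    assert a1.protein_to_terms == a2.protein_to_terms
    assert a1.terms == a2.terms


def test_different_seed_changes_output():
    t1, _, _ = generate_experiment(SimulationConfig(n_proteins=30, seed=1))
    t2, _, _ = generate_experiment(SimulationConfig(n_proteins=30, seed=2))
    assert not t1[0].df["intensity_127"].equals(t2[0].df["intensity_127"])


def test_noise_free_null_has_unit_ratios_everywhere():
    cfg = SimulationConfig(n_proteins=40, frac_spiked=0.0, cv_reporter=0.0, seed=3)
    tables, _, _ = generate_experiment(cfg)
    for t in tables:
        cols = t.intensity_columns
        for c in cols[1:]:
            assert (t.df[c] / t.df[cols[0]] == 1.0).all()


def test_noise_free_spike_propagates_exactly_through_rollup(prepared_noise_free):
    """A protein spiked at FC 2.0 yields combined FC exactly 2.0 with no noise."""
    tables, _, truth = prepared_noise_free
    spiked = truth.spike_group[truth.spike_group != ""]
    checked = 0
    for pid, group in spiked.items():
        fc_true = truth.multipliers.loc[pid, group]
        if fc_true != 2.0:
            continue
        other = next(g for g in truth.multipliers.columns if g != group)
        quant = quantify_contrast(
            tables, ContrastSpec("probe", group, other)
        ).set_index("protein_id")
        assert quant.loc[pid, "fc_geomean"] == 2.0
        checked += 1
    assert checked >= 1


def test_shared_peptides_have_two_parents_and_are_non_unique(default_experiment):
    tables, _, truth = default_experiment
    assert truth.shared_peptides, "generator should emit shared peptides at default settings"
    for seq in truth.shared_peptides:
        assert len(truth.peptide_map[seq]) >= 2
    flagged = assign_uniqueness(list(tables))
    df = flagged[0].df.set_index("peptide_sequence")
    for seq in truth.shared_peptides:
        assert not df.loc[seq, "is_unique"]


def test_shared_fraction_close_to_requested(default_experiment):
    _, _, truth = default_experiment
    frac = len(truth.shared_peptides) / len(truth.peptide_map)
    assert frac == pytest.approx(0.10, abs=0.03)


def test_spiked_truth_is_outside_null_band(default_experiment):
    _, _, truth = default_experiment
    groups = list(truth.multipliers.columns)
    for pid in truth.proteins:
        fcs = [
            truth.true_fc(a, b)[pid]
            for a in groups
            for b in groups
            if a != b
        ]
        if truth.spiked[pid]:
            assert any(fc <= 0.70 or fc >= 1.3 for fc in fcs)
        else:
            assert all(fc == 1.0 for fc in fcs)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_proteins": 0},
        {"n_replicate_pools": 0},
        {"frac_spiked": 1.5},
        {"frac_shared_peptides": -0.1},
        {"spike_fc_range_up": (1.1, 2.0)},
        {"spike_fc_range_down": (0.5, 0.9)},
        {"spike_fc_values": (1.1,)},
        {"peptides_per_protein": (0, 3)},
        {"channel_groups": (("A", "1"), ("B", "2"))},
        {"cv_reporter": -0.5},
    ],
)
def test_degenerate_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        SimulationConfig(**kwargs)


class TestDensitometry:
    def test_noise_free_ratio_equals_true_fc(self, prepared_noise_free):
        _, _, truth = prepared_noise_free
        spiked = truth.spike_group[truth.spike_group != ""]
        pid = next(
            p for p in spiked.index if truth.multipliers.loc[p, spiked[p]] == 0.5
        )
        table = generate_densitometry(truth, [pid], noise_cv=0.0, seed=1)
        values, summary = wb_relative_expression(table)
        ref_group = values["reference_group"].iloc[0]
        means = summary.set_index("group")["mean"]
        fc = truth.multipliers.loc[pid]
        for g in means.index:
            assert means[g] == fc[g] / fc[ref_group]

    def test_unknown_protein_rejected(self, default_experiment):
        _, _, truth = default_experiment
        with pytest.raises(DataError, match="NOSUCH"):
            generate_densitometry(truth, ["NOSUCH"], seed=0)

    def test_seed_reproducibility(self, default_experiment):
        _, _, truth = default_experiment
        p = truth.proteins[0]
        a = generate_densitometry(truth, [p], noise_cv=0.1, seed=9)
        b = generate_densitometry(truth, [p], noise_cv=0.1, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_monte_carlo_fc_estimate_unbiased(self, default_experiment):
        """True FC 2.0 with 5% noise, 3 lanes: mean estimated FC within 3 SE of 2.0."""
        _, _, truth = default_experiment
        spiked = truth.spike_group[truth.spike_group != ""]
        pid = next(
            p for p in spiked.index if truth.multipliers.loc[p, spiked[p]] == 2.0
        )
        group = spiked[pid]
        ref = next(g for g in truth.multipliers.columns if g != group)
        estimates = []
        for seed in range(300):
            table = generate_densitometry(truth, [pid], noise_cv=0.05, seed=seed)
            _, summary = wb_relative_expression(table, reference_group=ref)
            means = summary.set_index("group")["mean"]
            estimates.append(means[group] / means[ref])
        est = np.asarray(estimates)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 2.0) <= 3 * se


class TestFetalCountFixture:
    def test_group_means_match_printed_summaries(self):
        counts = fixture_fetal_counts()
        means = counts.groupby("group")["viable_fetuses"].mean()
        assert round(means["DUD72"], 2) == 8.67
        assert round(means["MSD49"], 1) == 16.3
        assert round(means["MSD72"], 1) == 14.3
        assert means["DUD49"] == 11.0

    def test_population_sds_match_printed_summaries(self):
        counts = fixture_fetal_counts()
        sds = counts.groupby("group")["viable_fetuses"].agg(lambda v: v.std(ddof=0))
        assert round(sds["MSD49"], 2) == 0.47
        assert round(sds["MSD72"], 2) == 0.47
        assert round(sds["DUD49"], 2) == 0.82
        assert round(sds["DUD72"], 2) == 0.47

    def test_three_sows_per_group(self):
        counts = fixture_fetal_counts()
        assert (counts.groupby("group").size() == 3).all()
        assert set(counts["group"]) == {"MSD49", "MSD72", "DUD49", "DUD72"}

    def test_duroc_loss_rounds_to_printed_value(self):
        r = fetal_loss_rate(fixture_fetal_counts(), "DUD49", "DUD72")
        assert round(r["loss_pct"], 1) == 21.2
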