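"""Bait-prey scoring: posterior oracle, BFDR construction, fold changes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import t as t_dist

from desmoprox.errors import DesignError
from desmoprox.quant_io import IntensityMatrix, SampleDesign
from desmoprox.scoring import (
    compute_bfdr,
    log2_enrichment,
    read_scores,
    score_group,
    write_scores,
)
from desmoprox.simulate import SimulationConfig, simulate_experiment


def one_bait_design(r_bait=3, r_ctrl=3):
    rows = []
    for i in range(r_bait):
        rows.append(dict(sample=f"b{i}", bait="B", condition="ca_dependent",
                         replicate=i + 1, is_control=False))
    for i in range(r_ctrl):
        rows.append(dict(sample=f"c{i}", bait="ctrl", condition="ca_dependent",
                         replicate=i + 1, is_control=True))
    return SampleDesign(pd.DataFrame(rows))


def matrix_for(bait_values, ctrl_values, extra_rows=None):
    """One prey of interest plus background rows that pin the control floor."""
    rows = {"prey": list(bait_values) + list(ctrl_values)}
    extra_rows = extra_rows or {
        f"bg{i}": [10.0] * (len(bait_values) + len(ctrl_values)) for i in range(3)
    }
    rows.update(extra_rows)
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"b{i}" for i in range(len(bait_values))] + [f"c{i}" for i in range(len(ctrl_values))],
    )
    return IntensityMatrix(df)


def oracle_posterior(x, mu0, s, df, n_ctrl, delta=2.0, prior=0.5):
    """Independent direct evaluation of the two predictive densities."""
    scale = s * np.sqrt(1 + 1 / n_ctrl)
    z = (x - mu0) / scale
    a = delta / scale
    z_peak = (a + np.sqrt(a**2 + 4 * df)) / 2
    z = min(z, z_peak)
    f1 = t_dist.pdf(z - a, df)
    f0 = t_dist.pdf(z, df)
    return prior * f1 / (prior * f1 + (1 - prior) * f0)


class TestScoreGroup:
    def test_prey_at_control_mean_scores_low(self):
        """Bait values equal to the control mean: posterior matches the direct
        density oracle and AvgP stays below 0.05."""
        m = matrix_for([12.0, 12.2, 11.8], [12.1, 12.0, 11.9])
        out = score_group(m, one_bait_design(), "B", "ca_dependent")
        row = out[out["prey"] == "prey"].iloc[0]
        ctrl = np.array([12.1, 12.0, 11.9])
        bait = np.array([12.0, 12.2, 11.8])
        mu0 = ctrl.mean()
        ss = ((bait - bait.mean()) ** 2).sum() + ((ctrl - mu0) ** 2).sum()
        s = max(np.sqrt(ss / 4), 0.25)
        expected = [oracle_posterior(x, mu0, s, 4, 3) for x in bait]
        assert np.allclose(row["posteriors"], expected, atol=1e-9)
        assert row["avg_p"] < 0.05

    def test_strongly_enriched_prey_scores_high(self):
        """Bait values at mu0 + 2*delta give AvgP above 0.95."""
        m = matrix_for([16.0, 16.2, 15.8], [12.1, 12.0, 11.9])
        out = score_group(m, one_bait_design(), "B", "ca_dependent")
        row = out[out["prey"] == "prey"].iloc[0]
        assert row["avg_p"] > 0.95

    def test_absent_prey_emits_no_record(self):
        m = matrix_for([np.nan, np.nan, np.nan], [12.0, 12.0, 12.0])
        out = score_group(m, one_bait_design(), "B", "ca_dependent")
        assert "prey" not in set(out["prey"])

    def test_missing_bait_replicates_count_as_zero_posterior(self):
        """AvgP averages over all bait replicates, missing ones at 0."""
        full = matrix_for([16.0, 16.0, 16.0], [12.0, 12.1, 11.9])
        partial = matrix_for([16.0, np.nan, np.nan], [12.0, 12.1, 11.9])
        avg_full = score_group(full, one_bait_design(), "B", "ca_dependent")
        avg_part = score_group(partial, one_bait_design(), "B", "ca_dependent")
        p_full = avg_full[avg_full["prey"] == "prey"]["avg_p"].iloc[0]
        p_part = avg_part[avg_part["prey"] == "prey"]["avg_p"].iloc[0]
        assert p_part < p_full
        assert p_part <= 1 / 3 + 1e-12

    def test_avg_p_monotone_in_bait_intensity(self, rng):
        """Raising a prey's bait intensities never lowers its AvgP."""
        for _ in range(20):
            base = rng.normal(12, 0.5, size=3)
            ctrl = rng.normal(12, 0.5, size=3)
            bumps = np.sort(rng.uniform(0, 6, size=5))
            prev = -1.0
            for bump in bumps:
                m = matrix_for(base + bump, ctrl)
                out = score_group(m, one_bait_design(), "B", "ca_dependent")
                avg_p = out[out["prey"] == "prey"]["avg_p"].iloc[0]
                assert avg_p >= prev - 1e-12
                prev = avg_p

    def test_missing_group_raises_design_error(self):
        m = matrix_for([12.0] * 3, [12.0] * 3)
        with pytest.raises(DesignError):
            score_group(m, one_bait_design(), "NOPE", "ca_dependent")
        with pytest.raises(DesignError):
            score_group(m, one_bait_design(r_ctrl=1), "B", "ca_dependent")


class TestComputeBfdr:
    def test_hand_oracle_sequence(self):
        """AvgP (1.0, 0.9, 0.8) gives BFDR (0.0, 0.05, 0.1) by cumulative means."""
        df = pd.DataFrame(
            dict(bait="B", condition="ca", prey=["a", "b", "c"],
                 avg_p=[1.0, 0.9, 0.8], log2fc=1.0)
        )
        out = compute_bfdr(df).set_index("prey")
        assert np.allclose(out["bfdr"][["a", "b", "c"]], [0.0, 0.05, 0.1])

    def test_all_perfect_scores_give_zero_bfdr(self):
        df = pd.DataFrame(
            dict(bait="B", condition="ca", prey=list("abc"), avg_p=1.0, log2fc=0.0)
        )
        out = compute_bfdr(df)
        assert (out["bfdr"] == 0.0).all()
        assert out["significant"].all()

    def test_ties_share_worst_bfdr(self):
        df = pd.DataFrame(
            dict(bait="B", condition="ca", prey=list("abcd"),
                 avg_p=[1.0, 0.8, 0.8, 0.5], log2fc=0.0)
        )
        out = compute_bfdr(df).set_index("prey")
        assert out["bfdr"]["b"] == out["bfdr"]["c"]
        # worst of the tie block: rank-3 value (0 + 0.2 + 0.2)/3
        assert out["bfdr"]["b"] == pytest.approx(0.4 / 3)

    def test_bfdr_non_decreasing_property(self, rng):
        """Against brute-force cumulative means on random score sets."""
        for _ in range(100):
            n = int(rng.integers(1, 30))
            avg_p = np.round(rng.random(n), 2)
            df = pd.DataFrame(
                dict(bait="B", condition="ca", prey=[f"p{i}" for i in range(n)],
                     avg_p=avg_p, log2fc=0.0)
            )
            out = compute_bfdr(df)
            ordered = out.sort_values(["avg_p", "prey"], ascending=[False, True])
            brute = np.cumsum(1 - ordered["avg_p"].to_numpy()) / np.arange(1, n + 1)
            assert (np.diff(ordered["bfdr"].to_numpy()) >= -1e-12).all()
            assert (ordered["bfdr"].to_numpy() >= brute - 1e-12).all()

    def test_empty_input_gives_empty_output(self):
        out = compute_bfdr(pd.DataFrame(columns=["bait", "condition", "prey", "avg_p"]))
        assert out.empty


class TestLog2Enrichment:
    def test_arithmetic_on_means(self):
        m = matrix_for([12.0, 12.0, 12.0], [10.0, 10.0, 10.0])
        fc = log2_enrichment(m, one_bait_design(), "B", "ca_dependent")
        assert fc["prey"] == pytest.approx(2.0)

    def test_undetected_prey_is_marked(self):
        m = matrix_for([np.nan] * 3, [10.0, 10.0, 10.0])
        fc = log2_enrichment(m, one_bait_design(), "B", "ca_dependent")
        assert np.isnan(fc["prey"])

    def test_simulated_constant_preys_recover_delta(self):
        """Averaged over >= 200 simulated constant preys, recovered log2FC is
        within 0.5 of the configured delta of 3."""
        config = SimulationConfig(
            n_background_preys=50, n_constant=220, n_calcium_only=0, n_hyper_only=0,
            n_contaminants=0, enrichment_delta_sd=0.3, seed=31,
        )
        matrix, design, truth = simulate_experiment(config)
        recovered = []
        for condition in design.conditions:
            for bait in design.baits:
                fc = log2_enrichment(matrix, design, bait, condition)
                for row in truth.data.itertuples(index=False):
                    if bait in str(row.baits).split("/"):
                        value = fc[row.prey]
                        if not np.isnan(value):
                            recovered.append(value)
        assert len(recovered) >= 200
        assert abs(np.mean(recovered) - 3.0) < 0.5


class TestScoresRoundTrip:
    def test_write_read_round_trip(self, tmp_path, scored_experiment):
        scores, _, _ = scored_experiment
        path = tmp_path / "scores.tsv"
        write_scores(scores, path)
        back = read_scores(path)
        assert len(back) == len(scores)
        merged = back.merge(scores, on=["bait", "condition", "prey"], suffixes=("_r", ""))
        assert np.allclose(merged["bfdr_r"], merged["bfdr"], atol=1e-6)
        assert (merged["significant_r"] == merged["significant"]).all()
        both_fc = merged.dropna(subset=["log2fc_r", "log2fc"])
        assert np.allclose(both_fc["log2fc_r"], both_fc["log2fc"], atol=1e-5)


def test_scoring_separates_truth_from_background(scored_experiment):
    """End-to-end sanity: most significant calls are truly enriched triples."""
    scores, _, truth = scored_experiment
    called = {
        (r.bait, r.condition, r.prey)
        for r in scores[scores["significant"]].itertuples(index=False)
    }
    true_pairs = truth.true_pairs()
    assert len(called & true_pairs) / len(true_pairs) > 0.9
    assert len(called - true_pairs) / max(len(called), 1) < 0.2


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    avg_ps=st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40
    )
)
def test_bfdr_is_running_mean_of_complement_for_any_scores(avg_ps):
    """For arbitrary AvgP lists the ranked BFDR equals the running mean of
    (1 - AvgP) with ties sharing their block maximum, and is bounded in [0, 1]."""
    df = pd.DataFrame(
        dict(bait="B", condition="ca", prey=[f"p{i:02d}" for i in range(len(avg_ps))],
             avg_p=avg_ps, log2fc=0.0)
    )
    out = compute_bfdr(df).sort_values(["avg_p", "prey"], ascending=[False, True])
    running = np.cumsum(1 - out["avg_p"].to_numpy()) / np.arange(1, len(out) + 1)
    # per tie block, every bfdr equals the block maximum of the running mean
    for _, block in out.groupby("avg_p", sort=False):
        idx = out.index.get_indexer(block.index)
        assert np.allclose(block["bfdr"], running[idx].max())
    assert ((out["bfdr"] >= -1e-12) & (out["bfdr"] <= 1 + 1e-12)).all()
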