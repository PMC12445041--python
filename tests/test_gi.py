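import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from slscreen.gi import (
    GIScoringError,
    HitCallConfig,
    assign_batches,
    bassik_filter,
    bliss_expected,
    call_hits,
    center_by_singles,
    loess_gi,
    pair_statistics,
    score_line,
    score_screen,
    summarize_pairs,
    variance_smooth,
)
from slscreen.library import LibraryAnnotation
from slscreen.simulate import SimConfig, simulate_screen
from slscreen.preprocess import preprocess
from slscreen.scaling import scale_lfc

from conftest import make_library


def _toy_scaled(toy_library):
    # singles median is 0.1; dual d1 at -1.0
    return pd.Series(
        {
            "d1": -1.0, "d2": -0.5,
            "s_x1": -0.4, "s_x2": -0.2, "s_y1": 0.1, "s_y2": 0.3,
            "s_e1": -1.2, "s_n1": 0.1,
            "ss1": 0.0, "ss2": 0.05,
        }
    )


class TestCentering:
    def test_subtracts_singles_median(self, toy_library):
        x = _toy_scaled(toy_library)
        centred = center_by_singles(x, toy_library)
        med = np.median([-0.4, -0.2, 0.1, 0.3, -1.2, 0.1])
        assert centred["d1"] == pytest.approx(-1.0 - med)
        singles = [c for c in toy_library.singles().index]
        assert centred[singles].median() == pytest.approx(0.0)

    def test_no_singles_is_error(self):
        lib = make_library([("ss1", "sf_1", "SAFE", "sf_2", "SAFE", "safe")])
        with pytest.raises(GIScoringError, match="single"):
            center_by_singles(pd.Series({"ss1": 0.0}), lib)


class TestBlissExpected:
    def test_additivity_of_position_matched_singles(self, toy_library):
        centred = center_by_singles(_toy_scaled(toy_library), toy_library)
        expected = bliss_expected(centred, toy_library)
        # d1 = gX_1 (pos A) + gY_1 -> gY_1 has its single in position A only,
        # so the other-position fallback applies to it
        assert expected["d1"] == pytest.approx(centred["s_x1"] + centred["s_y1"])
        assert expected["d2"] == pytest.approx(centred["s_y2"] + centred["s_x2"])

    def test_unmatchable_guide_dropped(self, toy_library):
        centred = center_by_singles(_toy_scaled(toy_library), toy_library)
        centred = centred.drop(["s_x1", "s_x2"])  # gene GX loses all singles
        expected = bliss_expected(centred, toy_library)
        assert "d1" not in expected.index and "d2" not in expected.index


class TestLoess:
    def _series(self, x, y):
        idx = [f"c{i}" for i in range(len(x))]
        return pd.Series(x, index=idx), pd.Series(y, index=idx)

    def test_identity_relation_gives_zero_residuals(self):
        x = np.linspace(-2, 1, 60)
        ex, ob = self._series(x, x.copy())
        fitted, resid = loess_gi(ex, ob, HitCallConfig())
        assert np.abs(resid.to_numpy()).max() < 1e-6

    def test_constant_offset_absorbed(self):
        x = np.linspace(-2, 1, 60)
        ex, ob = self._series(x, x + 0.5)
        _, resid = loess_gi(ex, ob, HitCallConfig())
        assert np.abs(resid.to_numpy()).max() < 1e-6

    def test_linear_limit_matches_ols(self):
        rng = np.random.default_rng(0)
        x = np.linspace(-3, 1, 400)
        y = 0.8 * x + rng.normal(0, 0.05, 400)
        ex, ob = self._series(x, y)
        _, resid = loess_gi(ex, ob, HitCallConfig(loess_span=1.0))
        slope, intercept = np.polyfit(x, y, 1)
        ols_resid = y - (slope * x + intercept)
        rms = np.sqrt(np.mean((resid.to_numpy() - ols_resid) ** 2))
        assert rms < 0.02

    def test_too_few_points_is_error(self):
        ex, ob = self._series(np.arange(5.0), np.arange(5.0))
        with pytest.raises(GIScoringError, match="span"):
            loess_gi(ex, ob, HitCallConfig())


class TestVarianceSmoothing:
    def test_unit_variance_within_every_batch(self):
        rng = np.random.default_rng(1)
        n = 750
        expected = pd.Series(rng.normal(size=n), index=[f"c{i}" for i in range(n)])
        resid = pd.Series(rng.normal(size=n) * (1 + np.abs(expected)), index=expected.index)
        out = variance_smooth(expected, resid, HitCallConfig(batch_size=200))
        for _, grp in out.groupby("batch_id"):
            assert grp["norm_gi"].var(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_single_batch_when_n_equals_batch_size(self):
        rng = np.random.default_rng(2)
        expected = pd.Series(rng.normal(size=200), index=[f"c{i}" for i in range(200)])
        resid = pd.Series(rng.normal(size=200), index=expected.index)
        out = variance_smooth(expected, resid, HitCallConfig(batch_size=200))
        assert out["batch_id"].nunique() == 1
        manual = resid / resid.std(ddof=1)
        pd.testing.assert_series_equal(out["norm_gi"], manual, check_names=False)

    def test_short_tail_batch_merged(self):
        expected = pd.Series(np.arange(230.0), index=[f"c{i}" for i in range(230)])
        ids = assign_batches(expected, 200)
        assert ids.nunique() == 1  # 30-element tail < batch_size/4 merges back
        expected = pd.Series(np.arange(260.0), index=[f"c{i}" for i in range(260)])
        ids = assign_batches(expected, 200)
        assert ids.nunique() == 2  # 60 >= 50 stays its own batch
        assert (ids.value_counts() == pd.Series({0: 200, 1: 60})).all()

    def test_heteroscedastic_residuals_flattened(self):
        """norm_gi spread is uniform across batches when raw SD grows with |expected|."""
        rng = np.random.default_rng(3)
        n = 1000
        expected = pd.Series(np.sort(rng.uniform(-3, 0, n)), index=[f"c{i}" for i in range(n)])
        resid = pd.Series(
            rng.normal(size=n) * (0.2 + 0.5 * np.abs(expected)), index=expected.index
        )
        out = variance_smooth(expected, resid, HitCallConfig(batch_size=200))
        sds = out.groupby("batch_id")["norm_gi"].std(ddof=1)
        assert (np.abs(sds - 1) < 0.15).all()


class TestPairStatistics:
    def _records(self, rng, shifts, n_per_pair=24):
        rows = []
        for i, shift in enumerate(shifts):
            for v in rng.normal(shift, 1.0, n_per_pair):
                rows.append((f"P{i:03d}", v))
        return pd.DataFrame(rows, columns=["gene_pair", "norm_gi"])

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(4)
        records = self._records(rng, [0] * 8 + [-2, -3])
        out = pair_statistics(records, HitCallConfig())
        p = out["p_value"].to_numpy()
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            idx = order[rank]
            running = min(running, p[idx] * n / (rank + 1))
            adj[idx] = running
        np.testing.assert_allclose(out["fdr"].to_numpy(), adj, atol=1e-10)

    def test_shifted_pair_detected(self):
        rng = np.random.default_rng(5)
        records = self._records(rng, [0] * 20 + [-3])
        out = pair_statistics(records, HitCallConfig())
        assert out.loc["P020", "fdr"] < 0.01
        assert out.loc["P020", "mean_norm_gi"] < -2

    def test_small_pairs_excluded(self):
        rng = np.random.default_rng(6)
        records = self._records(rng, [0] * 5)
        records = pd.concat(
            [records, pd.DataFrame({"gene_pair": ["TINY"] * 2, "norm_gi": [0.0, 0.1]})]
        )
        out = pair_statistics(records, HitCallConfig())
        assert "TINY" not in out.index

    def test_per_pair_switch(self):
        rng = np.random.default_rng(7)
        records = self._records(rng, [0, 0, -2])
        pooled = pair_statistics(records, HitCallConfig(t_test="pooled"))
        per_pair = pair_statistics(records, HitCallConfig(t_test="per_pair"))
        assert pooled.loc["P002", "p_value"] < 0.01
        assert per_pair.loc["P002", "p_value"] < 0.01


class TestBassikFilter:
    def _frames(self, rng, pair_shift, n_pair=24, n_null=200):
        records = pd.DataFrame(
            {"gene_pair": "P1", "norm_gi": rng.normal(pair_shift, 1.0, n_pair)}
        )
        nulls = pd.DataFrame({"norm_gi": rng.normal(0, 1.0, n_null)})
        return records, nulls

    def test_matches_closed_form_welch_oracle(self):
        rng = np.random.default_rng(8)
        records, nulls = self._frames(rng, -2.0)
        out = bassik_filter(records, nulls, HitCallConfig())
        x, y = records["norm_gi"].to_numpy(), nulls["norm_gi"].to_numpy()
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert out.loc["P1", "bassik_p"] == pytest.approx(p, abs=1e-10)
        assert bool(out.loc["P1", "bassik_significant"])

    def test_null_pair_not_significant(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(200):
            records, nulls = self._frames(rng, 0.0)
            out = bassik_filter(records, nulls, HitCallConfig())
            hits += int(out.loc["P1", "bassik_significant"])
        assert hits <= 0.08 * 200  # alpha 0.05 (one-sided-ish) + MC slack

    def test_disabled_filter_passes_everything(self):
        rng = np.random.default_rng(10)
        records, nulls = self._frames(rng, 0.0)
        out = bassik_filter(records, nulls, HitCallConfig(bassik_enabled=False))
        assert bool(out.loc["P1", "bassik_significant"])

    def test_empty_null_pool_warns_and_disables(self):
        rng = np.random.default_rng(11)
        records, _ = self._frames(rng, -2.0)
        with pytest.warns(UserWarning, match="null pool"):
            out = bassik_filter(records, records.iloc[:0], HitCallConfig())
        assert bool(out.loc["P1", "bassik_significant"])


class TestHitRule:
    def _stats_row(self, gi, fdr, bassik=True, pair="GDI1|GDI2"):
        pair_stats = pd.DataFrame(
            {
                "gene_pair": [pair],
                "n_constructs": [24],
                "mean_norm_gi": [gi],
                "median_norm_gi": [gi],
                "t_stat": [-5.0],
                "p_value": [fdr / 2],
                "fdr": [fdr],
            }
        ).set_index("gene_pair", drop=False).rename_axis(None)
        bassik_df = pd.DataFrame(
            {"gene_pair": [pair], "bassik_p": [0.001], "bassik_significant": [bassik]}
        ).set_index("gene_pair", drop=False).rename_axis(None)
        return pair_stats, bassik_df

    def test_gi_threshold_boundary(self):
        """A pair at GI -0.455 misses the -0.5 threshold regardless of FDR."""
        stats_df, bassik_df = self._stats_row(-0.455, 1e-6)
        out = call_hits(stats_df, bassik_df, {}, HitCallConfig())
        assert not out["hit"].iloc[0]

    def test_fdr_boundary(self):
        """A pair at FDR 0.066 misses the 0.01 threshold despite strong GI."""
        stats_df, bassik_df = self._stats_row(-1.2, 0.066)
        out = call_hits(stats_df, bassik_df, {}, HitCallConfig())
        assert not out["hit"].iloc[0]

    def test_essential_member_vetoes(self):
        stats_df, bassik_df = self._stats_row(-2.0, 1e-6)
        out = call_hits(stats_df, bassik_df, {"GDI1": True}, HitCallConfig())
        assert bool(out["either_gene_essential"].iloc[0])
        assert not out["hit"].iloc[0]

    def test_passing_pair_is_hit(self):
        stats_df, bassik_df = self._stats_row(-2.0, 1e-6)
        out = call_hits(stats_df, bassik_df, {"GDI1": False}, HitCallConfig())
        assert bool(out["hit"].iloc[0])


class TestOrientationSymmetry:
    def test_swapping_guide_positions_preserves_pair_results(self, analysed_screen):
        """Mirroring every construct's guide positions leaves pair stats unchanged."""
        library = analysed_screen["library"]
        scaled = analysed_screen["scaled"]
        samples = analysed_screen["counts"].samples
        flipped_frame = library.frame.rename(
            columns={
                "guide_a_id": "guide_b_id",
                "guide_b_id": "guide_a_id",
                "gene_a": "gene_b",
                "gene_b": "gene_a",
            }
        )
        flipped = LibraryAnnotation(flipped_frame.reset_index(drop=True))
        res_orig = score_screen(scaled, library, samples, HitCallConfig())
        res_flip = score_screen(scaled, flipped, samples, HitCallConfig())
        merged = res_orig.merge(res_flip, on="gene_pair", suffixes=("_o", "_f"))
        np.testing.assert_allclose(
            merged["mean_norm_gi_o"], merged["mean_norm_gi_f"], atol=1e-9
        )
        np.testing.assert_allclose(merged["p_value_o"], merged["p_value_f"], atol=1e-9)


class TestRecovery:
    def test_injected_interactions_recovered(self, analysed_screen, essentiality_calls):
        """Truth-SL pairs come out as hits; truth-null pairs do not."""
        truth = analysed_screen["truth"]
        res = score_screen(
            analysed_screen["scaled"],
            analysed_screen["library"],
            analysed_screen["counts"].samples,
            HitCallConfig(),
            essentiality_calls,
        )
        line = res["cell_line"].iloc[0]
        truth_ess = truth.essential_genes(line)
        labels = truth.sl_labels[line]
        for _, row in res.iterrows():
            a, b = row["gene_pair"].split("|")
            if a in truth_ess or b in truth_ess:
                assert not row["hit"]  # essential veto
            elif labels.get(row["gene_pair"], False):
                assert row["hit"], f"missed {row['gene_pair']}"

    def test_summary_partition_conserved(self, analysed_screen, essentiality_calls):
        res = score_screen(
            analysed_screen["scaled"],
            analysed_screen["library"],
            analysed_screen["counts"].samples,
            HitCallConfig(),
            essentiality_calls,
        )
        summary = summarize_pairs(res, n_lines=1)
        parts = summary[["strong_hit", "context_dependent", "never_hit"]].sum(axis=1)
        assert (parts == 1).all()  # every pair in exactly one partition
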