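"""Genetic-interaction scoring and synthetic-lethal hit calling.

The score is a Bliss-model residual. Within each scaled sample, fold changes
are first centred on the median of the single constructs. The expected fold
change of a dual construct is the sum of its two guides' single-construct fold
changes (Bliss independence: additivity in log2 space). A Loess regression of
observed on expected fold changes absorbs smooth systematic deviations, and
the residual from that fit is the guide-level GI score. Because residual
variance grows with the magnitude of the expected effect, duals are ranked by
expected fold change and binned into batches of 200; each residual is divided
by the square root of its batch's sample variance, yielding the normalised GI
score (norm_gi), a variance-smoothed z-like quantity.

Per cell line, norm_gi values are pooled across both orientations and all
retained replicates of a gene pair. The pair statistic compares the pair's
median norm_gi to the line's overall median with a pooled-variance t-test,
with BH control of the FDR. A pair is a synthetic-lethal hit iff
mean norm_gi < -0.5, FDR < 0.01, it passes the secondary (safe|safe null)
filter, and neither member gene is individually essential in that line.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .library import (
    CATEGORY_DUAL,
    LibraryAnnotation,
    POSITION_A,
    POSITION_B,
    ROLE_SCREEN,
    SAFE,
    pair_id,
)

logger = logging.getLogger(__name__)


class GIScoringError(ValueError):
    pass


@dataclass
class HitCallConfig:
    gi_threshold: float = -0.5
    fdr_threshold: float = 0.01
    batch_size: int = 200
    loess_span: float = 0.75
    bassik_alpha: float = 0.05
    bassik_enabled: bool = True
    min_pair_constructs: int = 3
    t_test: str = "pooled"  # or "per_pair" (one-sample t per pair)

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise GIScoringError("batch_size must be >= 2")
        if not 0 < self.loess_span <= 1:
            raise GIScoringError("loess_span must be in (0, 1]")
        if not 0 < self.fdr_threshold < 1 or not 0 < self.bassik_alpha < 1:
            raise GIScoringError("significance thresholds must be in (0, 1)")
        if self.t_test not in ("pooled", "per_pair"):
            raise GIScoringError("t_test must be 'pooled' or 'per_pair'")


def center_by_singles(
    scaled_sample: pd.Series, library: LibraryAnnotation
) -> pd.Series:
    """Subtract the median scaled LFC of the sample's single constructs."""
    single_ids = [c for c in library.singles().index if c in scaled_sample.index]
    if not single_ids:
        raise GIScoringError("no single constructs present to centre on")
    return scaled_sample - scaled_sample.loc[single_ids].median()


def single_guide_fc(
    centred_sample: pd.Series, library: LibraryAnnotation
) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """Mean centred fold change per (guide, position) and per gene, over singles."""
    singles = library.singles()
    present = singles.index.intersection(centred_sample.index)
    singles = singles.loc[present]
    by_guide: dict[tuple[str, str], list[float]] = {}
    by_gene: dict[str, list[float]] = {}
    for cid, row in singles.iterrows():
        value = float(centred_sample.loc[cid])
        if row["gene_a"] != SAFE:
            by_guide.setdefault((row["guide_a_id"], POSITION_A), []).append(value)
            by_gene.setdefault(row["gene_a"], []).append(value)
        else:
            by_guide.setdefault((row["guide_b_id"], POSITION_B), []).append(value)
            by_gene.setdefault(row["gene_b"], []).append(value)
    guide_fc = {k: float(np.mean(v)) for k, v in by_guide.items()}
    gene_fc = {k: float(np.mean(v)) for k, v in by_gene.items()}
    return guide_fc, gene_fc


def _lookup_single_fc(
    guide_id: str,
    position: str,
    gene: str,
    guide_fc: dict[tuple[str, str], float],
    gene_fc: dict[str, float],
) -> float | None:
    """Position-matched guide mean, then other-position, then gene-level mean."""
    other = POSITION_B if position == POSITION_A else POSITION_A
    for key in ((guide_id, position), (guide_id, other)):
        if key in guide_fc:
            return guide_fc[key]
    return gene_fc.get(gene)


def bliss_expected(
    centred_sample: pd.Series, library: LibraryAnnotation
) -> pd.Series:
    """Expected FC per dual construct: singleFC(g1) + singleFC(g2).

    Duals whose guides have no single construct anywhere are dropped (logged).
    """
    guide_fc, gene_fc = single_guide_fc(centred_sample, library)
    duals = library.duals()
    duals = duals.loc[duals.index.intersection(centred_sample.index)]
    expected = {}
    dropped = []
    for cid, row in duals.iterrows():
        fa = _lookup_single_fc(row["guide_a_id"], POSITION_A, row["gene_a"], guide_fc, gene_fc)
        fb = _lookup_single_fc(row["guide_b_id"], POSITION_B, row["gene_b"], guide_fc, gene_fc)
        if fa is None or fb is None:
            dropped.append(cid)
            continue
        expected[cid] = fa + fb
    if dropped:
        logger.warning(
            "%d dual construct(s) excluded from GI scoring (no matchable single): %s",
            len(dropped),
            dropped[:5],
        )
    return pd.Series(expected, dtype=float)


def loess_gi(
    expected: pd.Series, observed: pd.Series, config: HitCallConfig
) -> tuple[pd.Series, pd.Series]:
    """Loess fit of observed on expected; residual = observed - fitted (the GI)."""
    n = len(expected)
    if n < 10 or config.loess_span * n < 4:
        raise GIScoringError(
            f"too few dual constructs ({n}) for Loess at span {config.loess_span}; "
            "increase the span"
        )
    x = expected.to_numpy()
    y = observed.loc[expected.index].to_numpy()
    span_range = float(np.ptp(x))
    fitted = lowess(
        y,
        x,
        frac=config.loess_span,
        it=3,
        delta=0.001 * span_range,
        return_sorted=False,
    )
    fitted = pd.Series(fitted, index=expected.index)
    return fitted, observed.loc[expected.index] - fitted


def assign_batches(expected: pd.Series, batch_size: int) -> pd.Series:
    """Contiguous batches of ``batch_size`` along ascending expected FC.

    A trailing batch shorter than batch_size/4 is merged into its predecessor
    to avoid unstable variance estimates.
    """
    order = expected.sort_values(kind="mergesort").index
    n = len(order)
    ids = np.arange(n) // batch_size
    if n > batch_size and n % batch_size and n % batch_size < batch_size // 4:
        ids[ids == ids.max()] = ids.max() - 1
    return pd.Series(ids, index=order).reindex(expected.index)


def variance_smooth(
    expected: pd.Series, residuals: pd.Series, config: HitCallConfig
) -> pd.DataFrame:
    """Batch id, batch residual variance and norm_gi = residual / sqrt(variance)."""
    batch_id = assign_batches(expected, config.batch_size)
    out = pd.DataFrame(
        {"expected_fc": expected, "residual": residuals.loc[expected.index], "batch_id": batch_id}
    )
    batch_var = out.groupby("batch_id")["residual"].var(ddof=1)
    if (batch_var <= 0).any() or batch_var.isna().any():
        raise GIScoringError("degenerate data: a residual batch has zero variance")
    out["batch_variance"] = out["batch_id"].map(batch_var)
    out["norm_gi"] = out["residual"] / np.sqrt(out["batch_variance"])
    return out


def score_sample(
    scaled_sample: pd.Series, library: LibraryAnnotation, config: HitCallConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Guide-level GI records for one sample: (dual records, safe|safe null records).

    Safe|safe constructs are run through the same Loess/variance machinery
    (expected FC 0, fitted value interpolated from the dual fit, variance from
    the nearest batch) to provide the null pool for the secondary filter.
    """
    centred = center_by_singles(scaled_sample, library)
    expected = bliss_expected(centred, library)
    observed = centred.loc[expected.index]
    fitted, residual = loess_gi(expected, observed, config)
    records = variance_smooth(expected, residual, config)
    records.insert(0, "construct_id", records.index)
    records["observed_fc"] = observed
    records["fitted_fc"] = fitted

    duals = library.frame.loc[records.index]
    records["gene_pair"] = [
        pair_id(a, b) for a, b in zip(duals["gene_a"], duals["gene_b"])
    ]

    # null pool: safe|safe constructs through the same variance machinery.
    # Their residuals are taken about the safe|safe population median rather
    # than the Loess curve: with a noisy expected axis the fitted curve is
    # systematically offset at any single true location (errors-in-variables),
    # so anchoring the zero-effect pool to its own centre is what keeps it
    # exchangeable with the scores of interaction-free duals. The variance is
    # that of the expected-FC batch nearest the pool's Bliss location (twice
    # the centred safe|safe median).
    ss_ids = [c for c in library.safe_safes().index if c in centred.index]
    null_obs = centred.loc[ss_ids]
    null_residual = null_obs - float(null_obs.median())
    null_expected = 2.0 * float(null_obs.median())
    order = np.argsort(expected.to_numpy(), kind="mergesort")
    x_sorted = expected.to_numpy()[order]
    nearest = min(max(int(np.searchsorted(x_sorted, null_expected)), 0), len(x_sorted) - 1)
    null_var = float(records["batch_variance"].to_numpy()[order[nearest]])
    null_records = pd.DataFrame(
        {
            "construct_id": ss_ids,
            "expected_fc": null_expected,
            "residual": null_residual,
            "batch_variance": null_var,
            "norm_gi": null_residual / np.sqrt(null_var),
        }
    )
    return records, null_records


def score_line(
    scaled: pd.DataFrame,
    library: LibraryAnnotation,
    sample_ids: list[str],
    config: HitCallConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool guide-level records over a cell line's retained replicates."""
    recs, nulls = [], []
    for sid in sample_ids:
        r, nr = score_sample(scaled[sid], library, config)
        r["sample_id"] = sid
        nr["sample_id"] = sid
        recs.append(r)
        nulls.append(nr)
    return pd.concat(recs, ignore_index=True), pd.concat(nulls, ignore_index=True)


def pair_statistics(records: pd.DataFrame, config: HitCallConfig) -> pd.DataFrame:
    """Per-pair stats from pooled norm_gi values of one cell line.

    Pooled mode: m0 = median of all norm_gi in the line; pooled within-pair
    variance s^2 = sum_p sum_i (x_pi - xbar_p)^2 / (N - K); t_p =
    (median_p - m0) / (s / sqrt(n_p)) on N - K df, two-sided; BH across pairs.
    """
    m0 = float(records["norm_gi"].median())
    groups = records.groupby("gene_pair")["norm_gi"]
    sizes = groups.size()
    small = sizes.index[sizes < config.min_pair_constructs].tolist()
    if small:
        logger.warning("excluding %d pair(s) with < %d values: %s", len(small), config.min_pair_constructs, small[:5])
    kept = sizes.index[sizes >= config.min_pair_constructs]

    rows = []
    if config.t_test == "pooled":
        ss = 0.0
        n_total = 0
        for pair in kept:
            x = groups.get_group(pair).to_numpy()
            ss += float(np.sum((x - x.mean()) ** 2))
            n_total += len(x)
        df = n_total - len(kept)
        s2 = ss / df
        for pair in kept:
            x = groups.get_group(pair).to_numpy()
            med = float(np.median(x))
            t = (med - m0) / np.sqrt(s2 / len(x))
            p = 2.0 * stats.t.sf(abs(t), df)
            rows.append((pair, len(x), float(x.mean()), med, t, p))
    else:
        for pair in kept:
            x = groups.get_group(pair).to_numpy()
            res = stats.ttest_1samp(x, m0)
            rows.append((pair, len(x), float(x.mean()), float(np.median(x)),
                         float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(
        rows,
        columns=["gene_pair", "n_constructs", "mean_norm_gi", "median_norm_gi", "t_stat", "p_value"],
    )
    if out.empty:
        raise GIScoringError("no gene pair has enough GI values to test")
    out["fdr"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out.set_index("gene_pair", drop=False).rename_axis(None)


def bassik_filter(
    records: pd.DataFrame, null_records: pd.DataFrame, config: HitCallConfig
) -> pd.DataFrame:
    """Secondary filter: Welch t of each pair's norm_gi against the safe|safe null.

    Significant iff p < bassik_alpha and the pair mean is below the null mean.
    With the filter disabled (or an empty null pool) every pair passes.
    """
    pairs = sorted(records["gene_pair"].unique())
    if not config.bassik_enabled:
        return pd.DataFrame(
            {"gene_pair": pairs, "bassik_p": np.nan, "bassik_significant": True}
        ).set_index("gene_pair", drop=False).rename_axis(None)
    null = null_records["norm_gi"].to_numpy()
    if len(null) < 2:
        warnings.warn("empty safe|safe null pool; secondary filter disabled", stacklevel=2)
        return pd.DataFrame(
            {"gene_pair": pairs, "bassik_p": np.nan, "bassik_significant": True}
        ).set_index("gene_pair", drop=False).rename_axis(None)
    rows = []
    for pair, x in records.groupby("gene_pair")["norm_gi"]:
        res = stats.ttest_ind(x.to_numpy(), null, equal_var=False)
        significant = res.pvalue < config.bassik_alpha and x.mean() < null.mean()
        rows.append((pair, float(res.pvalue), bool(significant)))
    return pd.DataFrame(
        rows, columns=["gene_pair", "bassik_p", "bassik_significant"]
    ).set_index("gene_pair", drop=False).rename_axis(None)


def call_hits(
    pair_stats: pd.DataFrame,
    bassik: pd.DataFrame,
    essential_by_gene: dict[str, bool],
    config: HitCallConfig,
) -> pd.DataFrame:
    """Apply the hit rule for one cell line.

    hit <=> mean_norm_gi < gi_threshold AND fdr < fdr_threshold AND secondary
    filter significant AND neither member gene individually essential.
    """
    out = pair_stats.join(bassik[["bassik_p", "bassik_significant"]])
    genes = out["gene_pair"].str.split("|", expand=True)
    out["either_gene_essential"] = [
        bool(essential_by_gene.get(a, False) or essential_by_gene.get(b, False))
        for a, b in zip(genes[0], genes[1])
    ]
    out["hit"] = (
        (out["mean_norm_gi"] < config.gi_threshold)
        & (out["fdr"] < config.fdr_threshold)
        & out["bassik_significant"]
        & ~out["either_gene_essential"]
    )
    return out


def score_screen(
    scaled: pd.DataFrame,
    library: LibraryAnnotation,
    samples: pd.DataFrame,
    config: HitCallConfig | None = None,
    essentiality_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full GI scoring across cell lines; returns a long (pair, line) table."""
    config = config or HitCallConfig()
    screen = samples[samples["role"] == ROLE_SCREEN]
    results = []
    for line, group in screen.groupby("cell_line"):
        sids = [s for s in group.index if s in scaled.columns]
        if not sids:
            continue
        records, null_records = score_line(scaled, library, sids, config)
        pstats = pair_statistics(records, config)
        bassik = bassik_filter(records, null_records, config)
        ess = {}
        if essentiality_calls is not None:
            sub = essentiality_calls[essentiality_calls["cell_line"] == line]
            ess = dict(zip(sub["gene"], sub["essential"].astype(bool)))
        res = call_hits(pstats, bassik, ess, config)
        res.insert(1, "cell_line", line)
        results.append(res)
    if not results:
        raise GIScoringError("no screen samples to score")
    return pd.concat(results, ignore_index=True)


def summarize_pairs(pair_results: pd.DataFrame, n_lines: int | None = None) -> pd.DataFrame:
    """Cross-line summary per pair: hit frequency and strong/context flags.

    A strong hit is a pair hit in more than half the screened lines; a
    context-dependent hit is hit in at least one but no more than half.
    """
    if n_lines is None:
        n_lines = pair_results["cell_line"].nunique()
    grouped = pair_results.groupby("gene_pair")
    out = pd.DataFrame(
        {
            "n_lines_tested": grouped.size(),
            "hit_frequency": grouped["hit"].sum().astype(int),
        }
    )
    hit_rows = pair_results[pair_results["hit"]]
    out["median_gi_over_hits"] = hit_rows.groupby("gene_pair")["mean_norm_gi"].median()
    out["strong_hit"] = out["hit_frequency"] > n_lines / 2
    out["context_dependent"] = (out["hit_frequency"] > 0) & ~out["strong_hit"]
    out["never_hit"] = out["hit_frequency"] == 0
    return out.sort_index()
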