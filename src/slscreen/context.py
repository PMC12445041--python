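"""Context-dependence analyses of genetic-interaction scores across cell lines.

The GI score is treated as a quantitative trait: a one-way ANOVA asks whether
a pair's GI varies by cancer type; Pearson correlation against mRNA abundance
(TPM) asks whether expression of either member modulates the interaction;
hit-frequency analysis relates how often a pair is a hit to how strong its GI
is; and expression positioning flags hit pairs that are ubiquitously expressed
in normal tissues but lose one member in tumours (presence = TPM > 1).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class ContextError(ValueError):
    pass


def _gi_by_line(pair_results: pd.DataFrame) -> pd.DataFrame:
    """Wide pair x line matrix of mean_norm_gi."""
    return pair_results.pivot_table(
        index="gene_pair", columns="cell_line", values="mean_norm_gi"
    )


def anova_by_cancer_type(
    pair_results: pd.DataFrame, line_lineage: pd.Series
) -> pd.DataFrame:
    """One-way ANOVA of each pair's per-line GI on cancer type, BH-corrected.

    Pairs with fewer than two lineages carrying >= 2 lines each are skipped.
    Significance is conventionally read at FDR < 10%.
    """
    gi = _gi_by_line(pair_results)
    rows = []
    for pair, values in gi.iterrows():
        values = values.dropna()
        groups = [
            grp.to_numpy()
            for _, grp in values.groupby(line_lineage.reindex(values.index))
            if len(grp) >= 2
        ]
        if len(groups) < 2:
            continue
        f, p = stats.f_oneway(*groups)
        rows.append((pair, float(f), float(p)))
    out = pd.DataFrame(rows, columns=["gene_pair", "f_stat", "anova_p"])
    if not out.empty:
        out["anova_fdr"] = multipletests(out["anova_p"].to_numpy(), method="fdr_bh")[1]
    return out.set_index("gene_pair", drop=False).rename_axis(None)


def expression_correlation(
    pair_results: pd.DataFrame,
    tpm: pd.DataFrame,
    min_hit_lines: int = 1,
    min_lines: int = 5,
) -> pd.DataFrame:
    """Pearson r between each pair member's TPM and the pair's GI across lines.

    ``tpm`` is a gene x cell-line matrix. Only pairs hit in at least
    ``min_hit_lines`` lines are tested; BH correction is applied across all
    (pair, member gene) tests. Zero-variance expression vectors are skipped.
    """
    gi = _gi_by_line(pair_results)
    hit_counts = pair_results.groupby("gene_pair")["hit"].sum()
    tested_pairs = hit_counts.index[hit_counts >= min_hit_lines]
    rows = []
    for pair in tested_pairs:
        if pair not in gi.index:
            continue
        gi_vals = gi.loc[pair].dropna()
        for gene in pair.split("|"):
            if gene not in tpm.index:
                logger.warning("gene %s absent from expression table; skipped", gene)
                continue
            expr = tpm.loc[gene].reindex(gi_vals.index).dropna()
            if len(expr) < min_lines:
                continue
            y = gi_vals.loc[expr.index]
            if np.ptp(expr.to_numpy()) == 0:
                logger.warning("zero-variance expression for %s; skipped", gene)
                continue
            r, p = stats.pearsonr(expr.to_numpy(), y.to_numpy())
            rows.append((pair, gene, float(r), float(p), len(expr)))
    out = pd.DataFrame(rows, columns=["gene_pair", "gene", "pearson_r", "p_value", "n_lines"])
    if not out.empty:
        out["fdr"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out


def hit_frequency_analysis(
    pair_results: pd.DataFrame,
) -> tuple[pd.DataFrame, float, float]:
    """Per-pair hit count and median hit GI, and their global Pearson r.

    Pairs never hit are excluded (their median hit GI is undefined). Returns
    (per-pair table, r, p); r is NaN when degenerate (fewer than two hit pairs
    or zero variance on either axis).
    """
    hits = pair_results[pair_results["hit"]]
    table = pd.DataFrame(
        {
            "hit_frequency": hits.groupby("gene_pair").size(),
            "median_hit_gi": hits.groupby("gene_pair")["mean_norm_gi"].median(),
        }
    )
    if len(table) < 2 or table.nunique().min() < 2:
        return table, float("nan"), float("nan")
    r, p = stats.pearsonr(table["median_hit_gi"], table["hit_frequency"])
    return table, float(r), float(p)


def rank_hits_per_line(pair_results: pd.DataFrame) -> pd.DataFrame:
    """Dense per-line ranking of hits by mean GI, most negative first.

    Ties on GI break by FDR ascending, then by pair name.
    """
    hits = pair_results[pair_results["hit"]].copy()
    ranked = []
    for line, group in hits.groupby("cell_line"):
        group = group.sort_values(
            ["mean_norm_gi", "fdr", "gene_pair"], ascending=[True, True, True]
        ).copy()
        group["rank"] = np.arange(1, len(group) + 1)
        ranked.append(group)
    if not ranked:
        return hits.assign(rank=pd.Series(dtype=int))
    return pd.concat(ranked, ignore_index=True)[
        ["gene_pair", "cell_line", "mean_norm_gi", "fdr", "rank"]
    ]


def expression_positioning(
    tpm_normal: pd.DataFrame,
    tpm_tumour: pd.DataFrame,
    hit_pairs: Sequence[str],
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Flag hit pairs ubiquitously expressed in normal tissue with tumour loss.

    A pair is flagged iff both members exceed ``threshold`` TPM in every normal
    tissue sample AND exactly one member is at or below threshold in at least
    one tumour sample. Pairs with a gene missing from either table are skipped.
    """
    rows = []
    for pair in hit_pairs:
        genes = pair.split("|")
        if any(g not in tpm_normal.index or g not in tpm_tumour.index for g in genes):
            logger.warning("pair %s skipped: gene absent from an expression table", pair)
            continue
        ubiquitous = all((tpm_normal.loc[g] > threshold).all() for g in genes)
        lost = [g for g in genes if (tpm_tumour.loc[g] <= threshold).any()]
        flagged = bool(ubiquitous and len(lost) == 1)
        rows.append((pair, ubiquitous, ",".join(lost), flagged))
    return pd.DataFrame(
        rows, columns=["gene_pair", "ubiquitous_normal", "lost_in_tumour", "flagged"]
    )
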