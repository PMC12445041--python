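"""Single-gene essentiality calling from gene|safe and safe|gene constructs.

A gene is called essential in a cell line when two independent lines of
evidence agree, mirroring the conjunction rule used for combinatorial screens
(negative-selection FDR < 0.05 AND scaled Bayes factor > 0):

* a one-sided rank-sum depletion test of the gene's single-construct scaled
  LFCs against the safe|safe construct null, BH-corrected per line;
* a gene-level Bayes factor, the summed log2 ratio of Gaussian-KDE densities
  fitted to reference essential and non-essential single-construct pools,
  shifted by the ROC threshold maximising Youden's J on the reference genes so
  that scaled BF > 0 means depleted.

These are deliberately lightweight, deterministic scorers that preserve the
decision rule's structure; externally computed tables with columns
(gene, cell_line, depletion_fdr, scaled_bf) can be supplied instead for runs
on real data scored with dedicated tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .library import (
    CLASS_ESSENTIAL,
    CLASS_NON_ESSENTIAL,
    LibraryAnnotation,
    ROLE_SCREEN,
)

MIN_REFERENCE_POOL = 20
DENSITY_FLOOR = 1e-12


class EssentialityError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceGeneSets:
    """Known essential / non-essential gene lists used for calibration."""

    essential: tuple[str, ...]
    nonessential: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.essential or not self.nonessential:
            raise EssentialityError("reference gene sets must be non-empty")
        if set(self.essential) & set(self.nonessential):
            raise EssentialityError("reference gene sets must be disjoint")

    @classmethod
    def from_library(cls, library: LibraryAnnotation) -> "ReferenceGeneSets":
        ess = sorted(set(library.single_gene_of(library.control_single_ids(CLASS_ESSENTIAL))))
        non = sorted(
            set(library.single_gene_of(library.control_single_ids(CLASS_NON_ESSENTIAL)))
        )
        return cls(essential=tuple(ess), nonessential=tuple(non))


def gene_single_values(
    scaled: pd.DataFrame,
    library: LibraryAnnotation,
    sample_ids: Sequence[str],
) -> dict[str, np.ndarray]:
    """Per gene, scaled LFCs of its single constructs pooled across samples."""
    singles = library.singles()
    present = [c for c in singles.index if c in scaled.index]
    genes = library.single_gene_of(present)
    values = scaled.loc[present, list(sample_ids)]
    out: dict[str, np.ndarray] = {}
    for gene, idx in genes.groupby(genes).groups.items():
        out[str(gene)] = values.loc[idx].to_numpy().ravel()
    return out


def depletion_pvalue(gene_values: np.ndarray, null_values: np.ndarray) -> float:
    """One-sided Mann-Whitney p for the gene being depleted versus the null."""
    if len(gene_values) < 2:
        raise EssentialityError("depletion test needs >= 2 single-construct values")
    return float(
        stats.mannwhitneyu(gene_values, null_values, alternative="less").pvalue
    )


def bayes_factor(
    gene_values: np.ndarray,
    kde_essential: stats.gaussian_kde,
    kde_nonessential: stats.gaussian_kde,
) -> float:
    """Sum over values of log2(fE / fN), densities floored at 1e-12."""
    f_e = np.maximum(kde_essential(gene_values), DENSITY_FLOOR)
    f_n = np.maximum(kde_nonessential(gene_values), DENSITY_FLOOR)
    return float(np.sum(np.log2(f_e / f_n)))


def fit_reference_kdes(
    values_by_gene: Mapping[str, np.ndarray], refs: ReferenceGeneSets
) -> tuple[stats.gaussian_kde, stats.gaussian_kde]:
    pool_e = np.concatenate(
        [values_by_gene[g] for g in refs.essential if g in values_by_gene] or [[]]
    )
    pool_n = np.concatenate(
        [values_by_gene[g] for g in refs.nonessential if g in values_by_gene] or [[]]
    )
    if len(pool_e) < MIN_REFERENCE_POOL or len(pool_n) < MIN_REFERENCE_POOL:
        raise EssentialityError(
            f"reference pools need >= {MIN_REFERENCE_POOL} values "
            f"(got {len(pool_e)} essential, {len(pool_n)} non-essential)"
        )
    return stats.gaussian_kde(pool_e), stats.gaussian_kde(pool_n)


def roc_threshold(bayes_factors: pd.Series, refs: ReferenceGeneSets) -> float:
    """BF cut maximising Youden's J on the reference genes.

    Candidates are the observed reference BFs (predict essential iff BF >= t);
    ties resolved toward the smallest BF achieving the maximum, and the cut is
    placed midway between that BF and the next smaller observed BF.
    """
    bf_e = bayes_factors.reindex(refs.essential).dropna()
    bf_n = bayes_factors.reindex(refs.nonessential).dropna()
    if bf_e.empty or bf_n.empty:
        raise EssentialityError("degenerate ROC: a reference class has no scored genes")
    candidates = np.unique(np.concatenate([bf_e.to_numpy(), bf_n.to_numpy()]))
    sens = np.array([(bf_e >= t).mean() for t in candidates])
    spec = np.array([(bf_n < t).mean() for t in candidates])
    j = sens + spec - 1.0
    best = candidates[np.flatnonzero(j == j.max())[0]]
    lower = candidates[candidates < best]
    return float((best + lower[-1]) / 2.0) if len(lower) else float(best)


def call_essentiality(
    scaled: pd.DataFrame,
    library: LibraryAnnotation,
    samples: pd.DataFrame,
    refs: ReferenceGeneSets | None = None,
    depletion_fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per (gene, cell line) essentiality table over all retained screen samples.

    Columns: mean_single_lfc, depletion_p, depletion_fdr, bayes_factor,
    roc_threshold, scaled_bf, essential, testable. Genes without single
    constructs are flagged untestable rather than scored.
    """
    refs = refs or ReferenceGeneSets.from_library(library)
    screen = samples[(samples["role"] == ROLE_SCREEN)]
    safe_ids = [c for c in library.safe_safes().index if c in scaled.index]

    rows = []
    for line, group in screen.groupby("cell_line"):
        sids = [s for s in group.index if s in scaled.columns]
        if not sids:
            continue
        values_by_gene = gene_single_values(scaled, library, sids)
        null_pool = scaled.loc[safe_ids, sids].to_numpy().ravel()
        kde_e, kde_n = fit_reference_kdes(values_by_gene, refs)

        genes = sorted(values_by_gene)
        pvals = {}
        bfs = {}
        for gene in genes:
            vals = values_by_gene[gene]
            if len(vals) < 2:
                continue
            pvals[gene] = depletion_pvalue(vals, null_pool)
            bfs[gene] = bayes_factor(vals, kde_e, kde_n)
        p = pd.Series(pvals)
        fdr = pd.Series(
            multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index
        )
        bf = pd.Series(bfs)
        threshold = roc_threshold(bf, refs)
        scaled_bf = bf - threshold

        for gene in sorted(set(library.dual_genes()) | set(genes)):
            testable = gene in p.index
            rows.append(
                {
                    "gene": gene,
                    "cell_line": line,
                    "mean_single_lfc": float(np.mean(values_by_gene[gene]))
                    if gene in values_by_gene and len(values_by_gene[gene])
                    else np.nan,
                    "depletion_p": p.get(gene, np.nan),
                    "depletion_fdr": fdr.get(gene, np.nan),
                    "bayes_factor": bf.get(gene, np.nan),
                    "roc_threshold": threshold,
                    "scaled_bf": scaled_bf.get(gene, np.nan),
                    "testable": testable,
                    "essential": bool(
                        testable
                        and fdr[gene] < depletion_fdr_threshold
                        and scaled_bf[gene] > 0
                    ),
                }
            )
    return pd.DataFrame(rows)


def essential_lookup(calls: pd.DataFrame) -> dict[tuple[str, str], bool]:
    """(gene, cell_line) -> essential flag; untestable genes read as False."""
    return {
        (row["gene"], row["cell_line"]): bool(row["essential"])
        for _, row in calls.iterrows()
    }
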