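"""Simulation-based evaluation of the pipeline against known ground truth.

These helpers run the full analysis on synthetic screens and measure how well
it behaves where the answer is known: false-positive calibration on screens
with no injected interactions, and sensitivity/precision/effect-size recovery
on screens with a known fraction of synthetic-lethal pairs. They are used by
the package's own validation suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .essentiality import call_essentiality
from .gi import HitCallConfig, score_screen
from .preprocess import preprocess
from .qc import apply_exclusions, qc_screen
from .scaling import scale_lfc
from .simulate import SimConfig, TruthTable, simulate_screen


def analyse_simulated_screen(
    config: SimConfig, hit_config: HitCallConfig | None = None
) -> dict[str, Any]:
    """Simulate one screen and take it through every analysis stage in memory."""
    library, truth, counts = simulate_screen(config)
    pre = preprocess(counts)
    report = qc_screen(pre.lfc, counts.counts, library, counts.samples)
    retained, dropped_lines = apply_exclusions(report)
    out: dict[str, Any] = {
        "library": library,
        "truth": truth,
        "counts": counts,
        "qc": report,
        "retained": retained,
        "dropped_lines": dropped_lines,
    }
    if not retained:
        out["pair_results"] = None
        return out
    scaled, anchors = scale_lfc(pre.lfc[retained], library)
    ess = call_essentiality(scaled, library, counts.samples)
    out["scaled"] = scaled
    out["anchors"] = anchors
    out["essentiality"] = ess
    out["pair_results"] = score_screen(
        scaled, library, counts.samples, hit_config or HitCallConfig(), ess
    )
    return out


def count_veto_violations(pair_results: pd.DataFrame, truth: TruthTable) -> int:
    """Hits whose pair contains a truth-essential gene (must be zero)."""
    violations = 0
    for _, row in pair_results[pair_results["hit"]].iterrows():
        ess = truth.essential_genes(row["cell_line"])
        a, b = row["gene_pair"].split("|")
        if a in ess or b in ess:
            violations += 1
    return violations


def null_calibration(
    seeds: list[int],
    n_gene_pairs: int = 30,
    n_cell_lines: int = 1,
    ks_alpha: float = 0.01,
    **sim_overrides: Any,
) -> pd.DataFrame:
    """Per-seed calibration on screens with no injected interactions.

    Returns one row per screen: the (pair, line) hit rate, the KS test p-value
    for uniformity of the pair p-values, and the veto-violation count. Screens
    whose samples are all QC-excluded contribute a row of NaNs (nothing was
    screened, as when a cell line is dropped wholesale).
    """
    rows = []
    for seed in seeds:
        config = SimConfig(
            n_gene_pairs=n_gene_pairs,
            n_cell_lines=n_cell_lines,
            sl_fraction=0.0,
            seed=seed,
            **sim_overrides,
        )
        result = analyse_simulated_screen(config)
        res = result["pair_results"]
        if res is None or res.empty:
            rows.append((seed, np.nan, np.nan, np.nan, 0, 0))
            continue
        ks_p = stats.kstest(res["p_value"].to_numpy(), "uniform").pvalue
        rows.append(
            (
                seed,
                res["hit"].mean(),
                float(ks_p),
                float(ks_p >= ks_alpha),
                count_veto_violations(res, result["truth"]),
                len(res),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["seed", "hit_rate", "ks_p", "ks_uniform", "veto_violations", "n_tests"],
    )


def recovery_metrics(
    seed: int,
    n_gene_pairs: int = 100,
    n_cell_lines: int = 3,
    sl_fraction: float = 0.1,
    **sim_overrides: Any,
) -> dict[str, float]:
    """Hit-calling sensitivity/precision and GI effect-size recovery.

    Sensitivity is computed over truth-SL (pair, line) cells where neither
    member is individually essential -- pairs with an essential member are
    outside the method's search space by construction of the hit definition.
    Precision is over all called hits. The correlation is Pearson r between
    the estimated mean normalised GI and the injected GI across all
    (pair, line) cells.
    """
    config = SimConfig(
        n_gene_pairs=n_gene_pairs,
        n_cell_lines=n_cell_lines,
        sl_fraction=sl_fraction,
        seed=seed,
        **sim_overrides,
    )
    result = analyse_simulated_screen(config)
    res = result["pair_results"]
    truth = result["truth"]
    if res is None:
        raise RuntimeError("all samples excluded by QC; no recovery possible")

    tp = fp = fn = 0
    est, tru = [], []
    for _, row in res.iterrows():
        pair, line = row["gene_pair"], row["cell_line"]
        label = bool(truth.sl_labels[line].get(pair, False))
        ess = truth.essential_genes(line)
        a, b = pair.split("|")
        detectable = a not in ess and b not in ess
        if row["hit"] and label:
            tp += 1
        elif row["hit"] and not label:
            fp += 1
        elif not row["hit"] and label and detectable:
            fn += 1
        est.append(row["mean_norm_gi"])
        tru.append(float(truth.gi[line].get(pair, 0.0)))
    r = float(stats.pearsonr(est, tru).statistic)
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "gi_truth_pearson_r": r,
        "veto_violations": count_veto_violations(res, truth),
        "n_truth_sl": int(truth.sl_labels.to_numpy().sum()),
        "n_hits": int(res["hit"].sum()),
        "n_tests": len(res),
    }
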