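"""Synthetic dual-guide screens with known ground truth.

The generator reproduces the statistical structure the analysis pipeline
assumes: 6-8 guides per gene split across the two promoter positions, a full
A x B cross per gene pair in both orientations (18-32 dual constructs per
pair), every guide also emitted as a single paired with a safe-targeting
control, safe|safe constructs, essential and non-essential control genes,
technical replicates, and lineage-matched short-timepoint control samples.

Fitness and genetic-interaction effects are expressed directly on the scaled
log2-fold-change axis used downstream (0 = neutral, -1 = the essential-control
magnitude); construct abundance is lognormal and sequencing noise is negative
binomial with variance mu + mu^2 / dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .library import (
    CLASS_ESSENTIAL,
    CLASS_LIBRARY,
    CLASS_NON_ESSENTIAL,
    CLASS_SAFE,
    ROLE_CONTROL,
    ROLE_SCREEN,
    SAFE,
    CountsMatrix,
    LibraryAnnotation,
    pair_id,
    validate_samples,
)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of one simulated screen.

    ``reads_per_construct`` sets expected per-sample sequencing depth as
    depth = reads_per_construct * n_constructs. ``nb_dispersion`` is the
    negative-binomial size parameter k (variance = mu + mu^2/k).
    ``lfc_slope`` maps the scaled-effect axis onto raw LFCs; the default of 1
    makes downstream control-anchored scaling near-identity, keeping the truth
    table directly interpretable on the anchored axis.
    """

    n_gene_pairs: int = 30
    guides_per_gene: int = 6
    n_safe_guides: int = 8
    n_essential_controls: int = 10
    n_nonessential_controls: int = 10
    n_cell_lines: int = 3
    lineages: tuple[str, ...] = ("melanoma", "lung", "pancreas")
    replicates: int = 3
    reads_per_construct: float = 500.0
    nb_dispersion: float = 50.0
    abundance_logsd: float = 0.8
    guide_efficiency_sd: float = 0.15
    sl_fraction: float = 0.1
    gi_low: float = -2.0
    gi_high: float = -0.8
    sl_threshold: float = -0.5
    essential_gene_fraction: float = 0.1
    background_fitness_low: float = -0.4
    lfc_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 6 <= self.guides_per_gene <= 8:
            raise SimulationError("guides_per_gene must be in [6, 8]")
        for name in (
            "n_gene_pairs",
            "n_safe_guides",
            "n_essential_controls",
            "n_nonessential_controls",
            "n_cell_lines",
            "replicates",
        ):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be positive")
        if self.n_safe_guides < 2:
            raise SimulationError("need at least 2 safe guides for safe|safe constructs")
        for name in ("sl_fraction", "essential_gene_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.nb_dispersion <= 0 or self.abundance_logsd <= 0:
            raise SimulationError("nb_dispersion and abundance_logsd must be > 0")
        if self.guide_efficiency_sd < 0:
            raise SimulationError("guide_efficiency_sd must be >= 0")
        if self.gi_low > self.gi_high:
            raise SimulationError("gi_low must not exceed gi_high")
        if self.background_fitness_low > 0:
            raise SimulationError("background_fitness_low must be <= 0")

    def cell_lines(self) -> list[tuple[str, str]]:
        """(name, lineage) for each screened line, lineages assigned round-robin."""
        return [
            (f"LINE{i + 1:02d}", self.lineages[i % len(self.lineages)])
            for i in range(self.n_cell_lines)
        ]


@dataclass
class TruthTable:
    """Simulator ground truth on the scaled-LFC axis.

    ``fitness``: gene x line single-knockout effect (<= 0; essential controls
    exactly -1). ``gi``: pair x line interaction effect (negative = synthetic
    lethal). ``sl_labels``: True where gi <= sl_threshold.
    """

    fitness: pd.DataFrame
    gi: pd.DataFrame
    sl_labels: pd.DataFrame
    sl_threshold: float

    def fitness_of(self, gene: str, line: str) -> float:
        if gene == SAFE or gene not in self.fitness.index:
            return 0.0
        return float(self.fitness.loc[gene, line])

    def essential_genes(self, line: str) -> set[str]:
        col = self.fitness[line]
        return set(col.index[col <= -0.5])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.fitness.rename_axis("gene").to_csv(outdir / "truth_fitness.tsv", sep="\t")
        self.gi.rename_axis("gene_pair").to_csv(outdir / "truth_gi.tsv", sep="\t")
        self.sl_labels.rename_axis("gene_pair").to_csv(
            outdir / "truth_sl_labels.tsv", sep="\t"
        )


def _split_positions(guide_ids: list[str]) -> tuple[list[str], list[str]]:
    half = math.ceil(len(guide_ids) / 2)
    return guide_ids[:half], guide_ids[half:]


def simulate_library(config: SimConfig) -> LibraryAnnotation:
    """Build the construct catalogue. Deterministic given the config."""
    g = config.guides_per_gene
    pair_genes = [
        (f"GA{i + 1:03d}", f"GB{i + 1:03d}") for i in range(config.n_gene_pairs)
    ]
    ess_genes = [f"ESS{i + 1:02d}" for i in range(config.n_essential_controls)]
    non_genes = [f"NON{i + 1:02d}" for i in range(config.n_nonessential_controls)]

    def guides(gene: str) -> tuple[list[str], list[str]]:
        return _split_positions([f"{gene}_g{j + 1}" for j in range(g)])

    safes = [f"safe_{k + 1:02d}" for k in range(config.n_safe_guides)]
    safe_a, safe_b = _split_positions(safes)

    rows: list[tuple[str, str, str, str, str, str]] = []

    def add(ga: str, gene_a: str, gb: str, gene_b: str, cls: str) -> None:
        rows.append((f"{ga}|{gb}", ga, gene_a, gb, gene_b, cls))

    # duals: full A x B cross, both orientations
    for gx, gy in pair_genes:
        ax, bx = guides(gx)
        ay, by = guides(gy)
        for ga in ax:
            for gb in by:
                add(ga, gx, gb, gy, CLASS_LIBRARY)
        for ga in ay:
            for gb in bx:
                add(ga, gy, gb, gx, CLASS_LIBRARY)

    # singles: every gene-targeting guide paired with a safe guide in the
    # opposite position, cycling deterministically through the safe pool
    counter = 0
    gene_classes = [(gene, CLASS_LIBRARY) for gx, gy in pair_genes for gene in (gx, gy)]
    gene_classes += [(gene, CLASS_ESSENTIAL) for gene in ess_genes]
    gene_classes += [(gene, CLASS_NON_ESSENTIAL) for gene in non_genes]
    for gene, cls in gene_classes:
        a_guides, b_guides = guides(gene)
        for ga in a_guides:
            add(ga, gene, safe_b[counter % len(safe_b)], SAFE, cls)
            counter += 1
        for gb in b_guides:
            add(safe_a[counter % len(safe_a)], SAFE, gb, gene, cls)
            counter += 1

    # safe|safe cross
    for sa in safe_a:
        for sb in safe_b:
            add(sa, SAFE, sb, SAFE, CLASS_SAFE)

    frame = pd.DataFrame(
        rows,
        columns=["construct_id", "guide_a_id", "gene_a", "guide_b_id", "gene_b", "control_class"],
    )
    return LibraryAnnotation(frame)


def simulate_truth(config: SimConfig, library: LibraryAnnotation) -> TruthTable:
    """Draw per-line single-gene fitness and pair GI effects."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lines = [name for name, _ in config.cell_lines()]
    pair_genes = library.dual_genes()
    ess_ctrl = sorted(set(library.single_gene_of(library.control_single_ids(CLASS_ESSENTIAL))))
    non_ctrl = sorted(set(library.single_gene_of(library.control_single_ids(CLASS_NON_ESSENTIAL))))

    genes = pair_genes + ess_ctrl + non_ctrl
    fitness = pd.DataFrame(0.0, index=genes, columns=lines)
    fitness.loc[ess_ctrl, :] = -1.0

    # library genes carry mild knockout fitness costs (shared across lines),
    # giving the expected-FC axis the genuine spread real libraries of
    # candidate SL genes show; a fraction are outright essential
    background = rng.uniform(config.background_fitness_low, 0.0, size=len(pair_genes))
    fitness.loc[pair_genes, :] = background[:, None]
    n_ess = int(round(config.essential_gene_fraction * len(pair_genes)))
    if n_ess:
        chosen = rng.choice(pair_genes, size=n_ess, replace=False)
        fitness.loc[sorted(chosen), :] = -1.0

    pairs = sorted(library.gene_pairs)
    gi = pd.DataFrame(0.0, index=pairs, columns=lines)
    n_sl = int(round(config.sl_fraction * len(pairs)))
    for line in lines:
        if n_sl:
            hit_pairs = rng.choice(pairs, size=n_sl, replace=False)
            gi.loc[sorted(hit_pairs), line] = rng.uniform(
                config.gi_low, config.gi_high, size=n_sl
            )
    sl_labels = (gi <= config.sl_threshold) & (gi < 0)
    return TruthTable(fitness=fitness, gi=gi, sl_labels=sl_labels, sl_threshold=config.sl_threshold)


def control_line_name(lineage: str) -> str:
    return f"CAS9NULL_{lineage}"


def _sample_metadata(config: SimConfig) -> pd.DataFrame:
    rows = []
    for lineage in dict.fromkeys(lineage for _, lineage in config.cell_lines()):
        line = control_line_name(lineage)
        for r in range(1, config.replicates + 1):
            rows.append((f"{line}_R{r}", line, lineage, r, ROLE_CONTROL, 7))
    for line, lineage in config.cell_lines():
        for r in range(1, config.replicates + 1):
            rows.append((f"{line}_R{r}", line, lineage, r, ROLE_SCREEN, 28))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "cell_line", "lineage", "replicate", "role", "day"]
    )
    return validate_samples(meta)


def construct_phenotypes(
    library: LibraryAnnotation, truth: TruthTable, jitter: pd.Series
) -> pd.DataFrame:
    """Scaled-axis phenotype phi per (construct, line).

    phi = fitness(geneA) + fitness(geneB) + gi(pair) + per-guide efficiency
    jitter for each gene-targeting guide; safe guides contribute nothing.
    """
    frame = library.frame
    lines = truth.fitness.columns
    phi = pd.DataFrame(0.0, index=frame.index, columns=lines)
    for line in lines:
        fit = truth.fitness[line]
        fa = frame["gene_a"].map(fit).fillna(0.0).to_numpy()
        fb = frame["gene_b"].map(fit).fillna(0.0).to_numpy()
        gi = np.zeros(len(frame))
        dual_mask = (frame["category"] == "dual").to_numpy()
        if dual_mask.any():
            keys = [
                pair_id(a, b)
                for a, b in zip(
                    frame.loc[dual_mask, "gene_a"], frame.loc[dual_mask, "gene_b"]
                )
            ]
            gi[dual_mask] = truth.gi[line].reindex(keys).fillna(0.0).to_numpy()
        ja = (
            frame["guide_a_id"].map(jitter).fillna(0.0).to_numpy()
            * (frame["gene_a"] != SAFE).to_numpy()
        )
        jb = (
            frame["guide_b_id"].map(jitter).fillna(0.0).to_numpy()
            * (frame["gene_b"] != SAFE).to_numpy()
        )
        phi[line] = fa + fb + gi + ja + jb
    return phi


def simulate_counts(
    library: LibraryAnnotation, truth: TruthTable, config: SimConfig
) -> CountsMatrix:
    """Draw the raw counts matrix: lognormal abundance, NB sequencing noise."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    frame = library.frame
    n = len(frame)

    gene_guides = sorted(
        set(frame.loc[frame["gene_a"] != SAFE, "guide_a_id"])
        | set(frame.loc[frame["gene_b"] != SAFE, "guide_b_id"])
    )
    jitter = pd.Series(
        rng.normal(0.0, config.guide_efficiency_sd, size=len(gene_guides)),
        index=gene_guides,
    )
    phi = construct_phenotypes(library, truth, jitter)

    abundance = rng.lognormal(
        mean=math.log(config.reads_per_construct), sigma=config.abundance_logsd, size=n
    )
    depth = config.reads_per_construct * n
    meta = _sample_metadata(config)

    k = config.nb_dispersion
    cols = {}
    for sid in meta.index:
        row = meta.loc[sid]
        if row["role"] == ROLE_CONTROL:
            mu = abundance
        else:
            mu = abundance * np.exp2(phi[row["cell_line"]].to_numpy() * config.lfc_slope)
        mu = mu * (depth / mu.sum())
        cols[sid] = rng.negative_binomial(k, k / (k + mu))
    counts = pd.DataFrame(cols, index=frame.index)
    return CountsMatrix(counts=counts, library=library, samples=meta)


def simulate_screen(config: SimConfig) -> tuple[LibraryAnnotation, TruthTable, CountsMatrix]:
    """Library, truth and counts in one call (the usual entry point)."""
    library = simulate_library(config)
    truth = simulate_truth(config, library)
    counts = simulate_counts(library, truth, config)
    return library, truth, counts


def write_simulation(
    config: SimConfig,
    outdir: str | Path,
) -> tuple[LibraryAnnotation, TruthTable, CountsMatrix]:
    """Run the simulator and write library/counts/samples/truth TSVs."""
    from .library import write_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library, truth, counts = simulate_screen(config)
    library.write(outdir / "library.tsv")
    write_counts(counts, outdir / "counts.tsv")
    counts.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth.write(outdir)
    pd.Series(asdict(config)).to_json(outdir / "sim_config.json")
    return library, truth, counts
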