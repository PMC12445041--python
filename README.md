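# slscreen

Analysis of dual-guide (combinatorial) CRISPR/Cas9 screens for synthetic-lethal
gene pairs: count normalisation, replicate quality control, control-anchored
scaling, single-gene essentiality calling, Bliss/Loess genetic-interaction
scoring with batch variance smoothing, statistical hit calling, and
context-dependence analyses — plus a synthetic-screen generator with known
ground truth so the whole pipeline is testable end to end.

## Who this is for

Groups running pooled dual-guide screens in cancer cell line panels: each
lentiviral construct expresses two gRNAs from tandem promoters, so a library
of gene-pair constructs (plus gene|safe "singles", safe|safe controls, and
essential / non-essential control genes) measures single- and double-knockout
fitness in one experiment. The pipeline starts from a construct x sample
counts matrix (read-level quantification is out of scope) and ends with a
per-cell-line table of gene-pair genetic-interaction scores and hit calls.

## The model

Counts are normalised to reads per 10 million with a pseudocount of 5, and
log2 fold changes (LFC) are taken against lineage-matched early-timepoint
Cas9-null control samples. Replicates are excluded when the null-normalised
mean difference `NNMD = (muE − muNE) / sigmaNE` (essential vs non-essential
single constructs) exceeds −2 or the mean Spearman correlation against
sibling replicates falls below 0.55. Each retained sample is anchored so that
`median(safe|safe) = 0` and `median(essential singles) = −1`.

The genetic interaction score follows the Bliss independence model: in log2
space the expected fold change of a dual construct is additive,

    E[g1g2] = FC(g1) + FC(g2),

with each guide's fold change measured from its own single (guide + safe)
construct after centring on the singles median. A Loess regression of
observed on expected fold change absorbs smooth systematic deviations; the
residual is the guide-level GI score. Duals are ranked by expected FC and
binned into batches of 200; each residual is divided by its batch's residual
standard deviation, giving the normalised GI score `norm_gi` (a
variance-smoothed, z-like quantity; negative = stronger-than-additive
depletion). Per cell line, a pair's pooled `norm_gi` values are compared to
the line's overall median with a pooled-variance t-test and BH correction. A
pair is a synthetic-lethal **hit** iff

    mean(norm_gi) < −0.5  AND  FDR < 0.01  AND  secondary filter significant
    AND neither member gene individually essential,

where essentiality needs both a depletion FDR < 0.05 (rank-sum against the
safe|safe null) and a positive ROC-scaled Bayes factor (KDE log2 likelihood
ratio of essential vs non-essential reference pools). Hits are summarised
across the panel as strong (hit in > 50% of lines), context-dependent, or
never hit, and can be related to cancer type (one-way ANOVA), mRNA abundance
(Pearson correlation with TPM), and normal/tumour expression (presence =
TPM > 1).

## Worked example

Simulate a small 3-line screen (25 gene pairs, 10% with injected
interactions) and run every stage:

```sh
slscreen simulate --seed 7 --n-gene-pairs 25 --outdir demo/sim
slscreen run --library demo/sim/library.tsv --counts demo/sim/counts.tsv \
             --samples demo/sim/samples.tsv --outdir demo/out
```

which prints

```json
{
  "hits_per_line": {"LINE01": 1, "LINE02": 1, "LINE03": 1},
  "n_pairs": 25,
  "strong_hits": 0,
  "context_dependent": 3,
  "never_hit": 22
}
```

The called hits (from `demo/out/pair_results.tsv`):

```
  gene_pair cell_line  mean_norm_gi          fdr
GA014|GB014    LINE01     -1.525655 1.241900e-70
GA002|GB002    LINE02     -2.029421 3.715058e-80
GA007|GB007    LINE03     -1.528085 3.830879e-72
```

The simulator injected six (pair, line) interactions. Three are recovered
above. `GA022|GB022` carried an interaction in two lines but GA022 is
individually essential in this simulation, so the pair is vetoed — exactly
the behaviour the hit rule is designed to have, since a "synthetic lethal"
call is meaningless when one member kills on its own. `GA003|GB003` shows a
strong GI (mean norm_gi −3.5) but GA003 is moderately depleting and crossed
the essentiality caller's conservative threshold, so it is vetoed too; the
veto trades a little sensitivity for the guarantee that no hit contains an
essential gene.

Each stage writes its table under the output directory (`lfc.tsv`,
`qc_report.tsv`, `scaled_lfc.tsv`, `essentiality.tsv`, `pair_results.tsv`,
`pair_summary.tsv`, `context_anova.tsv`, ...) and `manifest.json` records the
configuration, seed and per-stage counts. The same stages are available as a
library (`slscreen.preprocess`, `slscreen.qc`, `slscreen.scaling`,
`slscreen.essentiality`, `slscreen.gi`, `slscreen.context`) on pandas
DataFrames.

## Limitations

Read-level quantification (demultiplexing, guide-pair matching) is upstream
of this package; counts are its input. Copy-number correction of GI scores is
not attempted. The secondary ("Bassik-style") filter and the essentiality
scorers are deliberately simple, deterministic stand-ins that preserve the
published decision rules' structure; externally computed essentiality tables
can be substituted for real-data runs. See `docs/methods.md` for the model,
parameter defaults, and known caveats — including the within-pair correlation
of guide-level GI scores, which makes pair-level p-values anti-conservative
(ranking and the conjunctive hit rule are unaffected).
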