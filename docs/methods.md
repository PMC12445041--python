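# Methods

This note documents the statistical model behind `slscreen`, the defaults and
why they were chosen, what the synthetic-screen generator does and does not
emulate, and the numerical and design choices a maintainer should know about.

## Screen structure and data model

A dual-guide library expresses two gRNAs per lentiviral construct from tandem
promoters (positions A and B). Constructs are *duals* (two gene-targeting
guides), *singles* (one gene-targeting guide plus one safe-targeting guide —
a guide cutting a site with no known function, controlling for double-strand
break toxicity), or *safe|safe*. Known essential and non-essential control
genes are included as singles. Gene pairs are unordered; both orientations
(geneA|geneB and geneB|geneA) contribute constructs to the same pair.
Libraries, counts and sample metadata are plain TSV; the library file's row
order is authoritative.

## Preprocessing

After removing any user-flagged artefact constructs, counts are normalised as
`(raw + 5) / total_raw_in_sample × 1e7` (reads per 10 million), with the
per-sample total computed after the exclusion so that flagged high-count
artefacts cannot distort it. Constructs below 20 reads-per-10M in **every**
control sample are dropped. LFCs are `log2(norm) − log2(mean of mapped
control samples)`, where a screen sample's controls default to the
early-timepoint Cas9-null samples of its lineage (the mapping is
configurable per cell line). The arithmetic mean of normalised counts (not of
logs) is used as the baseline. The pseudocount guarantees every LFC is
finite.

## Quality control

Per screen replicate, on unscaled LFCs (QC precedes scaling):

* **NNMD** `(muE − muNE) / sigmaNE` over essential / non-essential control
  singles, with the sample (n−1) standard deviation. More negative = better
  separation.
* **R**, the mean Spearman correlation against sibling replicates of the same
  line. A single-replicate line has undefined R and is flagged, not failed.
  (The aggregation across siblings — mean rather than minimum — is a choice;
  the gate value applies per sample either way.)
* **Gini index** of raw counts, reported descriptively for library skew.

A replicate is excluded iff `NNMD > −2` or `R < 0.55`, strict inequalities;
boundary values are retained. Cell lines losing all replicates are dropped
with a logged reason. Exclusion is idempotent.

## Control-anchored scaling

Each retained sample's LFC vector x is mapped affinely:
`scaled(x) = (x − m_ss) / (m_ss − m_se)` with `m_ss` the safe|safe median and
`m_se` the essential-singles median, putting those anchors at exactly 0 and
−1. `m_se >= m_ss` (no depletion signal) is an error. Scaling is per sample
by default so replicate-level pooling downstream is on a common axis; a
`per='line'` switch pools a line's replicates for shared anchors instead.

## Essentiality calling

A gene is essential in a line iff both of two independent scorers agree —
depletion FDR < 0.05 AND ROC-scaled Bayes factor > 0:

* depletion: one-sided Mann-Whitney rank-sum of the gene's single-construct
  scaled LFCs (pooled over retained replicates) against all safe|safe
  construct values, BH-corrected across genes within the line;
* Bayes factor: Gaussian KDEs (Scott bandwidth) are fitted to the pooled
  single-construct LFCs of reference essential and non-essential genes
  (reference pools must hold at least 20 values); `BF = Σ log2(fE(x)/fN(x))`
  over the gene's values, densities floored at 1e−12. The threshold
  subtracted from BF maximises Youden's J on the reference genes; ties go to
  the smallest BF achieving the maximum and the cut is the midpoint to the
  next smaller observed BF.

These are deliberately lightweight deterministic stand-ins that preserve the
conjunction decision rule used with dedicated tools on real data (a
negative-selection FDR and a scaled Bayes factor); bootstrap resampling is
omitted, so results are reproducible bit-for-bit. Externally computed tables
can replace them for real-data runs. The conjunction is conservative: it
sometimes flags moderately depleting genes (single-gene fitness ~ −0.3 to
−0.5), which costs hit-calling sensitivity on their pairs but never lets an
essential gene into a hit.

## GI scoring

Within each scaled sample:

1. **Centring** — subtract the median scaled LFC of all single constructs.
2. **Bliss expectation** — for each dual, `expected = FC(g1) + FC(g2)` where
   a guide's FC is the mean centred value of the single constructs carrying
   that exact guide in the same position (falling back to the other position,
   then to the gene-level single mean). Additivity in log space is the Bliss
   independence assumption; deviation from it is the interaction. Duals with
   an unmatchable guide are excluded and logged.
3. **Loess** — observed is regressed on expected (tricube weights, local
   linear, span 0.75 by default, three robustifying iterations); the residual
   is the GI score. The span is config-exposed; residuals depend mildly on it.
4. **Variance smoothing** — duals are sorted by expected FC into contiguous
   batches of 200 (a trailing batch shorter than batch_size/4 merges into its
   predecessor to avoid unstable variance estimates); `norm_gi = residual /
   sqrt(batch sample variance)`. Within-batch variance of `norm_gi` is 1 by
   construction; this flattens the strong heteroscedasticity (residual spread
   grows with depletion strength).

Per cell line, `norm_gi` is pooled over both orientations and all retained
replicates. With `m0` the line's overall median, pooled within-pair variance
`s² = Σ_p Σ_i (x_pi − x̄_p)² / (N − K)` over the K pairs with at least 3
values, the pair statistic is `t_p = (median_p − m0) / (s / √n_p)` on N − K
degrees of freedom, two-sided, BH-corrected across pairs. A one-sample
per-pair t is available as a config switch.

**Secondary filter** (the published analyses apply an additional
Bassik-method significance gate whose procedure is not specified; this
package's stand-in is): Welch's t between the pair's `norm_gi` values and a
null pool of safe|safe constructs run through the same variance machinery,
significant iff p < 0.05 and the pair mean lies below the null mean. The
null pool's residuals are taken about the safe|safe population median rather
than the Loess curve: because the expected-FC axis carries single-construct
measurement noise, the fitted curve at any single true location is offset by
errors-in-variables attenuation, and anchoring the pool to the curve would
shift it ~0.8 SD off the scores of interaction-free duals, making the filter
vacuous. Anchoring at the pool's own centre keeps it exchangeable in
location; its spread slightly understates the dual residual spread (safe|safe
scores carry no singles-estimation noise), which the pair-side variance
dominates in the Welch statistic. The filter can be disabled.

**Hit rule** — per (pair, line): `mean_norm_gi < −0.5` AND `FDR < 0.01` AND
secondary filter significant AND neither member essential (untestable genes
count as non-essential, logged). Cross-line summaries label pairs strong
(hit in more than half the screened lines), context-dependent (hit at least
once but in no more than half), or never hit.

### Known caveat: within-pair correlation and p-value calibration

Each guide has exactly one single construct, so its FC estimate carries full
construct-level noise, and that estimate enters the Bliss expectation of
every dual carrying the guide. Guide-level GI scores within a pair are
therefore positively correlated (measured r ≈ 0.4 between duals sharing a
guide under the default simulation), and the pooled t — whose SE assumes
independent values — is over-dispersed by roughly 3.5× at the pair level.
Pair p-values are consequently anti-conservative and should be read as
ranking scores, not calibrated tail probabilities. The hit rule remains
well-behaved because it is a conjunction: on simulated null screens the
(pair, line) hit rate stays at ~1% and recovery of injected effects is
essentially unaffected. This is structural (independent of sequencing depth
or dispersion) and applies equally to the published construction the
implementation follows.

## Context analyses

* **ANOVA by cancer type** — each pair's per-line mean `norm_gi` (including
  non-hit lines where defined) is the response in a one-way ANOVA on lineage
  (a type II ANOVA with a single factor reduces to this); pairs need at least
  two lineages with two or more lines each; BH across pairs, read at FDR 10%.
* **Expression correlation** — Pearson r between each member's TPM and the
  pair's per-line GI, for pairs hit in at least `min_hit_lines` lines
  (default 1; the stricter "three or more lines" gate is a config switch),
  requiring 5+ lines and non-degenerate expression; BH across all tests.
* **Hit frequency vs strength** — per pair, the number of hit lines and the
  median GI over those lines, plus their global Pearson correlation (NaN when
  degenerate).
* **Per-line ranking** — dense rank of each line's hits by mean GI ascending,
  ties broken by FDR then pair name.
* **Expression positioning** — a hit pair is flagged when both members exceed
  1 TPM in *every* supplied normal-tissue sample and exactly one member is at
  or below 1 TPM in *at least one* tumour sample (quantifiers stated because
  "ubiquitous" and "loss" need them).

## Synthetic screens

The generator reproduces the structures the analysis assumes: 6–8 guides per
gene split across promoters (18–32 duals per pair from the full A×B cross in
both orientations), one single per guide with cycling safe partners, a
safe-guide cross of safe|safe constructs, essential/non-essential control
genes, technical triplicates, and one lineage-matched Cas9-null control line
per lineage sequenced at day 7.

Truth is expressed directly on the anchored axis (0 neutral, −1 essential
magnitude; the raw-to-scaled slope defaults to 1 so anchoring is
near-identity and the truth table stays interpretable). Defaults, chosen once
as the conditions the simulated study represents:

| parameter | default | rationale |
| --- | --- | --- |
| replicates | 3 | technical triplicate screens |
| reads per construct | 500 | well-sequenced regime at desk scale (real screens run ~1,700; the dispersion term dominates noise well before depth does) |
| NB dispersion k | 50 | variance = mu + mu²/k; within the standard range for screen counts and reproduces the QC profile real passing screens show (NNMD ≈ −3.5, replicate Spearman ≈ 0.65, none near the gates) |
| abundance lognormal sdlog | 0.8 | implies Gini ≈ 0.45, matching libraries with Gini < 0.5 |
| guide efficiency jitter sd | 0.15 | per-guide, shared across a guide's constructs and lines (correlated error) |
| essential library-gene fraction | 0.10 | matches the observed share of screened pairs lost to an individually essential member (~95/472 pairs ⇒ ~10% of genes) |
| background fitness | U(−0.4, 0) per gene | knockouts show a continuum of mild fitness costs; also gives the expected-FC axis genuine spread, without which the Loess has no trend to model |
| injected GI | U(−2.0, −0.8) in 10% of pairs per line | emulates the strength range hit pairs show |

Counts are negative binomial around `abundance × 2^φ` (screen) or
`abundance` (control), with `φ = fitness(A) + fitness(B) + gi(pair) + guide
jitter`, sample means rescaled to the target depth (sequencing re-samples the
pool, so depleted constructs free reads for the rest — the anchoring handles
the induced shift). Same seed ⇒ bit-identical output; library, truth and
counts consume independent seed streams.

**What the generator does not emulate:** viral recombination and guide
swapping, MOI and infection bottlenecks, copy-number effects on cutting
toxicity, per-line biological heterogeneity of single-gene fitness
(background fitness is shared across lines), pan-lethal versus private
interaction structure (per-line interaction injection is independent), and
batch/plate effects. Passing the simulation-based tests therefore shows the
statistical machinery is correct and calibrated under the stated noise model,
not that real screens are free of these additional artefacts.

## Validation problem sizes

The package's own validation (test suite and `scripts/acceptance.py`) uses
30-pair single-line screens for null calibration (200 seeds) and a 100-pair,
3-line, 10%-synthetic-lethal screen for recovery — sizes chosen so a full
validation runs in about a minute on one CPU while every stage operates well
above its minimum data requirements (≥500 duals per sample, 3+ Loess batches).

## Numerical choices and degenerate inputs

Ties in Spearman use average ranks. Batch assignment sorts with a stable
mergesort so equal expected values resolve by library order. The Loess uses
`delta = 0.001 × range` for interpolation speed. KDE densities are floored at
1e−12 before ratios. Zero batch variance, zero-total samples, all-zero count
vectors, empty anchor or reference sets, inverted anchors, and single-class
ROC inputs are hard errors with named offenders; genes without single
constructs are flagged untestable rather than scored; pairs with fewer than
three GI values are excluded and logged.
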