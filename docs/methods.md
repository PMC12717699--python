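# Methods

`senindex` quantifies cellular senescence per cell from a directional gene
signature, aggregates it into a per-patient index, and searches for the
percentile thresholds at which that index best discriminates immunotherapy
responders (R) from non-responders (NR). This note documents the models,
the defaults and why, the numerical conventions, and what the synthetic
cohorts do and do not demonstrate.

## Per-cell signature score

For each cell, genes are ranked by decreasing expression with average ties.
Ranks beyond `max_rank` (default 1500) are set to `max_rank + 1`, so very
lowly expressed or undetected genes contribute a fixed floor instead of a
depth-dependent penalty. For a signature direction with $n$ matched genes
and capped ranks $r_i$,

$$U = \sum_i r_i - \frac{n(n+1)}{2}, \qquad s = 1 - \frac{U}{n \cdot r_{max}}$$

which is the Mann–Whitney U statistic of the signature genes against the
rest of the transcriptome, rescaled so that a set occupying the top $n$
ranks scores 1. The combined directional score is $s_{up} - s_{down} \in
[-1, 1]$; a direction with no matched genes contributes 0. The subtraction
(rather than a floor at 0) preserves the depletion signal from genes
expected to be down-regulated in senescence, which dominate the signature
(67 of 100 genes in the packaged placeholder's proportions); a
`floor_at_zero` option exists for users who want a pure enrichment readout.

Because the score depends on expression only through within-cell ranks, it
is invariant to any strictly monotone per-cell transform — counts, TPM and
log-TPM give identical scores — and insensitive to sequencing depth. The
`max_rank` cap bounds the influence of the unexpressed tail; with fewer
genes than `max_rank` the cap is inert (logged). `score_by_celltype` scores
each cell-type stratum separately so stratum diagnostics and all downstream
percentile logic share one grouping; with a per-cell rank construction the
numbers equal unstratified scoring.

## QC

Applied to expression input before scoring, in this order:

1. **Detected genes**: cells with fewer than 1000 nonzero genes are dropped
   (strict `<`; exactly 1000 is kept).
2. **Mitochondrial genes** (`MT-` prefix, case-insensitive) are removed
   from the gene axis — the mitochondrial compartment is excluded from
   ranking entirely rather than used as a per-cell fraction filter.
3. **TPM / log transform**: with gene lengths (kb), standard TPM; without,
   a counts-per-million surrogate (each cell scaled to $10^6$), appropriate
   for UMI data and logged as a surrogate. Working layer is
   $\log_2(\mathrm{TPM}+1)$.
4. **Housekeeping expression**: cells whose mean over a housekeeping panel
   is not strictly above 2.5 on the log layer (equivalently $2^{2.5}-1$ in
   TPM) are dropped. A 20-gene default panel ships with the package
   (`data/housekeeping_default.txt`); any list can be supplied.

## Dysfunction filtering

Exhaustion and senescence are distinct dysfunctional states. To stop
exhausted-but-not-senescent cells from inflating the low-senescence pool,
two exclusion rules run before index computation, stratified by cell type:

* **Joint percentile filter** — remove cells with senescence strictly below
  the stratum's 20th percentile *and* exhaustion strictly above its 80th
  percentile. Under independent null scores this removes ≈ 4% of cells.
  Strata under 5 cells are skipped with a warning.
* **Cluster exclusion** — given externally supplied cluster labels, drop
  clusters whose median senescence is below the cell type's 25th percentile
  and median exhaustion above its 75th. The quartile criteria are exposed
  as parameters because "low" and "high" admit no single canonical value.

`state_labels` assigns mutually exclusive labels (senescent-enriched /
exhausted / anergic / proliferative-reference / other) by the highest
percentile rank among the available score columns, with "other" when no
score exceeds its column's 80th percentile. That gate caps how many cells
can carry a state label, so label-recovery experiments use planted
fractions below 20% per state.

## Patient index and threshold search

Within a cell type, two percentile cutoffs over the *pooled* scores (all
patients together) classify cells as high (score ≥ upper cutoff) or low
(score ≤ lower cutoff). Pooling is deliberate: per-patient percentiles
would make every patient's high/low fractions identical by construction
and destroy discrimination. Percentiles use the linear-interpolation
convention everywhere; boundary ties are included (≥ / ≤). For a patient
with H high, L low and T total cells,

$$\mathrm{index} = \frac{H/T + ps}{L/T + ps}, \qquad ps = 0.01,$$

the pseudocount keeping the ratio finite when L = 0 (maximum 101 when every
cell is high). Patients contribute only with strictly more than
`min_cells = 10` cells in the stratum.

The grid search evaluates upper percentiles 55–95 and lower percentiles
5–45 in steps of 5 (81 pairs). Each pair yields patient indices and an ROC
AUC with NR as the positive class (higher senescence index ⇒ non-response).
AUC is computed as the Mann–Whitney probability (ties half-credited). The
selected pair maximizes AUC; ties break toward the pair retaining the
larger fraction of classified cells $\sum(H+L)/\sum T$ (a soft version of
"retain most cells", since no hard retention threshold is canonical), then
more patients, then lexicographically. At the optimum, the Youden cutoff
maximizes $J = \text{sens} + \text{spec} - 1$ over midpoints between
consecutive distinct index values (±∞ endpoints); J-ties break toward
higher specificity, then the smaller cutoff.

This is in-sample selection over 81 correlated candidates. The best AUC
therefore carries selection optimism — on null cohorts the mean selected
AUC sits near 0.58, not 0.50 — and `n_pairs_searched` is always part of
the result so readers can account for it. No cross-validated AUC is
offered. An optional patient-level bootstrap CI (seeded) is provided as a
reporting aid.

## Comparative statistics

* **Wilcoxon rank-sum** (R vs NR scores) delegates to
  `scipy.stats.mannwhitneyu`: exact when $n_x + n_y \le 12$ and tie-free,
  otherwise normal approximation with tie and continuity corrections.
  Per-cell-type comparisons report nominal and Benjamini–Hochberg adjusted
  p side by side.
* **Shapiro–Wilk gate**: two-group comparisons route to a t-test unless
  either group's Shapiro p < 0.05, then to the rank test.
* **Timepoint trend**: scores are averaged within each distinct timepoint
  and an OLS slope with t-test p is fit over the timepoint means, so
  unequal cell counts per timepoint do not dominate.
* **Segmented regression** fits $y = a + b_1 x + (b_2 - b_1)(x - bp)_+$ by
  exhaustive SSE minimization over a candidate grid (default: the interior
  observed x-values plus a 200-point fill). Exhaustive search was chosen
  over iterative breakpoint updating for determinism and oracle
  checkability. When SSE ties within numerical tolerance — noiseless data
  only set-identify a kink between two sampled x-values — a breakpoint at
  an observed timepoint is preferred, then the smallest candidate. Fits
  improving on the single line by < 1% SSE are flagged unidentifiable.
* **Pre-ranked GSEA**: genes sorted by decreasing metric (e.g. per-gene
  Pearson correlation with age via `rank_by_correlation`); hits advance the
  running sum by $|m|^p / \sum_{hits} |m|^p$ (default weight $p = 1$;
  $p = 0$ exposed for the analytic limits), misses retreat by
  $1/(N - n_{set})$; ES is the signed maximum deviation. The null is
  size-matched random gene sets (seeded) rather than phenotype permutation,
  because the intended age series are far too small to permute; NES divides
  by the mean |ES| of same-sign nulls and $p = (1 + k)/(1 + n_{same})$ so
  it is never exactly 0. Up and down sets are always tested separately.

## Functional-structure clustering

The binary gene × term association matrix is an input file (term retrieval
from GO/KEGG is out of scope; database versions drift). PCA retains the
smallest leading set of components explaining > 90% variance; k-means
(seeded, 10 restarts) over the k range selects k by silhouette, with the
inertia (elbow) curve emitted for inspection rather than folded into an ad
hoc tie rule; a Ward dendrogram over the same reduced matrix is returned
(Newick export available). Genes annotated across clusters are re-assigned
to the cluster holding their highest cumulative association score
(term-level scores if provided, else binary counts), ties broken by
cluster size then index.

## Synthetic cohorts

Defaults mirror the targeted study design: 48 patients (responder fraction
18/48), CD8+ and CD4+ T-cell strata, negative-binomial cell counts per
patient (mean 100, size 10). Per-patient senescent fractions are
Beta-distributed around the response-group mean (concentration 30) so
patients are heterogeneous. Effect presets fix (R, NR) senescent fractions
at (0.15, 0.15) "null", (0.10, 0.20) "weak", (0.05, 0.35) "strong" —
chosen once as a no-signal control, a marginal effect, and a clearly
separable effect of the kind the method is meant to detect.

Score mode draws baselines from Beta(2, 8) (mean 0.2), shifts senescent
cells up by `score_effect` (default 0.30, clipped to [0, 1]), and gives the
exhausted subpopulation (default 10%, disjoint from senescent cells) high
exhaustion (Beta(6, 4)) and low senescence (Beta(1.5, 13.5)). Expression
mode draws negative-binomial counts (size 2) with lognormal per-gene means,
multiplies planted up-genes by `up_effect` (4) and divides down-genes by
`down_effect` (4) in senescent cells, keeps housekeeping genes constitutive
(mean 50), includes a few `MT-` genes, and scales a configurable fraction
of cells to a tiny library so they fail the detected-genes QC.

The generator emits truth labels with every cohort, so every accuracy claim
in the test suite is computed against known ground truth. It does not
simulate doublets, ambient RNA, batch structure or realistic gene–gene
correlation; passing results demonstrate the statistical machinery, not
robustness to those artifacts. Test and acceptance problem sizes (one cell
type stratum, 100 replicates per preset, oracle checks on matrices up to
50 × 20) were chosen as the smallest scales at which the checked properties
are informative.

## Known limitations

* The packaged signature is a synthetic structural placeholder (33 up / 67
  down invented symbols); authoritative senescence/exhaustion/anergy gene
  lists must be supplied by the user from the original publications'
  supplements.
* Threshold selection is in-sample; reported best AUCs are optimistic and
  should be validated on held-out cohorts.
* Clustering for cluster-level exclusion, cell-type annotation and batch
  integration are upstream responsibilities; the pipeline consumes their
  labels.
* Without gene lengths, TPM is counts-per-million; QC thresholds defined in
  TPM units then shift meaning for length-biased protocols.
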