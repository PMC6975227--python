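# Methods

This note documents the models implemented in `ceranet`, the parameters that
matter, the design choices made where the procedure was genuinely open, and
what the synthetic cohorts do and do not establish about real data.

## Differential expression

Two branches, chosen per molecule by its zero fraction among tumor samples
after a prefilter on normal samples.

* **Prefilter** (`prefilter_by_normal_zeros`, default 0.10): molecules with
  more than 10% zeros among normal samples are eliminated. Rationale: a
  molecule undetected in normal tissue gives no usable baseline.
* **Routing** (`route_by_tumor_zeros`, default 0.30): strictly fewer than
  30% tumor zeros → continuous branch; otherwise binary. The boundary goes
  to the binary branch (the continuous rule is a strict "<").
* **Continuous branch**: Welch's unequal-variance t-test (robust to the
  extreme tumor/normal imbalance these cohorts have), fold change = ratio of
  raw arithmetic means with a 1e-9 pseudo-count entering the denominator
  only when it is exactly zero (rare after the prefilter). Calls require
  FC > 2 or FC < 0.5 *and* BH-adjusted p < 0.01. Molecules with zero
  variance in both arms and equal means get p = 1 and are never called.
* **Binary branch**: ON means value > 0. Direction is ON-in-cancer when
  on_freq_tumor ≥ 2 × on_freq_normal (a tie at exactly 2× counts as ON);
  significance from a two-sided Fisher's exact test (probability-ordering
  convention) at BH FDR < 0.01. Note an asymmetry inherited from the
  filtering scheme itself: a molecule that survives the 10% normal-zero
  prefilter has on_freq_normal ≥ 0.9, so the ON-in-cancer direction is
  essentially unreachable and binary calls are OFF-in-cancer in practice.
* **BH scope**: adjusted separately per (branch × RNA class) by default,
  mirroring per-class reporting conventions; `per_class=False` pools the
  classes within a branch. Whether pooled or per-class adjustment is "right"
  is not decidable from the procedure's description; per-class is the
  documented default.

## Target filtering

Candidate sites come from an external table or from a deliberately simple
surrogate predictor: one candidate per exact occurrence of the reverse
complement of the miRNA seed (positions 2–8, a 7-mer) in the searched region
(3'UTR for mRNA, full transcript for lncRNA). Full alignment/energy scoring
of production target predictors is intentionally out of scope — the package's
contribution is the CLIP filter and the downstream network, and the pipeline
accepts any externally produced candidate table.

CLIP filtering retains a candidate iff it shares ≥ 1 base with an AGO peak on
the same transcript. Coordinates are 0-based half-open throughout (BED
native); abutting intervals do not overlap; strand is ignored because
coordinates are transcript-space; AGO1/AGO2 peaks are pooled. The
implementation uses an interval tree; tests hold it to an all-pairs oracle.

## Network construction

The three steps run in order; each is monotone (tightening r_cut or p_cut
never adds edges). Correlations are computed on raw expression values across
**all** samples by default ("across samples"); a tumor-only mode exists.
Binary-branch molecules enter with their zeros; zero-variance profiles are
skipped with a warning. Step-2 p-values are deliberately not
multiplicity-adjusted (the filter is a raw p < 0.01 with |r| > 0.4).
The correlation sign is not constrained by default — the filter is on |r| —
but `negative_only=True` restricts edges to the repressive sign.

Topology: degree fractions below/above cuts (5 and 10); power-law fit as OLS
of log10(frequency) on log10(degree) over degrees ≥ 1 with frequency ≥ 1
(histogram, not CCDF, no binning — the convention is recorded in the output
because alternatives change R²); shortest-path histogram over unordered
connected pairs with disconnected pairs counted separately; closeness as
(n_c − 1)/Σd within each component, 0 for isolated nodes.

## Modules

Modules grow from maximal cliques (Bron–Kerbosch) by repeatedly absorbing
the outside vertex with the largest connectivity ratio
|N(v) ∩ cluster|/|cluster| ≥ threshold (default 0.6), ties broken by node
id; grown clusters that duplicate or are subsets of larger accepted clusters
are discarded, and clusters below `min_size` (3) are dropped. Every module
carries an audit trail of (vertex, ratio) additions so the growth is
replayable.

Two deliberate choices need flagging. First, the clique-extension tool this
emulates is published only as a name and a threshold; the exact update and
stopping rules implemented here are an interpretation and the single biggest
reproduction risk, which is why the parameters ride along in every module
record. Second, seeds are maximal cliques of size ≥ 2 rather than ≥ 3: the
dysregulated network is bipartite by construction (miRNA vs lncRNA/mRNA) and
therefore triangle-free, so 3-clique seeding would return nothing on exactly
the graphs this pipeline produces. Even so, at threshold 0.6 an edge seed can
only grow through triangles, so on strictly bipartite networks the detector
returns no modules ≥ 3 — module-level survival screening on synthetic runs
therefore uses the planted module, and the detector shows its behaviour on
dense (external or non-bipartite) graphs.

## Survival

Unit score = mean of per-molecule z-scored expression over tumor samples
(z-scoring makes miRNA/lncRNA/mRNA scales commensurable before averaging; a
raw-average mode exists). Grouping uses an exact 1-D two-means solver: the
1-D k-means optimum is a threshold split of the sorted scores, found by a
prefix-sum scan over all cutpoints. This is deterministic — the `seed`
argument is interface-only — and it is what lets the objective match the
exhaustive-scan oracle exactly; Lloyd-style iterations were observed to
stall marginally above the global optimum. Kaplan–Meier curves and the
two-group log-rank test are backed by lifelines with events processed before
censorings at tied times; single-gene screens reuse the module procedure on
the standardized gene profile. Samples without clinical records are dropped
with a logged count; a screen needs ≥ 10 tumor samples with follow-up.

## Enrichment

Upper-tail hypergeometric probability P(X ≥ hits) with the universe defined
as the expressed (post-prefilter) protein-coding genes — the universe behind
published enrichment p-values is often unstated, so it is always computed
from the run itself and reported beside the p-value. Up/down splits of
overlap genes map ON-in-cancer → up and OFF-in-cancer → down.

## Synthetic cohorts

Defaults emulate a scaled-down tumor/normal RNA-seq cohort: 100 tumor vs 50
normal samples (preserving the strong class imbalance of the motivating
cohorts), 300 mRNA / 160 lncRNA / 80 miRNA, 30% of molecules DE with a
log2 effect of 2, 20% zero-inflated, 40 planted regulatory edges at pooled
correlation −0.7, CLIP coverage 0.8, a 9-molecule prognostic module with
hazard ratio 3 for module-low samples, 20% censoring, and an exponential
baseline with median survival 1800 days. One seeded RNG stream drives
everything; identical config + seed is byte-identical on disk.

* **Ordinary molecules** are log-normal: log2 x = μ + δ·1[tumor] + σ·ε with
  μ ~ U(4, 9), σ ~ U(0.4, 0.8) per molecule.
* **Planted trios** (one miRNA with one lncRNA and one mRNA target, opposed
  DE directions, as miRNA repression implies) use a truncated-Gaussian model
  with dispersion proportional to the group mean (CV 0.45) and a
  within-group correlation solved in closed form so the *pooled* raw-scale
  Pearson correlation of each miRNA–target pair equals the configured value.
  Under the log-normal model, opposed 4-fold shifts dominate the pooled
  correlation and no loading keeps it near a chosen target; the trios get
  their own model so the planted-correlation contract is exact.
* **Zero inflation**: dropout depends on condition only for molecules
  planted as binary DE (normal ON 0.97, tumor ON 0.25 → OFF-in-cancer);
  null zero-inflated molecules get one condition-independent ON rate in
  [0.90, 0.97]. Making all dropout condition-dependent would plant real
  binary-branch signal and break null calibration.
* **CLIP coverage** is exact by construction: candidate sites are laid out
  on a disjoint per-transcript grid and peaks are placed inside exactly
  round(coverage × n_sites) of them, true regulatory sites first (genuine
  target sites are AGO-bound in vivo; decoy predictions are covered only by
  allotment). Background peaks sit in inter-site gaps.
* **Survival**: the module score's median split defines module-low samples,
  whose exponential hazard is multiplied by the configured hazard ratio —
  the discrete form makes the configured value exactly the two-group ratio a
  log-rank test sees. Censoring is administrative, C ~ U(0, c) with c solved
  numerically so the expected censored fraction equals the configured rate.
* **Decoy candidate pairs** are drawn among non-DE, non-trio molecules, so
  decoy acceptance isolates the correlation filter from the DE filter.

What passing tests show — and what they do not: recovery is measured under
planted effects that are large, homogeneous and independent across
molecules. Real cohorts have graded effect sizes, correlated co-expression
programs, batch structure, library-size artifacts and non-exponential
hazards, none of which are modeled (no read-level simulation, no
copy-number or mutation layers, no batch effects). Calibration and recovery
results here validate the machinery, not performance on any particular
real cohort.

## Numerical conventions

Fisher's exact test uses the probability-ordering two-sided convention;
tests hold it to exact rational enumeration at |margins| ≤ 15 within 1e-12.
BH is the standard step-up with capping at 1. Pearson p-values come from the
t-transform with n − 2 df. Fold-change pseudo-count is 1e-9, used only for
exactly-zero denominators. Degenerate inputs fail loudly and specifically:
zero-variance correlation inputs, empty networks, constant survival scores,
negative times, inconsistent enrichment counts. Problem sizes in tests and
in `scripts/acceptance.py` (e.g. 30–50 survival replicates, 10–20 null
seeds, graphs of n ≤ 60 for brute-force comparison) were chosen as the
smallest sizes at which the binomial noise of the measured rates is well
inside the asserted margins.
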