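# Methods

## Quality filtering

A coding sequence passes QC iff it (i) is at least `min_len_bp` long
(default 100 bp), (ii) has length divisible by 3, (iii) contains no in-frame
stop codon before the final codon, (iv) starts with ATG and ends with a stop
codon, and (v) is pure ACGT after uppercasing and U→T mapping.  The rules are
evaluated independently so the QC report attributes every failure correctly;
together, (i) and (ii) make 102 bp the effective minimum.  Only the standard
genetic code is supported, and the start codon is exactly ATG — alternative
starts are rejected.  Ambiguity codes (N, IUPAC) fail a dedicated `non_acgt`
rule rather than crashing, since real annotations contain them.  GFF3
extraction consults only `CDS` features, resolves parents in the order
`Parent=`, `transcript_id`, `ID=`, concatenates segments in genomic order
(reverse-complemented on the minus strand), and trims the leading `phase` of
the first segment in transcription order.  No isoform selection is performed;
the caller decides which CDS set to analyse.

## Indices

All indices exclude the terminal stop codon; stop usage is not analysed.
Genome-wide values are computed on codon counts pooled over all passing genes
(genes weighted by length), never as means of per-gene values.

* **Amino-acid composition**: percent of sense codons per residue.
* **RSCU**: count(c) / (family total / degeneracy).  Zero-count families are
  *undefined* (NaN), not 0, so cross-genome averages and clustering skip
  missing data instead of biasing toward 0; for clustering they are imputed
  with the family-neutral value 1.  Met and Trp report 1 when present.
  Thresholds 1.6 (overrepresented) and 0.6 (underrepresented).
* **Positional GC**: fraction of G+C at each codon position over sense
  codons; GC12 = (GC1 + GC2)/2.
* **ENC** (Wright): family homozygosity is estimated with the
  small-sample-corrected F̂ = (n·Σp̂ᵢ² − 1)/(n − 1), undefined for n ≤ 1 and
  discarded when ≤ 0.  Six-fold families (Leu, Ser, Arg) are treated as
  single families, not split 2+4.  If the three-fold class (Ile) has no
  defined family it is imputed as (F̄₂ + F̄₄)/2; a missing class elsewhere
  makes ENC undefined.  Sampling noise can push the corrected estimator above
  the theoretical maximum, so ENC is capped at 61.  ENC ≤ 35 is flagged as
  strong bias.  CAI is deliberately not computed: it requires a reference
  gene set that the analysis does not define.

## Mutation versus selection

The neutrality plot regresses per-gene GC12 on GC3 by unweighted OLS (each
gene one point; Pearson r and the two-sided test of zero slope are reported).
Selective constraint is summarised as selection% = (1 − |slope|) × 100.  A
fit is "significant" at p < 0.01; non-significant correlations are themselves
interpreted as selection dominating codon usage, so such genomes report
selection% = 100 with an explicit flag rather than being dropped.  Slopes
above 1 produce negative percentages and are left to the caller to flag.  No
sign assumption is made about r.

The expected ENC at a gene's GC3 is Wright's curve
ENCexp = 2 + s + K/(s² + (1 − s)²) with K = 29 by default.  The constant is a
configuration parameter so sensitivity analyses can substitute other
variants.  dNCsg = ENCobs − ENCexp uses strict inequality (ties are not
selection); genes with undefined ENC are excluded from both the numerator and
denominator of dNC.  The selected-subset profile pools counts over only the
genes below the curve and recomputes the genome-level indices, which enables
the genome-wide versus selected-subset GC3 comparison.

Note that the curve is an approximation to the exact expectation of ENC under
pure GC3 bias: evaluated against a generator that emits third bases with
probability s on G/C endings, the exact asymptotic ENC lies ~0.1–0.5 units
*above* the curve for s ≲ 0.7 and crosses below it near s ≈ 0.73.  Genes
under a pure mutation model therefore sit on or slightly above the curve at
moderate GC3, which is why dNC is a meaningful (one-sided) selection signal.

## Comparative statistics

Shapiro–Wilk and Bartlett are provided as reporting operations only; the
pipeline is always nonparametric (Kruskal–Wallis across groups, two-sided
Wilcoxon rank-sum per group pair, Bonferroni over the pairs; the exact null
distribution is used when both groups have ≤ 25 observations and no ties,
the tie-corrected normal approximation otherwise).  Groups with fewer than
two genomes are excluded with a warning.  The Bonferroni family for each
trait is its set of group pairs, and the family size is recorded in the
output.

Trait correlations are reported twice: Spearman on raw tip values, and
Pearson through the origin on Felsenstein's independent contrasts (signs of
contrasts are arbitrary, so the through-origin convention with n − 1 degrees
of freedom is required).  Polytomies are resolved into zero-length
bifurcations before the contrast recursion; a zero-length *sibling pair* at a
contrast is an error rather than a division by zero.  The implementation is
checked against the reference implementation in R's `ape` in the test suite.

Genome clustering uses Euclidean distance with complete linkage (the default
of the heatmap tooling this mirrors); the linkage method is configurable.
Term enrichment is a one-sided hypergeometric upper tail per term with at
least one study occurrence, Bonferroni-corrected over the tested terms, and
is database-agnostic: annotations are caller-provided gene→term pairs, with
no GO-graph propagation or semantic clustering.

## Synthetic data generator

The generator produces the quantities the pipeline estimates, with known
ground truth:

* Each gene draws a GC3 target from a normal distribution centred on the
  genome's `mut_gc3` (sd `gc3_spread` = 0.10, truncated at ±2 sd), giving the
  neutrality plot its x-axis range.
* The gene's GC12 target follows gc12 = a + β·gc3 + ε with β =
  `neutrality_slope`, ε ~ N(0, `gc12_sigma` = 0.02), and a defaulting to
  0.5 − β·`mut_gc3` so mean GC12 sits at a realistic 0.50.  The target is
  realised by exponentially tilting the amino-acid composition toward
  residues whose codons carry G/C at positions 1–2 (solved by bisection), so
  amino-acid usage covaries with GC12 as it does in real genomes.
* Third bases within each family receive weight g on G/C-endings and 1 − g on
  A/T-endings; g is solved per gene so the expected GC3 equals the target
  (Met/Trp are fixed at GC3 = 1 and Ile lacks a G-ending codon, so g is not
  identical to GC3).
* Selected genes (`sel_fraction`, default 0) multiply the preferred codon of
  each family by `sel_strength` before renormalising.  The default preferred
  set is the C-ending (else G-ending) codon of each family, matching the
  GC-ending codon preference typical of filamentous fungi.
* Defaults: 500 genes of 200–800 sense codons, `mut_gc3` = 0.65 — mid-range
  for GC-rich fungal genomes — and a fixed amino-acid composition following
  the near-universal ranking (Ala/Leu/Ser high; Cys/His/Met/Trp low).

Within-family codon counts are allocated by largest-remainder rounding of the
target distribution, with remainders assigned at random ("balanced" mode, the
default; `codon_sampling="multinomial"` gives fully independent draws).
Balanced allocation pins each gene's realised composition to its generating
parameters.  This is a deliberate design choice: with per-codon multinomial
draws, the finite-gene sampling noise of the homozygosity estimator (sd of
order 1 ENC unit at typical gene lengths) straddles the narrow margin between
the exact null expectation and Wright's approximate curve, and measurement
error in realised GC3 attenuates the neutrality regression slope.  Balanced
allocation removes both effects, so parameter-recovery experiments test the
estimators rather than the generator's sampling noise.  Consequently the
synthetic data do **not** emulate the per-gene stochastic scatter of real
ENC/GC3 clouds (real genes scatter around the curve far more), nor drift,
expression-correlated selection, amino-acid composition differences between
genomes, or sequence evolution along the tree (genomes are generated
independently given their specs).  Passing tests therefore demonstrate
correct estimation under the generating model, not robustness to every
feature of real data.

A single integer seed drives a hierarchical generator (cohort → genome →
gene, via hashed seed sequences), so any genome's output is byte-identical
regardless of cohort composition.  The companion phylogeny is a rate-1 Yule
tree (exponential waits; a final holding time keeps all branch lengths
positive) carrying two traits evolved by correlated Brownian motion.

## Numerical choices and degenerate inputs

* Neutrality fits require ≥ 3 genes and non-constant GC3; constant GC3 is an
  error (undefined slope).
* `enc_expected` rejects GC3 outside [0, 1].
* Empty gene lists, empty study sets, cohorts with duplicate genome ids, and
  profile vectors of unequal length raise errors rather than propagating
  NaNs.
* Tolerances in tests: exact identities are asserted to 1e-9 or tighter;
  stochastic recovery checks use 3 standard errors (slopes), ±0.02 (genome
  GC3), ±0.15 (Brownian correlation, median of 20 seeds).
* Problem sizes in the simulation-based tests (genomes of 80–500 genes,
  trees of 32–64 tips, 10–60 seeds) were chosen to keep the full suite fast
  while leaving comfortable statistical margins.

## Known limitations

* Standard genetic code only; no CAI; no correspondence analysis of RSCU.
* GFF3 handling takes annotations at face value (no isoform reconciliation).
* The ENC/GC3 decision rule inherits the bias of Wright's approximate curve
  at high GC3 (see above): above GC3 ≈ 0.73 even mutation-only genes fall
  slightly below the curve asymptotically, so dNC at very high GC3 should be
  read comparatively, not as an absolute rate.
* Wilcoxon p-values switch between exact and asymptotic methods at n = 25;
  near the boundary, p-values for borderline cases can differ slightly from
  tools that always use one method.
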