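# cubtools

Genome-wide codon usage bias (CUB) analysis for collections of coding
sequences, aimed at comparative genomics of closely related species (the
motivating use case is multi-genome fungal datasets, where CUB strength and
its drivers differ between families).

Synonymous codons are not used equally: mutational GC pressure and natural
selection for translation both shape codon choice, and disentangling the two
is the core of this package.  `cubtools` provides:

* **CDS handling** — reading CDS FASTA, extracting spliced CDS from a genome
  FASTA + GFF3, and quality filtering (length ≥ 100 bp, no partial codons, no
  internal stops, start and stop codons present).
* **Codon usage indices** — amino-acid composition, relative synonymous codon
  usage (RSCU = observed/expected under even synonymous usage; > 1.6
  overrepresented, < 0.6 underrepresented), positional GC (GC1/GC2/GC3,
  GC12), and Wright's effective number of codons

  ```
  ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,   Fk = mean (n·Σp̂ᵢ² − 1)/(n − 1)
  ```

  over the synonymous families of degeneracy *k* (ENC = 20 when one codon per
  amino acid is used, 61 when all are used evenly).  Genome-wide values are
  computed on codon counts pooled over all genes.
* **Mutation-vs-selection inference** — per-genome *neutrality plots* (OLS of
  per-gene GC12 on GC3; selection% = (1 − |slope|) × 100) and *ENC/GC3 plots*
  against the expected curve ENCexp = 2 + s + 29/(s² + (1 − s)²); genes with
  dNCsg = ENCobs − ENCexp < 0 are called under selection, and dNC is the
  percentage of such genes.
* **Comparative statistics** — Kruskal–Wallis and pairwise Wilcoxon rank-sum
  tests with Bonferroni adjustment, Spearman trait correlations with and
  without Felsenstein's phylogenetically independent contrasts, Euclidean
  hierarchical clustering of genome profiles, and hypergeometric enrichment
  of annotation terms in selected-gene sets.
* **Synthetic data** — a generator of multi-genome CDS cohorts with
  controllable mutational GC3, neutrality slope, selection fraction/strength,
  and group structure, plus pure-birth trees with correlated Brownian traits,
  so every stage is testable with known ground truth.

## Worked example

```python
import cubtools as ct

spec = ct.GenomeSimSpec(
    genome_id="demo", n_genes=400, neutrality_slope=0.3,
    sel_fraction=0.05, sel_strength=20.0, seed=2,
)
sim = ct.simulate_genome(spec)
profile, metrics, calls = ct.analyze_genome(sim.genes)
fit = profile.neutrality
print(f"neutrality slope = {fit.slope:.3f}, selection% = {fit.selection_pct:.1f}")
print(f"dNC = {profile.dnc_pct:.2f}%")
```

prints (see `examples/02_neutrality_and_selection.py` for the full script):

```
neutrality slope = 0.228 (generated with 0.3), r = 0.758
selection on codon usage = 77.2%  [(1 - |slope|) * 100]
dNC = 5.75% of genes fall below the expected ENC/GC3 curve
of 23 flagged genes, 23 were truly generated under selection
selected-subset GC3 = 0.963 vs genome-wide 0.664: selection pushes usage toward GC-ending codons
```

The slope near the generating value says ~23% of codon usage variation
follows mutational GC pressure (77% selective constraint); dNC ≈ 5.75% of
genes sit below the expected ENC/GC3 curve, and every flagged gene was truly
generated under codon-level selection.

The `examples/` directory has one short script per capability: genome
profiling, selection inference, group comparison + clustering, independent
contrasts, and the full pipeline.  The same pipeline is scriptable from the
shell:

```bash
cubtools simulate --outdir cohort --genomes-per-group 3 --mut-gc3 0.6,0.72
cubtools run --cds cohort/groupA_1.fasta --cds cohort/groupA_2.fasta ... \
    --groups-tsv cohort/groups.tsv --outdir report
```

All outputs are TSV tables (QC report, per-gene metrics, genome profiles,
selection calls, group comparisons, linkage, contrasts, enrichment), and
re-running with identical inputs reproduces them byte for byte.

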