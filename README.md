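# fbxscape

Desk-scale annotation and molecular-evolution analysis of F-box (*FBX*)
gene superfamilies, exercised end to end on synthetic genomes with planted
truth.

Plant *FBX* genes encode the substrate-recognition subunits of SCF-type
ubiquitin ligases: an N-terminal ~40-residue F-box domain (FBXD) anchors
the protein in the ligase, and a variable C-terminal recruitment module
(kelch, LRR, FBA, ...) selects ubiquitylation targets. The superfamily is
huge, riddled with tandem duplicates and pseudogenes, and its size swings
wildly between even closely related species. Surveying it therefore needs
a specialised toolchain, which this package implements as one library:

* **similarity search** — exact affine-gap Smith–Waterman, six-frame
  translated genome search with Karlin–Altschul E-values
  (E = K·m·n·e^(−λS)), PSSM domain scanning, and CD-HIT-style redundancy
  removal;
* **spliced annotation** — a reduced similarity-based gene-prediction DP
  (codon match / frameshift / GT..AG intron states) that reports
  frameshifts and premature stops explicitly, plus the Closing Target
  Trimming (CTT) loop that iteratively trims tandem neighbours out of a
  10-kb window (at most 6 rounds) until the best-matching reference's
  coding region covers the target domain hit;
* **consensus classification** — a locus is accepted as coding or
  pseudogene only when at least two of the top-scoring reference proteins
  agree on the verdict;
* **orthology** — all-vs-all similarity graph, Markov clustering
  (inflation 4), species-count bins: orphan + bins 1–4 are small
  taxonomic scale (STS), bins 5+ large taxonomic scale (LTS), with
  protein-coding members labelled STSP/LTSP;
* **birth/death** — neighbor-joining gene trees reconciled against a
  packaged 18-species plant tree by LCA duplication–loss parsimony,
  aggregated per branch (single-species clusters count as terminal gains;
  2–3-species clusters are excluded);
* **selection** — Ka/Ks of each gene against a Fitch-parsimony MRCA
  reconstructed from its two closest references, by both Nei–Gojobori
  (NG86) pathway counting and Goldman–Yang (GY94) codon maximum
  likelihood; the neutrality test is LR = 2(lnL_free − lnL_{ω=1}) against
  χ²₀.₀₅ = 3.84; records with Ks < 0.005 or Ks > 3 are filtered;
* **duplication mode** — DAGchainer-style collinear-block chaining
  (segmental) and proximity-based tandem calls;
* **expression** — EST support under the three criteria (>95% identity,
  ≥75% of read or CDS aligned, ≥50 aligned nt) and the statistical
  toolbox (one-sided Fisher exact, Spearman, Kolmogorov–Smirnov,
  one-tailed Wilcoxon) behind the group contrasts.

A synthetic-data module generates genomes with planted gene families
(tandem arrays, collinear blocks, pseudogene lesions, intron structures,
EST libraries, birth/death scenarios) so every stage can be scored against
exact truth. The package also ships a published 18-species census of the
plant *FBX* superfamily (per-species totals, LTSP/STSP/pseudogene splits,
expression counts) as a worked dataset.

## Worked example

```python
from fbxscape.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1)
report, artifacts = run_pipeline(cfg)
print(f"annotated {report.annotated} loci "
      f"({report.coding} coding, {report.pseudogene} pseudogene)")
print(f"locus recovery {report.locus_recovery:.3f}, "
      f"classification F1 {report.classification_f1:.3f}")
```

prints, for the default 50-locus genome (30 coding + 20 planted
pseudogenes):

```
annotated 50 loci (30 coding, 20 pseudogene)
locus recovery 1.000, classification F1 1.000
```

meaning every planted locus was re-discovered from raw sequence and every
recovered locus got the planted coding/pseudogene verdict. The same run
reports per-branch gain/loss totals, Ka/Ks selection classes, duplication
modes (tandem precision/recall ≥ 0.9 on this genome), and the
LTSP/STSP/pseudogene expression contrasts.

The published census is available directly:

```python
from fbxscape.stats import census_expression_tests, census_spearman
census_expression_tests("Cr")
# {'LTSP>STSP': 0.828, 'LTSP>pseudogene': 0.890, 'STSP>pseudogene': 0.787}
census_spearman()
# {'ltsp_vs_genome_size': 0.273, 'stsp_vs_genome_size': -0.098}
```

A thin CLI wraps the main stages: `fbxscape simulate`, `fbxscape search`,
`fbxscape annotate`, `fbxscape run`, `fbxscape stats`.

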