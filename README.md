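# auxopep

Amino-acid auxotrophy and extracellular peptidase profiling of gut
microbiome communities.

## The problem

The small and large intestine offer bacteria very different nutrition:
the small intestine is rich in free amino acids from dietary protein
digestion, while the large intestine forces microbes to scavenge amino
acids from host and bacterial proteins. Two genomic traits track this
gradient:

* **amino-acid auxotrophy** — a genome that cannot synthesize an amino
  acid *de novo* and must import it. Predicted here by flux-balance
  analysis (FBA) on genome-scale metabolic models: a genome is
  auxotrophic for amino acid *a* when its model grows on the full medium
  but not after removing *a* from the medium.
* **extracellular peptidase genes** — secreted or surface-attached
  proteolytic enzymes, detected by homology of genome proteins to
  MEROPS-style peptidase scan sequences, restricted to proteins carrying
  a signal peptide.

`auxopep` links these genome-level predictions to 16S amplicon surveys:
ASVs are mapped to a reference genome catalog (97% identity / 95% query
coverage, maximum-identity ties kept), per-sample genome relative
abundances `w` are derived, and community metrics are computed —

* auxotrophy abundance of amino acid *a*: `Σ_{i auxotrophic for a} w_i`
* abundance-weighted average of auxotrophies: `Σ_i w_i · n_i`, with
  `n_i ∈ [0, 20]` the genome's auxotrophy count (peptidase gene counts
  analogously)
* Bray–Curtis dissimilarities between per-sample peptidase profiles,

followed by the statistical layer: Kendall tau-b trends over ordered gut
regions (duodenum → jejunum → farthest distance → large intestine),
Wilcoxon rank-sum / signed-rank contrasts, Benjamini–Hochberg FDR,
Spearman auxotrophy×peptidase correlation matrices, PCoA, and one-way
PERMANOVA with seeded permutations.

The package ships a first-class synthetic-data generator
(`auxopep.synthetic`) that emulates every input — catalog, metabolic
models, scan database, signal-peptide table, ASV study — with planted
ground truth, so each stage and the end-to-end analysis can be scored
for recall and precision without any downloads.

## Worked example

```bash
python examples/fba_auxotrophy_screen.py
```

```
template growth on full medium: 10.0
mutant growth on full medium:   10.0
template: 0 auxotrophies []
his_trp_mutant: 2 auxotrophies ['His', 'Trp']
```

Both models grow identically on the full medium (the mutant imports
His/Trp), but the leave-one-out screen re-solves each model 20 times,
once per withheld amino acid, and growth of the mutant collapses exactly
when His or Trp is removed — so it is called auxotrophic for precisely
the two knocked-out biosynthesis routes.

The full pipeline on a synthetic study:

```bash
python examples/full_study.py
```

```
stages: ['map', 'abundances', 'screen-auxotrophy', 'call-peptidases', 'metrics', 'stats']
region PERMANOVA on peptidase profiles: R2 = 0.824, p = 0.001
amino acids decreasing along the tract (tau < 0, p_adj < 0.05): 12 of 15 testable
SIBO vs non-SIBO weighted peptidase genes: medians 5.27 vs 2.69, p = 1.83e-04
```

The planted structure is recovered: peptidase profiles separate the four
gut regions (R² = 0.824 at the permutation floor p = 0.001 with 999
permutations), most planted amino-acid auxotrophies decline from
duodenum to large intestine, and the simulated overgrowth (SIBO) group
carries about twice as many extracellular peptidase genes per genome.

Other examples: `asv_mapping.py` (identity thresholds and abundance
assignment), `peptidase_scan.py` (homology filters + signal-peptide
flagging), `community_metrics.py` (hand-checkable metric arithmetic).

A thin CLI wraps the same pipeline:

```bash
auxopep generate study_dir --n-genomes 40 --n-per-region 30 --seed 1
auxopep run-all --config config.json --outdir results --seed 1
```

## Layout

```
src/auxopep/
  model_io.py    domain types, JSON/SBML model I/O, FASTA, catalog I/O
  mapping.py     ASV -> genome mapping and relative abundances
  fba.py         LP-based FBA and the leave-one-out auxotrophy screen
  peptidases.py  local alignment, Karlin-Altschul scoring, peptidase calls
  community.py   community metrics, Bray-Curtis, range scaling
  stats.py       rank tests, BH-FDR, Spearman matrix, PCoA, PERMANOVA
  synthetic.py   synthetic catalog/study generator with planted truth
  pipeline.py    orchestration, config, manifest
  cli.py         click-based command line
```
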