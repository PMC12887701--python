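# nexuslipid

A tested, reusable re-implementation of a multi-stage pipeline linking
metabolic and neurocognitive disease traits, exercised end-to-end on seeded
synthetic data with planted ground truth:

1. **synthio** — seeded generators for every input the pipeline consumes
   (two-sample GWAS summary statistics with configurable causal effect,
   directional pleiotropy and heterogeneity; block LD matrices; trait panels
   with planted causal modules; expression matrices with pathway-restricted
   group effects; CTD-style chemical–gene edge lists with planted hubs;
   model-vs-control expression with planted fold changes), each with a
   machine-readable truth file.
2. **mr** — two-sample Mendelian randomization: greedy LD clumping,
   allele harmonization (palindromic-SNP handling), multiplicative
   random-effects IVW, MR-Egger, Cochran's Q, leave-one-out, radial outlier
   flagging, Steiger directionality filtering, and the three-criterion
   qualification rule (IVW P < 0.05, Egger intercept P > 0.05, Q P > 0.05).
3. **network** — trait-level causal graph, Walktrap module detection,
   core (intra-module) relationships, the bidirectional filter, instrument
   frequency prioritization, ±50 kb nearest-gene mapping (BED), and
   upset-style shared-SNP analysis.
4. **enrichment** — one-sided hypergeometric over-representation against a
   GMT collection (5–2000 member size gate) with BH-FDR control.
5. **ml** — pathway-restricted supervised evaluation: Z-score /
   low-variance / ANOVA-F (P < 0.01) preprocessing fitted inside each
   training fold, stratified k-fold CV of a pluggable classifier suite,
   six-metric scoring, composite (rank-sum) model ranking, and
   intrinsic/permutation importance extraction.
6. **scoring** — the gene-scoring cascade: Composite Model Performance
   Score, Performance-Weighted Importance, Gene Prioritization Score with
   top-1% retention, Dataset-Specific and Holistic Gene Scores with
   ln(1 + hits) robustness factors.
7. **chem** — hub-chemical identification over prioritized genes, Louvain
   communities, and cross-disease bipartite integration with per-gene
   convergence counts.
8. **invivo** — two-group differential expression with an
   empirical-Bayes-moderated t (moment-matched variance prior), DEG calling
   (P < 0.05, |log2FC| > 1), and the sum-of-ranks Comprehensive_Score
   target ranking.
9. **pipeline / cli** — YAML-configured orchestration of all stages with a
   hashing manifest; reruns with the same seed are byte-identical.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(estimator correctness on hand fixtures, Monte-Carlo calibration and
coverage, planted-structure recovery, determinism); the remaining files are
per-module unit and property tests.

## CLI

```bash
nexuslipid demo --seed 0 --out demo_run        # full synthetic pipeline
nexuslipid run --config cfg.yaml --out run/    # same, custom config
nexuslipid mr run --exposure X.tsv --outcome Y.tsv --ld L.tsv --out mr_out/
nexuslipid network map-genes --snps snps.tsv --bed genes.bed --out map.tsv
nexuslipid network modules --edges edges.tsv --out modules.tsv
nexuslipid enrich --query genes.txt --gmt c5.gmt --out enrich.tsv
nexuslipid ml evaluate --expr DS0 --k 10 --out metrics.tsv
nexuslipid chem hubs --edges chem.tsv --genes top.txt --out hubs.tsv
nexuslipid invivo de --expr expr.tsv --groups groups.tsv --out de.tsv
```

All interchange formats are plain text: summary statistics as TSV
(`snp chr pos ea oa eaf beta se pval n`, 1-based positions), LD as a square
r² TSV, expression as genes×samples TSV plus a sample/label TSV, gene sets
as GMT, annotation as BED4 (0-based half-open), chemical–gene edges as TSV
(`chemical_name chemical_id gene_symbol action`), truth as JSON.

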