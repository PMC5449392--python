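# netprio

Network-centrality and ontology-enrichment based disease-gene prioritization.

`netprio` is for computational biologists who have (i) a scored
protein–protein interaction list, (ii) a scored candidate-gene list, (iii) a
set of known disease genes and (iv) an ontology with gene annotations, and
who want a ranked, interpretable short-list of new candidate disease genes by
guilt-by-association. The package also ships a synthetic-data generator that
emulates the statistical structure such data exhibit (scale-free network,
hub-biased disease genes, disease-enriched annotation terms), so the whole
pipeline can be exercised and validated without any external download.

## Method

1. **Network construction.** Interactions with confidence score ≥ a cutoff
   (default 0.63) whose endpoints both pass the candidate-gene score cutoff
   (default 1.0) form an undirected simple graph; self-loops are dropped,
   parallel edges collapse to their maximum score, and the largest connected
   component is kept. The network is characterized by average degree,
   diameter, average distance, density, modularity, global efficiency,
   average clustering, and the exponent γ of a power-law fit
   P(K) ∝ K<sup>−γ</sup> to the degree distribution (OLS on log K vs log P(K)).
2. **Consensus ranking.** Eleven node centralities are supported: degree,
   closeness, radiality, shortest-path betweenness, current-flow betweenness,
   current-flow closeness (information centrality), centroid, PageRank,
   vulnerability, stress and eigenvector. Genes are ranked per measure
   (rank 1 = best). Measures whose rankings are perfectly Spearman-correlated
   (ρ = 1 − 6Σd²/(n(n²−1)), computed as the product-moment correlation of
   fractional ranks) are collapsed — on every connected graph radiality and
   closeness rank identically, so eleven measures reduce to ten. The
   consensus score of a gene is its rank sum over the retained measures.
3. **Enrichment.** Known disease genes (target) are tested against the
   candidate universe (background) per ontology term with the hypergeometric
   upper tail, p < 0.001 on raw p-values. Three selection criteria are
   compared: (1) term size 3 ≤ B ≤ 50; (2) top 20% of enriched terms per
   namespace; (3) criterion 2 plus semantic-redundancy pruning (Lin
   similarity > 0.7 on corpus information content; the less significant of a
   redundant pair is dropped).
4. **Prediction.** Set A = top 5% consensus genes, Set B = known disease
   genes in the network, Set C = network genes of the surviving terms.
   Candidates: **Set D = (A ∩ C) \ B**. Precision = 100·|list ∩ B|/|list|.
5. **Validation.** Genes are pooled into ten equal consensus-rank bins; the
   mean number of gene–disease associations per bin is regressed on bin
   index; a negative slope with high R² confirms the ranking is
   disease-relevant.

## Worked example

```python
from netprio import (CANONICAL_MEASURES, FAST_MEASURES, PipelineConfig,
                     SyntheticConfig, run_pipeline, build_annotation_map)
from netprio import simulate as sim, enrichment as en, pipeline as pl

syn = sim.SyntheticConfig(seed=1)           # 2000 genes, 150 hub-biased disease genes
cfg = pl.PipelineConfig(measures=FAST_MEASURES, seed=1)
ds = sim.generate_dataset(syn)
ann = en.build_annotation_map(ds.annotations, ds.dag)
res = pl.run_pipeline(cfg, ds.interactions, ds.gene_scores,
                      set(ds.disease_genes), ann, synthetic_cfg=syn)
print(res.summary["n_nodes"], res.summary["base_rate_pct"])
for row in res.precision_rows:
    if row.label == "consensus":
        print(row.cutoff, row.precision)
```

prints

```
1992 7.53
0.02 87.5
0.05 63.0
0.07 52.52
0.1 43.22
```

The filtered largest component keeps 1992 of 2000 genes, of which 7.53% are
known disease genes (the base rate). The top 2/5/7/10% of the consensus
ranking contain 87.5/63.0/52.5/43.2% known disease genes — precision far
above base rate and decreasing as the cutoff loosens, which is exactly the
hub-bias signal the generator plants. `res.sets.set_d` holds the predicted
candidates and `res.trend.r_squared` (0.94 here) the rank-bin
disease-association trend.

The same analysis is available from the shell:

```sh
netprio run-all --seed 1 --measures fast --out-dir out/
netprio simulate --seed 1 --out-dir data/
netprio build-network --edges data/edges.tsv --genes data/genes.tsv \
    --score-cutoff 0.63 --gene-cutoff 1.0 --out net.tsv
netprio topology --network net.tsv --seed 1 --out topo.json
```

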