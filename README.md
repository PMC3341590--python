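# exprmap

Multi-experiment gene-expression mapping: cluster a gene × condition
expression matrix assembled from heterogeneous experiments onto a 2-D grid,
then ask which functions, gene families, or gene sets occupy which parts of
the grid.

`exprmap` is for transcriptomics researchers who have expression values for
the same genes across many independent experiments (different publications,
platforms, tissues, time courses) and want a single ordered overview of
co-expression structure, rather than one dendrogram per experiment.

## What it computes

1. **Median-shift normalization.** Experiments without a common reference
   (single-channel intensities, global-reference ratios) have no shared zero
   point. Each gene's profile within each experiment block is centred by
   subtracting its median: values (11, 4, 6) become (5, −2, 0). After this,
   correlation across experiments is meaningful.

2. **Self-organizing map (SOM).** A width × height grid (default 25×20 =
   500 nodes) of condition-length reference vectors is trained competitively:
   gene profiles are presented at random (on average 20 times each), the best
   matching unit (BMU) — the node with the highest Pearson correlation to the
   profile, computed over jointly observed components so missing values need
   no imputation — and its grid neighbours within the current radius are
   pulled towards the profile by the current learning rate, with both radius
   (start 10) and learning rate (start 0.1) decaying linearly to zero.
   Finally each gene is assigned to its BMU; each node is a gene cluster and
   nearby nodes hold similar profiles.

3. **Per-node GO over-representation.** For every occupied node and every
   informative term (annotating ≥ 10 and ≤ ¼ of the mapped genes), a
   one-sided Fisher's exact test (upper hypergeometric tail) against the rest
   of the map, Benjamini–Hochberg FDR over all tests, and a reporting filter
   of at least 4 annotated genes in the node.

4. **Empirical spatial non-randomness test.** For a gene set of size *n* on
   the map, the mean city-block distance *d* from each member to its closest
   other member is compared with the same statistic *d′* for random *n*-gene
   sets sampled from the map; `p = #{d′ < d} / n_samples`, with Bonferroni
   correction across multiple sets.

5. **Reproducibility across re-mappings.** Gene pairs co-clustered in a main
   map are looked up in independently re-seeded maps, counting how often they
   co-cluster again or land within a few grid units.

6. **Regions and overlays.** Node sets selected by simple inequalities on
   node-vector components (e.g. `embryo > 0.25`) and per-node membership
   counts for gene categories — the data behind map outlines and pie charts.

A seeded synthetic-data generator with planted co-expression clusters and
planted annotation terms makes the whole pipeline testable end to end
without any external dataset.

## Worked example

```python
import exprmap as em

spec = em.SyntheticSpec(n_genes=500, n_clusters=5, seed=7)
matrix, truth = em.generate_matrix(spec)
normed = em.median_shift(matrix)
som = em.train(normed, em.SomConfig(width=12, height=8, seed=7))

ann = em.generate_annotations(truth, n_terms=5, seed=7)
results = em.run_enrichment(som, ann, fdr_threshold=0.01)
top = sorted((r for r in results if r.reported), key=lambda r: r.fdr)[:3]
for r in top:
    print(f"node {r.node}  {r.term_id}  k={r.counts.k}/{r.counts.n}  "
          f"K={r.counts.K}/{r.counts.N}  fdr={r.fdr:.3g}")

gs = em.GeneSet("cluster0", frozenset(truth.genes_of_cluster(0)))
st = em.nonrandom_test(som, gs, n_samples=1000, seed=7)
print(f"spatial test: n={st.n}  d={st.d_observed:.3f}  p_raw={st.p_raw}")

alts = [em.train(normed, em.SomConfig(width=12, height=8, seed=s)) for s in (8, 9)]
rep = em.cocluster_reproducibility(som, alts, n_pairs=10000, seed=7)
print(f"reproducibility: frac_same={rep.frac_same:.3f}  frac_near={rep.frac_near:.3f}")
```

prints

```
node (0, 2)  TERM:0002  k=15/18  K=96/500  fdr=1.14e-06
node (3, 0)  TERM:0003  k=10/10  K=113/500  fdr=2.87e-05
node (8, 3)  TERM:0000  k=11/12  K=108/500  fdr=2.87e-05
spatial test: n=100  d=0.000  p_raw=0.0
reproducibility: frac_same=0.292  frac_near=1.000
```

Reading this: node (0, 2) holds 18 genes, 15 of which carry `TERM:0002`
(96 of the 500 mapped genes carry it overall) — far more than expected
under random placement, hence the tiny FDR. The 100 genes of planted
cluster 0 sit at mean nearest-neighbour distance 0 (all co-located with
another member), and no random gene set of the same size was ever as
tight in 1000 draws, so the empirical p is 0. Across two re-seeded maps,
29% of co-clustered pairs land on the identical node again and every
sampled pair stays within 5 grid units — the map's fine detail moves
between runs, its topology does not.

The same stages are available as a CLI:

```sh
exprmap simulate --n-genes 500 --clusters 5 --seed 7 -o data/
exprmap normalize --matrix data/matrix.tsv --experiments data/experiments.tsv -o data/normed.tsv
exprmap train --matrix data/normed.tsv --experiments data/experiments.tsv \
    --width 12 --height 8 --seed 7 -o data/map.json
exprmap enrich --map data/map.json --annotations data/annotations.tsv -o data/enrichment.tsv
exprmap run --config pipeline.yaml     # or everything from one YAML file
```

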