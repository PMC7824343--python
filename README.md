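# perconet

Co-occurrence network inference for microbial community profiles, built
around the percolation threshold of weighted correlation networks.

Amplicon surveys of methanogen-containing habitats — sediments, peatland
soils, anoxic waters, enrichment slurries — often ask which taxa an
organism of interest rises and falls with across samples, because strong,
positive co-occurrence between, say, a methyl-reducing methanogen
(*Methanomassiliicoccales*) and H₂/acetate-producing fermenters hints at
syntrophy. `perconet` provides that analysis chain as a tested, reusable
package:

1. **Filtering** — unique singletons removed, prevalence floor applied.
2. **CSS normalization** — cumulative sum scaling: counts in sample *j* are
   divided by *s<sub>j</sub>*, the cumulative sum of that sample's counts up
   to the *p*-th quantile of its positive counts (default *p* = 0.5), times
   a scale constant *N* = 1000. This corrects library-size differences
   without letting dominant taxa drive the scaling.
3. **Spearman co-occurrence** — ρ between every OTU pair across samples
   (Pearson correlation of mid-ranks); only positive correlations become
   network edges, with weight *w* = ρ.
4. **Percolation threshold** — the largest cutoff *t\** at which edges of
   weight ≥ *t\** still connect the whole analysed network into one giant
   cluster; computed exactly as the bottleneck (minimum edge weight) of a
   maximum spanning tree, and cross-checked by a descending threshold scan.
5. **Modules** — seeded weighted Louvain optimization of modularity
   *Q* = (1/2m) Σ<sub>ij</sub> [A<sub>ij</sub> − γk<sub>i</sub>k<sub>j</sub>/2m] δ(c<sub>i</sub>, c<sub>j</sub>);
   the reported *Q* is always re-evaluated directly from the formula.
6. **Focus reports** — for every OTU of a target lineage, partners with
   *w* ≥ *w*<sub>min</sub> (default 0.7), annotated with lineage and module
   co-membership.

Supporting modules compute Shannon/Simpson alpha diversity, Bray–Curtis
sample dissimilarity networks, and absolute qPCR quantification (standard
curves with efficiency/r²/Ct quality gates, copies per gram or mL,
enrichment ANOVA/t-tests on log₁₀ copies). A synthetic-data generator
plants blocks of co-varying OTUs with known ground truth, so the whole
chain is testable without any external dataset.

## Worked example

```python
import perconet as pn

# a synthetic table: 300 OTUs x 40 samples, 4 planted blocks of 10,
# the first block carrying a Methanomassiliicoccales-style lineage
table, truth = pn.generate_table(pn.SyntheticSpec(seed=1))

model = pn.CooccurrenceAnalysis(table, target_lineage="Methanomassiliicoccales", seed=1)
res = model.fit()
print(res.summary())
```

```
Co-occurrence network analysis
==============================================
OTUs analysed                 290
Samples                        40
Positive edges              21527
Percolation threshold t*    0.321
Threshold applied           0.321
Edges at threshold           1425
Modules                        10
Modularity Q                0.526
Focus 'Methanomassiliicoccales' (w >= 0.7): 10 OTU(s), partners [9, 9, 9, 9, 9, 8, 8, 8, 8, 5]
```

Reading: after filtering, 290 OTUs remain (the 10 planted singletons are
dropped). The positive-correlation network stays fully connected down to a
weight cutoff of 0.321 — its percolation threshold — where Louvain finds 10
modules at *Q* = 0.526. Each of the 10 target-lineage OTUs co-occurs at
*w* ≥ 0.7 with 5–9 partners, almost all of them its planted block mates
(`pn.block_recovery_ari(res.partition.assignment, truth)` returns 1.0 here:
the planted blocks are recovered exactly). `res.plot_percolation()` draws
the giant-component trajectory *S(t)*.

The same chain is scriptable from a shell:

```sh
perconet simulate --seed 1 --out sim/
perconet network sim/counts.tsv sim/taxonomy.tsv sim/metadata.tsv --out net
perconet focus sim/counts.tsv sim/taxonomy.tsv sim/metadata.tsv \
    --target Methanomassiliicoccales --w-min 0.7 --out focus.json
```

Networks are written as Gephi-compatible GraphML/GML (node attributes
`taxonomy`, `module`; edge attribute `weight`) or a flat edge TSV.

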