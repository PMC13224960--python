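# omicnet

Correlation-based association networks for high-dimensional omics
feature tables — microbial co-occurrence networks, exposome–transcriptome
association maps, and anything else that starts as a feature × sample
abundance matrix. The package is aimed at microbial ecologists and
multi-omics analysts who need the whole chain — normalization, all-pairs
correlation with honest p-values, a defensible correlation threshold,
module and key-taxa analysis, topology and robustness metrics, and
publication-oriented layouts — in one scriptable, seeded, reproducible
toolkit.

## What it computes

**Correlation screen.** For features x, y over n shared samples the
screen computes Pearson or Spearman correlation for every pair at once
(row-standardization + one matrix product; Spearman is Pearson on
midranks) and converts each r to a two-sided p-value analytically via

    t = r·√((n−2)/(1−r²)),  df = n − 2,

with Benjamini–Hochberg, Holm or Bonferroni correction over exactly the
tests performed (upper triangle for one table, the full rectangle for
two). No permutations, no loops: a 200 × 50 table takes ~30 ms.

**RMT thresholding.** The hard threshold t is selected by a
random-matrix criterion: the nearest-neighbor spacing distribution of
the unfolded eigenvalues of the thresholded matrix follows the GOE
Wigner surmise (πs/2)·e^(−πs²/4) while noise correlations survive, and
collapses to the Poisson law e^(−s) once they are removed; the scan
picks the smallest t where the Poisson fit wins sustainably.

**Modules and roles.** Clauset–Newman–Moore greedy modularity (|r|
weights) partitions the network; each node gets a within-module degree
z-score Zi and a participation coefficient Pi = 1 − Σₘ(k_im/k_i)², and a
Guimerà–Amaral role: module hub (Zi ≥ 2.5), connector (Pi ≥ 0.62),
network hub (both), peripheral (neither).

**Topology and stability.** A versioned 17-metric report (density, path
length, diameter, clustering, transitivity, global efficiency,
modularity, natural connectivity ln((1/N)·Σe^λᵢ), component structure,
centrality summaries), Clauset-style discrete power-law degree fits,
z-scores against Erdős–Rényi and degree-preserving rewired nulls, and
node-removal robustness curves (random / degree-targeted /
betweenness-targeted).

**Layouts.** Grouped placements (per-group anchor + scale + inner
algorithm), regular-polygon and polygon-circle arrangements, module
circle packing, pseudo-3D multi-layer stacks, placement constrained to
arbitrary simple polygons (ear-clip triangulation sampling), and exact
affine transforms — all seeded and bit-reproducible.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
conventions.

## Worked example

```python
import omicnet as on

# seeded synthetic table: 100 features, 50 samples, 5 correlated blocks
table = on.planted_block_data(n_features=100, n_samples=50, n_blocks=5,
                              within_r=0.7, seed=1)
corr = on.c_net_calculate(table, method="spearman", adjust="BH")
net = on.c_net_build(corr, r_threshold=0.6, p_threshold=0.05)
modules = on.detect_modules(net)
roles = on.zipi(net, modules)
rep = on.topology_report(net)

print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")
print(f"modularity Q = {modules.modularity:.3f} over {modules.n_modules} modules")
g = rep.global_metrics
print(f"average path length = {g['average_path_length']:.3f}, "
      f"global efficiency = {g['global_efficiency']:.3f}, "
      f"natural connectivity = {g['natural_connectivity']:.3f}")
```

prints

```
network: 100 nodes, 811 edges
modularity Q = 0.799 over 5 modules
average path length = 1.105, global efficiency = 0.178, natural connectivity = 13.920
```

The detector recovers exactly the five planted blocks (Q ≈ 0.8: almost
all retained edges are intra-block), and on a larger 500 × 25 version of
the same generator the RMT scan chooses t = 0.60 — above the noise
correlations, below the planted within-block signal of 0.7:

```python
scan = on.rmt_scan(on.c_net_calculate(
    on.planted_block_data(n_features=500, n_samples=25, n_blocks=5,
                          within_r=0.7, seed=1)).r)
print(scan.chosen)   # 0.6
```

The same pipeline is available from the shell:

```sh
omicnet calc --in table.tsv --method spearman --adjust BH --out corr.npz
omicnet rmt --corr corr.npz --report rmt.json
omicnet build --corr corr.npz --rt 0.6 --pt 0.05 --out net.graphml
omicnet modules --net net.graphml --out modules.tsv
omicnet zipi --net net.graphml --modules modules.tsv --out roles.tsv
omicnet topo --net net.graphml --out topo.json --nodes centralities.tsv
omicnet stability --net net.graphml --strategy degree_targeted --out curve.tsv
```

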