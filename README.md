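# xmerge

Merging gene-expression studies with batch-effect removal, and validating
the merge.

Combining expression data sets produced by different labs or platforms is
attractive — it raises statistical power and lets public data be reused —
but naive column concatenation is dominated by *batch effects*: systematic,
non-biological differences between studies that swamp the biological signal.
`xmerge` merges two or more studies (genes × samples matrices of log2-scale
intensities, e.g. fRMA output) on their common genes with one of six
batch-effect-removal methods, and quantifies how well the merge worked.

## Methods

All methods operate per gene `g` on the common (lexicographically sorted)
gene set, with each study treated as one batch `i`:

| method | adjustment |
|---|---|
| `NONE` | column concatenation, no transformation |
| `BMC` | subtract each gene's per-batch mean: `y* = y − ȳ_ig` |
| `GENENORM` | per-batch z-score: `y* = (y − ȳ_ig)/s_ig` (sample sd, n−1) |
| `COMBAT` | empirical-Bayes location/scale model `y = α_g + Xβ_g + γ_ig + δ_ig ε`; per-batch `γ̂_ig`, `δ̂²_ig` are shrunk toward batch-level parametric priors (normal / inverse-gamma, method of moments) via the EB fixed point, then removed |
| `DWD` | find the distance-weighted-discrimination direction `w` between the two batches (min Σ 1/margin + C·Σ slack, ‖w‖ ≤ 1) and remove each batch's mean displacement along `w` relative to the grand mean |
| `XPN` | cluster genes (K=25) and samples (L=5) by k-means; fit `x_gj = A_[k(g),l(j)]·b_g + c_g + σ_g ε` per platform; replace block parameters by sample-size-weighted common estimates; average over 30 random clusterings |

XPN and DWD are pairwise methods; three or more studies are folded
two-by-two, the intermediate result acting as a single batch.

Merge quality is judged by five visual diagnostics (double-labeled MDS,
RLE boxes, gene-wise boxes, sample dendrogram, gene-wise densities) and six
quantitative indices, including the genes-overlap index **GOV**: with
`P_x`, `P_y` the Parzen–Rosenblatt density estimates of gene `g_i` in the
two studies, normalized on a shared grid so `Σ P = 1`,

```
GOV_i = (1/2) Σ |P_x − P_y|          GOV = (1/m) Σ_i GOV_i
```

Both are bounded in [0, 1]: 0 when the distributions coincide, 1 when they
are disjoint. A good merge drives GOV between batches toward 0.

## Worked example

```python
from xmerge import simulate_studies, merge, validation_report

studies, truth = simulate_studies(seed=0)   # 2 studies x 50 samples,
                                            # 500 genes, batch shift sd 2
none   = merge(studies, "NONE")
combat = merge(studies, "COMBAT")
report = validation_report(none, combat,
                           {"target_key": "Disease",
                            "control_genes": truth["de_genes"],
                            "top_n": 50, "originals": studies})
for name, res in sorted(report.indices.items()):
    print(name, res)
```

prints (values rounded):

```
asymmetry                 {'mean_abs_diff': 0.0277}
genes_mean_corr           {'mean': 0.5488}
genes_overlap             {'before': 0.749, 'after': 0.0952}
samples_mean_corr         {'mean': 0.8791}
samples_overlap           {'before': 63.02, 'after': 14.74}
significant_genes_overlap {'before': 50, 'after': 50, 'STUDY1': 50, 'STUDY2': 50, ...}
```

Read: before adjustment the two batches barely overlap (GOV 0.75, mean
nearest cross-batch distance 63); after the empirical-Bayes adjustment the
per-gene distributions nearly coincide (GOV 0.10, distance 14.7) while the
samples stay highly correlated with their unadjusted profiles (0.88), the
per-sample skewness is almost unchanged (0.028), and all 50 simulated
differentially-expressed genes are still recovered in the top 50 of the
Welch-t ranking.

The same pipeline from the shell:

```bash
xmerge simulate --out-dir fx --seed 0
xmerge merge --method COMBAT \
    --expr fx/STUDY1.tsv --annot fx/STUDY1.ann.tsv \
    --expr fx/STUDY2.tsv --annot fx/STUDY2.ann.tsv \
    --out merged.tsv --out-annot merged.ann.tsv
xmerge plot --kind mds --expr merged.tsv --annot merged.ann.tsv \
    --target Disease --out mds.png
```

Input format: tab-delimited text; the expression table has a `GENE` header
column and one column per sample, the annotation table has a `SAMPLE`
header column and one column per annotation key (at least one phenotype
column such as `Disease`). The merged output gains a `Study` column
recording each sample's study of origin.

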