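# scaledmr

Scale-aware calling of differentially methylated regions (DMRs) from
methylation-array beta values, for studies — rare-disease cohorts, sex
comparisons, chromatin-modifier syndromes — where the regions of interest
range from a single promoter (~100 bp) to an entire chromosome, and no
fixed window width can see both.

## The method in brief

Each probe carries a beta value β ∈ [0, 1] (methylated fraction at a CpG).
Given per-CpG two-group p-values p_i (built-in exact Wilcoxon rank-sum or
Welch t-test, or any user-supplied test), each probe gets a significance
rank K_i = #{j : p_j ≤ p_i}.  Windows of w *adjacent CpGs* (w = 4, 8, 16,
32, 64 by default; counts, not basepairs, so the scan is density-agnostic)
slide at stride 1.  A window's score conditions on its most significant
member having been drawn and asks how surprising the remaining m member
ranks are jointly, via a sequence of hypergeometric tests

    q = ∏_{i=1..m} P(X_i ≥ k_i),   X_i ~ Hypergeom(N_i, K_i, n_i),

whose variable updates (n_1 = m, n_i = k_{i−1} − 1; N_1 = N,
N_i = K_{i−1} − 1) make the factors independent uniforms under the null;
the product is calibrated against its Gamma null law and combined with a
robust prefix-enrichment statistic into a valid region p-value (see
`docs/methods.md`).  Window p-values are corrected within each layer
(Benjamini–Yekutieli by default, with the number of tests equal to the
number of probes below the individual-CpG cutoff), significant windows are
merged, and layers are integrated from small windows to large: a broad
region is retained only if it stays significant after removing each
overlapping smaller-window DMR individually, so every DMR nests inside
exactly one DMR of the next layer and the scale of each feature is the
smallest that explains it.

The package also ships the DMR-injection simulator used to benchmark such
callers (truth regions spanning 0.1 kb–1 Mb injected into a synthetic
array-like backbone, with interior-CpG masking and max-rescaling),
range-aware evaluation statistics (log-width correlation, mapping values,
feature/bp/CpG-level precision–recall, AUCPR, F1, MCC), and CpG-membership
enrichment analyses (Fisher exact odds ratios of layer gaps against
annotations, cross-condition DMR/gene overlap).

## Worked example

```python
import numpy as np, pandas as pd
from scaledmr import *

# synthetic array backbone + injected ground-truth DMRs
probes, beta = generate_backbone(BackboneConfig(n_probes=20000, n_samples=53), seed=1)
ds = simulate_dataset(probes, beta, SimulationConfig(n_dmrs_per_class=10, seed=1))

# per-CpG tests, permutation cutoff, and the iterative windowing run
track = rank_cpgs(wilcoxon_per_cpg(ds.beta, ds.samples))
est = permutation_fdr_cutoff(ds.beta, ds.samples, target_fdr=0.10, n_perm=20, seed=1)
print(f"individual-CpG cutoff: p < {est.cutoff:.3g}  ({est.n_below} probes below)")
res = call_dmrs(track, probes, CallerConfig(), locs_pval_cutoff=est.cutoff)
for li, (w, layer) in enumerate(zip(res.window_sizes, res.layers), 1):
    widths = [d.width for d in layer]
    print(f"layer {li} ({w:>2} adjacent CpGs): {len(layer):3d} DMRs, "
          f"median width {int(np.median(widths))} bp")
top = max(res.top_layer, key=lambda d: d.n_cpgs)
print(f"largest top-layer DMR: {top.chrom}:{top.start}-{top.end} "
      f"({top.n_cpgs} CpGs, p_adj={top.p_adjusted:.1e}, mean dBeta={top.mean_delta_beta:+.2f})")
```

prints, layer by layer:

```
individual-CpG cutoff: p < 0.00466  (753 probes below)
layer 1 ( 4 adjacent CpGs):  38 DMRs, median width 162 bp
layer 2 ( 8 adjacent CpGs):  49 DMRs, median width 12498 bp
layer 3 (16 adjacent CpGs):  40 DMRs, median width 7905 bp
layer 4 (32 adjacent CpGs):  40 DMRs, median width 7905 bp
layer 5 (64 adjacent CpGs):  37 DMRs, median width 7935 bp
largest top-layer DMR: chr1:29248634-30489698 (190 CpGs, p_adj=8.4e-48, mean dBeta=+0.07)
```

The first layer finds the small, dense features; later layers consolidate
broad regions (here a 1.2 Mb injected feature recovered as one DMR with
190 member CpGs) while the small stable DMRs carry through unchanged.
Scoring the top layer against the injected truth:

```python
called = pd.DataFrame({"chrom": [d.chrom for d in res.top_layer],
                       "start": [d.start for d in res.top_layer],
                       "end":   [d.end for d in res.top_layer],
                       "p_adjusted": [d.p_adjusted for d in res.top_layer]})
domain = pd.DataFrame([(c, int(probes.pos[s][0]), int(probes.pos[s][-1]))
                       for c, s in probes.chrom_slices.items()],
                      columns=["chrom", "start", "end"])
ev = evaluate_calls(ds.truth_frame(), called, domain, probes=probes)
print(f"width r(log10)={ev['widths'].pearson_r_log10:.2f}  "
      f"one-to-one={ev['mapping'].one_to_one_fraction:.0%}  "
      f"precision={ev['levels']['feature'].precision:.2f}  "
      f"AUCPR={ev['pr_curve'].aucpr:.2f}")
```

```
width r(log10)=0.89  one-to-one=85%  precision=0.92  AUCPR=0.82
```

i.e. called widths track true widths across four orders of magnitude
(Pearson r on log10 widths), 85% of truth regions are recovered by exactly
one called DMR, and 92% of called extent overlaps truth.

The same pipeline is available from the shell:

```
scaledmr simulate --backbone synthetic --per-class 25 --seed 1 --out sim/
scaledmr call --beta sim/beta.tsv --manifest sim/probes.tsv \
              --samples sim/samples.csv --locs-cutoff auto --seed 1 --out calls/
scaledmr evaluate --truth sim/truth.bed --called calls/layer_5.bed \
                  --manifest sim/probes.tsv --out metrics.json
scaledmr enrich --dmrs calls/layer_4.bed --annot escape_genes.bed \
                --manifest sim/probes.tsv --universe chrX --out enrich.json
```

`call` emits per-layer BED + TSV, a hierarchy edge list, and a JSON run
record; `call` also accepts a precomputed p-value table
(`--test precomputed --pvals pvals.tsv`) for covariate-adjusted designs.

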