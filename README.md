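# soldissect

Statistical dissection of sequence-derived biochemical determinants of
protein solubility.

Protein solubility governs recombinant expression yield, aggregation
behaviour, and downstream usability of a construct. High-capacity predictors
(ensembles, protein language models) score well on solubility benchmarks but
obscure a more basic question: how much signal do the *classical* global
descriptors — length, composition, charge, hydrophobicity, structural
propensities — actually carry, and how redundant are they with one another?
`soldissect` is a library and CLI for answering that question at scale, aimed
at computational biologists and protein engineers who want a transparent,
untrained statistical baseline rather than another black-box model.

## What it computes

For every protein sequence (single-letter FASTA, ambiguity codes preserved
but excluded from all calculations), 36 descriptors: the 20 amino-acid
frequencies `f_a = n_a / L`; six residue-group ratios (positive {K,R,H},
negative {D,E}, polar {S,T,N,Q}, hydrophobic {A,V,I,L,M,F,W,Y}, tiny
{A,G,S,T}, sulfur {C,M}); effective length `L`; molecular weight;
Henderson–Hasselbalch isoelectric point and net charge at pH 7; mean
Kyte–Doolittle hydropathy; mean Chou–Fasman helix/sheet/turn propensities; a
residue-scale disorder ratio; and an aggregation proxy `r_agg = l_max / L`
(longest hydrophobic run).

For each descriptor, soluble vs insoluble classes are compared with
rank-based statistics:

* Mann–Whitney U with Benjamini–Hochberg FDR control across the 36 tests;
* Cliff's delta `δ = P(X>Y) − P(X<Y)` with a percentile-bootstrap CI
  (B = 2,000), related to the tie-aware ROC AUC by `AUC = (δ+1)/2` exactly;
* the Hodges–Lehmann shift (median of all pairwise differences, computed by
  selection, never by enumerating the ~1.5 × 10⁹ pairs of a full-size run)
  with a distribution-free rank-inversion CI;
* Youden's J and its optimal threshold T\*.

Features with |Spearman ρ| ≥ 0.85 are treated as proxies of one latent axis
(connected-component clustering); one representative per cluster is kept.
The retained features define the **composite-δ index**

```
S = Σ_j δ_j · (x_j − median_j) / IQR_j ,      ŷ = soluble iff S > 0
```

with pooled medians/IQRs — no training, no tuning. In its published reduced
two-feature form (length and negative-charge proportion):

```
S = −0.215 · (L − 236)/231 + 0.150 · (N⁻ − 0.126531)/0.039934
```

A calibrated synthetic generator (log-normal class-conditional lengths,
Dirichlet-multinomial class-conditional compositions) emulates the
benchmark's class differences so the entire pipeline is testable offline.

## Worked example

```python
import soldissect as sd
from soldissect.univariate import StatsConfig, analyze_all

cfg = sd.default_config(n_soluble=5000, n_insoluble=5000, seed=1)
matrix = sd.extract_features(sd.sample_dataset(cfg))
results = analyze_all(matrix, StatsConfig(bootstrap_B=0, seed=1))
by = {r.feature_name: r for r in results}
for name in ("length", "neg_ratio"):
    r = by[name]
    print(f"{name}: delta={r.delta:+.3f}  AUC={r.auc:.3f}  "
          f"HL={r.hl_shift:+.4g} [{r.hl_ci_low:.4g}, {r.hl_ci_high:.4g}]  q={r.q_value:.3g}")

model = sd.fit_composite(matrix, results, ["length", "neg_ratio"])
scores = sd.composite_score(model, matrix)
labels = (matrix.labels == "soluble").astype(int)
m = sd.evaluate(scores, labels)
print(f"composite: AUC={m.auc:.4f}  Acc={m.accuracy:.4f}  MCC={m.mcc:.4f}")
```

Output:

```
length: delta=-0.250  AUC=0.375  HL=-66 [-72, -60]  q=1.01e-102
neg_ratio: delta=+0.177  AUC=0.589  HL=+0.008572 [0.007482, 0.009658]  q=2.45e-52
composite: AUC=0.6408  Acc=0.6016  MCC=0.2047
```

Reading this: on a synthetic draw emulating the benchmark, soluble proteins
are shorter (negative δ, AUC below 0.5 because the AUC is not
orientation-corrected; the HL estimate says soluble proteins are ~66
residues shorter at the median) and carry a higher fraction of D/E residues
(δ ≈ +0.18, a +0.0086 shift in the proportion). Each effect is individually
weak, but the two-feature composite-δ index separates the classes with
AUC ≈ 0.64 — discrimination comparable to classical feature-based
predictors, from an index with zero trained parameters.

The same run is available from the shell:

```bash
solubility-dissect run --synthetic --n-per-class 5000 --seed 1 --outdir run1
solubility-dissect extract --fasta proteins.fasta --labels sidecar:labels.csv --out features.csv
solubility-dissect stats --features features.csv --out results.csv --bootstrap 2000 --seed 1
```

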