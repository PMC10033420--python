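# sbbc — synchronous bilateral breast cancer analysis

Synchronous bilateral breast cancers (sBBCs) — tumors diagnosed in both
breasts within months of each other — pose two linked questions: are the two
tumors of a patient clonally related or independent primaries, and does the
presence of a contralateral tumor of a *different* subtype modify a tumor's
immune infiltration and its response to neoadjuvant chemotherapy?  `sbbc` is
a toolkit for analysts working on paired-tumor cohorts that answers both at
every molecular layer:

* **Somatic genomics** — population-frequency and confidence filtering of
  variant calls, COSMIC-census driver annotation, residual-disease QC
  (purity < 0.3 combined with a >25% PT/RD mutation-burden difference),
  CCF-based clone clustering and PT→RD clone tracking
  (emergence/extinction).
* **Pair relatedness** — shared-mutation percentage
  `100 · 2|A∩B| / (|A|+|B|)`, Venn partitions, cosine similarity of
  copy-number profiles after subtracting the diploid reference (2), and
  mutational-signature refitting of 96-channel trinucleotide spectra by
  sum-constrained non-negative least squares against a 13-signature breast
  catalogue; a configurable rule calls each pair independent or clonal.
* **Immune contexture & TCR** — the dissimilarity index
  `Σ_k (x_k − y_k)²` over 22 LM22 immune subsets with block means
  (PT–PT vs RD–RD vs cross), TIL-change categories, Chao-1 richness, D50
  diversity, and clonotype-sharing / public-clonotype statistics.
* **Expression** — median-of-ratios + log2 normalisation, the IQR
  inflection-point rule for variable-gene selection (knee of the ascending
  IQR curve, farthest point from the first–last chord), Pearson + Ward
  hierarchical clustering, PCA on the most variable genes, and the PT–RD
  co-pairing rate.
* **Clinical statistics** — pCR (ypT0/is N0), Cohen's kappa and Kendall
  tau-b pair concordance, and the central interaction test: linear (TILs) or
  logistic (pCR) models with a subtype × concordance term judged by a
  likelihood-ratio test at the 0.10 level.
* **Synthetic cohorts** — a generator with known ground truth reproducing
  the statistical structure of an sBBC study (84.7% concordant pairs, ~151.5
  somatic mutations per tumor, shared germline, independent or
  clonally-related pairs, PT→RD clonal evolution, post-treatment immune
  shifts, mostly-private TCR repertoires) so every stage runs and is tested
  at desk scale.

## Worked example

```python
from sbbc import SimConfig, simulate_bundle
from sbbc.io_cli import run_relatedness, run_cluster, run_clinstats

bundle = simulate_bundle(SimConfig(n_pairs=313, n_sequenced_pairs=6, seed=0))

pairs = run_relatedness(bundle)
print(pairs.groupby("pair_type")[["shared_pct", "cna_cosine_distance"]].mean().round(3))
#             shared_pct  cna_cosine_distance
# pair_type
# PT-RD           80.113                0.159
# left-right       0.000                0.925

clu = run_cluster(bundle)
print(clu["copair_rate"])          # 1.0
cs = run_clinstats(bundle)
print(round(cs["subtype_kappa"], 3))                    # 0.619
print(round(cs["til_interaction"].p_interaction, 4))    # 0.0004
```

Left–right tumor pairs share no somatic mutation and sit far apart in
copy-number space (mean cosine distance 0.925) — independent primaries —
while each primary tumor and its own residual disease share ~80% of their
mutations and stay close (0.159): the same tumor before and after therapy.
Every post-treatment expression profile clusters nearest its own primary
(co-pairing rate 1.0).  At the clinical level the left and right subtypes
agree far beyond chance (kappa 0.62), and the TIL interaction test detects
the simulated luminal-in-discordant-pair boost (p = 0.0004 < 0.10).

The same stages are available as a CLI over plain-text bundle directories:

```bash
sbbc simulate --seed 0 --out cohort/
sbbc relatedness --bundle cohort/ --seed 0 --out results/
sbbc clinstats   --bundle cohort/ --seed 0 --out results/
```

All outputs are deterministic under a fixed `--seed` and independent of
`--threads`.

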