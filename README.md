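# pidap — piRNA–disease association prediction with a multi-channel graph VAE

PIWI-interacting RNAs (piRNAs) are small non-coding RNAs implicated in a
growing list of human diseases, but experimentally validating individual
piRNA–disease links is slow and expensive. `pidap` implements a computational
screen: given known associations, piRNA sequences and a disease-term
hierarchy, it ranks the unknown (piRNA, disease) pairs by their predicted
probability of association, so laboratory follow-up can focus on the most
promising candidates.

## Method

The pipeline has four stages:

1. **Similarity networks.** Four weighted graphs are built:
   * piRNA sequence similarity `P(pᵢ,pⱼ) = Cov(F_{Pᵢ},F_{Pⱼ}) / (σ_{F_{Pᵢ}} σ_{F_{Pⱼ}})`,
     the Pearson correlation of 3-mer frequency vectors (4³ = 64 dimensions),
     clamped to [0, 1];
   * disease semantic similarity over the hierarchy DAG, where a term `t`
     contributes `D_d(t) = α^depth` to disease `d` (α = 0.5) and
     `D(dᵢ,dⱼ) = Σ_{t∈T(dᵢ)∩T(dⱼ)} (D_{dᵢ}(t)+D_{dⱼ}(t)) / (D(dᵢ)+D(dⱼ))`;
   * Gaussian Interaction Profile (GIP) kernels for both node classes,
     `exp(−λ‖A(i)−A(j)‖²)` over association-matrix rows/columns with
     bandwidth `λ = N / Σ‖A(m)‖²`.
2. **Multi-channel graph VAE.** Each network is encoded by a two-layer GCN
   (`Ĥ = ReLU(D̃^{-1/2}ÃD̃^{-1/2} H W)`, widths 48 → 16) into per-node Gaussian
   latents (μ, log σ); latents are sampled as `Z = μ + σ∘ε` and decoded by the
   inner product `sigmoid(ZZᵀ)`. Training minimizes reweighted binary
   cross-entropy against the similarity matrix plus the KL divergence to the
   standard-normal prior (Adam, lr 0.001, 50 epochs). The two piRNA channels
   share one encoder, and likewise the two disease channels.
3. **Pair classifier.** A pair (p, d) is represented by the 64-dimensional
   concatenation `F = (Z_PS[p] ‖ Z_DS[d] ‖ Z_PG[p] ‖ Z_dG[d])` and scored by a
   three-layer network (64 → 48 → 16 → 1, sigmoid output); `ŷ > 0.5` calls a
   positive.
4. **Evaluation.** Equal-count negative sampling from the unknown cells,
   stratified five-fold cross-validation with per-fold masking of test
   positives before the GIP kernels are built, and AUC / AUPR / accuracy /
   precision / recall / F1 / MCC reporting, plus ablation presets
   (`no_gvae`, `no_nn`, `association_only`, `attribution_only`).

A synthetic generator (`pidap.synthetic`) plants consistent 3-block structure
in sequences, hierarchy and associations so the whole pipeline is testable
offline.

## Worked example

```python
from pidap import default_fixture, run_cv

seqs, assoc, dag, truth = default_fixture()   # 60 piRNAs x 12 diseases, 3 blocks
report = run_cv(seqs, assoc, dag, seed=7)
print(report.round(3))
```

```
           auc   aupr  accuracy  precision  recall     f1    mcc
fold1    0.823  0.791     0.794      0.852   0.719  0.780  0.596
fold2    0.870  0.855     0.810      0.857   0.750  0.800  0.625
fold3    0.919  0.943     0.857      0.958   0.742  0.836  0.732
fold4    0.883  0.866     0.857      0.806   0.935  0.866  0.724
fold5    0.816  0.761     0.806      0.732   0.968  0.833  0.648
Average  0.862  0.843     0.825      0.841   0.823  0.823  0.665
```

Each row is one held-out fold of the sampled pair list (157 positives + 157
negatives); the `Average` row is the across-fold mean. A mean AUC of 0.86
means a randomly chosen true association outranks a randomly chosen
non-association 86% of the time — the planted block structure is recovered
far above the shuffled-label chance level of ≈ 0.5.

The same pipeline runs from the shell:

```bash
pidap simulate --out-dir fixture --seed 7
pidap evaluate --fasta fixture/sequences.fasta --assoc fixture/associations.tsv \
  --dag-edges fixture/dag_edges.tsv --dag-map fixture/dag_map.tsv \
  --seed 7 --report report.tsv
```

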