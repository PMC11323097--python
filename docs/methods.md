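# Methods

## Model

`pidap` predicts missing links in a bipartite piRNA–disease association
network. The modelling assumption is homophily on both sides: piRNAs with
similar sequences or similar association profiles tend to share diseases, and
diseases close in the descriptor hierarchy or with similar profiles tend to
share piRNAs. Four views of that homophily are encoded as weighted graphs
(sequence, semantic, and one interaction-profile kernel per node class), a
variational graph autoencoder compresses each view into 16-dimensional node
embeddings, and a small feed-forward network scores pairs from the
concatenated embeddings.

### Similarity layer

* **Sequence channel.** Overlapping k-mer counting (k = 3, 64 features,
  lexicographic column order) normalized by the window count, so sequence
  length does not confound the profile; similarities are Pearson
  correlations. Negative correlations are clamped to 0 because the GCN's
  symmetric normalization `D̃^{-1/2}ÃD̃^{-1/2}` requires non-negative weights.
  Uracil is normalized to thymine at load so one 4-letter alphabet suffices.
* **Semantic channel.** For disease d anchored at term a, every ancestor t
  of a contributes `D_d(t) = α^(shortest child-path distance from t to a)`
  with α = 0.5 — the closed form of the recursion "max over children of
  α·D_d(child)" on the ancestor closure T(d). Pair similarity is the shared
  contribution mass normalized by `D(dᵢ) + D(dⱼ)`. The package consumes a
  pre-extracted parent→child edge list rather than parsing MeSH XML; any
  acyclic vocabulary works.
* **GIP channels.** `exp(−λ‖A(i)−A(j)‖²)` on association-matrix rows
  (piRNAs) or columns (diseases). The default bandwidth is the normalized
  convention `λ = N / Σ_m‖A(m)‖²` (one over the mean squared profile norm),
  which keeps the kernel scale stable as data grow; the inverted form
  `λ = (1/N)Σ_m‖A(m)‖²` is available as `gip_bandwidth="as_printed"` for
  strict fidelity to the formula as sometimes typeset.

All four matrices are exactly symmetric with unit diagonal and entries in
[0, 1]; the diagonal is forced to 1 even where the formula already yields it,
as cheap numerical hygiene.

### Representation learning

Each channel's encoder is a two-layer GCN: a shared ReLU layer of width 48,
then separate linear heads of width 16 for μ and log σ (linear so log σ can be
negative). The similarity matrix's unit diagonal serves as the self-loop, so
Ã = S. Latents are sampled with the reparameterization trick and decoded by
`sigmoid(ZZᵀ)`. The loss per channel is

* reconstruction: mean binary cross-entropy between the decoded matrix and
  the similarity entries used as soft labels, with the positive term
  reweighted by `(p² − ΣS)/ΣS` (standard practice for sparse graphs,
  configurable);
* regularization: the Gaussian KL to the standard-normal prior, averaged
  over nodes, with weight β (default 1.0 — with the KL already per-node,
  a further 1/p factor would double-normalize).

The two channels of one node class are trained under a single parameter set:
each epoch accumulates both channels' gradients before one Adam step
(lr 0.001, betas 0.9/0.999, full batch, 50 epochs). Node features are the
association-matrix rows for piRNA channels and columns for disease channels.
Embeddings handed to the classifier are the means (Z = μ), keeping the
downstream evaluation deterministic; sampling remains active during
training. One epoch draws one ε sample per channel. Everything is plain
numpy with analytic gradients, verified against central finite differences in
the test suite; training is bit-reproducible given a seed. The
`encoder="identity"` option replaces Â with I, giving the graph-free VAE
baseline used in the tests to show that the graph convolution contributes to
planted-structure recovery.

### Classification and evaluation

Pairs are featurized as `(Z_PS[p] ‖ Z_DS[d] ‖ Z_PG[p] ‖ Z_dG[d])` (64 dims)
and scored by a 64→48→16→1 network, ReLU hidden activations, logistic output,
trained with binary cross-entropy by Adam (lr 0.001). Classifier epochs
default to 200 with early stopping once the training loss improves by less
than 1e−5 for 10 consecutive epochs; no dropout or weight decay. The
positive call is the strict rule `ŷ > 0.5` (a tie at exactly 0.5 is
negative). The fit is delegated to scikit-learn's multilayer perceptron;
scoring is an explicit forward pass over the stored weight matrices.

Cross-validation samples negatives once (uniformly, without replacement, 1:1
with positives), splits the pooled pairs into five stratified folds, and for
each fold masks the test-fold positives out of the association matrix before
building the GIP kernels and the GVAE node features — the leakage-safe
default. `gip_from="full"` instead feeds the complete matrix to the kernels,
reproducing the common (leaky) protocol; the switch deliberately governs only
the kernels, since the node features' role in reconstruction makes masking
them unambiguous good practice. AUC uses the rank statistic with ties
counted half; AUPR is the precision–recall step integral; threshold metrics
come from the confusion matrix at the strict 0.5 rule.

## Synthetic data

The generator emulates the statistical shape of a curated piRNA–disease
benchmark: a sparse binary matrix with low-rank block structure
(within-block association probability 0.6, background 0.02 — a clearly
planted but noisy signal), piRNA-length sequences (26–32 nt) carrying two
copies of an 8-nt block motif over a uniform background, and a depth-3
hierarchy whose subtrees coincide with the disease blocks. Planting the
signal in all three modalities makes each of the four channels individually
informative, which is what gives the ablation comparisons content. The
default sizes (60 piRNAs, 12 diseases, 3 blocks) keep a full five-fold run
near one second, so multi-seed protocols remain cheap.

What the fixture does **not** emulate: the extreme piRNA/disease asymmetry of
real catalogues (thousands of piRNAs, tens of diseases), realistic MeSH
topology (multiple parentage, depth variation), k-mer composition bias, or
label noise. Passing tests therefore demonstrate correct mechanics and
recoverability of planted structure, not expected performance on real data.

## Numerical choices

* Similarity matrices are symmetrized as `(S + Sᵀ)/2` (exact in IEEE
  arithmetic) and clamped; probabilities entering logs are clipped at 1e−7.
* The stable softplus form of BCE-with-logits is used inside training.
* Weight init is Glorot-uniform from a seeded generator; every derived seed
  is drawn below 2³¹ from one root generator, so runs are reproducible
  end-to-end from a single integer.
* A zero-variance feature row (constant k-mer profile) has undefined Pearson
  correlation; its off-diagonal similarities are set to 0 with a warning.
* An all-zero association matrix leaves the GIP bandwidth undefined and is a
  hard error; a single all-zero profile among non-zero ones is allowed.

## Design choices on genuinely open points

* **Sharing granularity.** "Shared parameters for homogeneous networks" is
  read as one encoder per node class applied to both of that class's
  channels; sharing across classes is impossible because node counts and
  feature widths differ.
* **μ/log σ heads** share the first GCN layer and keep separate second-layer
  weights, the convention of reference VGAE implementations.
* **Sequential staging.** Embeddings are frozen before the classifier is
  fitted; no end-to-end fine-tuning.
* **Stratified folds** are used although plain equal splitting would also be
  defensible; stratification stabilizes small-fold metrics.
* **Negatives are sampled once** before fold splitting, so the pair list is
  fixed across folds.

## Known limitations

* At the default fixture scale the sequence+semantic channels alone nearly
  saturate the recoverable signal, so the two-channel `association_only`
  ablation can score within seed noise of — and occasionally above — the
  full four-channel model (mean AUC gap ≈ 0.003–0.009 against a seed spread
  of ≈ 0.01). Two scale effects drive this: the leakage-safe per-fold
  masking creates a train/test feature shift in the GIP channels (a training
  pair's own association is visible in its GIP profile, a test pair's is
  masked), and with only 12 diseases each masked link perturbs the kernels
  noticeably. Under `gip_from="full"` the shift disappears but the raw
  similarity-row baseline (`no_gvae`) then inherits the leak directly and
  can overtake the full model. The advantage of the four-channel design is
  expected to assert itself at realistic scale, where profiles are long and
  single links are individually negligible.
* The `no_nn` ablation scores near chance here by construction: without the
  classifier, the piRNA and disease latent spaces are produced by separate
  encoders and share no alignment, so cross-class inner products are
  uninformative in a sequential pipeline.
* Embedding quality depends on the association matrix through both the GIP
  kernels and the node features; for diseases with no remaining training
  links the embeddings fall back to graph-smoothed priors.
* The package does not download or parse external resources (benchmark
  associations, MeSH XML); it consumes the documented plain-text formats.
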