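# Methods

## The model

`mampep` predicts whether a short peptide (8–11 residues) binds a class I
MHC molecule, and — more importantly — explains the prediction per site so
that the explanation can drive peptide design.

Each residue is embedded into a trainable `d = 15` dimensional vector (the
20×15 table is initialized uniform ±0.05 and learned jointly with the rest
of the network; no pretrained residue embeddings are used). Two 1-D
convolutional levels follow, with 16 and 32 filters respectively, kernel
length 7, stride 1 and zero "same" padding, each passed through a leaky
rectifier with negative slope 0.3; dropout (rate 0.25) is applied between
level 1 and level 2 during training only. "Same" padding is essential: it
keeps every level's feature map exactly L sites long, which is what lets
the attribution below index features by input site and lets one trained
model score any peptide length without rebuilding.

Each level `i` is reduced by a bias-free global-average-pooling (GAP) head,

    c_i = Σ_j W_ij · mean_k F_ijk ,

where `F_ijk` is the post-activation value of filter `j` at site `k`.
A second bias-free linear map fuses the level contributions into the
binding probability

    P = sigmoid(Σ_i m_i · c_i).

Training minimizes binary cross-entropy plus an L2 penalty (coefficient
0.01, Keras convention `λ·Σw²`) on the convolution kernels and both linear
heads — not the embedding and not the convolution biases — using Adam
(base learning rate 1e-3, β₁ = 0.9, β₂ = 0.999), mini-batches of 64 and a
maximum of 400 epochs. A binder is defined as IC50 < 500 nM, strictly; a
peptide at exactly 500 nM is a non-binder.

The whole network, including backpropagation through the embedding,
convolutions, dropout and both heads, is implemented directly on numpy
arrays in `mampep.network`. Every random draw (initialization, shuffling,
dropout, mutation) flows from explicit `numpy.random.Generator` seeds, so a
(config, seed, data) triple reproduces trained parameters bit-for-bit on
one platform.

### Early stopping

Training monitors the epoch's mean minibatch loss as optimized (dropout
noise and L2 term included — the convention of mainstream deep-learning
frameworks when monitoring "loss"), stops after `patience = 20` epochs
without an improvement larger than `min_delta = 1e-4`, and restores the
best-loss parameter snapshot. The `min_delta` floor exists because a
strictly-positive improvement test on a continuously decreasing training
loss would never plateau; 1e-4 is well below any meaningful loss change at
these data sizes. An optional validation-split monitor
(`TrainConfig(monitor="val")`) is available.

### Ensembling and transfer

`train_ensemble` trains `n_models` members (default 10; member `i` uses
seed `config.seed + i`) and merges both probabilities and site scores by
arithmetic mean. Transfer to a new allele comes in two modes: *zero-shot*
(apply the ensemble unchanged) and *fine-tune* (`fine_tune`, continue
training every member on the new data at `0.1 ×` the base learning rate,
same early stopping; the input ensemble is never modified in place).

## Site attribution (the motif activation map)

Because the heads are linear, the trained weights map back onto the feature
maps as a per-site contribution score

    S_k = Σ_i m_i · Σ_j W_ij · F_ijk .

`S` deliberately omits the 1/L pooling factor: under "same" padding that
factor is a uniform positive rescaling (identical for both levels), so
signs and rankings are unchanged and the exact identity

    sigmoid(mean_k S_k) = P

holds, i.e. the attribution provably decomposes the prediction. The test
suite checks this identity to 1e-6 and checks `S` itself against an
independent loop-wise evaluation of the triple sum to 1e-5.
`sign(S_k)` marks motif-candidate sites; a site whose score is negative
cannot be a motif site. Over a peptide set, a site is called *important*
iff its mean score is strictly positive (the reading rule applied to the
boxplot export). Exported artifacts (`export_views`) are a peptides × sites
heatmap TSV, a per-site statistics TSV and a position frequency matrix in a
plain tab-separated layout consumable by standard logo tools; PNG renders
are optional and the text artifacts are byte-reproducible.

## Generation by lowest-score mutation

Anchor motifs dominate binding, and low-contribution sites are expendable.
`generate` keeps the peptides the ensemble predicts as binders (averaged
probability strictly above 0.5 — the cutoff is configurable since the
generation step's threshold is a free choice), computes member-averaged
site scores, and substitutes the argmin-score site (leftmost on ties) with
a residue drawn uniformly from the 19 alternatives. One round, one site:
every product is Hamming distance 1 from its parent. `random_site_control`
draws the site uniformly instead and is the package's evaluation baseline.
Uniform replacement is deliberate — weighting replacements by observed
binder frequencies would leak the target motif into the generator.

## The synthetic oracle

`mampep.synthetic` supplies the ground truth that real affinity data and
external scoring servers would otherwise provide. An allele is an additive
position-energy model over the 20-letter alphabet: `E(p) = Σ_k w_k(p_k)`,
mapped to affinity by `IC50 = 50000 · exp(−E)` nM. The 50 µM ceiling is the
conventional assay upper bound, and the log-linear map turns the 500 nM
binder rule into a clean energy cutoff `ln(100) ≈ 4.61`. The default allele
is a 9-mer model with anchors at site 2 and the C-terminal site 9 (the
classic HLA-A2-like pattern), each anchor holding 2–3 preferred residues at
energy `3.2 ± 5%` and a small negative energy elsewhere chosen to make the
anchor row mean-zero — so an all-anchors-matched peptide sits at `E ≈ 6.1`
(comfortably a binder) while a random peptide has expected energy 0 (the
assay ceiling). Binders are sampled per-site from the softmax of the
energies and rejection-filtered to label 1; non-binders are uniform
peptides filtered to label 0; class counts are exact and every record
carries its oracle IC50. `make_related_allele` keeps a chosen fraction of
anchor columns verbatim and re-draws the rest at fresh sites, producing
"near" (zero-shot-friendly) and "far" (fine-tune-needing) alleles.

What the simulator does *not* emulate: assay noise and censoring, mixtures
of quantitative and binary measurements, duplicate/conflicting records,
length polymorphism within one allele's data, and epistatic (non-additive)
site interactions. Passing tests therefore demonstrate correctness of the
machinery and the qualitative behavior of the method under a clean additive
ground truth — not performance on measured affinity data.

## Reference benchmark and measured behavior

`mampep.benchmarks` fixes the package's reference protocol, used by the
test suite and by `scripts/acceptance.py`: per seed, sample 1000 binders +
1000 non-binders from the default allele, split 95:5, train a 3-member
ensemble (3 members keep a five-seed study on one CPU in the tens of
minutes; the ensembling default elsewhere remains 10), and evaluate.
Transfer runs use 300 + 300 peptide samples of the related alleles for
evaluation and for fine-tuning.

Under this protocol the predictor itself is essentially perfect (held-out
AUC 1.0 across seeds) and transfer behaves as the motif-sharing model
predicts: zero-shot AUC is ~1.0 on a fully-shared allele, near chance on a
motif-disjoint one, and fine-tuning at 1/10 learning rate recovers the far
allele (AUC ≳ 0.85) in every seed.

## Known limitations

**Attribution is receptive-field-blurred, and that bounds what generation
can do.** The per-site score attributes to *feature* sites, but a kernel-7
filter that detects an anchor residue at position `p` can place its
response at any site `k` with |k−p| ≤ 3 — global average pooling makes all
placements exactly equivalent for the loss, so nothing in training favors
the aligned placement. Anchor credit therefore smears over a ±3-site band,
and terminal sites are additionally attenuated because their windows
overlap the zero padding (fewer active taps). In the reference benchmark
the mean-score profile over true binders is reliably *positive around* both
anchors (sites 1–3 and 6–8 bright) but its top-2 sites are typically
neighbors of the anchors rather than the anchors themselves, and the
C-terminal anchor's own score is often negative. Consequently, argmin-score
mutation occasionally lands on the C-terminal anchor and destroys binding:
the guided generator's oracle high-affinity rate (~0.72 seed-mean) does not
beat a single-site random-mutation control (~0.79) under the additive
oracle, although it trivially dominates fully random peptides (rate ≈ 0.01
at these anchor strengths). Sharper localization would require an
architectural change outside this package's scope — smaller kernels,
positional regularization of the attribution, or occlusion-style scoring.

Other limitations: the binder threshold enters training only through
labels (no regression head), SRCC against continuous affinities is
therefore computed on a classifier's probabilities; class weighting is not
implemented (the simulator produces balanced data); and the optimizer,
batch size and initialization schemes are fixed choices exposed through
`TrainConfig`/`ArchSpec` rather than searched.
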