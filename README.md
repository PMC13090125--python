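# dreams-desk

Self-supervised molecular representations of tandem mass spectra, at desk
scale. The package implements the full method stack behind transformer
embeddings of MS/MS spectra — from raw LC-MS/MS files to a similarity atlas —
so that every stage can be exercised, tested, and studied on a single CPU
with synthetic data.

## Who this is for

Computational metabolomics researchers who want a transparent, hackable
implementation of the components used in repository-scale MS/MS
representation learning: quality-controlled spectrum mining, spectral
deduplication, leakage-controlled dataset splitting, a spectrum transformer
with self-supervised and supervised objectives, and molecular-network
construction over embeddings.

## The method

**Mining and QC.** mzML/mzXML runs are screened at the file level (retention
time order, MS-level sequences) and the spectrum level (peak counts,
intensity amplitude *i*max/*i*min, precursor charge and m/z, positive mode,
centroidedness). Instrument m/z accuracy is estimated as the median of m/z
standard deviations within extracted ion chromatograms: a coarse 0.5 Da XIC
pass over MS1 base peaks seeds a fine 0.01 Da pass, and only XICs with ≥ 5
points contribute. Filtered spectra are packed into an HDF5 tensor store
(fixed-width zero-padded peak matrices plus metadata vectors).

**LSH deduplication.** A spectrum binned into 1 Da bins over [0, 1000) Da is
hashed by *m* random hyperplanes, h(**s**) = [**Ws** ≥ 0]. Two spectra share
a hash bit with probability 1 − arccos(cos(**s**i, **s**j))/π, so exact-key
grouping clusters by cosine similarity in linear time; clusters are capped
at a fixed number of randomly retained representatives.

**Murcko-histogram splits.** A molecule's Murcko scaffold is summarized as a
histogram over (fused-ring-neighbor count *r*, adjacent-linker count *l*)
pairs. Two histograms are "related" when either has fewer than *k* = 4 rings
and they are identical, or the L1 distance between their ring-neighbor
marginals is below *m* = 5. Validation molecules related to any training
molecule are relocated to training, eliminating near-duplicate scaffold
leakage that structure-disjoint (InChI-key) splits miss.

**The spectrum transformer.** Each spectrum is a 2×(n+1) matrix: a precursor
token (m₀, 1.1) followed by (m/z, relative intensity) peaks. Every m/z value
is expanded into mass-tolerant Fourier features over a fixed frequency grid
(1,000 low frequencies 1/k for integer masses, plus high frequencies down to
the instrument accuracy; 6,000 in the default grid), passed through a
feed-forward branch of width *d*ₘ and concatenated with a shallow branch of
the raw (m, i) pair of width *d*ₚ. A pre-norm transformer encoder (no linear
biases, ReLU) refines the peak set; attention scores receive an additive
Graphormer-style term, the summed difference of Fourier features between the
two peaks, which exposes every pairwise m/z difference (neutral loss)
directly to each head. The network runs on a compact numpy autodiff engine
included in the package.

**Self-supervised objectives.** 30% of peaks per spectrum (sampled
proportionally to intensity, never the precursor token) have their m/z
replaced by −1.0, and the model classifies each masked mass into one of
c = 20,000 bins over (0, 1000) Da. Pairs of spectra from one run are also
classified by retention order. The total loss is 0.8·L_mass + 0.2·L_order.
Spectra are augmented by shifting all m/z values by a shared random scalar
in (0, 50) Da with probability 0.2.

**Transfer learning.** Task heads and losses for contrastive embedding
refinement (hinge triplet margin loss on cosine similarities, with hard
negatives mined within 0.05 Da of the reference precursor mass), Morgan
fingerprint prediction (1 − cosine loss, DeepSets-style head over all peak
embeddings), 11-property regression (min-max scaled MSE), and fluorine
detection (focal BCE, α = 0.8, γ = 0.5), plus evaluation metrics
(Pearson correlation, AUROC, retrieval accuracy@k).

**Atlas.** A directed k-NN graph (k = 3) over embeddings with
cosine-similarity edges; neighborhoods with similarity ≥ 0.9 to their
highest-degree node are collapsed by BFS, the graph is rebuilt on
representatives, and annotations propagate along shortest high-similarity
paths.

## Worked example

```bash
python examples/04_pretrain_tiny_model.py
```

prints

```
per-masked-peak cross-entropy: 6.82 -> 5.42 nats
uniform-prediction baseline ln(1000) = 6.91 nats
```

meaning: after 100 steps on 400 synthetic spectra, the tiny model's
masked-mass predictions already carry ≈ 1.5 nats of information beyond the
uniform guess over the 1,000 mass bins — it has started learning which
fragment masses co-occur. The other examples (`examples/01…06`) walk through
QC, LSH deduplication, Murcko splitting, fingerprint fine-tuning with
retrieval, and atlas construction, each printing the quantities it computes.

A command-line face covers the shell-level workflows:

```bash
dreams simulate run --seed 1 --out run.h5
dreams cluster run.h5 --planes 64 --cap 10 --out dedup.h5
dreams pretrain --store dedup.h5 --steps 100 --out model.ckpt
dreams embed dedup.h5 --ckpt model.ckpt --out emb.npy
dreams atlas build --emb emb.npy --k 3 --out atlas.graphml
```

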