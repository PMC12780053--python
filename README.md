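# fgcnmf

Fast graph-convolutional matrix-factorization link prediction for
microbe–disease association networks.

## The problem

Curated databases of microbe–disease associations (HMDAD, Disbiome and the
analogous microbe–drug resources) are sparse: a few hundred confirmed links
among tens of thousands of possible pairs. Prioritizing which unobserved
pairs to investigate next is a link-prediction problem on a heterogeneous
network whose nodes are microbes and diseases, with within-type functional
similarity edges and cross-type association edges. `fgcnmf` is for
computational biologists who have (a) a known-association list and (b) two
within-space similarity matrices, and want ranked novel candidates plus a
rigorous, leakage-safe estimate of predictive performance.

## The method

1. **Network assembly.** Each similarity matrix is sparsified to a binary
   top-*n* neighbor graph (`SM`, `SD`). With the binary association matrix
   `MD`, the heterogeneous adjacency is

   ```
   H = [[SM, MD],
        [MDᵀ, SD]],     D_ii = Σ_j H_ij,     Ĥ = D^{-1/2} H D^{-1/2}.
   ```

2. **Matrix-factorization initialization.** On the support of `H`, a sparse
   log-ratio proximity matrix is built from the random-walk transition
   probabilities `p_ij = H_ij / D_ii` and per-node negative-sampling
   weights `N_j ∝ Σ_i p_ij` (normalized to sum to 1):

   ```
   C_ij = log p_ij − log N_j    if H_ij = 1, else 0.
   ```

   `C` is factorized by randomized SVD: project through a Gaussian test
   matrix `U ~ N(0, 1/d)`, orthonormalize `CU = QR`, take the small dense
   SVD `QᵀC = SΣVᵀ`, and set the initial embedding `F⁽⁰⁾ = QSΣ^{1/2}`.

3. **Parameter-free propagation.** Embeddings are refined by `l` rounds of
   normalized-adjacency multiplication and the layer outputs are averaged:
   `F = (ĤF⁽⁰⁾ + Ĥ²F⁽⁰⁾ + … + ĤˡF⁽⁰⁾)/l`, which mixes neighborhood
   smoothing at several radii without trainable weights.

4. **Pair classification.** A (microbe, disease) pair is represented by the
   elementwise product of the two nodes' final embedding rows
   (concatenation and averaging are also available) and scored by a seeded
   extremely-randomized-trees ensemble (six other backends selectable:
   random forest, XGBoost, GBDT, AdaBoost, SVM, logistic regression).
   Unobserved pairs are treated as unlabeled and sampled 1:1 as negatives.

Evaluation uses repeated 5-fold cross-validation over the known links with
strict leakage control: held-out test links are removed from the adjacency
*before* the proximity matrix, factorization and propagation are computed,
and an internal assertion aborts any fold in which a test edge reaches the
training graph. AUC (midrank ties) and AUPR (step-curve average precision)
are reported as mean ± sd over repeats.

Because the public benchmark datasets are distributed only as summary
statistics, the package ships a planted-block synthetic generator that
emulates their scale and density (292×39 at density 0.0395; 1052×218 at
0.0189) for end-to-end testing and calibration.

## Worked example

```python
import fgcnmf as f

sim_m, sim_d, MD = f.generate(f.hm_like(seed=1))   # synthetic benchmark-scale data
model = f.FGCNMFModel(MD, sim_m, sim_d)            # default HM-style config
res = model.fit(seed=1)
print(res.summary())
for rank, (microbe, score) in enumerate(res.rank_candidates("d0003", top_k=5), 1):
    print(rank, microbe, f"{score:.3f}")
cv = model.cross_validate(n_repeats=3, seed=1)
print(f"AUC  {cv.auc_mean:.4f} +/- {cv.auc_std:.4f}")
print(f"AUPR {cv.aupr_mean:.4f} +/- {cv.aupr_std:.4f}")
```

prints

```
FGCNMF link-prediction results
==============================================
microbes                                   292
diseases                                    39
known links                                459
sparseness                              0.0403
network edges (H nnz)                     2968
----------------------------------------------
top-n neighbors                              5
embedding dim d                             32
propagation layers l                         3
pair operator                         hadamard
classifier                         extra_trees
seed                                         1
==============================================
1 m0155 0.815
2 m0179 0.795
3 m0099 0.790
4 m0003 0.775
5 m0059 0.775
AUC  0.9117 +/- 0.0080
AUPR 0.8803 +/- 0.0230
```

The summary describes the dataset (459 realized links at density 0.0403 for
this draw) and the configuration; the ranked list gives the five strongest
novel microbe candidates for disease `d0003` with their association scores;
the cross-validation lines estimate out-of-sample ranking quality — here the
planted block structure is recovered well above chance.

The same stages are scriptable from a shell:

```sh
fgcnmf synth --preset hm --seed 1 --out data/
fgcnmf cv --assoc data/associations.tsv --sim-m data/microbe_similarity.tsv \
          --sim-d data/disease_similarity.tsv --repeats 3 --seed 1 --out results.json
```

(`fgcnmf build`, `embed`, `enhance`, `train` and `rank` expose the
individual stages.)

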