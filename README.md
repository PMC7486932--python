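# structkit

Statistics for fine-grained population structure inferred from haplotype
sharing. `structkit` consumes the outputs of chromosome-painting and
IBD-detection tools — ChromoPainter-style chunklength (coancestry)
matrices and RefinedIBD-style segment lists — and implements the layer of
bespoke statistics that turns them into population-genetic conclusions:

* **Cluster validation by total variation distance (TVD).** The copying
  vector of a cluster *A* is its average donation profile over all
  clusters; the distinctness of clusters *A* and *B* is
  `TVD(A,B) = ½ Σ_k |v_A,k − v_B,k|` on normalized vectors. Significance
  comes from a permutation test that reassigns the pooled members of the
  two clusters to pseudo-clusters of the original sizes (enumerated
  exhaustively whenever the number of distinct splits permits). Cluster
  relations are summarized by a tree built in k−1 successive lowest-TVD
  merges, with TVD recomputed over the reduced cluster set at each step.
* **NNLS ancestry profiles.** Each target's normalized copying vector
  `Y_p` over G donor groups is decomposed as
  `Y_p = β₁X₁ + … + β_G X_G` with `β ≥ 0, Σβ = 1`, where `X_g` is donor
  group g's own average copying profile. Groups contributing under 5%
  are pruned and the model refit; shares aggregate by country. The
  geographic axis of each ancestry component is found by scanning compass
  bearings in 1° steps for the projection maximizing regression r², and
  spatial autocorrelation is assessed by Moran's I and the Mantel test.
* **Time-stratified IBD analysis.** Pairwise sharing matrices are built
  per segment-length bin [L1, L2) cM; in a large population segments in
  that bin coalesce at `E[T] = 75(1/L1 + 1/L2)` generations (×28 years
  per generation), so the 3–5 cM bin reflects structure ~1120 years ago
  and the 5–7 cM bin ~720 years ago. Individuals are clustered per bin by
  PCA plus a BIC-selected Gaussian mixture, and within/between-group mean
  sharing uses exact pair-count denominators `(N²−N)/2` and `NM`.
* **GWAS confounding.** Nagelkerke pseudo-R² of a binary phenotype on
  structure covariates (e.g. coancestry PCs) quantifies stratification.
* **A synthetic structured-cohort generator** with known ground truth:
  block-structured coancestry with spatial decay (`exp(−d/ρ)`, within-deme
  boost 1+κ, Dirichlet row noise), IBD segments with Poisson event counts,
  gamma coalescence times and Erlang(2, t/50 per cM) lengths — the unique
  length law under which the bin-dating formula above is exact — linear
  spatial ancestry gradients, and deme-stratified case/control labels.
  Everything downstream is verified against this generator; no external
  or access-controlled data are required.

## Worked example

```python
import structkit as sk
from sklearn.metrics import adjusted_rand_score

cfg = sk.ScenarioConfig(n_demes=3, n_per_deme=20, within_deme_boost=50.0,
                        spatial_decay=0.2, seed=7)
cohort = sk.generate_cohort(cfg)
clusters = sk.ClusterAssignment(cohort.deme_labels())

vectors = sk.copying_vectors(cohort.coancestry, clusters)
print("TVD(deme0, deme1) =", round(sk.tvd_pair(vectors, "deme0", "deme1"), 3))
res = sk.tvd_permutation_test(cohort.coancestry, clusters, "deme0", "deme1",
                              n_perm=1000, seed=0)
print("permutation p:", res.p_label)

gen, years = sk.expected_tmrca(sk.SegmentBin(3, 5))
print("3-5 cM bin dates to", gen, "generations =", years, "years")

m = sk.binned_sharing_matrix(cohort.ibd, sk.SegmentBin(5, 30), roster=cohort.ids)
assignment, bic, k = sk.pca_gmm_cluster(m, n_pcs=5, k_max=5, seed=0)
ari = adjusted_rand_score(cohort.deme_labels().loc[m.ids],
                          assignment.labels.loc[m.ids])
print("IBD 5-30 cM clustering: k =", k, ", ARI vs true demes =", round(ari, 2))
```

prints

```
TVD(deme0, deme1) = 1.0
permutation p: <0.001
3-5 cM bin dates to 40.0 generations = 1120.0 years
IBD 5-30 cM clustering: k = 4 , ARI vs true demes = 0.98
```

The two demes are maximally distinct in haplotype donation (TVD ≈ 1.0;
none of 1000 permutations reaches the observed value, so p is reported as
an upper bound), the 3–5 cM segment bin corresponds to an expected common
ancestor 40 generations (1120 years) ago, and Gaussian-mixture clustering
of the long-segment sharing matrix recovers the simulated demes almost
perfectly (a BIC tie between k = 3 and a finer split gives k = 4 here,
with ARI 0.98 against the 3 true demes).

A command-line interface mirrors the library:

```sh
structkit simulate --out cohort/ --seed 3
structkit pca --chunklengths cohort/chunklengths.txt --components 10 --out scores.tsv
structkit tvd --chunklengths cohort/chunklengths.txt --clusters clusters.tsv \
          --n-perm 1000 --seed 0 --out tvd.tsv
structkit ibd-age --l1 3 --l2 5      # prints 40 generations / 1120 years
```

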