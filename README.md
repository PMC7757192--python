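# pgtm

Generative Topographic Mapping (GTM) for large chemical libraries:
standard, incremental and **parallel** manifold training, density and
class landscapes, a log-likelihood applicability domain, and the metrics
used to decide how large a frame set needs to be.

## The problem

GTM embeds a regular 2-D grid of *K* latent nodes into a *D*-dimensional
molecular-descriptor space through a smooth mapping
**y**(**x**) = **φ**(**x**) **W**, where **φ** is a fixed basis of *M*
Gaussian radial basis functions of the latent coordinates, **W** is the
*M × D* mixing matrix and each node is the center of an isotropic Gaussian
of precision β.  Fitting **W** and β by expectation-maximization yields a
curved "map" of chemical space on which compounds are located by their
posterior node memberships (*responsibilities* r<sub>nk</sub>).  Summing
responsibilities per node gives a density landscape; averaging class
labels with responsibility weights gives a class landscape usable as a
QSAR classifier.

Standard GTM must hold every frame-set compound in memory at every EM
iteration, which in practice caps the frame set at a few 10⁴ compounds.
This package implements two block-based ways around the cap:

* **iGTM** — blocks are fitted sequentially with warm starts (the result
  depends on block order);
* **pGTM** — one incremental PCA over the whole frame set builds a shared
  initialization, every block of ≤ 5000 compounds is fitted independently
  (dispatchable to any number of workers without changing the result),
  and the block manifolds are merged by element-wise averaging:
  w̄<sub>m,d</sub> = Σᵢ w<sub>m,d,i</sub>/N,  β̄ = Σᵢ βᵢ/N over the N blocks.

Map quality is scored by (i) the per-descriptor Kullback–Leibler
divergence between frame-set and library histograms (frame-set
representativity), (ii) the normalized Shannon entropy
E<sub>norm</sub> = −100 · Σ p<sub>k</sub> ln p<sub>k</sub> / ln K of the
density landscape (0 = all compounds in one node, 100 = uniform
coverage), and (iii) the number of biological targets whose 3-fold
cross-validated balanced accuracy reaches 0.7 (N<sub>BA</sub>), using a
per-target IC50 labeling protocol that picks active/inactive thresholds
from a fixed nanomolar grid.

Defaults follow the published "universal map" setting: 841 nodes (29×29),
324 RBFs (18×18), weight-decay λ = 3.236, RBF width factor w = 0.4,
block size 5000.

## Worked example

```python
import numpy as np
import pgtm

# 2000 compounds sampled from a planted GTM (20 descriptors, beta = 4)
universe = pgtm.generate_gtm_universe(k_side=10, m_side=5, D=20, N=2000,
                                      true_beta=4.0, seed=1)
data = universe.as_descriptor_matrix()

config = pgtm.TrainingConfig(k_side=10, m_side=5, rel_tol=1e-5)
manifold = pgtm.train_sgtm(data, config)
print(f"converged after {manifold.training_history[-1][0]} EM iterations")
print(f"noise precision beta = {manifold.beta:.3f}  (planted: 4.0)")

resp = pgtm.responsibilities(manifold, data)
thr = pgtm.fit_ad(resp.per_molecule_llh)
mask = pgtm.apply_ad(thr, resp.per_molecule_llh)
print(f"AD threshold = {thr.threshold:.3f}; "
      f"{mask.sum()}/{len(mask)} compounds in domain")

density = pgtm.density_landscape(resp.subset(np.flatnonzero(mask)))
print(f"normalized map entropy = {pgtm.normalized_entropy(density):.2f}")

pg = pgtm.train_pgtm(data, pgtm.TrainingConfig(k_side=10, m_side=5,
                                               block_size=500, rel_tol=1e-5))
print(f"pGTM merged {pg.merge_report.n_blocks} block manifolds; "
      f"beta = {pg.beta:.3f}")
```

prints

```
converged after 48 EM iterations
noise precision beta = 4.082  (planted: 4.0)
AD threshold = -24.785; 1974/2000 compounds in domain
normalized map entropy = 99.95
pGTM merged 4 block manifolds; beta = 4.135
```

The EM fit recovers the planted noise precision within 2 %; the
applicability domain (Gaussian fit to the log-likelihood histogram, cut
at peak − 3σ) keeps almost all of the frame set itself; the near-100
entropy reflects the uniform node occupancy of the generative model; and
splitting the same data into four 500-compound blocks and merging the
independently fitted manifolds lands close to the single-block fit.

A command-line interface mirrors the library
(`pgtm simulate|train|project|landscape|predict|ad|labels|metrics`); each
run writes a JSON manifest with its configuration, seed and input digests
so it can be replayed exactly.

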