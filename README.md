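# spatent

Spatial entropy analysis of multitype cell patterns: per-subject **SPI
curves**, sparse **functional PCA**, and a **Cox likelihood-ratio test**
for whether spatial heterogeneity in the tumor microenvironment carries
survival signal.

## The problem

Multiplexed imaging platforms (mIHC, MIBI, CODEX, IMC, ...) deliver, for
each tissue image, the centroid coordinates and phenotype label of every
cell.  Aspatial diversity indices (Shannon, Simpson) summarize the type
*frequencies* only: any spatial rearrangement of the same cells gives the
same score.  `spatent` quantifies the part of the heterogeneity that is
*due to space* and relates it to patient outcome.

## The method

**Spatial entropy decomposition.** For a pattern with `J` cell types, the
unordered type pair of two cells defines a co-occurrence variable `Z`
with `R = J(J+1)/2` categories.  Cell pairs are binned by inter-cell
distance into ranges `w_k = (d_{k-1}, d_k]` with `d_0 = 0`, `d_K` the
median pairwise distance, breaks decreasing geometrically from `d_K`
("linearly on a log scale") and `K <= 50`.  The Shannon entropy of `Z`
then splits exactly:

```
H(Z) = SPI(Z) + H^W(Z)
SPI_k = sum_r p(z_r | w_k) log[ p(z_r | w_k) / p(z_r) ]      (per-bin spatial information)
H_k^W = sum_r p(z_r | w_k) log[ 1 / p(z_r | w_k) ]           (per-bin residual entropy)
```

with `SPI(Z) = sum_k p(w_k) SPI_k` the mutual information between pair
type and distance.  Under complete spatial randomness `SPI_k ≈ 0` at
every distance; type-segregated (clustered) tissue pushes `SPI_k` up at
short range.  `SPI_k` versus distance is the subject's **SPI curve**.

**Sparse FPCA.** SPI curves are irregularly observed (distance ranges are
subject-specific; empty bins are missing, not zero).  The curves are
modelled as `SPI_ik = mu(s_ik) + sum_l xi_il phi_l(s_ik) + eps_ik`;
mean and covariance are estimated by local-linear smoothing of pooled
observations and of within-subject cross-products, eigenanalysis of the
covariance surface gives `(lambda_l, phi_l)`, and subject scores
`xi_il` are best linear predictors (PACE conditional expectations).  The
number of components `L` is the smallest reaching 92% of the variance.

**Survival.** The hazard model `log h_i(t) = log h_0(t) + U_i' gamma +
xi_i' beta` is fitted by Cox partial likelihood (Breslow ties), and
`H0: beta_1 = ... = beta_L = 0` is tested by the likelihood-ratio
statistic `2 (l_full - l_restricted) ~ chi^2_L`.

A **simulation framework** reproduces the validation design end to end:
clustered vs. random Thomas-process cohorts, noisy SPI curves, linked
proportional-hazards survival with calibrated censoring, and a
three-model NRMSE comparison on train/test splits.

## Worked example

```python
from spatent import simulate_pattern, spi_from_pattern

pattern = simulate_pattern("clustered", n_types=3, cells_per_type=300, seed=1)
curve = spi_from_pattern(pattern, n_bins=15)
print(round(curve.total_entropy, 4), round(curve.spatial_information, 4))
print(curve.spi[:3].round(3))
```

prints

```
1.7436 0.0104
[0.092 0.118 0.098]
```

i.e. the clustered pattern's co-occurrence entropy is 1.7436 nats of
which 0.0104 nats are explained by distance overall, concentrated at
short range (`SPI_k ≈ 0.09-0.12` in the first bins, ~13-36 µm).  The same
cells rearranged uniformly at random give `SPI(Z) = 0.0002` and a flat
curve — identical Shannon/Simpson diversity, different spatial story.
The scripts in `examples/` walk through each capability (SPI curves,
permutation null, sparse FPCA, the survival LRT, the simulation
experiment) and print annotated output.

A thin CLI mirrors the library for shell pipelines:

```bash
spatent entropy --cells cells.csv --K 50 --out curves.csv
spatent fpca --curves curves.csv --fve 0.92 --out fpca/
spatent survtest --clinical clinical.csv --scores fpca/scores.csv --out lrt.json --covars age
spatent run --config pipeline.yaml     # cells -> curves -> FPCA -> LRT + manifest
```

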