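# oasisnet

Spatial network analysis of foraging Egyptian fruit bats (*Rousettus
aegyptiacus*): from radio-telemetry fixes and microsatellite genotypes to
home ranges, pairwise relatedness, space-sharing networks and permutation
inference.  Built for movement ecologists who want the full chain —
triangulation → nightly site visits → networks → MR-QAP — as tested,
scriptable Python rather than a GIS/UCINET/ML-Relate tool chain.

Bats that forage at the same food patch on the same night share space, and
space sharing is the observable proxy for association.  The package asks the
questions that follow: how large are individual home ranges per season
(MCP 95% / core area 50%), are more related bats more likely to share
foraging sites (MR-QAP of the dyadic sharing matrix on the relatedness
matrix), does co-roosting explain sharing instead, and how do network
density, degree, clustering and strength shift between a food-rich and a
food-poor season.  Because the original field data are not public, a
synthetic generator reproduces the study's structure (two seasonal regimes,
~32 bats x 8 nights, 13 microsatellite loci, pedigree kinship, optional kin
attraction) with known ground truth.

## The core quantities

- **Relatedness** r̂ = k̂1/2 + k̂2 from maximum likelihood over the IBD
  simplex: L(k) = Π_loci (k0·P0 + k1·P1 + k2·P2), with the standard
  IBD-conditional genotype-pair probabilities under HWE.
- **Sharing weight** w_ij = |shared sites, same night| / |S_i ∪ S_j|,
  in [0, 1]; an edge exists iff the pair shared at least one site-night.
- **Network metrics** ρ = edges/(n(n−1)/2), k_i = deg_i/(n−1), local
  clustering C_i, strength s_i = Σ_j w_ij.
- **MR-QAP (double semi-partialling)**: OLS over off-diagonal cells; each
  predictor's residual matrix is row/column-permuted to generate its null,
  p = (#{|β*| ≥ |β|} + 1)/(n_perm + 1).  Node-permutation Welch t,
  Kruskal–Wallis and slope tests cover the per-node metrics.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Run the numbered analysis scripts (each is a thin driver over the library;
all randomness flows from `--seed`):

```sh
python analysis/01_simulate.py --seed 0
python analysis/02_visits_homeranges.py
python analysis/03_relatedness.py --n-perm 2000
python analysis/04_networks.py
python analysis/05_inference.py --n-perm 2000
```

Output (seed 0):

```
winter: 32 bats, 3584 fixes, 512 true visits -> results/data/winter
spring: 32 bats, 2639 fixes, 377 true visits -> results/data/spring
MCP spring: median 10.57 ha (IQR 8.38-11.37, n=32)
MCP winter: median 304.38 ha (IQR 232.56-340.31, n=32)
68 individuals, 2278 pairs, mean r = 0.0714
KS winter vs spring: D = 0.052, p = 0.3768
winter: n=32, density=0.9335, mean_degree_norm=0.9335, mean_clustering=0.9397, mean_strength=6.6743
spring: n=32, density=1.0, mean_degree_norm=1.0, mean_clustering=1.0, mean_strength=30.625
winter sharing_vs_relatedness: r = 0.122, p = 0.005997
spring sharing_vs_relatedness: r = 0.001, p = 0.9885
winter sharing_vs_coroosting: r = 0.017, p = 0.6947
degree_norm: t = -5.614, p = 0.0004998
```

Reading it: in the food-poor spring the two remaining date patches force
every bat into the same sites — tiny home ranges (10.6 vs 304 ha), a fully
connected network (ρ = 1.0) and no room for kin preference (QAP p = 0.99).
In the food-rich winter, bats can choose where and with whom to forage: the
network is less saturated (ρ = 0.93) and sharing correlates with relatedness
(QAP r = 0.12, p = 0.006) while co-roosting explains nothing.  The seasonal
contrast in degree is significant under node permutations (t = −5.6).  This
is the qualitative pattern the pipeline is designed to expose; the
relatedness distributions themselves do not differ between seasons
(KS p = 0.38), as expected since both samples come from one population.

The same stages run as one call — `oasisnet.pipeline.run_pipeline(RunConfig(...),
outdir)` — which writes every intermediate artifact plus `report.json` /
`report.md`, byte-identical on rerun with the same seed.

## Acceptance script

`scripts/acceptance.py` re-runs the entire pipeline from scratch on the
study-scale synthetic configuration (two seasons, 32 bats each, 13 loci,
kin attraction on) at the given seed, prints the per-season network metrics
and QAP results it computed, and writes the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/oasisnet/      library: synthdata, telemetry, homerange, relatedness,
                   spacenet, inference, pipeline
analysis/          numbered narrative drivers (simulate -> ... -> inference)
tests/             pytest suite incl. brute-force oracles and acceptance checks
scripts/           acceptance runner
docs/methods.md    models, defaults, numerical choices, limitations
```
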