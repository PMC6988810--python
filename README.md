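# protistnet

Statistical analysis of protist metabarcoding OTU tables from **two
connected habitats** (e.g., a coastal lagoon and the adjacent sea): library
normalization, diversity summaries, habitat generalist/specialist
classification, and signed co-occurrence network inference with a
random-graph null comparison.

The package is aimed at microbial ecologists who already have a processed
OTU table (reads quality-filtered, clustered, taxonomically assigned
upstream) and want the downstream comparative statistics, plus a
synthetic-data generator with planted ground truth for validating every
stage.

## What it computes

**Normalization.** Replicates are pooled per station and date, singleton
OTUs removed, and samples rarefied — random subsampling *without*
replacement (multivariate hypergeometric) — to a common depth (fixed,
lowest, or second-lowest column total).

**Diversity.** Observed richness and Shannon index
H = −Σᵢ pᵢ ln pᵢ per sample; exact analytic rarefaction curves
E[S(d)] = Σᵢ [1 − C(N−Nᵢ, d)/C(N, d)]; Bray–Curtis dissimilarity and the
Hellinger transform (exported for ordination elsewhere); the
shared/exclusive OTU-and-read partition between the two habitats.

**CLAM classification.** Each OTU's depth-equalized pooled counts (a, b)
in the two habitats are modelled conditionally as a ∼ Bin(a+b, π) with
π = p_A/(p_A+p_B). A Clopper–Pearson interval for π at level 1−2α is
compared with the supermajority threshold K (default 2/3, α = 0.005):
interval above K → habitat-A specialist; below 1−K → habitat-B specialist;
inside [1−K, K] → generalist; anything else → *too rare to classify*.

**MIC network.** For every OTU pair (after a minimum-abundance filter,
default ≥ 50 reads) the maximal information coefficient

MIC(x, y) = max₍kₓ·k_y ≤ n^0.6₎ I\*(x, y; kₓ, k_y) / log₂ min(kₓ, k_y)

is computed with the ApproxMaxMI heuristic (equipartition one axis,
optimize the other exactly by dynamic programming over clump boundaries;
both orientations). Significance comes from an explicit permutation null
(default 1000 shuffles, edge kept if p < 0.01), and each edge's sign from
the nonlinearity statistic MIC − r²: values > 0.5 are treated as negative
(exclusion-like) associations. The resulting graph is annotated with CLAM
classes, taxonomy and trophic categories; its clustering coefficient C and
characteristic path length L are compared against means (Cr, Lr) over 100
random G(n, m) graphs (degree-preserving edge swaps available), and
high-degree nodes are flagged as hubs.

**Trophic annotation.** Lineages are mapped to autotroph / heterotroph /
mixotroph / parasite / NA by rank-aware rules (species > genus > family >
group), seeded with the standard group-level conventions for marine
protists (only diatoms and Mamiellophyceae as strict autotrophs, other
plastid-bearing groups as mixotrophs, Syndiniales/Labyrinthulea/Oomycota
as parasites).

## Worked example

Generate a synthetic two-habitat survey (7 stations × 4 dates × 2
replicates = 56 samples) with one planted association block per habitat,
normalize it, classify habitat preference and infer the network:

```python
from protistnet import (SyntheticConfig, AssociationBlock, generate_dataset,
                        pool_replicates, remove_singletons, rarefy,
                        resolve_depth, pool_by_habitat, ClamTest,
                        MicParams, MicNetworkModel)

cfg = SyntheticConfig(
    n_otus=120, seed=42, depth_mean=20000, otu_noise_sigma=0.8,
    association_blocks=(AssociationBlock("A", 12, 1.5),
                        AssociationBlock("B", 12, 1.5)))
table, meta, taxonomy, truth = generate_dataset(cfg)

pooled, pooled_meta = pool_replicates(table, meta)       # 56 -> 28 samples
nosingle = remove_singletons(pooled)
rarefied = rarefy(nosingle, resolve_depth(nosingle, "second-lowest"), seed=43)
meta_r = pooled_meta[pooled_meta["sample_id"].isin(rarefied.sample_ids)]

clam = ClamTest.from_pools(pool_by_habitat(rarefied, meta_r, seed=44)).fit()
print(clam.summary())

net = MicNetworkModel(rarefied, mic_params=MicParams(seed=45),
                      clam_classes=clam.classes, taxonomy=taxonomy,
                      n_random=100, min_hub_degree=12).fit()
print(net.summary())
```

Output:

```
CLAM habitat classification
===========================
OTUs: 103   K = 0.6667   alpha = 0.005   CI = exact_binomial
class             OTUs   read fraction
generalist           6          0.0589
specialist_A        29          0.4200
specialist_B        18          0.5149
too_rare            50          0.0062

MIC co-occurrence network
=========================
nodes: 57   edges: 189   negative edges: 74 (39.2%)
C  = 0.3080   L  = 3.0114 (largest component: 3.0128)
Cr = 0.1174   Lr = 2.3073 (mean over 100 same_n_m replicates)
hubs (degree >= 12): 9
  OTU00004  degree=19
  OTU00006  degree=19
  ...
```

Reading this: the rarefaction depth resolved to the second-lowest pooled
library (28,181 reads; the one sample below it was dropped with a warning).
Of 103 surviving OTUs, 47 are confidently habitat specialists carrying ~93%
of the reads, while the 50 "too rare" OTUs carry 0.6%. The observed network
is far more clustered than its random counterpart (C = 0.31 vs Cr = 0.12)
with a longer characteristic path (L = 3.01 vs Lr = 2.31) — the signature
of modular, habitat-structured co-occurrence rather than homogeneous random
mixing — and the planted block members dominate the hub list.

The same pipeline runs from the shell:

```bash
protistnet simulate --seed 42 --n-otus 120 --blocks A:12:1.5,B:12:1.5 --outdir sim
protistnet run-all --otu-table sim/otu_table.tsv --metadata sim/metadata.tsv \
    --taxonomy sim/taxonomy.tsv --seed 7 --outdir results
```

`run-all` writes per-stage TSV/JSON/GraphML outputs and a `manifest.json`
recording every parameter and derived stage seed; re-running with the same
seed reproduces every output byte-for-byte.

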