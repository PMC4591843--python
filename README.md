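# phylosalt

Phylogenetically resolved salinity preferences of bacterial taxa from
reciprocal-transplant community data.

When fresh- and saltwater wetland soils are reciprocally transplanted, each
taxon's presence/absence pattern across the four origin × host treatments
(FF, FS, SF, SS) reveals whether it tolerates only one salinity or both.
`phylosalt` turns a taxon count table, a rooted phylogeny and the
transplant design into:

1. **Salinity preference calls** per taxon — *freshwater*, *saltwater*,
   *no preference*, or *unclassified* — from a conservative,
   replicate-majority presence rule (present in a treatment iff detected in
   strictly more than half of its replicates; 3 of 5 in the reference
   design).
2. **Phylogenetic clustering tests** of each preference group:
   SES-PD = (PD_obs − mean PD_null) / sd PD_null for Faith's phylogenetic
   diversity, and the nearest taxon index NTI = −SES(MNTD), against a null
   of equal-size tip sets drawn uniformly from the community tree.
   Negative SES-PD / positive NTI indicate that a preference is
   phylogenetically clustered (ecological coherence).
3. **Clade-level enrichment**: percentile bootstrap confidence intervals
   (6000 iterations, 95% by default) for the share of each preference in
   each taxonomic clade, versus the community-wide expectation.
4. **Composition–function coupling**: weighted UniFrac distances
   d(A,B) = Σ_b ℓ_b · |p_A(b) − p_B(b)| between samples, Gower distances
   over functional measurements (enzyme activities, gas production), and a
   permutation Mantel test linking the two.
5. A **synthetic-data generator** — Yule trees, a Brownian salinity-niche
   trait with Pagel's λ signal strength, niche-dependent detection with
   residual-DNA carryover and host colonization, multinomial read depth —
   providing ground truth against which the whole chain is validated.

It is intended for microbial ecologists analysing 16S community surveys
from transplant or paired-habitat designs, and for methodologists who need
a testable, seeded reference implementation of these statistics.

## Worked example

```python
import phylosalt as ps

params = ps.SimulationParams(seed=7)          # 200 taxa, 2x2x5 design, λ=1
data = ps.simulate_dataset(params)
model = ps.TransplantExperiment(data["table"], data["tree"],
                                data["metadata"],
                                functions=data["functions"])
print(model.fit(seed=1).summary())
```

```
Reciprocal-transplant salinity-preference analysis
==================================================
taxa: 200   samples: 20   seed: 1

Preference counts:
              count  fraction
preference
fresh            44     0.220
salt             71     0.355
none             73     0.365
unclassified     12     0.060

Phylogenetic signal (SES-PD / NTI; negative SES-PD and positive NTI = clustering):
group metric  size  observed  null_mean  null_sd    ses   nti  p_lower  clustered
fresh     PD    44    12.651     17.900    0.829 -6.331   NaN    0.001       True
fresh   MNTD    44     0.256      0.522    0.054 -4.916 4.916    0.001       True
 salt     PD    71    19.263     24.055    0.914 -5.244   NaN    0.001       True
 salt   MNTD    71     0.279      0.410    0.034 -3.838 3.838    0.001       True
 none     PD    73    22.112     24.454    0.872 -2.686   NaN    0.004       True
 none   MNTD    73     0.364      0.405    0.033 -1.227 1.227    0.106      False

Composition-function coupling: Mantel r = 0.93, p = 0.0010 (999 permutations)
```

Reading the output: of the 200 simulated taxa, 44 classify as freshwater-
and 71 as saltwater-preferring, 73 show no preference, and 12 patterns
match no rule. With full phylogenetic signal (λ = 1) each preference group
spans far less branch length than random same-size tip sets (SES-PD of
−6.3 and −5.2 at the permutation floor p = 1/1000), and its members sit
near each other at the tree's tips (positive NTI). The Mantel correlation
reports how strongly the between-sample functional distances track the
weighted UniFrac distances.

A command-line interface mirrors the library
(`phylosalt simulate | filter | rarefy | presence | classify | phylosig |
enrich | coupling | run-all`); `phylosalt run-all counts.tsv tree.nwk
metadata.tsv --functions functions.tsv --taxonomy taxonomy.tsv` writes
every result table to an output directory.

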