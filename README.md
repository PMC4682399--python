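# argwalker

Individual-specific strengths of meiotic recombination hotspots, estimated
by deterministic backward/forward walks on ancestral recombination graphs
(ARGs).

Most recombination-rate estimators (LD-based, coalescent-based) return one
average rate per population, yet recombination frequency varies between
individuals.  `argwalker` is for population geneticists who want a
*per-haplotype* phenotype at a hotspot — e.g. to run a GWAS of hotspot
usage against SNP genotypes, or to separate hot-allele from cold-allele
carriers in a sample — using nothing but phased SNP haplotypes and an ARG
over the hotspot window.

## The estimator

Given an ARG `G(V, E)` with ancestor→descendant edges, leaves labelled by
sampled haplotypes, and recombination events visible as nodes with
in-degree ≥ 2:

1. **Backward walk** — each edge gets an integer weight
   `W(u→v) = 1 + Σ_{(v,w)∈E} W(v→w)`: one plus the number of descendants
   of `v`, counted with path multiplicity, so recombination nodes are
   double-counted once per incoming path.
2. **Normalization** — `T(u→v) = W(u→v) / Σ_k W(u→k)` turns weights into a
   row-stochastic transition matrix with absorbing leaves.
3. **Forward walk** — signal `I` starts on the roots (each root's outgoing
   weight sum) and `I ← I·T`, `V_L ← V_L + I` iterate until no mass is in
   transit.  The mass `V_L` absorbed at each labelled leaf is that
   haplotype's recombination strength; normalized to unit sum it is the
   probability profile `V_p`.

Haplotypes whose ancestry is rich in recombination events collect more
mass.  Profiles without strength variation are screened out with
Hartigan's dip test (Monte-Carlo p against a uniform null, keep when
`−log10(p) ≥ 2.473`), and the surviving strength phenotypes can be scanned
against SNP alleles with an unpaired t-test (thresholds `1e-7.3`, and
`5e-8` for MHC-style screens), per haplotype or combined per chromosome as
means of `(x − mean)/SD`-standardized hotspot vectors.

A forward-time Wright–Fisher simulator with a two-allele hotspot (hot/cold
crossover ratio, causal-SNP MAF, biased gene conversion) generates phased
haplotypes **with the true ARG of the sample**, so the whole pipeline is
testable without any external ARG-reconstruction tool.  See
`docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

The walker on a six-node ARG with two roots and one recombination node
(node 2, reachable from both roots):

```
$ cat edges.tsv              $ cat labels.tsv
0	2                        3	x
1	2                        4	y
2	3                        5	z
2	4
0	5
$ argwalker walk --arg edges.tsv --labels labels.tsv --out profile.tsv
wrote profile for 3 haplotypes to profile.tsv
$ cat profile.tsv
hotspot_id	haplotype_id	V_L	V_p
hotspot	x	3.0	0.42857142857142855
hotspot	y	3.0	0.42857142857142855
hotspot	z	1.0	0.14285714285714285
```

Leaves `x` and `y` sit below the recombination node and gather 3/7 of the
signal each; leaf `z`, on a recombination-free branch, gets 1/7.  Mass is
conserved: 3 + 3 + 1 equals the root initialization 4 + 3.

The same pipeline on a simulated two-allele sample (90 diploid
individuals, ~100 SNPs over 200 kb, hot/cold crossover ratio 10):

```python
from argwalker import (Scenario, simulate_sample, sample_profile,
                       classify_hot_cold, confusion_metrics,
                       dip_statistic, dip_pvalue)

sample = simulate_sample(Scenario(seed=2))
profile = sample_profile(sample)            # walk true ARG + symmetrize
vp = profile.values("probabilities")
res = dip_pvalue(dip_statistic(vp), vp.size, n_null=10_000)
pred, _ = classify_hot_cold(profile)
m = confusion_metrics(pred, sample.truth)
print(f"dip -log10(p) = {res.neg_log10_p:.2f}")
print(f"accuracy = {m.accuracy:.3f} (sens {m.sensitivity:.3f}, "
      f"spec {m.specificity:.3f})")
```

prints

```
dip -log10(p) = 3.70
accuracy = 0.828 (sens 0.680, spec 0.933)
```

— the profile is clearly bimodal (kept by the filter at threshold 2.473),
and the 2-means split of `V_p` recovers the hot/cold truth labels well
above chance.

The CLI mirrors the library: `argwalker simulate | walk | dipfilter |
gwas | evaluate`; every run writes a `manifest.json` with parameters,
seeds and input checksums.

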