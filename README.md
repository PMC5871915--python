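# netprop

Network propagation of somatic-mutation signals for mutated-pathway
detection and patient stratification.

Recurrently mutated cancer driver genes are rare; in most tumors the driver
mutations are dispersed across many genes of a pathway, each mutated in well
under 5% of patients and often mutually exclusively. Gene-level frequency
tests and the standard hypergeometric enrichment of "highly mutated" genes
both lose this signal. `netprop` implements the network-based alternative:
mutation profiles are smoothed over a gene interaction network by label
propagation, so that mutually exclusive hits scattered across a pathway
accumulate into a coherent subnetwork signal, and pathways are scored
against empirical nulls of random gene sets.

## Model

Let `W` be the symmetric adjacency matrix of an undirected gene network and
`D` the diagonal matrix of weighted degrees. The normalized adjacency is

    S = D^{-1/2} W D^{-1/2}        (spectral radius ≤ 1)

and the normalized graph Laplacian is `L = I − S`. Given a non-negative
seed vector `f⁰` — per-gene mutation frequencies for a cohort (λ = 0.5), or
one patient's mutated-gene indicator normalized to sum to 1 (λ = 0.1) —
label propagation iterates

    f ← λ S f + (1 − λ) f⁰

to its unique fixed point `f = (1 − λ)(I − λS)^{-1} f⁰`. A pathway's score
is the sum of the stationary scores of its member genes, and its empirical
p-value is `(r + 1)/(N + 1)` where `r` counts random same-size gene sets
(default `N = 10,000`) scoring at least as high. For stratification, each
patient's pathway p-values become `−log10 p` features; patients are
clustered hierarchically and subgroup survival is compared with the
standard log-rank test (implemented from first principles with the
hypergeometric variance at each event time). A no-network baseline —
hypergeometric over-representation of genes above a mutation-frequency
cutoff — is included as the comparator, and a synthetic-data module
generates planted-partition networks, module-aligned pathways, mutually
exclusive driver cohorts and subgroup-dependent survival so every stage is
testable without external downloads.

## Worked example

Score pathways on a synthetic cohort of 120 patients in which each of three
planted driver pathways (20 genes) is hit mutually exclusively in 60% of
its subgroup — every driver gene stays near 3% marginal frequency:

```python
import netprop as nps

cfg = nps.ScenarioConfig(seed=7)
net, pathways, cohort, clinical, truth = nps.generate_scenario(cfg)
op = nps.normalize_adjacency(net)
table = nps.score_all_pathways(cohort, op, pathways, mode="cohort",
                               n_null=10_000, rng_seed=1)
print(table.sort_values(["p_empirical", "pathway"]).head(5).to_string(index=False))
```

```
pathway  n_genes  n_in_network    score  p_empirical  n_null
   P002       20            20 0.199062     0.001200   10000
   P014       20            20 0.199040     0.001200   10000
   P003       20            20 0.195733     0.002100   10000
   P001       20            20 0.184124     0.007799   10000
   P015       20            20 0.179873     0.013899   10000
```

The planted drivers (`P001`–`P003`) and the decoy pathways overlapping
their network modules head the list with p-values far below the 0.05 level.
The no-network baseline finds nothing on the same cohort: no gene reaches
the 5% frequency cutoff, so every hypergeometric p-value is 1.0:

```python
from netprop.enrichment import select_highly_mutated, enrich
selected = select_highly_mutated(cohort, min_freq=0.05)   # -> empty set
enrich(selected, pathways, frozenset(cohort.genes))       # all p = 1.0
```

The same pipeline runs from the shell:

```sh
netprop simulate --preset mini --seed 21 --outdir fixture/
netprop run-all --outdir results/ --seed 1 \
    --network fixture/network.tsv --mutations fixture/mutations.tsv \
    --pathways fixture/pathways.gmt --clinical fixture/clinical.tsv
```

Every subcommand writes TSV outputs plus a JSON manifest recording inputs,
parameters and seeds; identical manifests reproduce byte-identical results.

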