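# refog-bench

Phylogeny-based benchmarking of orthology predictions.

Orthologs are homologous genes that diverged at a speciation event; an
orthologous group (OG) collects all genes descending from a single ancestral
gene at the last common ancestor (LCA) of the species compared.  Orthology
databases (eggNOG-style clusterings and their relatives) predict such groups
at scale, but validating the predictions is hard: the usual proxies —
conserved protein domains, conserved gene order, shared enzymatic activity —
measure *function*, while orthology is an *evolutionary* definition.
Function-based tests therefore systematically miss false assignments,
especially xenologs (genes acquired by horizontal gene transfer, HGT, which
tend to keep their domain architecture while landing at random genomic
positions).

`refog-bench` is a toolkit for people who build or evaluate orthology
resources.  Given curated reference orthologous groups (RefOGs) with known
membership, it

* matches each reference group to the predicted group with the highest
  coverage and partitions the result into **true assignments**
  (TA = members ∩ prediction), **false assignments** (FA = prediction \
  members) and **missing assignments** (MA = members \ prediction), with
  recall = |TA| / (|TA| + |MA|);
* computes the three classical function-based conservation scores — domain
  content, gene order over ±5-gene neighbourhoods with single-linkage
  homology families (links at E ≤ 1e-5 covering ≥ 90% of the shorter gene),
  and hierarchically expanded EC numbers — each against family-specific
  conserved features (the 75% rule), and asks per group whether the score
  could have flagged any false assignment;
* automates the decidable tree steps of the curation protocol: outgroup
  rooting, delineation of candidate OGs as maximal ingroup clades relative
  to the ingroup LCA, flagging of ingroup sequences nested within the
  distant outgroups as xenolog candidates, and bit-score-range recruitment;
* tallies errors per species and compares two datasets' per-species error
  distributions with a two-sample Kolmogorov–Smirnov test;
* ships a gene-family **birth-death-transfer simulator** that evolves
  families along an ultrametric species tree and fabricates genomes,
  annotations, homology hits and error-injected predictions — so every
  analysis above can be exercised against exact ground truth without any
  external dataset.

## Worked example

```python
from refog_bench import (RefOG, PredictedOGSet, benchmark_dataset,
                         recall_percent, per_species_error_counts)

refogs = [
    RefOG("RefOG100", frozenset({"83333.p1", "83333.p2", "99287.p3",
                                 "99287.p4", "71421.p5", "71421.p6"})),
]
predictions = PredictedOGSet("gproNOG-like", {
    "OG1": frozenset({"83333.p1", "83333.p2", "99287.p3", "99287.p4",
                      "198214.q1", "198214.q2"}),
    "OG2": frozenset({"71421.p5"}),
})
report = benchmark_dataset(refogs, predictions)
ta, fa, ma = report.totals
print(f"TA={ta}  FA={fa}  MA={ma}  recall={recall_percent(report)}%")
print(per_species_error_counts(report))
```

prints

```
TA=4  FA=2  MA=2  recall=67%
         FA  MA
species
198214    2   0
71421     0   2
```

OG1 covers four of the six reference members, so it is the match; its two
extra genes (species 198214) are false assignments, and the two members it
excludes (species 71421, stranded in OG2) are missing assignments.  Recall
is 100·4/6 ≈ 67%.

The same pipeline runs from the shell against simulated ground truth:

```sh
refog-bench simulate --seed 1 --n-families 8 --n-ingroup 12 --out world
refog-bench benchmark --refogs world/refogs.tsv \
                      --predictions world/predictions.tsv --out bench
```

```
simulated 11 reference groups, 23 xenologs -> world
TA=159 FA=77 MA=16 recall=91%
```

`world/truth.json` records the injected error expectations per group; the
benchmark report reproduces them exactly.  Other subcommands:
`function-test` (domain / gene-order / EC scoring), `delineate` (candidate
OGs and xenologs from a Newick gene tree plus a clade map), `perturb`
(error-inject a membership table) and `compare` (KS test between two
reports).

## Layout

| module | contents |
|---|---|
| `refog_bench.benchmark_core` | RefOG/prediction types, TA/FA/MA classification, recall, per-species errors, species restriction, KS comparison |
| `refog_bench.function_tests` | conserved-feature sets, domain/gene-order/EC scores, neighbourhoods, single-linkage families, accuracy calls |
| `refog_bench.tree_ops` | outgroup/midpoint rooting, maximal ingroup clades, OG delineation, xenolog flagging, bit-score recruitment |
| `refog_bench.simulator` | species-tree scaffold, birth-death-transfer process, ground-truth OGs and xenologs, genomes/annotations/hits, error injection |
| `refog_bench.io` / `refog_bench.cli` | TSV/OrthoXML/Newick/JSON readers and writers, run configuration, the `refog-bench` command |

See `docs/methods.md` for the models, parameter choices and known
limitations.
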