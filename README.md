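# karyoevo

Karyotype evolution analysis for helicoid land snails (Gastropoda:
Stylommatophora): chromosome measurement and Levan-style classification, a
rearrangement event calculus on karyotype formulae, and Sankoff parsimony
reconstruction of ancestral diploid chromosome numbers on a phylogeny.

## The problem

Helicoidea karyotypes vary widely in diploid number (2n ≈ 40–62) and in
chromosome morphology, from all-metacentric complements to karyotypes with
many telocentric pairs. Comparative cytogenetics explains this diversity
with three rearrangement types:

* **translocation** (tandem/Robertsonian fusion) — two chromosome pairs merge
  into one biarmed pair: 2n → 2n − 2;
* **fission** — one biarmed pair splits into two telocentrics: 2n → 2n + 2;
* **pericentric inversion** — one pair changes morphology class
  (m/sm/st/t, by centromeric index); 2n unchanged.

Between two diploid numbers the minimal event count is |Δ2n| / 2; between two
equal-n karyotype formulae (class-count vectors, e.g. `10m+1sm+16t`) the
minimal inversion count is half the L1 distance, since each inversion
re-classifies exactly one pair. Placing observed karyotypes on a phylogeny
and minimising total event cost (Sankoff parsimony over even 2n states,
cost(a, b) = w·|a − b|/2) yields ancestral diploid numbers and per-branch
event annotations. On the curated helicoid data this reconstruction places
**2n = 60 with all biarmed chromosomes at the root of Helicoidea**, with
independent chromosome-number reductions in multiple families.

The package is aimed at comparative cytogeneticists and anyone who wants a
tested, scriptable implementation of karyotype-formula arithmetic and
discrete ancestral-state parsimony with event-style cost models.

## Worked example

Event counts between printed karyotype formulae:

```sh
$ karyoevo distance "24m+2sm+1st" "10m+1sm+16t"   # Helix straminea vs H. lucorum
16 inversions
$ karyoevo distance "30m" "26m"                   # 2n = 60 vs 2n = 52
4 translocations
```

Ancestral reconstruction on the built-in curated records and tree:

```python
from karyoevo import (paper_fixtures, tip_states_from_records,
                      sankoff_reconstruct, annotate_branch_events)

records, tree = paper_fixtures()
states = tip_states_from_records(records, tree)
result = sankoff_reconstruct(tree, states)
print("tips used:        ", len(states))
print("total cost:       ", int(result.total_cost), "events")
print("root 2n (optimal):", sorted(result.root_states))
events = annotate_branch_events(result)
node = result.tree.find("Hygromiidae-Geomitridae")
print("branch into Hygromiidae+Geomitridae:", events[id(node)])
```

prints

```
tips used:         36
total cost:        46 events
root 2n (optimal): [60]
branch into Hygromiidae+Geomitridae: EventCount(translocations=4, fissions=0, inversions=0)
```

i.e. the most parsimonious labeling needs 46 rearrangement events in total,
assigns the superfamily root a unique diploid number of 60, and explains the
2n = 52 ancestor of the Hygromiidae + Geomitridae clade by four
translocations.

The same pipeline runs from the shell: `karyoevo fixtures --out data/` dumps
the curated table and tree, `karyoevo ancestors data/helicoidea_karyotypes.tsv
data/helicoidea_tree.nwk --out report/` writes per-node state sets, branch
events, and an annotated Newick. `karyoevo classify` turns an arm-length
table into RL/CI/class values and a formula, and `karyoevo simulate`
generates seed-reproducible synthetic datasets from the built-in
karyotype-evolution simulator (see `docs/methods.md`).

## Layout

* `karyoevo.core` — measurements, centromeric-index classification,
  karyotype formulae.
* `karyoevo.rearrangements` — event types, minimal counts, explicit event
  paths.
* `karyoevo.parsimony` — trees, cost models, Sankoff and brute-force
  reconstruction, branch annotation.
* `karyoevo.dataset` — curated records, TSV I/O, p-distance utilities.
* `karyoevo.synth` — karyotype-evolution simulator and recovery experiments.
* `karyoevo.cli` — the `karyoevo` command.
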