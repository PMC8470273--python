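# Methods

## The model

`karyoevo` treats a karyotype as a *formula*: a multiset of chromosome-pair
morphology classes (m, sm, st, t) whose size is the haploid number n, with
diploid number 2n. Three rearrangement event types act on formulae:

* **translocation** (tandem/Robertsonian fusion): two pairs merge into one
  biarmed pair; 2n decreases by 2;
* **fission**: one biarmed pair splits into two telocentric pairs; 2n
  increases by 2;
* **pericentric inversion**: one pair moves to a different morphology class;
  2n is unchanged.

From this model two minimal distances follow. Between diploid numbers, the
minimal translocation-or-fission count is |Δ2n| / 2 (a single event type in
one direction). Between two formulae with equal n, each inversion
re-classifies exactly one pair, so the minimal inversion count is the number
of pairs that must change class — half the L1 distance between the two
class-count vectors. Reciprocal translocations that conserve 2n are not
modeled: every per-lineage count in the underlying comparative data is of the
|Δ2n|/2 form. `combined_event_path` makes unequal-n comparisons explicit by
emitting the |Δ2n|/2 merges (or splits) first and an inversion tail second;
merge products default to class m and fission products to two telocentrics,
the standard Robertsonian expectation, and both defaults are arguments. A path
can be legitimately infeasible (a fission with no biarmed pair left); the
error names the blocking class rather than inventing events outside the model.

## Chromosome measurement and classification

Relative length RL_i = 100·(short_i + long_i) / Σ_j (short_j + long_j) and
centromeric index CI_i = 100·short_i / (short_i + long_i). Levan-convention
class boundaries on CI: m = [37.5, 50], sm = [25, 37.5), st = [12.5, 25),
t = [0, 12.5); a boundary value goes to the more metacentric side. The
convention's source prints no thresholds, so the quarter-splits of the 0–50
range are fixed here as the package's convention and the classifier is a step
function, monotone by construction. RL and CI are stored at full precision
and rounded to one decimal only for display. Measurement rows with
short > long are swapped with a logged warning (tables list arms in either
order); rejecting them would discard usable data.

## Ancestral-state reconstruction

The character is 2n on a finite grid of even states, by default 40–64: the
observed helicoid range (roughly 2n = 40–62) padded to an even window, and a
finite grid is what the dynamic program requires. The transition cost from
ancestral a to descendant b is w_T·(a−b)/2 for decreases and w_F·(b−a)/2 for
increases, with w_T = w_F = 1 by default (one event per step of 2), matching
every printed per-lineage count. `sankoff_reconstruct` runs the
leaves-to-root Sankoff recursion and then an outside (root-to-leaves) pass,
so each node's reported state set is exactly the states realised by at least
one globally optimal labeling. Ties are always reported as sets.
`brute_force_reconstruct` enumerates all internal labelings (refusing more
than 8 internal nodes) and is the independent oracle; the suite checks
equivalence on 200 random ≤5-tip instances.

`annotate_branch_events` projects one optimal labeling onto the branches:
`prefer-ancestral-max` (default) resolves each top-down tie toward the larger
state, which favours the chromosome-number-reduction reading of the data;
`prefer-ancestral-min` does the opposite; `all-optimal` returns, per branch,
the event counts of every (parent, child) pair realised by some optimal
labeling, using the inside/outside vectors for the feasibility test.

## The curated fixture

The record set has two layers: the 16 newly karyotyped records (15 species;
*Theba pisana* from two localities) and the literature/clade-level
karyotypes quoted in the same synthesis (e.g. *Helix straminea* 24m+2sm+1st,
the polygyrid 2n = 62 species, tribe-level records such as Allognathini
2n = 44). The phylogeny is a Newick transcription of the named clades of the
source tree: only clades the text commits to are resolved, everything else is
a polytomy. Two inter-family attachments the text leaves unplaced
(Xanthonychidae; the Camaenidae+Polygyridae clade) carry an `[&uncertain]`
flag; reconstruction treats them as ordinary branches and
`collapse_uncertain()` turns them into polytomies for sensitivity checks
(the root state is unchanged).

Curation notes, all carried in the records' `notes` field rather than
resolved silently:

* Trochoideini (*Trochoidea*, *Xerocrassa*) is placed inside Geomitridae,
  following the discussion and figure rather than the sample table's layout.
* *Monacha* sp. is printed with 2n = 44 in the sample table but described
  with 2n = 46; the tabulated value is stored, no formula is attached, and
  the conflict is flagged.
* The three *Trochoidea* pair-by-pair descriptions disagree slightly with
  their printed formulae; the printed formulae are used for distances.
* *Cochlicella acuta* is stored with this study's 2n = 52; the literature
  2n = 46 is flagged as a candidate cryptic-lineage conflict.
* The printed "three" inversions for *T. trochoides* is not reproducible
  under the half-L1 rule, which gives 4 for (20m, 4sm) → (16m, 7sm, 1t);
  the implementation does not special-case it.

On this fixture the reconstruction yields a unique root state of 2n = 60 at
a total cost of 46 events, with 4 translocations on the branch into the
Hygromiidae+Geomitridae ancestor — the quantities the acceptance script
recomputes.

## The simulator

`evolve_karyotypes` evolves formulae down a tree from a root of thirty
metacentric pairs (2n = 60, the inferred ancestral condition). Per branch,
the count of each event type is Poisson(rate × branch length) — a discrete
stand-in chosen because the empirical reasoning is in counts per lineage, not
a continuous-time chain — and the drawn events apply in shuffled order.
Pairs are chosen uniformly (classes weighted by their counts). Events that
would cross the 2n floor/ceiling (default 40/64) or need an unavailable class
are resampled up to 10 times, then dropped with a log message; the drop
counter is part of the result. Random trees are pure-birth (Yule) with
exponential branch lengths of mean 0.5. Everything is reproducible from the
seed, and the per-branch event log replays to the exact tip formulae.

Default rates are rate_T = 0.30, rate_F = 0.03, rate_I = 0.27 per unit
branch length. The mix mirrors the relative frequencies of the three event
types in the empirical reconstruction (translocations and inversions roughly
equally common, fissions rare), and the total — 0.6 × mean branch length
0.5 = 0.3 expected events per branch — keeps the simulation in the
low-rate regime the comparative data occupy.

What the generator emulates: clade-correlated karyotype divergence, rare
reversals, bounded diploid numbers, morphology drift by single-pair steps.
What it does not: within-species polymorphism, reciprocal (2n-conserving)
translocations, size information (formulae carry classes, not lengths),
rate heterogeneity across lineages. Recovery results on simulated data
therefore validate the inference machinery under the package's own model,
not the cytogenetic measurement process.

`recovery_experiment` reports, over replicates: the fraction in which the
true root state lies in the minimal-cost root set, the tie frequency, the
mean absolute difference between the parsimony total and the true number of
2n-changing events, and the fraction in which parsimony is a true lower
bound (always 1.0 — inversions are excluded from the true count because the
cost model cannot see them). The headline validation setting is 8-tip trees,
default rates, 200 replicates (100 in the acceptance script, which also has
a simulation-free part); at that setting the stored calibration run gives a
root-recovery rate of 0.915.

## Numerical and degenerate-input choices

* Pair sorting by decreasing RL is stable: measurement-order ties keep their
  input order, and re-indexing is 1-based.
* Formula parsing accepts "+", comma or whitespace separators and optional
  space before the class token; the canonical form omits zero classes.
  Haploid class counts map directly to pair counts; diploid counts must be
  even per class.
* Reconstruction state sets use exact integer costs (unit weights) compared
  through `np.isclose` to stay correct under fractional weights.
* Tips missing from the state map are pruned with a warning (or rejected via
  `prune_missing=False`); unary nodes created by pruning are contracted.
* A single-tip tree reconstructs to that tip's state at cost 0.

## Known limitations

* The inversion distance assumes every class change is achievable by one
  pericentric inversion; it is a lower bound if some transitions require two.
* The event calculus ignores chromosome size, so fusions of non-homologous
  size classes are indistinguishable.
* The fixture tree is a clade-level transcription with polytomies, not a
  resolved species tree; branch-level conclusions inside unresolved groups
  are not meaningful.
* Parsimony reconstruction has no branch-length or rate model; for rate
  estimation a likelihood framework (ChromEvol-style) would be required and
  is out of scope.
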