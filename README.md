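# antlerevo

Burr-projection diagrams, element homology, and ancestral-state
reconstruction for cervid antlers.

## The problem

Antlers are the most diagnostic skeletal structure deer leave behind, yet
their branching characters have long been considered unusable for
phylogeny: tines compared by overall shape are rampantly homoplasious.
The way out is structural. Antlers grow from the tip, and their surface
grooves (growth streaks and arterial impressions) record where every tine's
material comes from. Tracing each tine's *branching direction* — the point
opposite its fork — and each fork's position down the grooves to the burr
(the bony ring at the antler base) projects the whole branching structure
onto one circular cross-section. Elements that occupy the same position on
this diagram, relative to fixed skull landmarks, are homologous; elements
coded per species can then be optimized on a molecular phylogeny.

`antlerevo` is for comparative morphologists and palaeontologists who want
to apply this projection arithmetic, compare diagrams, and rerun or extend
the ancestral reconstruction — e.g. to place a fossil antler by its
structure rather than its outline.

## What it computes

* **Projection** (`antlerevo.projection`) — tine trees with per-fork
  ridge/groove-boundary geometry; the opposite-point construction
  `o(r) = (r + C/2) mod C`; prorating over an overlapping proximal tine
  (`x : y = X : Y`, centred on the groove boundary) with the guarantee that
  deleting the proximal tine leaves all distal projections unchanged;
  fork marks, zones that partition the burr circle, and SVG rendering.
* **Homology** (`antlerevo.homology`) — symbolic diagram signatures
  (ordinal relations to skull indices SR/TR/IFST/SPO/LMOF/PEOI/BN, fork
  marks and other tines; hierarchy depth; fork partner) and
  rotation/scale-invariant homology verdicts with violated predicates
  reported.
* **Coding** (`antlerevo.coding`) — specimen presence matrices to adult
  percentages to three-state characters: 2 at >= 80%, 1 in (0, 80), 0 at 0.
* **Reconstruction** (`antlerevo.parsimony`, `antlerevo.model`) — Dollo
  presence (single gain on the MRCA stem of the present tips, minimal
  unique losses) layered with Fitch/ACCTRAN grades over the present region
  (root ambiguity resolved to grade 2), assembled into ancestral antlers
  with structural-dependency checks and point counts.
* **Simulation** (`antlerevo.synthetic`) — Dollo-consistent character
  histories, Bernoulli specimen sampling, and random antler geometries,
  all seeded.

The packaged registry replicates the study system: 25 species in 16 genera
with adult antler counts, 33 named elements (brow tine B, lower beam L,
trez tine T, higher beam H, frontal tine F, upper beam U, bez tine Z, crown
tines, ...), the seven skull indices, species-level element frequencies,
and a fixed rooted topology with labelled clades (user-replaceable Newick).

## Worked example

```python
from antlerevo import AntlerCharacterModel

results = AntlerCharacterModel.from_registry().fit()
print(results.summary(nodes=["Cervidae", "Cervini", "Capreolinae"]))
```

prints

```
Ancestral antler reconstruction (Dollo presence + ACCTRAN grades)
  species: 25    elements: 33

Per-element events
                    gain_edge  n_losses  n_grade_changes
element
B                    Cervidae         4                1
...
F                 Capreolinae         3                1
...
T                     Cervini         2                1
...

Ancestral antlers
             points      elements  violations
node
Cervidae          2           B L           0
Cervini           3  B BWP H L T           0
Capreolinae       3      B F L U           0
```

Read: the brow tine (B) and lower beam (L) gain on the root stem — the most
recent common ancestor of living deer had a two-pointed antler. The trez
tine gains on the Cervini stem and the frontal tine on the Capreolinae
stem: the two subfamilies reached three-pointed antlers independently, with
different second-fork elements (trez tine + higher beam vs frontal tine +
upper beam). Per-element results expose the gain edge, loss edges, 1<->2
grade-change edges and per-node states
(`results.reconstruction("T").gain_edge == "Cervini"`), and
`results.ancestral_antler("Cervini")` returns the assembled element set,
skeleton and point count for any node.

A diagram, from geometry to SVG:

```python
from antlerevo import build_diagram, render_diagram
from antlerevo.synthetic import SimulationConfig, synthetic_antler

tree = synthetic_antler(SimulationConfig(seed=5), depth=3)
diagram = build_diagram(tree)     # dots, fork marks, zones, hierarchy
svg = render_diagram(diagram)
```

## Command line

```sh
antlerevo run --registry --out runs/fixed      # packaged frequency registry
antlerevo run --matrix specimens.csv --out runs/full   # full pipeline
antlerevo code --matrix specimens.csv --out coded.csv
antlerevo diagram --tine-tree antler.json --out antler.svg
antlerevo simulate --seed 3 --out runs/sim
antlerevo validate-fixtures
```

Each run directory receives the coded matrix (CSV + NEXUS block), the edge
event table, per-element node states, per-node ancestral antlers, and a
human-readable summary.

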