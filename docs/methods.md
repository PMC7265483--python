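# Methods

## The problem

Antler branching structure is the richest morphological character system in
deer (Cervidae), but tines have historically been compared by overall shape,
which confounds homology: the "second tine" of a red deer and of a roe deer
turn out to be different structures. This package implements a geometric
solution — project every branching direction and fork down the antler's
growth lines onto the circular cross-section of the burr, compare the
resulting circular diagrams symbolically, code each homologous element as a
three-state character per species, and reconstruct ancestral antlers on a
fixed molecular topology with a hybrid Dollo + ACCTRAN parsimony.

## Burr-projection geometry

**Coordinate model.** Each branch segment carries a cross-section circle.
Arc positions are stored as fractions of the local circumference in
`[0, 1)`, with the origin at the segment's *attachment crotch* (the point
where the segment meets its fork). Positions are measured in each antler's
own anatomical handedness — the arc increases toward that antler's lateral
side — so a right antler and its mirror-image left twin carry identical
records and produce identical diagrams (this is how right antlers are
normalized into the left-antler convention).

**Fork records.** A fork is recorded on the stem circle just below the
bifurcation by two positions: the *ridge* (lateral end of the fork crotch)
and the *groove boundary* (its medial end), with
`0 <= ridge <= boundary < 1`. The window `[ridge, boundary]` carries the
grooves of the branching child; the complement carries the continuation.
The root fork's ridge anchors the burr origin and is fixed at 0.

**Primitives.** `opposite_point(ridge, C) = (ridge + C/2) mod C` gives a
tine's branching direction on its own cross-section (it is an involution).
`remap_across_tine` prorates a descending point over an overlapping proximal
tine, centring the groove boundary: with `x`, `y` the arc lengths
ridge→point and point→boundary, the image lies at `X = x·(X+Y)/(x+y)` from
the opposite point on the arc opposite-point→boundary. The ridge maps to
the opposite point, the boundary is fixed, the map is strictly monotone and
invertible, and the zero-width interval degenerates to the boundary.

**Chain.** Projection to the burr composes one affine, order-preserving arc
map per fork: each child circle unrolls onto its window (or the
complementary arc), the crotch mapping to both window ends. This unroll is
the totalization of the prorating primitive — its restriction to the fold
side is exactly the prorate — and composing affine maps keeps every
subtree's burr region a single circular arc, which makes the following
exact (not approximate) properties hold:

* the two burr marks of one fork are the images of (ridge, boundary); they
  coincide exactly when ridge = boundary;
* zones partition the circle: a leaf element's zone is its whole region; a
  beam that forks distally retains the arc between its region start and the
  lateral mark of its own fork (its children own the rest). Every element's
  branching direction — the image of the opposite point of its crotch, i.e.
  the midpoint of its window (for a distally forking beam, of its retained
  arc) — lies inside its own zone;
* *deletion invariance*: removing an overlapping proximal tine and pushing
  the spliced fork's record forward through the unroll map leaves every
  more-distal branching direction and fork mark at exactly the same burr
  point. This is the design goal of the prorated projection — the diagram
  position of an element is unchanged whether or not a more proximal tine
  intervenes — and it is verified numerically to 1e-9 over hundreds of
  random geometries.

Deleting a tine of the *first* fork is refused: its ridge anchors the
coordinate origin.

**What is not modelled.** Groove fields are not traced from images; input
geometry supplies the per-fork ridge/boundary positions directly (physical
tracing is a manual step). Arc-length interpolation between cross-sections
is piecewise linear. Oblique arterial impressions versus fine streaks are
not distinguished: one groove field is taken as given.

## Homology by diagram signature

An element's *signature* is symbolic: its ordinal relations to every other
mark on the diagram (branching directions, fork marks, skull indices), its
fork count from the base, and its fork partner. Directional predicates
encode on which side of a reference mark the element lies — the signed
circular displacement from reference to element, named by the compass pole
nearest the reference (anterior = SR, lateral = TR, posterior = BN, medial =
opposite TR). Marks within the coincidence tolerance (default 5°,
configurable) coincide; near-antipodal pairs carry no stable side and yield
no predicate.

Two elements are homologous iff their relation sets agree when restricted to
reference marks available and informative in both diagrams, and their
hierarchy depth and fork partner agree. Verdicts are reflexive, symmetric,
and invariant under rotation of a whole diagram and uniform scaling of the
geometry, because only ordinal structure enters. Species-level signatures
are majority-rule consensuses over specimen signatures, ties following the
largest-weight specimen set. The tolerance and majority rules quantify a
comparison the source method performs by inspection; they are package
decisions.

Tines and beams are distinguished from processes by the length rule: length
strictly greater than twice the basal diameter.

## Character coding

Percentages are computed over *adult* antlers only, left and right counted
separately; species with no adult antlers are reported and excluded, never
imputed. States: 2 at ≥ 80% (boundary inclusive), 1 in (0, 80), 0 at exactly
0 — so a single observation forces state ≥ 1 regardless of sample size.
Percentages are carried at full precision internally.

## Reconstruction model

Presence (0 vs {1,2}) follows Dollo parsimony: one gain, unlimited losses.
With a single permitted gain the optimum is forced and unique: the gain sits
on the stem edge of the MRCA of the present tips, a node inside that clade
is present iff its subtree retains a present tip, and the losses are the
stem edges of the maximal all-absent subtrees. (Exhaustive enumeration over
all rooted binary shapes with ≤ 6 leaves and all tip assignments confirms
minimality and uniqueness.)

Grade (1 vs 2) is Fitch parsimony over the present region with ACCTRAN
resolution: state-0 tips are pruned first (their stem edges are losses; the
scheme never grades absent taxa), a node with a single in-region child
passes its state set through, and a residual ambiguity at the region root
resolves to grade 2 — the acceleration assumption that an adaptive new
element fixes in the population immediately after its gain, while demotions
to rarity happen independently later. The change count equals the Fitch
minimum and no equally-minimal assignment places a change strictly closer to
the root (again verified exhaustively on small trees). An element present in
a single species at grade 1 gains on that terminal edge at grade 1.

A reported `grade_change_edge` names the full-tree edge on which the change
is realized; where pruning a state-0 sister makes an in-region node unary,
the change sits on the rootward half of the merged path.

**Ancestral antlers.** An element is placed at a node iff its state exceeds
0 there and its structural prerequisites (registry `requires` closure) are
present; violations are reported, never silently repaired. *Points* are the
free tips of tines and beams: an element counts one point unless a present
child arises at its terminal fork (consuming the tip); side branches do not
consume tips, and processes never count. This is what makes the two-pointed
ancestral antler {brow tine, lower beam} and the three-pointed
{brow tine, lower beam, frontal tine, upper beam} count 2 and 3.

Unrooted input is rejected; the method is defined on the rooted fixed
topology, and branch lengths are ignored throughout.

## Packaged fixtures

The species table (25 species, 16 genera, adult antler counts), the element
catalogue (33 named elements with categories and attachment structure), the
seven skull indices, and the fixed rooted topology with labelled clades are
shipped as plain-text fixtures. Within-genus branching not fixed by the
named-clade structure uses a packaged default resolution (user-replaceable
via any rooted binary Newick): Cervini as
(Axis, (Rucervus, (Dama, ((Elaphurus, Panolia), (Rusa, Cervus))))) and
Capreolinae as (((Capreolus), Hydropotes), (Alces, (Rangifer, (Odocoileus,
(Blastocerus, Mazama))))). The headline reconstructions depend only on the
named-clade structure, which any such resolution preserves.

The species-level frequency registry is curated from explicitly stated
percentages and qualitative observations; qualitative classes map onto
percentages by a fixed table (all→100, almost_all→95, common→50, rare→10,
very_rare→2, absent→0) chosen so that coding a class reproduces the state
the class implies. The registry is exact at the level of coded states
{0,1,2}, which is all the reconstruction consumes; per-species percentages
of minor elements are approximate. The water deer (*Hydropotes inermis*)
is coded 0 throughout (no antlers). Elements described as plural sets
(pre-cacuminal tines, frontal-posterior tines, terminal-posterior-anterior
tines) are single characters.

## Synthetic data

The generators define the study conditions for testing:

* `simulate_dollo_character` evolves one element down the fixed tree —
  gain on a chosen (or random) edge at state 1 with immediate upgrade to 2
  at probability 0.9 on the gain edge, per-edge loss probability 0.1
  (irreversible), per-edge 1→2 at 0.9 and 2→1 at 0.05 thereafter;
* `simulate_specimens` inverts the coding step: each adult antler carries an
  element independently at a state-conditional frequency (2→0.95, 1→0.3,
  0→0; within-species frequency given a state is not part of the source
  model, and these defaults make coding recovery well conditioned), default
  20 antlers per species, alternating sides;
* `synthetic_antler` draws random tine trees (lengths 8–40, basal diameters
  up to length/4, non-degenerate fork windows) satisfying every structural
  invariant, so diagram assembly always succeeds on its output.

All randomness flows from the single explicit seed in `SimulationConfig`;
there is no global random state. What the generators do *not* emulate:
observation error in groove tracing, correlated presence among elements,
allometry and growth, and asymmetric left/right expression — so passing
recovery tests demonstrate the pipeline's internal consistency under its own
assumptions, not robustness to those real-data features.

## Numerical and scale choices

Exhaustive optimality checks enumerate rooted binary tree *shapes*
(Wedderburn–Etherington: 1, 1, 2, 3, 6 shapes for 2–6 leaves) crossed with
all tip assignments, which covers all labelled trees up to leaf relabelling.
Stochastic recovery checks use 1000 seeded replicates for gain-edge recovery
(no losses; recovery is then exact) and for coding recovery at frequency
0.95 with n = 100 (binomial tail below the 80% threshold ≈ 3e-8).
Projection properties are checked on 1000 random geometries; deletion
invariance on 60 random antlers at absolute tolerance 1e-9. Diagram angles
are exported at two decimal places; zone arithmetic tolerates 1e-6 in the
partition check. Coincidence tolerance defaults to 5°.

## Known limitations

* The frequency registry is a curated approximation: reconstructions of
  minor elements (crown tines, upper tines) reflect its choices, though the
  headline nodes are insensitive to them.
* Homology verdicts near predicate boundaries (coincidence tolerance,
  antipodal band) can flip for marks sitting exactly at a boundary; the
  exclusion rule for uninformative references mitigates but cannot remove
  discretization sensitivity.
* No DELTRAN option; the method specifies ACCTRAN. No likelihood or
  Bayesian reconstruction.
* The projection takes fork geometry as given; it does not extract grooves
  from photographs or 3D meshes.
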