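# Methods

## The qualitative-network semantics

Every node holds an integer level in `[range_min, range_max]` (all
breast-model nodes use 0..4; the engine supports heterogeneous ranges and
linearly rescales an input's level onto the consumer's range before
averaging, which is the identity for a uniform model).  One synchronous
tick computes every target on the *current* state and moves each free node
one level toward it; perturbed nodes keep their clamped level.  Dynamics
are therefore deterministic over a finite space, so every trajectory ends
in a cycle (an attractor); a fixed point is a period-1 attractor.

Targets are kept **real-valued**: the step rule compares the real target
with the integer level, so a fractional target (say 2.5) yields a
sustained two-cycle 2 ↔ 3.  This choice reproduces the convention that a
node oscillating between two levels of activity is summarized by the mean
of its minimum and maximum value; rounding targets before comparison
would instead freeze such nodes at an arbitrary side of the band.

Default target: `avg(activators) − avg(inhibitors)`, an empty inhibitor
set contributing 0.  A node with **no activators** tends toward a
per-node constitutive constant minus the average inhibition; the constant
defaults to `range_max` (an unopposed ligand/receptor node is fully on)
and is overridden per node in the model file.  Division by zero in a
custom formula is a hard error, never a silent clamp.

## Interval narrowing

Starting from the full box (perturbed nodes start at point intervals),
variables are swept round-robin in id order; for each free node the exact
range `[tmin, tmax]` of its target over the current box is computed —
directly from the interval endpoints for the monotone default function,
by enumerating the formula's support-variable combinations otherwise
(budget 10^5 combinations, above which conservative interval arithmetic
is used: exact for avg/min/max/±, widening for × and ÷) — and the node's
interval is replaced by `[clamp(⌊tmin⌋), clamp(⌈tmax⌉)]`.  Iteration
stops when a full pass changes nothing.  Sweep order cannot change the
fixpoint (property-tested with shuffled orders); from the full box the
intervals shrink monotonically, so termination is guaranteed.

Soundness: in any cycle, a node's maximum level M is entered from M−1
(target > M−1, so ⌈tmax⌉ ≥ M) or held at M (target = M, or clamped at a
range end); symmetrically for the minimum.  Hence every attractor state
lies inside the returned box, and an all-point box is a proof of
stabilization at that unique fixed point.  This is verified against
exhaustive enumeration on a battery of 200 seeded random 4-node networks
(levels 0..2, 81 states each — sized so brute force stays trivial while
still exercising thousands of attractors).

When bounds do not collapse, a node is summarized over the union of
attractors reached from a deterministic sample of initial states inside
the box: the all-low corner, the all-high corner, the floor-midpoint, and
32 draws from a seeded generator (the seed is part of every provenance
record).  Sampling can in principle miss an attractor of a tiny basin;
summaries are therefore reported as min/max/midpoint of what was reached,
and the containment property guarantees they never leave the narrowed
box.  Budgets: simulation `max_steps = 10 × Σ(levels per node)`,
brute-force bound 10^6 states; exceeding either raises an explicit error.

## The curated breast-tumor network

35 nodes (in-vivo variant), range 0..4 throughout — consistent with the
healthy-cell toxicity rule "apoptosis above 3".  The wiring follows the
mechanisms the biology dictates: Wnt1 → Frizzled → (GSK3β ⊣) β-catenin
feeding Myc, cell-cycle drive and — via quenching of ARF induction — cell
survival; EGF → EGFR → Ras → Raf → MEK → ERK feeding proliferation, COX2
and the antiapoptotic pool; Myc fed by ERK and β-catenin, driving
proliferation, p19ARF, VEGF/angiogenesis and repressing Wnt1 and p21;
p19ARF ⊣ Mdm2 ⊣ p53 → {PUMA, NOXA, p21}; hypoxia → HIF1α (degraded by
the PHD2/VHL machinery) → VEGF.  The in-vitro variant adds HER2 upstream
of EGFR and has no angiogenesis node (VEGF instead feeds autocrine
survival so it stays on a path to a phenotype); the in-vivo variant drops
HER2 and adds the angiogenesis phenotype.

Custom target functions (all others are the default):

* **p19ARF** `2·Myc − 4 − Frizzled`: ARF responds only to
  supraphysiological Myc (zero through the physiological mid-range), and
  active Wnt signaling quenches the induction.  The receptor-proximal
  signal (Frizzled) is used because the quenching acts upstream of
  β-catenin target genes and must not be re-routed by direct GSK3β
  manipulation.
* **HIF1α** `2·Hypoxia − avg(PHD2, VHL)`: nuclear HIF1α marks only
  strongly hypoxic tissue; the gain makes deep hypoxia dominate the
  normoxic degradation capacity.
* **Bnip3** `2·|PHD2 − VHL| − 2`: a modeling device for the observation
  that blocking exactly one arm of the sequential PHD2 → VHL degradation
  route is catastrophic (a BNIP3-type mitochondrial death signal from
  aberrantly processed HIF species) while blocking both yields a coherent
  pseudohypoxic state without it.  This is the least literature-anchored
  element of the model; it exists to express the screen's
  degradation-machinery toxicity rule as network behavior rather than as
  a special case in the filtering code.
* **Apoptosis** `max(avg(PUMA, NOXA) + Stress − Survival, Bnip3)`: the
  BH3 program must overcome the antiapoptotic buffer (ERK and
  prostaglandin survival signaling averaged in `Survival`); the tumor's
  constitutive stress load adds to the BH3 side, and the BNIP3 arm acts
  on mitochondria independently of the buffer.

The antiapoptotic pool deliberately averages the two *pharmacologically
separable* channels (ERK, PGE2).  Canonical Wnt survival is not pooled
there: it acts through the ARF–p53 quenching route, which is the
experimentally demonstrated mechanism of the paracrine rescue.  Keeping
the pool two-channel also keeps single-drug effects at the scale of one
activity level; the min/max summary convention quantizes midpoints to
half-levels, so sub-level effects would otherwise vanish into the
oscillation bands.

Clone configurations are pure node fixings: all tumor clones force the
Wnt transgene drive (`WntDrive = 4`) and a background stress level 1 (the
"mutations unaffected by the treatments" background); Myc-high clones
force `Myc = 4`; the paracrine Wnt source (`WntEnv`) is 4 wherever Myc-low
cells are nearby (pure Myc-low tumors and both mixed-clone settings) and
0 in pure Myc-high tumors whose neighbors have all silenced Wnt1; pure
Myc-low tumors are hypoxic (`Hypoxia = 3`, they cannot instruct stroma)
while Myc-high-containing tumors are angiogenic and normoxic
(`Hypoxia = 1`).  The healthy configuration fixes nothing and uses the
baseline microenvironment constants.

Druggability is a static annotation: EGFR, MEK, COX2, Wnt1, GSK3β, PHD2,
VHL and VEGF (plus HER2 in vitro).  Ras and ERK lack clinically
established direct inhibitors in this snapshot; RAF is excluded because
RAF inhibitors paradoxically activate MAPK signaling in Ras-driven cells;
Mdm2 antagonists and direct p53 modulators are likewise outside the
curated set.

## The screen

For each clone and each treatment (every druggable mono plus every
unordered pair; same-node pairs rejected), the clone fixings plus
inhibit-fixings are stabilized and the two phenotype nodes summarized.
An outcome label compares midpoints: net apoptosis if
apoptosis − proliferation > 0.5, net proliferation if < −0.5, else
balanced.  Filters:

* **healthy toxicity** — any treatment with healthy-cell apoptosis
  midpoint strictly above 3.0 is masked everywhere downstream (a midpoint
  of exactly 3 is retained); the PHD2+VHL mutual pair passes the filter
  as emergent model behavior, not as a code exception;
* **effective monotherapy** — a target enters the change-matrix rows if
  its mono treatment moves the metric in the beneficial direction
  (apoptosis up / proliferation down) by more than ε (default 0, strict)
  in at least one of the two mixed-tumor clones;
* **change matrices** — Δ[a][b] = metric(pair {a,b}) − metric(mono a),
  averaged over the two *mixed* clone configurations (the biclonal-tumor
  context; pure clones are reported separately in the screen table).  A
  flag additionally masks PHD2/VHL rows and columns for presentation
  (they otherwise dominate the color scale); the flag never alters the
  stored values.

"Mean change across both clones" could alternatively average the pure
clones; the mixed pair was chosen because the combination question is
posed for the biclonal tumor, and the pure-clone table remains available
in the exported screen CSV.

## The synthetic generator

`random_qn` draws a signed Erdős–Rényi digraph (default n = 4, edge
probability 0.5, activator fraction 0.5, levels 0..2, seeded) with
default target functions.  It emulates the *shape* of regulatory QNs —
sparse signed influence structure, default-averaging semantics — but not
the modular pathway organization, the long feed-forward cascades or the
curated formula targets of the tumor model; generator-based properties
therefore certify the engine's semantics and soundness, not the biology.
Test-battery sizes (200 models × 81 states) were chosen so exhaustive
enumeration remains a trivial oracle.

## Known limitations

* The network is a reconstruction constrained by published mechanism
  statements, not a copy of any specific curated edge list; its acceptance
  surface is the qualitative-claim suite.
* Inhibition is binary (fix at 0): no dose–response, no partial target
  engagement.
* Clonal population dynamics during treatment are not modeled; each clone
  is simulated at a fixed microenvironment snapshot.
* Attractor sampling inside non-point boxes is heuristic (corners,
  midpoint, 32 seeded draws); exhaustive enumeration is only feasible at
  test scale.
* Asynchronous update semantics and temporal-logic queries are out of
  scope.
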