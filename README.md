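# clonalqn

Qualitative-network modeling of oncogenic signaling in biclonal breast
tumors, with stable-state analysis and exhaustive in-silico inhibitor
screening.

## The problem

Breast tumors commonly contain stably coexisting clones with high and low
Myc activity.  High Myc drives proliferation, invasion and angiogenesis but
also primes cells for apoptosis through the p19ARF → p53 → PUMA/NOXA axis;
it simultaneously represses the cells' own Wnt1, a key autocrine survival
factor.  Myc-low neighbors supply paracrine Wnt that quenches the ARF–p53
response — an obligate mutualism that makes mixed tumors more resilient
than either pure clone, and that creates targetable vulnerabilities.  This
package provides an executable model of that circuit for exploring which
single and pairwise node inhibitions shift each clone from net
proliferation to net apoptosis.

## The formalism

A *qualitative network* (QN) generalizes a Boolean network: each node `v`
holds an integer level in `[0, r_v]` and at every synchronous tick moves
one step toward a real-valued *target function* `T_v` of its inputs,

    T_v(s) = avg(activators) − avg(inhibitors)

by default (a node with no activators uses a constitutive constant minus
the average inhibition); custom targets are expression trees over `var`,
`avg`, `min`, `max`, arithmetic, `ceil` and `floor`.  Long-run behavior is
analyzed by

* **exhaustive attractor enumeration** — brute force over the whole state
  space (test-scale models only), and
* **interval narrowing** — iterating per-node bounds
  `[lo_v, hi_v] ← [⌊min T_v⌋, ⌈max T_v⌉]` over the current box to a
  fixpoint.  The resulting box contains every attractor; if it collapses
  to a point the network provably stabilizes there.

A node that cannot be pinned to a single level (e.g. it oscillates between
two levels) is summarized by the mean of its minimum and maximum long-run
level.

Drug inhibition fixes a node at 0; clone identities (Myc forced to
maximum, paracrine Wnt supply raised or lowered, hypoxic vs normoxic
stroma) are node fixings too, so every condition in the screen is just a
set of clamped nodes on one shared network.

## Worked example

Stabilize the built-in in-vivo model for a pure Myc-high clone:

```
$ clonal-qn stabilize --clone myc_high_pure
model: breast_in_vivo   unique stable state proven: True
node             min max midpoint
...
Wnt1               0   0     0.00
BetaCatenin        0   0     0.00
p19ARF             4   4     4.00
Proliferation      2   2     2.00
Apoptosis          1   1     1.00
```

Myc at maximum has silenced the clone's own Wnt1, so Wnt signaling
(BetaCatenin) is lost, the ARF–p53 axis is fully engaged (p19ARF = 4) and
apoptosis runs above the Myc-low baseline while proliferation stays high.
Re-running with `--clone myc_high_mixed` (same mutations, but a raised
paracrine Wnt source from Myc-low neighbors) gives `p19ARF 2.00`,
`Apoptosis 0.00`, `Proliferation 2.50`: the in-silico restatement of the
clonal mutualism.

`clonal-qn validate` evaluates the full suite of qualitative claims
(12/12 pass on the shipped model), and

```
$ clonal-qn screen --seed 1 --out screen_out
top apoptosis change: first=COX2 added=MEK delta=+1.00
```

runs the druggable-target mono + pairwise inhibition screen across all
five clone configurations, masks treatments that push healthy-cell
apoptosis above level 3, and reports the add-a-second-inhibitor change
matrices.  The top apoptosis cell is the MEK + COX2 combination: MEK
inhibition removes antiapoptotic ERK signaling (hitting the
apoptosis-primed Myc-high clone hardest), and COX2 inhibition removes the
prostaglandin survival signal, extending the effect to the Myc-low clone.
`clonal-qn reproduce --out DIR` runs validation plus the screen in one
command; `clonal-qn synth` emits seeded random models for engine testing.

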