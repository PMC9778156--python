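# Methods

`hicspring` represents a binned genome as a **multigraph** and computes a
whole-genome 3D *pseudo-structure* by a modified force-directed layout.
This note describes the model, its parameters, the synthetic data used for
validation, and the numerical choices — in enough detail to reproduce or
modify any of them.

## The multigraph model

A genome binned at resolution *b* (default 10 kb) is a set of chains: one
node per bin boundary (a chromosome of *n* bins has *n*+1 nodes), and one
**genomic edge** per bin connecting consecutive boundaries.  Genomic edges
are the physical objects — elastic segments ("cylinders") with a rest
length proportional to the bin's bp length (`L1` per full bin) and
stiffness `k1`.  Terminal nodes have one genomic edge, interior nodes two,
so with no other forces each chromosome is a simple path.

Hi-C interactions add a second edge class over the same node set.  Each
retained contact between bins *i* and *j* becomes one **contact edge**
between the start nodes of the two bins, a Hooke spring with rest length
`L2 = L1/4` and the stiffest coefficient in the system (`k2 >> k1`, a
"hard" spring).  Multiple observations of the same bin pair collapse to a
single edge whose weight is the summed count; by default the weight does
not change the stiffness (an option scales stiffness by log-weight).
Contacts are attached to bin *start* nodes; attaching to both flanking
nodes would double the spring count without adding information, and the
start-node convention keeps the bin→node map trivial.

Intra-bin contacts (self-loops) are always discarded.

## Contact filtering

Raw contact lists (5-column TSV or BEDPE) are binned, canonicalised
(`i <= j`, duplicates merged) and filtered for **strong interactions**:

1. compute the per-bin total contact count over all records touching the
   bin (both endpoints count);
2. express a count threshold *t* as its empirical-percentile order
   `(#bins with total < t) / (#bins with >= 1 contact)` — the denominator
   is contact-bearing bins, a stated convention since the alternative
   (all bins) is equally defensible;
3. keep a record only if **both** endpoint bins have totals at or above
   *t* (inclusive, "this value or higher"; a strict mode exists, as does
   an alternative per-record count threshold).

Published cutoffs for real libraries (85 counts for barley bulk, 11/36
for rice single-cell inter/intra) are provided as CLI presets; on data
with heavy-tailed per-bin totals these sit near percentile order 0.5.

## Contact-graph analyses

Pure contact graphs (bins as nodes, weighted contacts as edges) are built
per scope — intra-, interchromosomal, or merged.  Because the two scopes
partition the records, merging is an exact edge-set union: merging graphs
with 1861 and 122 edges yields 1983 edges.  Conserved contact paths are
extracted by a **single-pass degree filter** (induced subgraph on nodes of
degree ≥ cutoff, not an iterated k-core — the induced-subgraph reading is
our documented choice) followed by largest-connected-component
extraction, ties broken toward the smallest bin index.  2D layout is
delegated to external tools through GEXF/GraphML export; exported nodes
carry chromosome, bp position and a telomere-to-telomere color rank.

## The layout engine

The pseudo-structure is the damped equilibrium of four forces:

1. **Hooke springs** on both edge classes: `F = k (|r| - L0) û`.
2. **Node repulsion**: inverse-square `c_rep / r²` with cutoff `r_cut`
   (neighbour search via a k-d tree), magnitude capped below `r_floor`.
3. **Segment self-avoidance**: every iteration, all non-adjacent pairs of
   *genomic* segments (contact edges are exempt) are tested for minimum
   distance `d < d_min`; a force `c_avoid (d_min - d)/d_min` along the
   closest-point separation is distributed to the four endpoints with the
   closest-point barycentric weights `(1-s, s)` and `(1-t, t)`.  Candidate
   pairs are pruned with a k-d tree on segment midpoints (radius
   `d_min + 2·max half-length`).  Segment–segment minimum distance uses
   the standard clamped closest-point algebra, vectorised; it is validated
   against a zooming 512×512 parameter-grid search to 1e-6.
4. **Confinement and drag**: nodes outside the nucleus radius `R` feel an
   inward spring `k_nuc (|p| - R)`; all motion is damped by `γ`.

Integration is semi-implicit Euler, `v ← (v + F·dt)(1 − γ·dt)`,
`p ← p + v·dt`, with a per-step displacement cap `max_disp`.  The cap
never moves a fixed point but keeps dense hard-spring networks (hundreds
of `k2` springs per node region) stable at `dt = 0.02`.  Initial positions
are uniform in the nucleus sphere — or in the genome-sized sphere if the
confinement radius is much larger — with a 1e-9 jitter so no two nodes
coincide; coincident nodes during a run simply skip the undefined spring
direction for that step.  A layout is a pure function of (multigraph,
parameters, seed): reruns are bit-identical.

### Parameters, units, defaults

Layout units are set by `L1 = 1` per full bin.  The model's *relations*
are fixed (hard short contact springs, `L2 = L1/4`); the numeric values
below are this package's own calibration and are all overridable via
`LayoutParams` or a `key = value` config file.

| parameter | default | meaning |
|---|---|---|
| `k1` | 1 | genomic spring stiffness |
| `k2` | 50 | contact spring stiffness ("maximum"/hard) |
| `L1`, `L2` | 1, 0.25 | rest lengths |
| `c_rep`, `r_cut`, `r_floor` | 0.5, 6, 0.05 | node repulsion |
| `d_min`, `c_avoid` | 0.3, 5 | self-avoidance (cylinder diameter, force scale) |
| `R` | auto | nucleus radius; auto sizes the sphere so total genomic edge length = 8·V^(1/3) (a crowded nucleus) |
| `k_nuc` | 50 | confinement stiffness (keeps the excess radius below ~5 %) |
| `γ`, `dt`, `max_disp` | 5, 0.02, 0.1 | integrator |
| `max_iter`, `tol` | 2000, 1e-4 | stop when the max per-step displacement falls below `tol` |

`c_rep`/`r_cut` are sized so that contact-compacted chromosome bodies
(~1–2 units across) separate cleanly inside an auto-sized nucleus;
repulsion with a short cutoff leaves neighbouring chromosome bodies
overlapping at their margins and territory verdicts become marginal.

## Structure statistics

**Territories.**  From the all-node distance matrix we compute the
chromosome-level mean-distance matrix; entry (*i*, *j*) is the mean
distance between nodes of chromosomes *i* and *j*, the diagonal averaging
over *distinct* node pairs only (including self-pairs would bias the
diagonal toward zero and trivialise the test).  The structure is
*territorial* when every diagonal entry is strictly the minimum of its
row; ties count as failure (conservative reading of "the lowest"), and a
chromosome with fewer than two nodes is "indeterminate".  The plot helper
shades each row from white (row minimum) to dark (row maximum) for
display only; the numeric matrix is never rescaled.

**Telomere clustering.**  The distal region is the terminal
`end_fraction` (default 0.1) of each chromosome's nodes at both ends.
The score is the mean pairwise distance among all distal nodes (across
chromosomes) divided by the mean pairwise distance among all nodes:
exchangeable labels give ≈ 1, pole-pooled telomeres give < 1.  The ratio
is invariant to rigid motions and uniform scaling; the degenerate
all-coincident case returns 1 by convention.

## Condensation and untangling

`condense(mg, factor)` multiplies every genomic rest length by `factor`
(default experiment: 0.5) and removes all contact edges — a condensed
metaphase-like state.  The untangling experiment then pulls every node
toward one of two poles at ±R/2 on the x-axis (chromosomes assigned
alternately) with a constant-magnitude force, integrating with the same
engine.  With breaking enabled, after a warm-up phase every genomic edge
whose extension ratio exceeds `beta` is removed each iteration.  The
warm-up is necessary because immediately after condensation *every* edge
sits at ratio `1/factor`; checks start once contraction has completed
(default 200 iterations).  The threshold is on extension ratio rather
than force so it is independent of the unit system.

"Locked" is quantified by the **residual close-pair count**: the number
of non-adjacent genomic segment pairs from *different* chromosomes closer
than `d_min` at the end of the run.  Interlocked rings pulled taut press
against each other at the link (count > 0); separated chains have none.
This is a proxy — loosely linked rings that are not taut can evade it,
which is why the experiment pulls hard enough to reach tautness.

## Synthetic ground truth

The generators produce idealized geometric configurations — not polymer
simulations — whose only purpose is to make recovery properties
assertable:

* **Rabl**: each chromosome is a hairpin walked along the polyline
  telomere → centromere → telomere with *exactly* equal node spacing
  (equal-chord walking, so the corner never breaks spacing).  Telomere
  anchors sit on a tight ring (0.05 R) near the +z pole — the Rabl
  telomere pool, which is what makes terminal bins of *different*
  chromosomes mutually contactable — while centromeres fan out at 0.5 R
  near the −z pole.  Ground-truth telomere score ≈ 0.24.
* **Rosette**: chromosomes loop from near-core anchors (0.3 R) out to
  0.85 R apices with a 0.08 R pericentromeric dip, each in its own
  angular sector; territorial by construction, telomere score ≈ 0.8
  in truth but ends are not mutually pooled.
* **Contact sampling**: bin-pair probabilities ∝ `exp(−d/λ)` over all
  distinct pairs, drawn multinomially (closed-form pair probabilities
  make the sampler exactly testable); counts aggregate per pair, no
  self-loops, deterministic per seed.  Exponential decay is a modelling
  choice — any monotone decay supports recovery testing.
* **Interlocked rings / parallel chains**: hand-built genomic-edge cycles
  (Hopf link) and straight path pairs for the untangling experiment; the
  rings deliberately violate the chains-are-paths invariant because no
  contact table can produce a cycle of genomic edges.

What the generators do **not** emulate: ligation noise, PCR duplicates,
mappability and coverage biases, distance-decay exponents of real
chromatin, or single-cell dropout beyond a uniform `subsample` flag.
Passing recovery tests therefore demonstrates that the layout inverts the
generative geometry under clean conditions, not that it resolves real
nuclear architecture.

## Validation conditions (problem sizes)

The recovery experiment uses 3 chromosomes × 50 bins (153 nodes), 5·10⁴
sampled contacts with λ = 0.8 (≈ 0.76 × the ground-truth node spacing),
strong-interaction filtering at percentile order 0.1, and 1500 layout
iterations per seed; ten seeds for the Rabl condition and three for the
Rosette contrast.  On synthetic homogeneous coverage the per-bin totals
are tightly concentrated, so a median-order filter (appropriate for
heavy-tailed experimental libraries) would discard bins essentially at
random; order 0.1 trims only the weak tail.  The untangling experiment
uses 20-bin rings, pole force 2, 4000 iterations, `beta = 2.5`, warm-up
200, and a stronger avoidance (`c_avoid = 20`) with a smaller step
(`dt = 0.01`, `max_disp = 0.05`) so that ring segments cannot tunnel
through each other while taut.

## Known limitations

* The pseudo-structure is a heuristic embedding, inherent to its
  parameter settings and initial state; it is not an inferred physical
  structure, and chromatin fibre thickness is not modelled (`d_min` is a
  layout-unit cylinder diameter, not nanometres).
* Long free chains crumpled at high density can lock into frustrated
  avoidance equilibria with residually stretched springs — the same
  phenomenon the untangling experiment studies deliberately.
* The percentile convention (contact-bearing bins, strict CDF) matters
  near ties; published orders computed under a different denominator will
  differ in the third decimal.
* Graphs with more than a few thousand contact edges per 150 nodes crush
  the structure into a ball (every contacted pair is pulled to `L2`
  regardless of count); informative layouts need the sparse, filtered
  contact sets the filtering stage is designed to produce.
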