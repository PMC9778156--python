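"""Modified force-directed 3D layout of the genome multigraph.

The pseudo-structure is the equilibrium of a damped particle system with
four force classes:

* Hooke springs on both edge classes — soft genomic springs (stiffness
  ``k1``, rest length ``L1`` per 10 kb bin) and hard contact springs
  (``k2``, rest length ``L2 = L1/4``);
* inverse-square node–node repulsion with a cutoff radius;
* segment–segment self-avoidance — whenever two non-adjacent *genomic*
  segments approach closer than ``d_min`` (the cylinder diameter), a
  repulsive force along their closest-point separation is distributed to
  the four endpoints; contact edges never participate;
* viscous drag, plus a soft spherical "nucleus" confinement of radius ``R``.

Positions are dimensionless layout units with ``L1 = 1`` per full bin.
Integration is semi-implicit Euler with velocity damping and a per-step
displacement cap; the cap leaves fixed points untouched but keeps stiff
contact-spring networks stable at practical time steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .genome_model import Multigraph

__all__ = [
    "LayoutParams",
    "LayoutState",
    "segment_min_distance",
    "segment_min_distances",
    "spring_force",
    "spring_forces",
    "node_repulsion",
    "avoidance_forces",
    "compute_forces",
    "step",
    "run_layout",
    "spring_energy",
    "load_params",
]

_EPS = 1e-12


@dataclass
class LayoutParams:
    """Physical and numerical parameters of the layout.

    The structure of the model fixes only the *relations*
    (hard, short contact springs: ``k2 >> k1``, ``L2 = L1/4``); the numeric
    defaults below are this package's own calibration, all in layout units
    where ``L1 = 1``.
    """

    k1: float = 1.0          # genomic spring stiffness
    k2: float = 50.0         # contact spring stiffness ("hard spring")
    L1: float = 1.0          # genomic rest length per full-size bin
    L2: float = 0.25         # contact rest length (= L1/4)
    c_rep: float = 0.5       # node repulsion constant (force = c_rep / r^2)
    r_cut: float = 6.0       # node repulsion cutoff radius
    r_floor: float = 0.05    # repulsion magnitude capped below this radius
    d_min: float = 0.3       # self-avoidance distance threshold (cylinder diameter)
    c_avoid: float = 5.0     # self-avoidance force scale
    R: float | None = None   # nucleus radius; None -> sized from total genomic length
    k_nuc: float = 50.0      # confinement stiffness beyond R
    gamma: float = 5.0       # drag coefficient
    dt: float = 0.02         # integration step
    max_disp: float = 0.1    # per-step displacement cap (layout units)
    max_iter: int = 2000
    tol: float = 1e-4        # convergence: max node displacement per step
    seed: int = 0

    def validate(self) -> None:
        for name in ("k1", "k2", "L1", "L2", "dt", "d_min", "r_cut", "r_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.L2 > self.L1:
            raise ValueError("L2 must not exceed L1")
        if not 0 < self.gamma * self.dt < 1:
            raise ValueError("require 0 < gamma*dt < 1 for stable damping")
        if self.c_rep < 0 or self.c_avoid < 0 or self.k_nuc < 0:
            raise ValueError("force constants must be non-negative")
        if self.R is not None and self.R <= 0:
            raise ValueError("R must be positive")

    def resolve_radius(self, mg: Multigraph) -> float:
        """Nucleus radius: explicit, or sized so the total genomic edge
        length is 8x the cube root of the sphere volume."""
        if self.R is not None:
            return float(self.R)
        total = max(mg.total_genomic_rest_length(), 1.0)
        return (total / 8.0) / (4.0 * np.pi / 3.0) ** (1.0 / 3.0)


def load_params(path) -> LayoutParams:
    """Read a flat ``key = value`` config file into LayoutParams."""
    p = LayoutParams()
    fields = {f: type(getattr(p, f)) for f in vars(p)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        if key in ("max_iter", "seed"):
            setattr(p, key, int(val))
        elif key == "R":
            setattr(p, key, None if val.lower() in ("none", "auto") else float(val))
        else:
            setattr(p, key, float(val))
    p.validate()
    return p


@dataclass
class LayoutState:
    """Per-node positions/velocities of a (possibly converged) layout."""

    positions: np.ndarray  # (n, 3)
    velocities: np.ndarray  # (n, 3)
    iteration: int = 0
    converged: bool = False

    def copy(self) -> "LayoutState":
        return LayoutState(self.positions.copy(), self.velocities.copy(), self.iteration, self.converged)


def _positions_of(state_or_positions) -> np.ndarray:
    if isinstance(state_or_positions, LayoutState):
        return state_or_positions.positions
    return np.asarray(state_or_positions, float)


# ---------------------------------------------------------------------------
# segment-segment minimum distance (Ericson closest-point clamping)

def segment_min_distances(P1, P2, Q1, Q2):
    """Vectorised minimum distance between segment batches.

    Returns ``(d, s, t)`` where the closest points are ``P1 + s*(P2-P1)`` and
    ``Q1 + t*(Q2-Q1)`` with ``s, t`` clamped to [0, 1].  Degenerate
    (zero-length) segments are handled as points.
    """
    P1, P2, Q1, Q2 = (np.atleast_2d(np.asarray(x, float)) for x in (P1, P2, Q1, Q2))
    d1 = P2 - P1
    d2 = Q2 - Q1
    r = P1 - Q1
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)

    s = np.zeros(len(a))
    t = np.zeros(len(a))

    both = (a <= _EPS) & (e <= _EPS)          # point-point
    p_deg = (a <= _EPS) & ~both               # P degenerate
    q_deg = (e <= _EPS) & ~both               # Q degenerate
    gen = ~(both | p_deg | q_deg)

    # P degenerate: closest point on Q to the point P1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p_deg, np.clip(f / np.where(e > _EPS, e, 1.0), 0.0, 1.0), t)
        # Q degenerate: closest point on P to Q1
        s = np.where(q_deg, np.clip(-c / np.where(a > _EPS, a, 1.0), 0.0, 1.0), s)
        # general case
        denom = a * e - b * b
        s_gen = np.where(denom > _EPS, np.clip((b * f - c * e) / np.where(denom > _EPS, denom, 1.0), 0.0, 1.0), 0.0)
        t_gen = (b * s_gen + f) / np.where(e > _EPS, e, 1.0)
        t_cl = np.clip(t_gen, 0.0, 1.0)
        s_re = np.clip((b * t_cl - c) / np.where(a > _EPS, a, 1.0), 0.0, 1.0)
        s_gen = np.where(t_cl != t_gen, s_re, s_gen)
        s = np.where(gen, s_gen, s)
        t = np.where(gen, t_cl, t)

    cp = P1 + s[:, None] * d1
    cq = Q1 + t[:, None] * d2
    d = np.linalg.norm(cp - cq, axis=1)
    return d, s, t


def segment_min_distance(p1, p2, q1, q2):
    """Minimum distance between segments [p1,p2] and [q1,q2].

    Returns ``(distance, s, t)`` with the closest-point parameters in [0,1].
    Symmetric in segment order; degenerate segments are allowed.
    """
    d, s, t = segment_min_distances(
        np.asarray(p1)[None], np.asarray(p2)[None], np.asarray(q1)[None], np.asarray(q2)[None]
    )
    return float(d[0]), float(s[0]), float(t[0])


# ---------------------------------------------------------------------------
# force terms

def spring_force(pa, pb, k: float, L0: float) -> np.ndarray:
    """Hooke force on node *a* of a spring a—b: ``k (|pb-pa| - L0) u_ab``.

    Attractive when stretched, repulsive when compressed; the force on *b*
    is the negation.  Coincident endpoints give a zero force (the spring
    direction is undefined for that step).
    """
    pa = np.asarray(pa, float)
    pb = np.asarray(pb, float)
    delta = pb - pa
    r = np.linalg.norm(delta)
    if r < _EPS:
        return np.zeros(3)
    return k * (r - L0) * delta / r


def spring_forces(positions: np.ndarray, edges: np.ndarray, k, rest) -> np.ndarray:
    """Accumulated Hooke forces for an edge array; ``k``/``rest`` scalar or per-edge."""
    F = np.zeros_like(positions)
    if len(edges) == 0:
        return F
    delta = positions[edges[:, 1]] - positions[edges[:, 0]]
    r = np.linalg.norm(delta, axis=1)
    safe = np.where(r > _EPS, r, 1.0)
    mag = np.asarray(k) * (r - np.asarray(rest))
    fvec = (mag / safe)[:, None] * delta
    fvec[r <= _EPS] = 0.0
    np.add.at(F, edges[:, 0], fvec)
    np.add.at(F, edges[:, 1], -fvec)
    return F


def node_repulsion(positions, c_rep: float, r_cut: float, r_floor: float = 0.05) -> np.ndarray:
    """Pairwise inverse-square repulsion with cutoff.

    Force magnitude ``c_rep / r^2`` for ``r_floor <= r < r_cut``, capped at
    ``c_rep / r_floor^2`` below ``r_floor``; exactly coincident nodes exert
    no force on each other (direction undefined).
    """
    positions = _positions_of(positions)
    F = np.zeros_like(positions)
    if c_rep == 0 or len(positions) < 2:
        return F
    pairs = cKDTree(positions).query_pairs(r_cut, output_type="ndarray")
    if len(pairs) == 0:
        return F
    delta = positions[pairs[:, 0]] - positions[pairs[:, 1]]
    r = np.linalg.norm(delta, axis=1)
    ok = r > _EPS
    pairs, delta, r = pairs[ok], delta[ok], r[ok]
    mag = c_rep / np.maximum(r, r_floor) ** 2
    fvec = (mag / r)[:, None] * delta
    np.add.at(F, pairs[:, 0], fvec)
    np.add.at(F, pairs[:, 1], -fvec)
    return F


def _candidate_segment_pairs(positions: np.ndarray, edges: np.ndarray, d_min: float) -> np.ndarray:
    """Candidate non-adjacent genomic edge pairs possibly closer than d_min.

    Pruned with a KD-tree on segment midpoints: two segments can only come
    within d_min if their midpoints are within d_min plus the two
    half-lengths, bounded by the global maximum.
    """
    if len(edges) < 2:
        return np.empty((0, 2), dtype=np.int64)
    a = positions[edges[:, 0]]
    b = positions[edges[:, 1]]
    mid = 0.5 * (a + b)
    half = 0.5 * np.linalg.norm(b - a, axis=1)
    radius = d_min + 2.0 * float(half.max())
    pairs = cKDTree(mid).query_pairs(radius, output_type="ndarray")
    if len(pairs) == 0:
        return pairs
    e1 = edges[pairs[:, 0]]
    e2 = edges[pairs[:, 1]]
    shares = (
        (e1[:, 0] == e2[:, 0]) | (e1[:, 0] == e2[:, 1])
        | (e1[:, 1] == e2[:, 0]) | (e1[:, 1] == e2[:, 1])
    )
    return pairs[~shares]


def avoidance_forces(state_or_positions, mg: Multigraph, params: LayoutParams) -> np.ndarray:
    """Segment self-avoidance forces between non-adjacent genomic edges.

    For each genomic edge pair whose minimum separation ``d`` is below
    ``d_min``, a force of magnitude ``c_avoid * (d_min - d) / d_min`` acts
    along the closest-point separation and is distributed to the four
    endpoints with weights ``(1-s, s)`` and ``(1-t, t)``.  Contact edges are
    excluded from the check entirely.
    """
    positions = _positions_of(state_or_positions)
    F = np.zeros_like(positions)
    if params.c_avoid == 0:
        return F
    edges = mg.genomic_edges
    pairs = _candidate_segment_pairs(positions, edges, params.d_min)
    if len(pairs) == 0:
        return F
    e1 = edges[pairs[:, 0]]
    e2 = edges[pairs[:, 1]]
    d, s, t = segment_min_distances(
        positions[e1[:, 0]], positions[e1[:, 1]], positions[e2[:, 0]], positions[e2[:, 1]]
    )
    close = (d < params.d_min) & (d > _EPS)
    if not close.any():
        return F
    e1, e2, d, s, t = e1[close], e2[close], d[close], s[close], t[close]
    cp = positions[e1[:, 0]] + s[:, None] * (positions[e1[:, 1]] - positions[e1[:, 0]])
    cq = positions[e2[:, 0]] + t[:, None] * (positions[e2[:, 1]] - positions[e2[:, 0]])
    sep = (cp - cq) / d[:, None]
    mag = params.c_avoid * (params.d_min - d) / params.d_min
    fvec = mag[:, None] * sep
    np.add.at(F, e1[:, 0], (1.0 - s)[:, None] * fvec)
    np.add.at(F, e1[:, 1], s[:, None] * fvec)
    np.add.at(F, e2[:, 0], -(1.0 - t)[:, None] * fvec)
    np.add.at(F, e2[:, 1], -t[:, None] * fvec)
    return F


def confinement_forces(positions: np.ndarray, R: float, k_nuc: float) -> np.ndarray:
    """Soft inward radial spring ``k_nuc (|p| - R)`` for nodes outside R."""
    r = np.linalg.norm(positions, axis=1)
    out = r > R
    F = np.zeros_like(positions)
    if out.any():
        F[out] = (-k_nuc * (r[out] - R) / r[out])[:, None] * positions[out]
    return F


def compute_forces(
    positions: np.ndarray,
    mg: Multigraph,
    params: LayoutParams,
    *,
    include_avoidance: bool = True,
    include_contacts: bool = True,
) -> np.ndarray:
    """Total force: springs (both edge classes), node repulsion,
    self-avoidance and spherical confinement."""
    F = spring_forces(positions, mg.genomic_edges, mg.k1, mg.genomic_rest)
    if include_contacts and mg.n_contact_edges:
        F += spring_forces(positions, mg.contact_edges, mg.contact_k(), mg.contact_rest)
    F += node_repulsion(positions, params.c_rep, params.r_cut, params.r_floor)
    if include_avoidance:
        F += avoidance_forces(positions, mg, params)
    F += confinement_forces(positions, params.resolve_radius(mg), params.k_nuc)
    return F


def step(
    state: LayoutState,
    mg: Multigraph,
    params: LayoutParams,
    *,
    extra_forces: np.ndarray | None = None,
) -> LayoutState:
    """One semi-implicit Euler update (in place):
    ``v <- (v + F dt)(1 - gamma dt)``, ``p <- p + v dt``, with the step
    displacement capped at ``max_disp`` per node."""
    F = compute_forces(state.positions, mg, params)
    if extra_forces is not None:
        F = F + extra_forces
    if not np.isfinite(F).all():
        raise FloatingPointError(
            f"non-finite forces at iteration {state.iteration}; "
            f"reduce dt (currently {params.dt}) or stiffnesses"
        )
    v = (state.velocities + F * params.dt) * (1.0 - params.gamma * params.dt)
    disp = np.linalg.norm(v, axis=1) * params.dt
    too_fast = disp > params.max_disp
    if too_fast.any():
        v[too_fast] *= (params.max_disp / disp[too_fast])[:, None]
    state.velocities = v
    state.positions = state.positions + v * params.dt
    state.iteration += 1
    return state


def initial_state(mg: Multigraph, params: LayoutParams, rng: np.random.Generator) -> LayoutState:
    """Nodes uniform in the nucleus sphere, with a tiny jitter so that no
    two nodes are exactly coincident.

    With a confinement radius much larger than the genome itself, the start
    is drawn from the genome-sized sphere instead, so relaxation times do
    not scale with the (irrelevant) empty volume."""
    n = mg.n_nodes
    R = min(params.resolve_radius(mg), replace(params, R=None).resolve_radius(mg))
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = R * rng.random(n) ** (1.0 / 3.0)
    pos = dirs * radii[:, None] + rng.normal(scale=1e-9, size=(n, 3))
    return LayoutState(positions=pos, velocities=np.zeros((n, 3)))


def run_layout(
    mg: Multigraph,
    params: LayoutParams | None = None,
    *,
    snapshot_every: int | None = None,
    snapshot_callback=None,
) -> LayoutState:
    """Iterate :func:`step` from a seeded random start until the maximum
    node displacement drops below ``tol`` or ``max_iter`` is reached.

    Pure function of ``(mg, params)`` including the seed: identical inputs
    give bit-identical layouts.  With ``snapshot_every = N``,
    ``snapshot_callback(state)`` is invoked every N iterations (trajectory
    recording); the callback must not mutate the state.
    """
    if mg.n_nodes == 0:
        raise ValueError("multigraph has no nodes")
    params = params or LayoutParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    state = initial_state(mg, params, rng)
    for _ in range(params.max_iter):
        prev = state.positions
        step(state, mg, params)
        if snapshot_every and snapshot_callback and state.iteration % snapshot_every == 0:
            snapshot_callback(state)
        if np.abs(state.positions - prev).max() < params.tol:
            state.converged = True
            break
    return state


def spring_energy(positions, mg: Multigraph, *, include_contacts: bool = True) -> float:
    """Total elastic energy ``sum 1/2 k (r - L0)^2`` of the spring network."""
    positions = _positions_of(positions)
    e = 0.0
    for edges, k, rest in (
        (mg.genomic_edges, mg.k1, mg.genomic_rest),
        (mg.contact_edges, mg.contact_k(), mg.contact_rest) if include_contacts else ((), 0, ()),
    ):
        if len(edges) == 0:
            continue
        r = np.linalg.norm(positions[np.asarray(edges)[:, 1]] - positions[np.asarray(edges)[:, 0]], axis=1)
        e += float(np.sum(0.5 * np.asarray(k) * (r - np.asarray(rest)) ** 2))
    return e
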