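"""Prestressed hexagonal spring networks and their mechanical equilibrium.

A lung slice is modeled as a honeycomb lattice of identical linear
springs (unit stiffness).  Prestress is imposed by giving every spring a
rest length shorter than the lattice edge (``L0 = edge / prestress_ratio``
with ``prestress_ratio > 1``), so the intact network is everywhere under
tension, like parenchyma distended by transpulmonary pressure.  Springs
under high-attenuation structures (vessels) get a doubled rest length so
they never contract; nodes in a band along the lung boundary are fixed.

Equilibrium is found by minimizing the total elastic energy
``sum 1/2 k (L - L0)^2`` over free-node positions, either with simulated
annealing (single-node Gaussian proposals, geometric cooling, then a
local polish) or with a deterministic quasi-Newton descent that serves
as the reference solver.  Springs are linear and bidirectional by
default (the lattice is under global tension, so compression appears
only transiently around carved voids); an optional tension-only mode
makes compressed springs slack instead, emulating buckling septa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage, optimize

from .config import DEFAULT_CONFIG, RunConfig
from .errors import InvalidTemplateError


@dataclass
class HexSpringNetwork:
    """Honeycomb lattice of nodes and linear springs.

    positions : (n, 2) float, node coordinates in pixel units (x, y)
    fixed     : (n,) bool, nodes that never move during minimization
    edges     : (m, 2) int, spring endpoints (node indices)
    rest_length : (m,) float, spring rest lengths L0
    stiffness : (m,) float, spring constants k
    alive     : (m,) bool, springs not yet carved/ruptured
    """

    positions: np.ndarray
    fixed: np.ndarray
    edges: np.ndarray
    rest_length: np.ndarray
    stiffness: np.ndarray
    alive: np.ndarray
    lattice_edge: float
    prestress_ratio: float
    tension_only: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_springs(self) -> int:
        return len(self.edges)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def copy(self) -> "HexSpringNetwork":
        return HexSpringNetwork(
            positions=self.positions.copy(),
            fixed=self.fixed.copy(),
            edges=self.edges.copy(),
            rest_length=self.rest_length.copy(),
            stiffness=self.stiffness.copy(),
            alive=self.alive.copy(),
            lattice_edge=self.lattice_edge,
            prestress_ratio=self.prestress_ratio,
            tension_only=self.tension_only,
        )

    def compact(self, keep_nodes: np.ndarray) -> "HexSpringNetwork":
        """Drop nodes not in ``keep_nodes`` (bool mask) and reindex springs."""
        keep_nodes = np.asarray(keep_nodes, dtype=bool)
        new_index = -np.ones(self.n_nodes, dtype=int)
        new_index[keep_nodes] = np.arange(int(keep_nodes.sum()))
        keep_springs = keep_nodes[self.edges[:, 0]] & keep_nodes[self.edges[:, 1]]
        return HexSpringNetwork(
            positions=self.positions[keep_nodes],
            fixed=self.fixed[keep_nodes],
            edges=new_index[self.edges[keep_springs]],
            rest_length=self.rest_length[keep_springs],
            stiffness=self.stiffness[keep_springs],
            alive=self.alive[keep_springs],
            lattice_edge=self.lattice_edge,
            prestress_ratio=self.prestress_ratio,
            tension_only=self.tension_only,
        )

    def spring_lengths(self, positions: Optional[np.ndarray] = None) -> np.ndarray:
        pos = self.positions if positions is None else positions
        d = pos[self.edges[:, 1]] - pos[self.edges[:, 0]]
        return np.linalg.norm(d, axis=1)

    def energy(self, positions: Optional[np.ndarray] = None) -> float:
        lengths = self.spring_lengths(positions)
        ext = lengths - self.rest_length
        if self.tension_only:
            ext = np.maximum(ext, 0.0)
        e = 0.5 * self.stiffness * ext**2
        return float(e[self.alive].sum())


@dataclass
class EquilibriumState:
    """Node positions and per-spring tensions after energy minimization."""

    positions: np.ndarray
    forces: np.ndarray          # per spring; 0 for dead or slack springs
    energy: float
    converged: bool
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_hex_cells(
    m: int,
    n: int,
    lattice_edge: float = 1.0,
    prestress_ratio: float = DEFAULT_CONFIG.prestress_ratio,
    tension_only: bool = False,
) -> HexSpringNetwork:
    """Honeycomb of m x n hexagonal cells with unit-stiffness springs."""
    if lattice_edge <= 0:
        raise ValueError("lattice_edge must be positive")
    if prestress_ratio <= 1:
        raise ValueError("prestress_ratio must exceed 1")
    graph = nx.hexagonal_lattice_graph(m, n)
    nodes = list(graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    pos = np.array([graph.nodes[nd]["pos"] for nd in nodes], dtype=float)
    pos *= lattice_edge
    edges = np.array([[index[u], index[v]] for u, v in graph.edges], dtype=int)
    n_springs = len(edges)
    return HexSpringNetwork(
        positions=pos,
        fixed=np.zeros(len(nodes), dtype=bool),
        edges=edges,
        rest_length=np.full(n_springs, lattice_edge / prestress_ratio),
        stiffness=np.ones(n_springs),
        alive=np.ones(n_springs, dtype=bool),
        lattice_edge=lattice_edge,
        prestress_ratio=prestress_ratio,
        tension_only=tension_only,
    )


def build_hex_network(
    grid_shape: Tuple[int, int],
    lattice_edge: float = 1.0,
    prestress_ratio: float = DEFAULT_CONFIG.prestress_ratio,
    tension_only: bool = False,
) -> HexSpringNetwork:
    """Honeycomb lattice covering a pixel grid of ``(rows, cols)``.

    Node spacing equals ``lattice_edge`` so every spring starts stretched
    by the factor ``prestress_ratio`` relative to its rest length.
    """
    rows, cols = grid_shape
    if rows <= 0 or cols <= 0:
        raise ValueError("grid dimensions must be positive")
    a = lattice_edge
    # nx.hexagonal_lattice_graph(m, n) spans x in [0, (3n/2 + 1/2)] and
    # y in [0, (2m+1) * sqrt(3)/2] in units of the edge length.
    n_cells = int(np.ceil((cols / a - 0.5) * 2.0 / 3.0)) + 1
    m_cells = int(np.ceil((rows / (a * np.sqrt(3) / 2.0) - 1.0) / 2.0)) + 1
    net = build_hex_cells(
        max(m_cells, 1), max(n_cells, 1), a, prestress_ratio, tension_only
    )
    net.positions += np.array([-0.5, -0.5])  # cover pixel extent from -0.5
    return net


# ---------------------------------------------------------------------------
# carving and templating
# ---------------------------------------------------------------------------

def _node_pixels(net: HexSpringNetwork, shape) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest pixel (row, col) per node plus an in-bounds mask."""
    cols = np.floor(net.positions[:, 0] + 0.5).astype(int)
    rows = np.floor(net.positions[:, 1] + 0.5).astype(int)
    inside = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    return np.stack([rows, cols]), inside


def apply_lung_template(
    net: HexSpringNetwork,
    lung_mask: np.ndarray,
    high_atten_mask: Optional[np.ndarray] = None,
    fixed_band: Optional[float] = None,
) -> HexSpringNetwork:
    """Restrict the lattice to the lung region and pin its rim.

    Nodes outside the lung mask are removed together with their springs;
    nodes within ``fixed_band`` lattice edges of the lung boundary are
    flagged fixed.  Springs whose midpoint falls in the high-attenuation
    mask get a doubled rest length, making them slack placeholders that
    never contract under the tension-only rule.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if not lung_mask.any():
        raise InvalidTemplateError("lung mask is empty")
    if fixed_band is None:
        fixed_band = DEFAULT_CONFIG.fixed_band
    (rows, cols), inside = _node_pixels(net, lung_mask.shape)
    keep = inside.copy()
    keep[inside] = lung_mask[rows[inside], cols[inside]]
    out = net.compact(keep)

    # distance to lung boundary; the image border also counts as boundary
    padded = np.pad(lung_mask, 1)
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    (rows, cols), inside = _node_pixels(out, lung_mask.shape)
    band = fixed_band * out.lattice_edge + 1e-9
    out.fixed = np.zeros(out.n_nodes, dtype=bool)
    out.fixed[inside] = edt[rows[inside], cols[inside]] <= band
    # under-coordinated nodes only occur where the lattice was trimmed,
    # i.e. on the lung boundary; a free degree-<3 node is mechanically
    # unbalanced under prestress and would drag the lattice sideways
    degree = np.zeros(out.n_nodes, dtype=int)
    live = out.edges[out.alive]
    np.add.at(degree, live[:, 0], 1)
    np.add.at(degree, live[:, 1], 1)
    out.fixed |= degree < 3

    if high_atten_mask is not None:
        high_atten_mask = np.asarray(high_atten_mask, dtype=bool)
        mid = 0.5 * (out.positions[out.edges[:, 0]] + out.positions[out.edges[:, 1]])
        mc = np.floor(mid[:, 0] + 0.5).astype(int)
        mr = np.floor(mid[:, 1] + 0.5).astype(int)
        ok = (mr >= 0) & (mr < high_atten_mask.shape[0]) & \
             (mc >= 0) & (mc < high_atten_mask.shape[1])
        hit = np.zeros(out.n_springs, dtype=bool)
        hit[ok] = high_atten_mask[mr[ok], mc[ok]]
        out.rest_length = np.where(
            hit, 2.0 * out.lattice_edge / out.prestress_ratio, out.rest_length
        )
    return out


def carve_mask(net: HexSpringNetwork, laa_mask: np.ndarray) -> HexSpringNetwork:
    """Kill every alive spring whose midpoint lies in a foreground pixel.

    Nodes left without any alive spring are pruned.  An empty mask is a
    no-op (a copy is still returned).
    """
    laa_mask = np.asarray(laa_mask, dtype=bool)
    out = net.copy()
    if laa_mask.any():
        mid = 0.5 * (out.positions[out.edges[:, 0]] + out.positions[out.edges[:, 1]])
        mc = np.floor(mid[:, 0] + 0.5).astype(int)
        mr = np.floor(mid[:, 1] + 0.5).astype(int)
        ok = (mr >= 0) & (mr < laa_mask.shape[0]) & \
             (mc >= 0) & (mc < laa_mask.shape[1])
        hit = np.zeros(out.n_springs, dtype=bool)
        hit[ok] = laa_mask[mr[ok], mc[ok]]
        out.alive &= ~hit
    degree = np.zeros(out.n_nodes, dtype=int)
    live = out.edges[out.alive]
    np.add.at(degree, live[:, 0], 1)
    np.add.at(degree, live[:, 1], 1)
    return out.compact(degree > 0)


# ---------------------------------------------------------------------------
# equilibrium
# ---------------------------------------------------------------------------

def _energy_and_grad(net: HexSpringNetwork, positions: np.ndarray):
    """Total elastic energy and per-node gradient (all nodes)."""
    e0 = net.edges[net.alive, 0]
    e1 = net.edges[net.alive, 1]
    k = net.stiffness[net.alive]
    l0 = net.rest_length[net.alive]
    d = positions[e1] - positions[e0]
    lengths = np.linalg.norm(d, axis=1)
    ext = lengths - l0
    if net.tension_only:
        ext = np.maximum(ext, 0.0)
    energy = 0.5 * float(np.sum(k * ext**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = np.where(lengths > 0, k * ext / lengths, 0.0)
    fvec = coef[:, None] * d  # force on e0 toward e1
    grad = np.zeros_like(positions)
    for axis in range(2):
        grad[:, axis] = np.bincount(
            e0, weights=-fvec[:, axis], minlength=net.n_nodes
        ) + np.bincount(e1, weights=fvec[:, axis], minlength=net.n_nodes)
    return energy, grad


def residual_forces(net: HexSpringNetwork, positions: np.ndarray) -> np.ndarray:
    """Net force magnitude on every node at the given positions."""
    _, grad = _energy_and_grad(net, positions)
    return np.linalg.norm(grad, axis=1)


def spring_forces(
    net: HexSpringNetwork, state: EquilibriumState
) -> np.ndarray:
    """Tension ``k * (L - L0)`` per spring; 0 for dead or slack springs."""
    lengths = net.spring_lengths(state.positions)
    ext = lengths - net.rest_length
    if net.tension_only:
        ext = np.maximum(ext, 0.0)
    forces = net.stiffness * ext
    forces[~net.alive] = 0.0
    return forces


def _solve_deterministic(
    net: HexSpringNetwork, x0: np.ndarray, tol: float
) -> Tuple[np.ndarray, bool]:
    free = ~net.fixed
    n_free = int(free.sum())
    if n_free == 0:
        return x0, True
    pos = x0.copy()

    def fun(flat):
        pos[free] = flat.reshape(n_free, 2)
        e, g = _energy_and_grad(net, pos)
        return e, g[free].ravel()

    res = optimize.minimize(
        fun,
        x0[free].ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 20000, "maxfun": 50000,
                 "gtol": 0.1 * tol, "ftol": 1e-16},
    )
    pos[free] = res.x.reshape(n_free, 2)
    ok = bool(np.all(residual_forces(net, pos)[free] < tol))
    return pos, ok


def _solve_anneal(
    net: HexSpringNetwork,
    x0: np.ndarray,
    seed: int,
    config: RunConfig,
) -> np.ndarray:
    """Simulated annealing: Metropolis over random single-node displacements
    with geometric cooling.  Returns the best configuration visited."""
    rng = np.random.default_rng(seed)
    pos = x0.copy()
    free_idx = np.flatnonzero(~net.fixed)
    if len(free_idx) == 0:
        return pos
    # incidence lists for O(degree) energy deltas
    incident = [[] for _ in range(net.n_nodes)]
    for s, (a, b) in enumerate(net.edges):
        if net.alive[s]:
            incident[a].append(s)
            incident[b].append(s)
    edges = net.edges
    l0 = net.rest_length
    k = net.stiffness
    tension_only = net.tension_only

    def local_energy(node, p):
        e = 0.0
        for s in incident[node]:
            a, b = edges[s]
            q = pos[b] if a == node else pos[a]
            length = float(np.hypot(p[0] - q[0], p[1] - q[1]))
            ext = length - l0[s]
            if tension_only and ext < 0:
                ext = 0.0
            e += 0.5 * k[s] * ext * ext
        return e

    e_total = net.energy(pos)
    n_springs = max(net.n_alive, 1)
    temp = config.anneal_t0_scale * e_total / n_springs
    sigma = config.anneal_sigma * net.lattice_edge
    best_pos = pos.copy()
    best_e = e_total
    for _ in range(config.anneal_sweeps):
        order = rng.permutation(free_idx)
        steps = rng.normal(0.0, sigma, size=(len(order), 2))
        accept_u = rng.random(len(order))
        for j, node in enumerate(order):
            p_old = pos[node].copy()
            e_old = local_energy(node, p_old)
            p_new = p_old + steps[j]
            e_new = local_energy(node, p_new)
            de = e_new - e_old
            if de <= 0 or (temp > 0 and accept_u[j] < np.exp(-de / temp)):
                pos[node] = p_new
                e_total += de
                if e_total < best_e:
                    best_e = e_total
                    best_pos = pos.copy()
        temp *= config.anneal_cooling
    return best_pos


def solve_equilibrium(
    net: HexSpringNetwork,
    method: str = "deterministic",
    seed: int = 0,
    config: RunConfig = DEFAULT_CONFIG,
    initial_positions: Optional[np.ndarray] = None,
) -> EquilibriumState:
    """Minimize total elastic energy over free-node positions.

    ``deterministic`` runs a quasi-Newton (L-BFGS) descent from the
    initial configuration and is the reference solver; ``anneal`` runs
    simulated annealing followed by the same deterministic polish.  Both
    leave every free node with a residual net force below
    ``config.force_tolerance * k * lattice_edge`` when converged.  The
    returned energy never exceeds the initial configuration's.
    """
    x0 = (
        net.positions.copy()
        if initial_positions is None
        else np.asarray(initial_positions, dtype=float).copy()
    )
    x0[net.fixed] = net.positions[net.fixed]
    tol = config.force_tolerance * net.lattice_edge * float(
        net.stiffness.max() if net.n_springs else 1.0
    )
    e_init = net.energy(x0)
    if method == "anneal":
        pos = _solve_anneal(net, x0, seed, config)
        pos, ok = _solve_deterministic(net, pos, tol)
    elif method == "deterministic":
        pos, ok = _solve_deterministic(net, x0, tol)
    else:
        raise ValueError(f"unknown method {method!r}")
    energy = net.energy(pos)
    if energy > e_init:  # descent guarantee; annealing can only improve on x0
        pos, energy = x0, e_init
        ok = bool(np.all(residual_forces(net, pos)[~net.fixed] < tol))
    if not ok:
        warnings.warn("equilibrium solve did not reach force tolerance",
                      stacklevel=2)
    state = EquilibriumState(
        positions=pos, forces=np.empty(0), energy=energy, converged=ok,
        seed=seed,
    )
    state.forces = spring_forces(net, state)
    return state
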