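"""Force-based network breakdown simulating emphysema progression.

At each iteration every alive spring carrying a tension at or above a
fraction (default 80%) of the current maximum is ruptured, the network
is re-equilibrated, and the apparent CT is re-thresholded to track the
evolving LAA structure (%LAA, largest cluster A_L, exponent D, energy).
Rupture redistributes force onto neighboring springs, so damage clusters
and neighboring voids coalesce — the mechanism behind the sudden jumps
in the largest-cluster trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig
from .errors import ProgressionTerminated
from .imaging import (
    binarize_apparent,
    cluster_stats,
    d_local,
    render_apparent_ct,
)
from .network import (
    EquilibriumState,
    HexSpringNetwork,
    solve_equilibrium,
    spring_forces,
)


@dataclass
class ProgressionRecord:
    iteration: int
    pct_laa: float
    largest: int
    second_largest: int
    exponent: float
    energy: float
    springs_removed: int
    laa_mask: np.ndarray


@dataclass
class ProgressionTrace:
    records: List[ProgressionRecord]
    force_fraction: float
    n_iterations: int
    terminated_early: bool = False
    all_converged: bool = True

    def __len__(self) -> int:
        return len(self.records)

    @property
    def pct_laa(self) -> np.ndarray:
        return np.array([r.pct_laa for r in self.records])

    @property
    def largest(self) -> np.ndarray:
        return np.array([r.largest for r in self.records], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": r.iteration,
                    "pct_laa": r.pct_laa,
                    "largest": r.largest,
                    "exponent": r.exponent,
                    "energy": r.energy,
                    "springs_removed": r.springs_removed,
                }
                for r in self.records
            ]
        )


def degrade_step(
    net: HexSpringNetwork,
    state: EquilibriumState,
    force_fraction: float = DEFAULT_CONFIG.force_fraction,
) -> Tuple[HexSpringNetwork, int]:
    """Rupture all springs at or above ``force_fraction`` of the max force.

    The comparison includes the maximum itself so at least one spring
    ruptures per step (a strict inequality would be a no-op in exact-tie
    degeneracies).  Returns the degraded network and the removal count.
    """
    if not 0.0 < force_fraction < 1.0:
        raise ValueError("force_fraction must be in (0, 1)")
    if net.n_alive == 0:
        raise ProgressionTerminated("no alive springs left")
    forces = spring_forces(net, state)
    fmax = float(forces[net.alive].max())
    threshold = force_fraction * fmax
    doomed = net.alive & (forces >= threshold - 1e-12)
    out = net.copy()
    out.alive &= ~doomed
    return out, int(doomed.sum())


def simulate_progression(
    net: HexSpringNetwork,
    lung_mask: np.ndarray,
    reference_intensity: float,
    n_iter: int = DEFAULT_CONFIG.n_iterations,
    force_fraction: float = DEFAULT_CONFIG.force_fraction,
    seed: int = 0,
    config: RunConfig = DEFAULT_CONFIG,
    method: str = "deterministic",
) -> ProgressionTrace:
    """Iterate degrade -> re-equilibrate -> render -> threshold -> measure.

    The trace starts with the initial equilibrium (iteration 0) and adds
    one record per iteration; re-equilibration is warm-started from the
    previous configuration.  Early termination (no springs left) is
    recorded in the trace, not raised.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    state = solve_equilibrium(net, method=method, seed=seed, config=config)
    records: List[ProgressionRecord] = []
    terminated = False
    all_converged = state.converged

    def record(i: int, removed: int) -> None:
        ct = render_apparent_ct(net, state, lung_mask.shape,
                                smooth_sigma=config.render_smooth_sigma)
        laa = binarize_apparent(
            ct, lung_mask, reference_intensity,
            fraction=config.binarize_fraction,
        )
        stats = cluster_stats(laa, lung_mask, fit_range=config.fit_range)
        records.append(
            ProgressionRecord(
                iteration=i,
                pct_laa=stats.pct_laa,
                largest=stats.largest,
                second_largest=stats.second_largest,
                exponent=stats.exponent,
                energy=state.energy,
                springs_removed=removed,
                laa_mask=laa,
            )
        )

    record(0, 0)
    for i in range(1, n_iter + 1):
        try:
            net, removed = degrade_step(net, state, force_fraction)
        except ProgressionTerminated:
            terminated = True
            break
        state = solve_equilibrium(
            net, method=method, seed=seed + i, config=config,
            initial_positions=_carry_positions(net, state),
        )
        all_converged &= state.converged
        record(i, removed)
    return ProgressionTrace(
        records=records,
        force_fraction=force_fraction,
        n_iterations=n_iter,
        terminated_early=terminated,
        all_converged=all_converged,
    )


def _carry_positions(net: HexSpringNetwork, state: EquilibriumState):
    """Warm start: positions carry over (degrade_step preserves node set)."""
    if len(state.positions) == net.n_nodes:
        return state.positions
    return None


def largest_cluster_trajectory(
    trace: ProgressionTrace, jump_factor: float = 0.5
) -> Tuple[np.ndarray, List[int]]:
    """A_L per iteration plus flagged coalescence jumps.

    A jump is flagged at iteration i+1 when A_L grows by more than
    ``jump_factor`` times the second-largest cluster at iteration i —
    growth that cannot come from boundary erosion alone and signals two
    clusters merging.
    """
    sizes = trace.largest
    flags: List[int] = []
    for i in range(len(sizes) - 1):
        second = trace.records[i].second_largest
        if second > 0 and sizes[i + 1] > sizes[i] + jump_factor * second:
            flags.append(i + 1)
    return sizes, flags


def paired_local_difference(
    trace_a: ProgressionTrace,
    trace_b: ProgressionTrace,
    square_size: int = DEFAULT_CONFIG.dlocal_square_size,
    pairing: str = "iteration",
) -> pd.DataFrame:
    """D_local between two traces of the same slice, per iteration.

    ``pairing='iteration'`` compares same-numbered iterations;
    ``pairing='nearest_pct'`` compares each iteration of trace_a with the
    trace_b iteration of closest %LAA (matching severity rather than
    time, as when two mapping methods degrade at different rates).
    """
    rows = []
    pct_b = trace_b.pct_laa
    for i, rec in enumerate(trace_a.records):
        if pairing == "iteration":
            if i >= len(trace_b.records):
                break
            j = i
        elif pairing == "nearest_pct":
            j = int(np.argmin(np.abs(pct_b - rec.pct_laa)))
        else:
            raise ValueError(f"unknown pairing {pairing!r}")
        res = d_local(
            rec.laa_mask, trace_b.records[j].laa_mask, square_size=square_size
        )
        rows.append(
            {
                "iteration": rec.iteration,
                "paired_iteration": trace_b.records[j].iteration,
                "pct_laa_a": rec.pct_laa,
                "pct_laa_b": trace_b.records[j].pct_laa,
                "d_local": res.d_local,
                "n_squares": res.n_squares_used,
            }
        )
    return pd.DataFrame(rows)
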