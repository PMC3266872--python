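"""Stimulation-grid orchestration.

Stratifies excitatory neurons into disjoint subpopulations by an
embeddedness metric, applies the identical Poisson stimulus to each group in
turn, and quantifies the evoked network response (population PSTH peak and
network-wide spike count in a response window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import EmbeddednessProfile
from .netgen import EXC, DirectedNetwork
from .simlif import (LIFParams, SimulationError, SpikeData, make_stimulus,
                     simulate)


@dataclass
class SubpopulationPlan:
    """Disjoint excitatory node groups with strictly increasing mean metric."""

    groups: list[np.ndarray]
    stratifying_metric: str
    group_means: np.ndarray

    def __post_init__(self):
        flat = np.concatenate(self.groups) if self.groups else np.empty(0)
        if len(np.unique(flat)) != len(flat):
            raise ValueError("groups must be disjoint")
        if np.any(np.diff(self.group_means) <= 0):
            raise ValueError("group mean metric values must strictly increase")


@dataclass
class PSTH:
    bin_width: float
    window: tuple[float, float]
    counts: np.ndarray

    @property
    def bin_edges(self) -> np.ndarray:
        t0, t1 = self.window
        return np.arange(t0, t1 + 0.5 * self.bin_width, self.bin_width)


@dataclass
class ResponseRecord:
    network_id: int | str
    group_id: int
    mean_out_degree: float
    mean_k_shell_out: float
    psth_peak: float
    total_spikes: int
    baseline_spikes: float
    trial: int
    failed: bool = False

    def __post_init__(self):
        if not self.failed and self.psth_peak > self.total_spikes:
            raise ValueError("PSTH peak cannot exceed the total spike count")


def select_subpopulations(
    profile: EmbeddednessProfile,
    node_kinds: np.ndarray,
    metric: str = "out_degree",
    n_groups: int = 30,
    group_size: int = 250,
    seed: int = 0,
) -> SubpopulationPlan:
    """Partition excitatory nodes into ``n_groups`` disjoint blocks of
    ``group_size`` spanning the sorted metric range.

    Nodes are sorted by (metric, node id); block starts are equally spaced
    over the sorted order when there are more excitatory nodes than needed,
    which guarantees disjointness and strictly increasing group means for
    any non-degenerate metric.
    """
    exc = np.flatnonzero(np.asarray(node_kinds) == EXC)
    if n_groups * group_size > len(exc):
        raise ValueError(
            f"need {n_groups * group_size} excitatory nodes, have {len(exc)}")
    values = getattr(profile, metric)
    if values is None:
        raise ValueError(f"profile does not carry metric {metric!r}")
    values = np.asarray(values, dtype=float)[exc]
    if np.ptp(values) == 0:
        raise ValueError("cannot stratify: metric is constant over nodes")
    order = np.lexsort((exc, values))
    ranked = exc[order]
    ranked_values = values[order]
    if n_groups == 1:
        starts = [0]
    else:
        starts = np.round(
            np.linspace(0, len(exc) - group_size, n_groups)).astype(int)
    groups = [ranked[s:s + group_size] for s in starts]
    means = np.array([ranked_values[s:s + group_size].mean() for s in starts])
    return SubpopulationPlan(groups=groups, stratifying_metric=metric,
                             group_means=means)


def compute_psth(spikes: SpikeData, bin_width: float,
                 window: tuple[float, float]) -> PSTH:
    """Population-summed spike histogram; bins are left-closed right-open."""
    t0, t1 = window
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if t1 <= t0:
        raise ValueError("empty PSTH window")
    edges = np.arange(t0, t1 + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(spikes.times, bins=edges)
    return PSTH(bin_width=bin_width, window=(t0, t1), counts=counts)


def response_peak(psth: PSTH, baseline: float | None = None) -> float:
    """Maximum bin count of the PSTH, optionally baseline-subtracted."""
    peak = float(psth.counts.max()) if psth.counts.size else 0.0
    if baseline is not None:
        peak -= baseline
    return peak


@dataclass
class GridSpec:
    """Everything one stimulation run of the grid needs besides the network."""

    params: LIFParams = field(default_factory=LIFParams)
    metric: str = "out_degree"
    n_groups: int = 30
    group_size: int = 250
    stim_rate: float = 8000.0
    stim_weight: float = 0.1
    stim_duration: float = 30.0
    onset: float = 200.0
    response_window: float = 100.0
    psth_bin: float = 5.0
    t_stop: float = 300.0
    n_trials: int = 1


def run_group_trial(
    network: DirectedNetwork,
    group: np.ndarray,
    spec: GridSpec,
    background_rate: float,
    seed: int,
) -> tuple[SpikeData, PSTH, int]:
    """One stimulation simulation; returns spikes, response-window PSTH and
    the network-wide spike count in the response window."""
    stim = make_stimulus(group, onset=spec.onset, duration=spec.stim_duration,
                         rate=spec.stim_rate, weight=spec.stim_weight)
    spikes = simulate(network, spec.params, background_rate, stimulus=stim,
                      t_stop=spec.t_stop, seed=seed)
    window = (spec.onset, spec.onset + spec.response_window)
    psth = compute_psth(spikes, spec.psth_bin, window)
    total = spikes.count_in(*window)
    return spikes, psth, total


def run_experiment_grid(
    networks: dict,
    profiles: dict,
    backgrounds: dict,
    spec: GridSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full (network x group x trial) grid.

    ``networks`` maps network id -> DirectedNetwork, ``profiles`` the
    matching EmbeddednessProfile, ``backgrounds`` the calibrated background
    rate. The stimulus differs between runs only in its target set. Records
    are keyed by (network, group, trial) and the whole grid is deterministic
    under the master seed; a failing simulation yields a record marked
    ``failed`` and the grid continues.
    """
    rows = []
    for net_pos, net_id in enumerate(sorted(networks, key=str)):
        network = networks[net_id]
        profile = profiles[net_id]
        plan = select_subpopulations(
            profile, network.node_kind, metric=spec.metric,
            n_groups=spec.n_groups, group_size=spec.group_size)
        out_deg = np.asarray(profile.out_degree, dtype=float)
        kshell = np.asarray(profile.k_shell_out, dtype=float)
        baseline_rate = None
        for g_idx, group in enumerate(plan.groups):
            for trial in range(spec.n_trials):
                # common random numbers across groups: every group of a
                # network sees the same background realization, so response
                # differences are attributable to the target set alone
                child = np.random.SeedSequence(
                    seed, spawn_key=(net_pos, trial))
                run_seed = int(child.generate_state(1)[0] % (2**31))
                try:
                    _, psth, total = run_group_trial(
                        network, group, spec, backgrounds[net_id], run_seed)
                    if baseline_rate is None:
                        baseline_rate = _baseline_count(
                            network, spec, backgrounds[net_id], run_seed)
                    rows.append(ResponseRecord(
                        network_id=net_id, group_id=g_idx,
                        mean_out_degree=float(out_deg[group].mean()),
                        mean_k_shell_out=float(kshell[group].mean()),
                        psth_peak=response_peak(psth),
                        total_spikes=total,
                        baseline_spikes=baseline_rate,
                        trial=trial))
                except SimulationError:
                    rows.append(ResponseRecord(
                        network_id=net_id, group_id=g_idx,
                        mean_out_degree=float(out_deg[group].mean()),
                        mean_k_shell_out=float(kshell[group].mean()),
                        psth_peak=0.0, total_spikes=0, baseline_spikes=0.0,
                        trial=trial, failed=True))
    return pd.DataFrame([r.__dict__ for r in rows])


def _baseline_count(network, spec: GridSpec, background_rate, seed) -> float:
    """Expected network-wide spike count in the response window without any
    stimulus, from one unstimulated run with the same seed."""
    spikes = simulate(network, spec.params, background_rate, stimulus=None,
                      t_stop=spec.t_stop, seed=seed)
    return float(spikes.count_in(spec.onset, spec.onset + spec.response_window))
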