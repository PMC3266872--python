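"""Leaky integrate-and-fire network simulation with current-based synapses.

The model is the canonical sparse excitatory/inhibitory network with
homogeneous synaptic weights: every excitatory spike deposits a voltage jump
``j_exc`` on each of its targets after a fixed axonal delay, every inhibitory
spike deposits ``-g * j_exc``. Each neuron additionally receives an
independent external Poisson event stream (the background drive), and a
stimulus adds an extra Poisson stream to a chosen subpopulation during a
timed window. Between events the membrane decays exponentially toward rest;
crossing threshold emits a spike, resets the membrane and clamps it for an
absolute refractory period (inputs arriving while refractory are discarded).

Integration is exact-exponential per time step ``dt``; all event streams are
drawn on a fixed (step, neuron) lattice from dedicated seeded generators, so
results are deterministic given the master seed and independent of iteration
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netgen import INH, DirectedNetwork

__all__ = [
    "LIFParams",
    "StimulusProtocol",
    "SpikeData",
    "SimulationError",
    "make_stimulus",
    "simulate",
    "calibrate_background",
    "write_spikes",
    "read_spikes",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LIFParams:
    """Membrane and synapse constants (times in ms, potentials in mV).

    Defaults are the classical current-based regime: 20 ms membrane time
    constant, 20 mV threshold above rest, 2 ms refractoriness, 1.5 ms delay,
    0.1 mV excitatory jump and relative inhibition g = 5.
    """

    tau_m: float = 20.0
    v_rest: float = 0.0
    v_reset: float = 0.0
    v_th: float = 20.0
    t_ref: float = 2.0
    delay: float = 1.5
    j_exc: float = 0.1
    g: float = 5.0
    dt: float = 0.1

    def __post_init__(self):
        if min(self.tau_m, self.dt, self.delay, self.t_ref) <= 0:
            raise ValueError("tau_m, dt, delay and t_ref must be positive")
        if self.v_th <= self.v_reset:
            raise ValueError("v_th must exceed v_reset")
        if self.g < 0:
            raise ValueError("g must be non-negative")
        if self.delay < self.dt:
            raise ValueError("delay must be at least one time step")


@dataclass(frozen=True)
class StimulusProtocol:
    """Extra Poisson drive to ``targets`` during [onset, onset + duration)."""

    targets: tuple[int, ...]
    onset: float
    duration: float = 30.0
    rate: float = 8000.0  # events/s per target
    weight: float = 0.1  # mV per event

    def __post_init__(self):
        if not self.targets:
            raise ValueError("stimulus targets must be nonempty")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.rate < 0:
            raise ValueError("stimulus rate must be non-negative")
        object.__setattr__(self, "targets", tuple(int(t) for t in self.targets))


def make_stimulus(
    targets, onset: float, duration: float = 30.0,
    rate: float = 8000.0, weight: float = 0.1,
) -> StimulusProtocol:
    return StimulusProtocol(tuple(int(t) for t in targets), float(onset),
                            float(duration), float(rate), float(weight))


@dataclass
class SpikeData:
    """Time-sorted spike events of one simulation run."""

    times: np.ndarray  # ms
    ids: np.ndarray
    t_stop: float
    n_nodes: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must align")
        if self.times.size and (self.times.min() < 0
                                or self.times.max() > self.t_stop):
            raise ValueError("spike time outside [0, t_stop]")

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def spikes_of(self, node: int) -> np.ndarray:
        return self.times[self.ids == node]

    def count_in(self, t0: float, t1: float, nodes=None) -> int:
        """Number of spikes with t0 <= t < t1, optionally restricted."""
        mask = (self.times >= t0) & (self.times < t1)
        if nodes is not None:
            mask &= np.isin(self.ids, np.asarray(nodes))
        return int(mask.sum())

    def mean_rate(self, t0: float = 0.0, t1: float | None = None,
                  nodes=None) -> float:
        """Mean per-neuron firing rate in spikes/s over [t0, t1)."""
        t1 = self.t_stop if t1 is None else t1
        n = len(np.asarray(nodes)) if nodes is not None else self.n_nodes
        if n == 0 or t1 <= t0:
            return 0.0
        return self.count_in(t0, t1, nodes) / n / ((t1 - t0) / 1000.0)

    def min_isi(self) -> float:
        """Smallest inter-spike interval of any single neuron (inf if none)."""
        best = np.inf
        order = np.lexsort((self.times, self.ids))
        ids, times = self.ids[order], self.times[order]
        if len(ids) > 1:
            same = ids[1:] == ids[:-1]
            if same.any():
                best = float(np.min(np.diff(times)[same]))
        return best


def _poisson_counts(rng: np.random.Generator, lam: float, size: int):
    if lam <= 0:
        return None
    return rng.poisson(lam, size=size)


def simulate(
    network: DirectedNetwork,
    params: LIFParams,
    background_rate: float,
    stimulus: StimulusProtocol | list[StimulusProtocol] | None = None,
    t_stop: float = 1000.0,
    seed: int = 0,
    i_ext: float | np.ndarray = 0.0,
    v_init: str = "uniform",
) -> SpikeData:
    """Run the network for ``t_stop`` ms and return every spike.

    ``background_rate`` is the external Poisson event rate per neuron in
    events/s (weight ``j_exc``); ``i_ext`` is an optional constant drive in
    mV (the steady-state depolarization R*I it would cause). Background,
    stimulus and initial-condition randomness use separate child streams of
    ``seed``, so adding a stimulus never perturbs the background realization.
    """
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    if t_stop <= 0:
        raise ValueError("t_stop must be positive")
    n = network.n_nodes
    dt = params.dt
    n_steps = int(round(t_stop / dt))
    decay = np.exp(-dt / params.tau_m)
    delay_steps = max(1, int(round(params.delay / dt)))
    ref_steps = int(round(params.t_ref / dt))

    ss = np.random.SeedSequence(seed)
    ss_bg, ss_stim, ss_init = ss.spawn(3)
    rng_bg = np.random.default_rng(ss_bg)
    rng_stim = np.random.default_rng(ss_stim)
    rng_init = np.random.default_rng(ss_init)

    # outgoing adjacency, CSR by presynaptic node
    pre = network.edges[:, 0]
    out_counts = np.bincount(pre, minlength=n)
    out_indptr = np.concatenate([[0], np.cumsum(out_counts)])
    out_indices = network.edges[:, 1].astype(np.int64)  # already pre-sorted
    syn_weight = np.where(network.node_kind == INH,
                          -params.g * params.j_exc, params.j_exc)

    stimuli = ([] if stimulus is None
               else [stimulus] if isinstance(stimulus, StimulusProtocol)
               else list(stimulus))
    stim_specs = []
    for st in stimuli:
        targets = np.asarray(st.targets, dtype=np.int64)
        if targets.size and (targets.min() < 0 or targets.max() >= n):
            raise ValueError("stimulus target outside the network")
        s0 = int(round(st.onset / dt))
        s1 = int(round((st.onset + st.duration) / dt))
        stim_specs.append((s0, s1, targets, st.rate * dt * 1e-3, st.weight))

    lam_bg = background_rate * dt * 1e-3
    i_drive = np.broadcast_to(np.asarray(i_ext, dtype=float), (n,))
    v_target = params.v_rest + i_drive  # steady state of the free membrane

    if v_init == "uniform":
        v = rng_init.uniform(params.v_reset, params.v_th, size=n)
    elif v_init == "rest":
        v = np.full(n, params.v_rest, dtype=float)
    else:
        raise ValueError("v_init must be 'uniform' or 'rest'")
    refrac = np.zeros(n, dtype=np.int64)
    buf = np.zeros((delay_steps, n))
    v_bound = 50.0 * max(abs(params.v_th), abs(params.v_reset), 1.0)

    spike_steps: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []

    for step in range(n_steps):
        slot = step % delay_steps
        incoming = buf[slot].copy()
        buf[slot] = 0.0

        counts = _poisson_counts(rng_bg, lam_bg, n)
        if counts is not None:
            incoming += counts * params.j_exc
        for s0, s1, targets, lam, w in stim_specs:
            if s0 <= step < s1 and lam > 0:
                c = rng_stim.poisson(lam, size=len(targets))
                np.add.at(incoming, targets, c * w)

        # exact exponential relaxation toward v_rest + RI, then jumps
        v = v_target + (v - v_target) * decay + incoming
        in_ref = refrac > 0
        v[in_ref] = params.v_reset
        refrac[in_ref] -= 1

        fired = np.flatnonzero(~in_ref & (v >= params.v_th))
        if fired.size:
            v[fired] = params.v_reset
            refrac[fired] = ref_steps
            spike_steps.append(np.full(fired.size, step + 1, dtype=np.int64))
            spike_ids.append(fired)
            if out_indptr[-1]:
                tgt = np.concatenate(
                    [out_indices[out_indptr[f]:out_indptr[f + 1]]
                     for f in fired])
                wts = np.concatenate(
                    [np.full(out_counts[f], syn_weight[f]) for f in fired])
                np.add.at(buf[(step + delay_steps) % delay_steps], tgt, wts)

        if np.abs(v).max() > v_bound:
            raise SimulationError(
                f"membrane potential exceeded sanity bound {v_bound} mV "
                f"with params {params}")

    if spike_steps:
        steps_arr = np.concatenate(spike_steps)
        ids_arr = np.concatenate(spike_ids)
    else:
        steps_arr = np.empty(0, dtype=np.int64)
        ids_arr = np.empty(0, dtype=np.int64)
    times = steps_arr * dt
    order = np.lexsort((ids_arr, times))
    return SpikeData(
        times=times[order], ids=ids_arr[order], t_stop=t_stop, n_nodes=n,
        meta={"seed": int(seed), "background_rate": float(background_rate),
              "n_stimuli": len(stim_specs)},
    )


def theoretical_lif_rate(params: LIFParams, drive: float) -> float:
    """Closed-form firing rate (spikes/s) under constant suprathreshold
    drive ``R*I = drive`` mV:  1 / (t_ref + tau * ln((RI - v_reset + v_rest)
    / (RI - v_th + v_rest))).
    """
    num = drive - params.v_reset + params.v_rest
    den = drive - params.v_th + params.v_rest
    if den <= 0:
        return 0.0
    t_isi_ms = params.t_ref + params.tau_m * np.log(num / den)
    return 1000.0 / t_isi_ms


def calibrate_background(
    network: DirectedNetwork,
    params: LIFParams,
    target_rate: float = 5.0,
    band: tuple[float, float] = (2.0, 10.0),
    t_run: float = 600.0,
    t_discard: float = 200.0,
    n_iter: int = 12,
    rel_tol: float = 0.1,
    seed: int = 0,
) -> float:
    """Bisect the background event rate so the baseline population rate sits
    in the asynchronous-irregular band (spikes/s). Returns the rate found;
    raises SimulationError if the band cannot be bracketed.
    """
    nu_thr = params.v_th / (params.j_exc * params.tau_m) * 1000.0  # events/s
    lo, hi = 0.3 * nu_thr, 5.0 * nu_thr

    def rate_at(bg):
        sd = simulate(network, params, bg, t_stop=t_run, seed=seed)
        return sd.mean_rate(t_discard, t_run)

    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if r_hi < target_rate:
        if band[0] <= r_hi <= band[1]:
            return hi
        raise SimulationError("cannot reach target rate: network too quiet")
    if r_lo > target_rate:
        if band[0] <= r_lo <= band[1]:
            return lo
        raise SimulationError("baseline rate already above target at the "
                              "lowest background considered")
    best_bg, best_err = lo, abs(r_lo - target_rate)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        r_mid = rate_at(mid)
        if abs(r_mid - target_rate) < best_err:
            best_bg, best_err = mid, abs(r_mid - target_rate)
        if band[0] <= r_mid <= band[1] and abs(
                r_mid - target_rate) < rel_tol * target_rate:
            return mid
        if r_mid < target_rate:
            lo = mid
        else:
            hi = mid
    final = rate_at(best_bg)
    if not band[0] <= final <= band[1]:
        raise SimulationError(
            f"calibration failed: baseline rate {final:.2f} spikes/s outside "
            f"band {band}")
    return best_bg


def write_spikes(spikes: SpikeData, path) -> None:
    """Two-column whitespace text: time_ms neuron_id, time-sorted."""
    with open(path, "w") as fh:
        fh.write(f"# t_stop={spikes.t_stop} n_nodes={spikes.n_nodes}\n")
        for t, i in zip(spikes.times, spikes.ids):
            fh.write(f"{t:.3f} {i}\n")


def read_spikes(path) -> SpikeData:
    t_stop, n_nodes = None, None
    times, ids = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("t_stop="):
                        t_stop = float(tok[7:])
                    elif tok.startswith("n_nodes="):
                        n_nodes = int(tok[8:])
                continue
            t_str, i_str = line.split()
            times.append(float(t_str))
            ids.append(int(i_str))
    times = np.array(times)
    ids = np.array(ids, dtype=np.int64)
    if t_stop is None:
        t_stop = float(times.max()) if times.size else 0.0
    if n_nodes is None:
        n_nodes = int(ids.max()) + 1 if ids.size else 0
    return SpikeData(times=times, ids=ids, t_stop=t_stop, n_nodes=n_nodes)
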