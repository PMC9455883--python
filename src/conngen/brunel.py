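"""Balanced random network: fixed in-degree vs. fixed out-degree.

A sparse recurrent network of excitatory (E) and inhibitory (I) leaky
integrate-and-fire neurons with delta synapses, in the inhibition-dominated
asynchronous-irregular regime.  The demonstration builds the same network
under two readings of "randomly connected with C_E excitatory and C_I
inhibitory inputs":

- *fixed in-degree*: every neuron receives exactly C_E excitatory and C_I
  inhibitory connections (the classic formulation);
- *fixed out-degree*: every source sends a fixed number of connections,
  chosen so the total edge count matches the fixed in-degree variant
  exactly.

Both networks share the connection probability and the network-averaged
rate profile, but per-neuron rates are narrow under fixed in-degree and
broadly distributed under fixed out-degree — the in-degree a neuron happens
to receive sets its operating point.

Membrane dynamics between spikes is exact exponential decay with time
constant tau_m; an arriving spike after delay d jumps the membrane by the
connection weight (J for excitatory, -g*J for inhibitory); crossing theta
emits a spike and resets to V_reset with an absolute refractory period.
Each neuron receives an independent external Poisson drive of rate
eta * nu_thr * C_E with nu_thr = theta / (J * C_E * tau_m), delivered as
J-sized jumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Constraints, EdgeList, Population, Role, degree_counts, derive_rng
from .probabilistic import connect_fixed_indegree, connect_fixed_outdegree

__all__ = [
    "LifParams",
    "SpikeData",
    "BalancedNetwork",
    "build_balanced_network",
    "simulate_lif",
    "spike_statistics",
    "compare_variants",
    "run_demo",
]


@dataclass(frozen=True)
class LifParams:
    """LIF and network parameters (times in ms, potentials in mV).

    Defaults follow the widely used public reference implementation of the
    two-population balanced random network (g=5, eta=2 places the network
    in the asynchronous-irregular regime); all values are plain config
    entries, overridable per run.
    """

    n_e: int = 10_000
    n_i: int = 2_500
    epsilon: float = 0.1            # connection density: C = epsilon * N
    tau_m: float = 20.0             # membrane time constant
    theta: float = 20.0             # spike threshold
    v_reset: float = 0.0
    t_ref: float = 2.0              # absolute refractory period
    j: float = 0.1                  # excitatory efficacy (delta-synapse jump)
    g: float = 5.0                  # inhibition ratio, w_I = -g * J
    delay: float = 1.5
    eta: float = 2.0                # external rate in units of nu_thr

    def __post_init__(self) -> None:
        if min(self.tau_m, self.theta - self.v_reset, self.delay) <= 0:
            raise ValueError("tau_m, theta - V_reset, and delay must be > 0")
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must lie in (0, 1]")

    @property
    def c_e(self) -> int:
        return round(self.epsilon * self.n_e)

    @property
    def c_i(self) -> int:
        return round(self.epsilon * self.n_i)

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i

    @property
    def nu_thr(self) -> float:
        """Threshold rate (spikes/ms): constant drive at this rate just reaches theta."""
        return self.theta / (self.j * self.c_e * self.tau_m)

    @property
    def ext_rate(self) -> float:
        """External Poisson rate per neuron (spikes/ms)."""
        return self.eta * self.nu_thr * self.c_e

    def scaled(self, scale: float) -> "LifParams":
        """Network with neuron numbers scaled by ``scale`` (density kept)."""
        return replace(self, n_e=round(self.n_e * scale), n_i=round(self.n_i * scale))


@dataclass
class SpikeData:
    """Spike times in ms, sorted by time, with emitting neuron indices."""

    neurons: np.ndarray
    times: np.ndarray
    duration: float
    n_neurons: int

    def __post_init__(self) -> None:
        order = np.argsort(self.times, kind="stable")
        self.neurons = np.asarray(self.neurons, dtype=np.int64)[order]
        self.times = np.asarray(self.times, dtype=float)[order]

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class BalancedNetwork:
    """Populations, recurrent projections, and per-projection weights."""

    variant: str
    params: LifParams
    exc: Population
    inh: Population
    projections: list[tuple[EdgeList, float]] = field(default_factory=list)

    @property
    def n_syn_total(self) -> int:
        return sum(len(e) for e, _ in self.projections)

    def indegrees(self) -> np.ndarray:
        """Total recurrent in-degree per neuron (E then I)."""
        deg = np.zeros(self.params.n_total, dtype=np.int64)
        for edges, _ in self.projections:
            deg[edges.target_pop.offset:
                edges.target_pop.offset + edges.target_pop.size] += \
                degree_counts(edges, "in")
        return deg


def build_balanced_network(
    variant: str,
    params: LifParams,
    rng: np.random.Generator,
) -> BalancedNetwork:
    """Build the recurrent connectivity for one variant.

    ``fixed_in``: every target draws exactly C_E sources from E and C_I
    from I (autapses prohibited, multapses allowed).  ``fixed_out``: each
    source's out-degree per target population is fixed at the value that
    makes every projection's total match the fixed in-degree variant
    exactly (C_E * N_t / N_E for excitatory sources into a population of
    size N_t, analogously for inhibitory); non-integer cases are rejected
    with the sizes that would work.
    """
    if variant not in ("fixed_in", "fixed_out"):
        raise ValueError("variant must be 'fixed_in' or 'fixed_out'")
    exc = Population("E", params.n_e, offset=0, role=Role.excitatory)
    inh = Population("I", params.n_i, offset=params.n_e, role=Role.inhibitory)
    w_e, w_i = params.j, -params.g * params.j
    within = Constraints(allow_autapses=False, allow_multapses=True)

    net = BalancedNetwork(variant, params, exc, inh)
    plan = [(exc, exc, params.c_e, w_e), (exc, inh, params.c_e, w_e),
            (inh, exc, params.c_i, w_i), (inh, inh, params.c_i, w_i)]
    for src, tgt, c, w in plan:
        if variant == "fixed_in":
            edges = connect_fixed_indegree(src, tgt, c, within, rng)
        else:
            total = c * tgt.size
            if total % src.size:
                raise ValueError(
                    f"cannot fix out-degree for {src.name}->{tgt.name}: total "
                    f"{total} edges not divisible by N_s={src.size}; choose sizes "
                    f"with N_s dividing C*N_t (e.g. N_t a multiple of N_s/gcd)")
            edges = connect_fixed_outdegree(src, tgt, total // src.size, within, rng)
        net.projections.append((edges, w))
    return net


def simulate_lif(
    network: BalancedNetwork,
    duration: float,
    dt: float = 0.1,
    rng: np.random.Generator | None = None,
) -> SpikeData:
    """Simulate the network for ``duration`` ms on a grid of step ``dt``.

    Exact exponential decay between grid points; spikes are delivered on
    the grid after the transmission delay via a ring buffer, so ``dt`` must
    divide the delay.  Refractory neurons are clamped at V_reset and ignore
    input.  Same generator state gives bit-identical spike data.
    """
    p = network.params
    rng = np.random.default_rng() if rng is None else rng
    steps_delay = p.delay / dt
    if abs(steps_delay - round(steps_delay)) > 1e-9:
        raise ValueError(f"dt={dt} must divide the delay {p.delay} "
                         "(ring-buffer delay handling)")
    d_steps = round(steps_delay)
    n_steps = round(duration / dt)
    n = p.n_total

    # per-source flattened adjacency (targets sorted by source)
    srcs = [e.sources for e, _ in network.projections] or [np.empty(0, np.int64)]
    all_src = np.concatenate(srcs)
    all_tgt = np.concatenate([e.targets for e, _ in network.projections]
                             or [np.empty(0, np.int64)])
    all_w = np.concatenate([np.full(len(e), w) for e, w in network.projections]
                           or [np.empty(0)])
    order = np.argsort(all_src, kind="stable")
    all_tgt, all_w = all_tgt[order], all_w[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, all_src[order] + 1, 1)
    indptr = np.cumsum(indptr)

    decay = np.exp(-dt / p.tau_m)
    lam_ext = p.ext_rate * dt
    ref_steps = max(1, round(p.t_ref / dt))

    v = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)
    ring = np.zeros((d_steps, n))
    spike_neurons: list[np.ndarray] = []
    spike_steps: list[np.ndarray] = []

    for t in range(n_steps):
        slot = t % d_steps
        inp = ring[slot] + p.j * rng.poisson(lam_ext, size=n)
        ring[slot] = 0.0
        active = refr == 0
        v[active] = v[active] * decay + inp[active]
        refr[~active] -= 1
        fired = np.nonzero(v >= p.theta)[0]
        if fired.size:
            v[fired] = p.v_reset
            refr[fired] = ref_steps
            spike_neurons.append(fired)
            spike_steps.append(np.full(fired.size, t))
            dest = ring[(t + d_steps) % d_steps]
            idx = np.concatenate([np.arange(indptr[s], indptr[s + 1])
                                  for s in fired])
            np.add.at(dest, all_tgt[idx], all_w[idx])
    if spike_neurons:
        neurons = np.concatenate(spike_neurons)
        times = (np.concatenate(spike_steps) + 1) * dt
    else:
        neurons = np.empty(0, dtype=np.int64)
        times = np.empty(0)
    return SpikeData(neurons, times, duration=duration, n_neurons=n)


def spike_statistics(
    spikes: SpikeData,
    time_bin: float = 5.0,
    rate_bin: float = 2.0,
) -> dict:
    """Time-resolved rate, per-neuron rates, and the per-neuron rate histogram.

    ``time_bin`` is the width (ms) of the spike-count histogram across time;
    the time-resolved rate is count / (bin width * number of neurons), in
    spikes/s.  Per-neuron rates are count / duration (spikes/s) and their
    distribution is binned at ``rate_bin`` (1/s) and normalized to unit mass.
    """
    if spikes.duration <= 0:
        raise ValueError("duration must be > 0")
    n_bins = max(1, round(spikes.duration / time_bin))
    t_edges = np.linspace(0.0, n_bins * time_bin, n_bins + 1)
    counts, _ = np.histogram(spikes.times, bins=t_edges)
    rate_t = counts / (time_bin * 1e-3) / spikes.n_neurons

    per_neuron = np.bincount(spikes.neurons, minlength=spikes.n_neurons)
    rates = per_neuron / (spikes.duration * 1e-3)

    top = max(rates.max(), rate_bin) if rates.size else rate_bin
    r_edges = np.arange(0.0, top + 2 * rate_bin, rate_bin)
    hist, _ = np.histogram(rates, bins=r_edges, density=True)
    return {
        "time_edges": t_edges, "rate_vs_time": rate_t,
        "per_neuron_rates": rates,
        "rate_hist_edges": r_edges, "rate_hist_density": hist,
        "mean_rate": float(rates.mean()), "sd_rate": float(rates.std(ddof=0)),
        "iqr_rate": float(np.subtract(*np.percentile(rates, [75, 25]))),
    }


def compare_variants(stats_in: dict, stats_out: dict) -> dict:
    """Contrast per-neuron rate statistics of the two variants."""
    mean_in, mean_out = stats_in["mean_rate"], stats_out["mean_rate"]
    sd_in, sd_out = stats_in["sd_rate"], stats_out["sd_rate"]

    def ratio(a: float, b: float) -> float:
        if b:
            return a / b
        return 1.0 if a == b else float("inf")

    return {
        "mean_rate_fixed_in": mean_in, "mean_rate_fixed_out": mean_out,
        "sd_fixed_in": sd_in, "sd_fixed_out": sd_out,
        "iqr_fixed_in": stats_in["iqr_rate"], "iqr_fixed_out": stats_out["iqr_rate"],
        "mean_ratio": ratio(mean_out, mean_in),
        "sd_ratio": ratio(sd_out, sd_in),
    }


def run_demo(
    variant: str,
    scale: float = 0.2,
    duration: float = 1000.0,
    seed: int = 1,
    dt: float = 0.1,
    params: LifParams | None = None,
) -> tuple[BalancedNetwork, SpikeData, dict]:
    """Build, simulate, and summarize one variant at the given scale."""
    p = (params or LifParams()).scaled(scale)
    rng_build = derive_rng(seed, stream=0)
    rng_sim = derive_rng(seed, stream=1)
    net = build_balanced_network(variant, p, rng_build)
    spikes = simulate_lif(net, duration=duration, dt=dt, rng=rng_sim)
    return net, spikes, spike_statistics(spikes)
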