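"""Ground-truth spiking networks: LIF simulation and regime calibration.

The benchmark network is a randomly connected (Erdos-Renyi) population of
leaky integrate-and-fire neurons, split into excitatory and inhibitory
cells, driven by (i) an external spiking input population that mimics the
slow, bursty comodulation of cultured networks and (ii) per-neuron white
noise current. Varying the noise configuration (mu_noise, sigma_noise)
moves the network through dynamical regimes that are summarised by three
statistics: population burst rate, mean per-neuron firing rate, and the
coefficient of variation of the population rate.

Membrane dynamics (forward Euler, 0.1 ms step)::

    tau_m dV/dt = -(V - V_rest) + R * (I_syn + I_input + mu_noise) + noise

with threshold crossing emitting a spike, reset to ``V_reset`` and an
absolute refractory period. Synaptic currents are delayed exponentials.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter1d

from .spike_trains import SpikeTrainSet

__all__ = [
    "GroundTruthNetwork",
    "LifParams",
    "NoiseConfig",
    "ExternalInputSpec",
    "RegimeStats",
    "CalibrationError",
    "build_random_network",
    "generate_external_input",
    "simulate_lif",
    "summarize_regime",
    "calibrate_noise",
    "split_subnetworks",
    "load_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("low", "intermediate", "high", "poisson_8020")


class CalibrationError(RuntimeError):
    """Raised when noise calibration cannot reach the target regime."""

    def __init__(self, msg, best_config=None, best_stats=None):
        super().__init__(msg)
        self.best_config = best_config
        self.best_stats = best_stats


@dataclass
class LifParams:
    """Single-neuron and synapse constants (standard cortical-culture values).

    All time constants in ms, voltages in mV, resistance in MOhm; synaptic
    weights are peak currents in nA, drawn log-normal with coefficient of
    variation ``weight_cv``; inhibitory synapses are ``weight_scale_inh``
    (4x the excitatory scale by default, reflecting the stronger unitary
    IPSCs needed for balance at a 50:50 E/I ratio).
    """

    tau_m_ms: float = 20.0
    v_rest_mV: float = -65.0
    v_thresh_mV: float = -50.0
    v_reset_mV: float = -65.0
    refractory_ms: float = 2.0
    syn_delay_ms: float = 1.5
    tau_syn_ms: float = 2.0
    resistance_MOhm: float = 100.0
    weight_scale_exc: float = 0.25
    weight_scale_inh: float = 1.0
    weight_cv: float = 1.0

    def __post_init__(self):
        if not self.v_reset_mV < self.v_thresh_mV:
            raise ValueError("v_reset must be below v_thresh")
        for name in ("tau_m_ms", "tau_syn_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class NoiseConfig:
    """Mean input current and white-noise SD, both in nA."""

    mu_noise: float
    sigma_noise: float

    def __post_init__(self):
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")


@dataclass
class ExternalInputSpec:
    """External spiking drive to the LIF network.

    ``poisson`` mode produces homogeneous Poisson input units; ``bursty``
    mode produces doubly-stochastic Poisson units whose common rate is a
    baseline plus boxcar bursts occurring at ``burst_rate_hz`` (a synthetic
    stand-in for an empirical culture recording); ``file`` mode passes a
    user-supplied SpikeTrainSet through unchanged. Input units contact each
    LIF neuron independently with probability ``p_input_conn``.
    """

    mode: str = "bursty"
    n_input_units: int = 30
    rate_hz: float = 2.0
    burst_rate_hz: float = 1.0
    burst_width_ms: float = 120.0
    burst_amplitude_hz: float = 60.0
    burst_min_gap_ms: float = 500.0
    p_input_conn: float = 0.1
    input_weight_scale: float = 0.15
    file_sts: SpikeTrainSet | None = None

    def __post_init__(self):
        if self.mode not in ("poisson", "bursty", "file"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if not 0 <= self.p_input_conn <= 1:
            raise ValueError("p_input_conn must be in [0, 1]")


@dataclass
class RegimeStats:
    """Summary of a recording's dynamical regime."""

    burst_rate_hz: float
    mean_rate_hz: float
    cv: float
    cv_isi: float = float("nan")


@dataclass
class GroundTruthNetwork:
    """Signed weighted adjacency with E/I labels; ``adjacency[i, j]`` is the
    synaptic weight of the connection i -> j (0 = no synapse)."""

    n_neurons: int
    adjacency: np.ndarray
    ei_labels: np.ndarray
    p_conn: float

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.ei_labels = np.asarray(self.ei_labels, dtype=object)
        n = self.n_neurons
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-connections are not allowed")
        exc = self.ei_labels == "E"
        if np.any(self.adjacency[exc] < 0):
            raise ValueError("excitatory rows must be non-negative")
        if np.any(self.adjacency[~exc] > 0):
            raise ValueError("inhibitory rows must be non-positive")

    @property
    def binary(self) -> np.ndarray:
        return self.adjacency != 0

    @property
    def n_connections(self) -> int:
        return int(np.count_nonzero(self.adjacency))

    def restrict(self, idx) -> "GroundTruthNetwork":
        idx = np.asarray(idx, dtype=int)
        return GroundTruthNetwork(
            n_neurons=len(idx),
            adjacency=self.adjacency[np.ix_(idx, idx)],
            ei_labels=self.ei_labels[idx],
            p_conn=self.p_conn,
        )


def build_random_network(n: int, frac_exc: float, p_conn: float,
                         lif: LifParams | None = None,
                         seed: int = 0) -> GroundTruthNetwork:
    """Erdos-Renyi directed network with log-normal |weights|.

    The first ``round(frac_exc * n)`` neurons are excitatory; the sign of
    each synapse follows its presynaptic label.
    """
    if n < 2:
        raise ValueError("need at least 2 neurons")
    if not (0 <= frac_exc <= 1 and 0 <= p_conn <= 1):
        raise ValueError("frac_exc and p_conn must be in [0, 1]")
    lif = lif or LifParams()
    rng = np.random.default_rng(seed)
    n_exc = int(round(frac_exc * n))
    ei = np.array(["E"] * n_exc + ["I"] * (n - n_exc), dtype=object)
    present = rng.random((n, n)) < p_conn
    np.fill_diagonal(present, False)

    def lognormal(mean, cv, size):
        s2 = np.log1p(cv ** 2)
        mu = np.log(mean) - s2 / 2.0
        return rng.lognormal(mu, np.sqrt(s2), size=size)

    mags = np.zeros((n, n))
    mags[present] = 1.0
    scale = np.where(ei == "E", lif.weight_scale_exc, lif.weight_scale_inh)
    mags *= lognormal(1.0, lif.weight_cv, (n, n))
    mags *= scale[:, None]
    sign = np.where(ei == "E", 1.0, -1.0)
    adj = np.where(present, mags * sign[:, None], 0.0)
    return GroundTruthNetwork(n_neurons=n, adjacency=adj, ei_labels=ei,
                              p_conn=p_conn)


# ---------------------------------------------------------------------------
# external input
# ---------------------------------------------------------------------------

def generate_external_input(spec: ExternalInputSpec, duration_s: float,
                            seed: int, n_targets: int | None = None):
    """Generate the external input spike trains and the input->LIF weights.

    Returns ``(SpikeTrainSet, weights)`` where ``weights`` has shape
    ``(n_input_units, n_targets)``; an entry of 0 means no contact.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    if spec.mode == "file":
        if spec.file_sts is None:
            raise ValueError("file mode requires file_sts")
        sts = spec.file_sts
        n_in = sts.n_units
    elif spec.mode == "poisson":
        trains = []
        for _ in range(spec.n_input_units):
            n = rng.poisson(spec.rate_hz * duration_s)
            trains.append(np.sort(rng.uniform(0, duration_s, size=n)))
        sts = SpikeTrainSet.from_unsorted(
            [f"in{k}" for k in range(spec.n_input_units)], trains, duration_s)
        n_in = spec.n_input_units
    else:  # bursty: common doubly-stochastic rate
        # population bursts as a renewal process with a refractory gap, so
        # that the realized rate of distinguishable bursts matches the spec
        gap = spec.burst_min_gap_ms / 1000.0
        mean_iv = 1.0 / max(spec.burst_rate_hz, 1e-9)
        if mean_iv <= gap:
            raise ValueError("burst_rate_hz too high for burst_min_gap_ms")
        n_draw = int(duration_s * spec.burst_rate_hz * 2) + 20
        ivals = gap + rng.exponential(mean_iv - gap, size=n_draw)
        burst_t = np.cumsum(ivals)
        burst_t = burst_t[burst_t < duration_s]
        width = spec.burst_width_ms / 1000.0
        trains = []
        for _ in range(spec.n_input_units):
            # baseline + per-burst inhomogeneous spikes
            nb = rng.poisson(spec.rate_hz * duration_s)
            t = rng.uniform(0, duration_s, size=nb)
            extra = []
            for tb in burst_t:
                ne = rng.poisson(spec.burst_amplitude_hz * width)
                extra.append(tb + rng.uniform(0, width, size=ne))
            t = np.concatenate([t] + extra) if extra else t
            t = t[t < duration_s]
            trains.append(t)
        sts = SpikeTrainSet.from_unsorted(
            [f"in{k}" for k in range(spec.n_input_units)], trains, duration_s)
        sts = SpikeTrainSet(sts.unit_ids, sts.spikes, duration_s)
        n_in = spec.n_input_units
    if n_targets is None:
        raise ValueError("n_targets required to draw input connectivity")
    contacts = rng.random((n_in, n_targets)) < spec.p_input_conn
    s2 = np.log1p(0.25)
    w = rng.lognormal(np.log(spec.input_weight_scale) - s2 / 2, np.sqrt(s2),
                      size=(n_in, n_targets))
    weights = np.where(contacts, w, 0.0)
    return sts, weights


# ---------------------------------------------------------------------------
# LIF integration core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lif_core(n, steps, dt_ms, tau_m, v_rest, v_thresh, v_reset,
              ref_steps, delay_steps, syn_decay, r_mohm,
              mu_noise, sigma_noise,
              rec_indptr, rec_indices, rec_weights,
              ev_step, ev_target, ev_weight,
              out_unit, out_step, seed):
    np.random.seed(seed)
    v = np.full(n, v_rest)
    i_syn = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)
    ring_len = delay_steps + 1
    ring = np.zeros((ring_len, n))
    n_out = 0
    cap = out_unit.shape[0]
    ev_ptr = 0
    n_ev = ev_step.shape[0]
    dt_over_tau = dt_ms / tau_m
    noise_scale = r_mohm * sigma_noise * np.sqrt(dt_ms / tau_m)
    for t in range(steps):
        cur = t % ring_len
        # synaptic state: exponential decay plus impulses due this step
        for k in range(n):
            i_syn[k] = i_syn[k] * syn_decay + ring[cur, k]
            ring[cur, k] = 0.0
        while ev_ptr < n_ev and ev_step[ev_ptr] == t:
            i_syn[ev_target[ev_ptr]] += ev_weight[ev_ptr]
            ev_ptr += 1
        for k in range(n):
            if refr[k] > 0:
                refr[k] -= 1
                v[k] = v_reset
                continue
            dv = dt_over_tau * (-(v[k] - v_rest)
                                + r_mohm * (i_syn[k] + mu_noise))
            v[k] += dv + noise_scale * np.random.standard_normal()
            if not np.isfinite(v[k]):
                return -t - 1  # numerical failure, report step
            if v[k] >= v_thresh:
                if n_out >= cap:
                    return -steps - 1  # spike buffer overflow
                out_unit[n_out] = k
                out_step[n_out] = t
                n_out += 1
                v[k] = v_reset
                refr[k] = ref_steps
                slot = (t + delay_steps) % ring_len
                for p in range(rec_indptr[k], rec_indptr[k + 1]):
                    ring[slot, rec_indices[p]] += rec_weights[p]
    return n_out


def simulate_lif(net: GroundTruthNetwork, external, noise: NoiseConfig,
                 duration_s: float, seed: int, lif: LifParams | None = None,
                 dt_ms: float = 0.1, max_rate_hz: float = 200.0
                 ) -> SpikeTrainSet:
    """Simulate the LIF network; returns the recorded spike trains.

    Parameters
    ----------
    external
        Either ``None`` (no external drive) or a tuple
        ``(SpikeTrainSet, weights)`` as returned by
        :func:`generate_external_input`.
    noise
        Per-neuron white-noise configuration (nA).
    dt_ms
        Forward-Euler step; spike times are resolved at this step.
    max_rate_hz
        Sizing bound for the pre-allocated spike buffer.
    """
    lif = lif or LifParams()
    n = net.n_neurons
    steps = int(round(duration_s * 1000.0 / dt_ms))
    delay_steps = max(1, int(round(lif.syn_delay_ms / dt_ms)))
    ref_steps = int(round(lif.refractory_ms / dt_ms))
    syn_decay = float(np.exp(-dt_ms / lif.tau_syn_ms))

    # recurrent adjacency as CSR over presynaptic rows
    adj = net.adjacency
    rec_indptr = np.zeros(n + 1, dtype=np.int64)
    idx_list = []
    w_list = []
    for i in range(n):
        nz = np.flatnonzero(adj[i])
        idx_list.append(nz)
        w_list.append(adj[i, nz])
        rec_indptr[i + 1] = rec_indptr[i] + nz.size
    rec_indices = (np.concatenate(idx_list) if idx_list else
                   np.empty(0, dtype=np.int64)).astype(np.int64)
    rec_weights = (np.concatenate(w_list) if w_list else
                   np.empty(0)).astype(np.float64)

    # external input events: (step, target, weight) sorted by step
    if external is not None:
        in_sts, in_w = external
        ev_steps = []
        ev_tgt = []
        ev_wt = []
        for u in range(in_sts.n_units):
            tgts = np.flatnonzero(in_w[u])
            if tgts.size == 0:
                continue
            st = np.round(in_sts.spikes[u] * 1000.0 / dt_ms).astype(np.int64)
            st = st[st < steps] + delay_steps  # same conduction delay
            for tg in tgts:
                ev_steps.append(st)
                ev_tgt.append(np.full(st.size, tg, dtype=np.int64))
                ev_wt.append(np.full(st.size, in_w[u, tg]))
        if ev_steps:
            ev_step = np.concatenate(ev_steps)
            ev_target = np.concatenate(ev_tgt)
            ev_weight = np.concatenate(ev_wt)
            order = np.argsort(ev_step, kind="stable")
            ev_step, ev_target, ev_weight = (ev_step[order],
                                             ev_target[order],
                                             ev_weight[order])
        else:
            ev_step = np.empty(0, dtype=np.int64)
            ev_target = np.empty(0, dtype=np.int64)
            ev_weight = np.empty(0)
    else:
        ev_step = np.empty(0, dtype=np.int64)
        ev_target = np.empty(0, dtype=np.int64)
        ev_weight = np.empty(0)

    cap = int(n * duration_s * max_rate_hz) + 1000
    out_unit = np.empty(cap, dtype=np.int64)
    out_step = np.empty(cap, dtype=np.int64)
    rc = _lif_core(n, steps, dt_ms, lif.tau_m_ms, lif.v_rest_mV,
                   lif.v_thresh_mV, lif.v_reset_mV, ref_steps, delay_steps,
                   syn_decay, lif.resistance_MOhm, noise.mu_noise,
                   noise.sigma_noise, rec_indptr, rec_indices, rec_weights,
                   ev_step, ev_target, ev_weight, out_unit, out_step,
                   int(seed) % (2 ** 31))
    if rc == -steps - 1:
        raise RuntimeError(
            f"spike buffer overflow: rate exceeded {max_rate_hz} Hz")
    if rc < 0:
        raise FloatingPointError(
            f"non-finite membrane state at step {-rc - 1}")
    n_out = int(rc)
    trains = [np.empty(0)] * n
    units = out_unit[:n_out]
    t_s = out_step[:n_out] * (dt_ms / 1000.0)
    order = np.argsort(units, kind="stable")
    units, t_s = units[order], t_s[order]
    bounds = np.searchsorted(units, np.arange(n + 1))
    for k in range(n):
        trains[k] = t_s[bounds[k]:bounds[k + 1]].copy()
    return SpikeTrainSet([f"n{k}" for k in range(n)], trains, duration_s,
                         ei_labels=net.ei_labels.copy())


# ---------------------------------------------------------------------------
# regime statistics and calibration
# ---------------------------------------------------------------------------

def summarize_regime(sts: SpikeTrainSet) -> RegimeStats:
    """Burst rate, mean firing rate and population-rate CV of a recording.

    Bursts are detected on the 10 ms-binned, 50 ms-Gaussian-smoothed
    population rate as excursions above ``baseline + 4 * SD`` of the rate's
    lower half (values below the median), merging excursions separated by
    gaps shorter than 100 ms. ``cv`` is SD/mean of the 1 s-binned population
    rate; ``cv_isi`` additionally reports the mean per-unit inter-spike
    interval CV, since burstiness of cultures is often quoted that way.
    """
    if sts.n_units == 0:
        raise ValueError("empty recording")
    total = sts.total_spikes
    if total == 0:
        warnings.warn("recording has zero spikes; all-zero regime stats")
        return RegimeStats(0.0, 0.0, 0.0, 0.0)
    mean_rate = total / (sts.n_units * sts.duration_s)

    # population rate at 10 ms resolution, in Hz per neuron
    bw = 0.010
    n_bins = max(1, int(np.floor(sts.duration_s / bw)))
    allt = np.concatenate([t for t in sts.spikes if t.size])
    counts = np.bincount(np.minimum((allt / bw).astype(int), n_bins - 1),
                         minlength=n_bins)
    rate = counts / (bw * sts.n_units)
    smooth = gaussian_filter1d(rate.astype(float), sigma=5.0)  # 50 ms

    baseline = np.median(smooth)
    lower = smooth[smooth <= baseline]
    # robust noise scale: RMS deviation of the lower half from the baseline
    sd_lower = (np.sqrt(np.mean((lower - baseline) ** 2))
                if lower.size else 0.0)
    thresh = baseline + 4.0 * sd_lower
    above = smooth > thresh
    if sd_lower == 0:
        above = np.zeros_like(above)
    runs = []
    in_run = False
    for k, a in enumerate(above):
        if a and not in_run:
            s = k
            in_run = True
        elif not a and in_run:
            runs.append((s, k))
            in_run = False
    if in_run:
        runs.append((s, len(above)))
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < 10:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    burst_rate = len(merged) / sts.duration_s

    # population-rate CV on 1 s bins
    nb1 = max(1, int(np.floor(sts.duration_s)))
    c1 = np.bincount(np.minimum(allt.astype(int), nb1 - 1), minlength=nb1)
    cv = float(c1.std() / c1.mean()) if c1.mean() > 0 else 0.0

    isi_cvs = []
    for t in sts.spikes:
        if t.size >= 3:
            isi = np.diff(t)
            if isi.mean() > 0:
                isi_cvs.append(isi.std() / isi.mean())
    cv_isi = float(np.mean(isi_cvs)) if isi_cvs else float("nan")
    return RegimeStats(float(burst_rate), float(mean_rate), cv, cv_isi)


def calibrate_noise(target: RegimeStats, net: GroundTruthNetwork,
                    input_spec: ExternalInputSpec, tolerance: float = 0.15,
                    seed: int = 0, probe_duration_s: float = 120.0,
                    initial: NoiseConfig | None = None,
                    sigma_grid=(0.05, 0.1, 0.15),
                    max_probes: int = 24):
    """Search (mu_noise, sigma_noise) until probe simulations match a target.

    Mean firing rate is matched by bisection on ``mu_noise`` (rate is
    monotone in the mean drive); the burst rate is checked against the
    target and, if off, the search moves to the next ``sigma_noise`` value.
    The population-rate CV is reported but not matched, because the short
    probe simulations do not constrain it tightly. Returns
    ``(NoiseConfig, achieved RegimeStats)``.
    """
    if target.mean_rate_hz <= 0 or target.mean_rate_hz > 1000:
        raise CalibrationError(
            f"infeasible target mean rate {target.mean_rate_hz} Hz")

    probes = 0
    best = None  # (err, config, stats)

    def probe(mu, sig, k):
        nonlocal probes, best
        probes += 1
        ext = generate_external_input(input_spec, probe_duration_s,
                                      seed=seed + 7919, n_targets=net.n_neurons)
        sts = simulate_lif(net, ext, NoiseConfig(mu, sig), probe_duration_s,
                           seed=seed + 104729 + k)
        st = summarize_regime(sts)
        rel_rate = abs(st.mean_rate_hz - target.mean_rate_hz) / target.mean_rate_hz
        if target.burst_rate_hz > 0:
            rel_burst = abs(st.burst_rate_hz - target.burst_rate_hz) / target.burst_rate_hz
        else:
            rel_burst = 0.0 if st.burst_rate_hz <= 0.1 else 1.0
        err = max(rel_rate, rel_burst)
        cfg = NoiseConfig(mu, sig)
        if best is None or err < best[0]:
            best = (err, cfg, st)
        return st, rel_rate, rel_burst

    sigmas = list(sigma_grid)
    if initial is not None:
        sigmas = [initial.sigma_noise] + [s for s in sigmas
                                          if s != initial.sigma_noise]
    for sig in sigmas:
        mu_lo, mu_hi = -0.1, 0.4
        mu = initial.mu_noise if initial is not None else 0.1
        mu = min(max(mu, mu_lo), mu_hi)
        for it in range(7):
            if probes >= max_probes:
                break
            st, rel_rate, rel_burst = probe(mu, sig, probes)
            if rel_rate < tolerance and rel_burst < tolerance:
                return NoiseConfig(mu, sig), st
            if st.mean_rate_hz < target.mean_rate_hz:
                mu_lo = mu
            else:
                mu_hi = mu
            if mu_hi - mu_lo < 1e-4:
                break
            mu = 0.5 * (mu_lo + mu_hi)
        initial = None  # warm start only applies to the first sigma
        if probes >= max_probes:
            break
    assert best is not None
    raise CalibrationError(
        f"calibration failed after {probes} probes; best error "
        f"{best[0]:.2f} at {best[1]}", best_config=best[1],
        best_stats=best[2])


def split_subnetworks(sts: SpikeTrainSet, net: GroundTruthNetwork,
                      k: int, size: int, balanced: bool = True,
                      seed: int = 0):
    """Partition units into k disjoint subsets of a given size.

    Returns a list of ``(SpikeTrainSet, GroundTruthNetwork)`` restrictions;
    connections leaving a subset become unobserved. With ``balanced`` the
    subsets carry equal numbers of E and I neurons.
    """
    from .spike_trains import subsample_units
    n = net.n_neurons
    if k * size > n:
        raise ValueError("k * size exceeds the number of neurons")
    rng = np.random.default_rng(seed)
    if balanced:
        if size % 2:
            raise ValueError("balanced split requires even subset size")
        exc = np.flatnonzero(net.ei_labels == "E")
        inh = np.flatnonzero(net.ei_labels == "I")
        if len(exc) < k * size // 2 or len(inh) < k * size // 2:
            raise ValueError("not enough E or I neurons for balanced split")
        exc = rng.permutation(exc)
        inh = rng.permutation(inh)
        subsets = [np.sort(np.concatenate([
            exc[j * size // 2:(j + 1) * size // 2],
            inh[j * size // 2:(j + 1) * size // 2]])) for j in range(k)]
    else:
        perm = rng.permutation(n)
        subsets = [np.sort(perm[j * size:(j + 1) * size]) for j in range(k)]
    out = []
    for idx in subsets:
        ids = [sts.unit_ids[i] for i in idx]
        out.append((subsample_units(sts, ids), net.restrict(idx)))
    return out


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def load_preset(name: str) -> dict:
    """Load a shipped regime preset (calibration target + network recipe)."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = (resources.files("spikeconn") / "presets" / f"{name}.json"
            ).read_text()
    return json.loads(text)


def preset_components(preset: dict):
    """Materialize (target, ExternalInputSpec, network kwargs, initial noise)
    from a preset dictionary."""
    target = RegimeStats(**preset["target"])
    spec = ExternalInputSpec(**preset["input"])
    initial = (NoiseConfig(**preset["initial_noise"])
               if preset.get("initial_noise") else None)
    return target, spec, preset["network"], initial
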