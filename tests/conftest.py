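"""Shared fixtures: programmatically generated spike-train data.

The planted-network fixture builds spike trains with known excitatory and
inhibitory couplings directly (independent Poisson background, spike
insertion at a fixed synaptic lag for excitation, spike deletion after
presynaptic spikes for inhibition), so tests can check inference against a
construction that is independent of the LIF simulator.
"""

import numpy as np
import pytest

from spikeconn import SpikeTrainSet


def make_poisson_set(n_units, rate_hz, duration_s, seed=0, **kw):
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_units):
        n = rng.poisson(rate_hz * duration_s)
        trains.append(np.sort(rng.uniform(0, duration_s, size=n)))
    return SpikeTrainSet.from_unsorted(
        [f"u{k}" for k in range(n_units)], trains, duration_s, **kw)


def make_planted_network(n_units=20, rate_hz=1.5, duration_s=600.0,
                         n_exc_edges=10, n_inh_edges=5,
                         transmission=0.25, inh_deletion=0.6,
                         lag_ms=2.0, seed=0):
    """Spike trains with planted monosynaptic structure.

    Excitatory edge i->j: each i-spike inserts a j-spike at lag ~2 ms with
    probability ``transmission``. Inhibitory edge i->j: j-spikes within
    (0, 5] ms of an i-spike are deleted with probability ``inh_deletion``.
    Returns (SpikeTrainSet, adjacency) where adjacency holds +1/-1.
    """
    rng = np.random.default_rng(seed)
    base = []
    for _ in range(n_units):
        n = rng.poisson(rate_hz * duration_s)
        base.append(np.sort(rng.uniform(0, duration_s, size=n)))
    adj = np.zeros((n_units, n_units))
    pairs = [(i, j) for i in range(n_units) for j in range(n_units)
             if i != j]
    rng.shuffle(pairs)
    chosen = pairs[:n_exc_edges + n_inh_edges]
    exc_edges = chosen[:n_exc_edges]
    inh_edges = chosen[n_exc_edges:]
    trains = [t.copy() for t in base]
    for (i, j) in exc_edges:
        adj[i, j] = 1.0
        src = base[i]
        fire = src[rng.random(src.size) < transmission]
        extra = fire + (lag_ms + rng.normal(0, 0.3, fire.size)) / 1000.0
        extra = extra[(extra > 0) & (extra < duration_s)]
        trains[j] = np.concatenate([trains[j], extra])
    for (i, j) in inh_edges:
        adj[i, j] = -1.0
    sts_pre = [np.unique(t) for t in trains]
    # apply inhibition after insertion so I edges also act on inserted spikes
    for (i, j) in inh_edges:
        src = sts_pre[i]
        tgt = sts_pre[j]
        lo = np.searchsorted(tgt, src)
        hi = np.searchsorted(tgt, src + 0.005)
        kill = set()
        for a, b in zip(lo, hi):
            for k in range(a, b):
                if rng.random() < inh_deletion:
                    kill.add(k)
        keep = np.setdiff1d(np.arange(tgt.size), np.array(sorted(kill),
                                                          dtype=int))
        sts_pre[j] = tgt[keep]
    sts = SpikeTrainSet.from_unsorted(
        [f"u{k}" for k in range(n_units)], sts_pre, duration_s)
    return sts, adj


@pytest.fixture(scope="session")
def poisson_pair():
    return make_poisson_set(2, 2.0, 200.0, seed=3)


@pytest.fixture(scope="session")
def planted_fixture():
    """20-unit planted network used across method sanity tests."""
    return make_planted_network(seed=11)
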