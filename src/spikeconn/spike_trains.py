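"""Core spike-train and inference-result containers, binning and surrogates.

Conventions used throughout the package
---------------------------------------
* Spike times are stored in **seconds** as float64; every window, lag or bin
  parameter in the public API is expressed in **milliseconds** and converted
  at the boundary.
* Directed quantities are stored with **row = presynaptic** unit ``i`` and
  **column = postsynaptic** unit ``j``: entry ``[i, j]`` refers to the
  putative connection ``i -> j``.
* Diagonals of score/weight matrices are undefined and stored as NaN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrainSet",
    "BinnedSpikeMatrix",
    "InferenceResult",
    "ValidationError",
    "FormatError",
    "load_spike_trains",
    "save_spike_trains",
    "bin_spikes",
    "jitter_surrogate",
    "subsample_units",
    "clip_scores",
    "METHOD_NAMES",
]

METHOD_NAMES = ("CI", "sCCG", "dSTTC", "GLMCC", "TE", "GLMPP", "eANN")


class ValidationError(ValueError):
    """Raised when spike-train data violates a container invariant."""


class FormatError(ValueError):
    """Raised when an on-disk file is structurally invalid."""


@dataclass
class SpikeTrainSet:
    """A set of per-unit spike trains with a common recording duration.

    Parameters
    ----------
    unit_ids
        Ordered sequence of opaque unit labels (converted to ``str``).
    spikes
        One sorted float64 array of spike times (seconds) per unit, aligned
        with ``unit_ids``.
    duration_s
        Total recording duration in seconds; every spike lies in
        ``[0, duration_s)``.
    positions_um
        Optional ``(n_units, 2)`` array of (x, y) positions in micrometers.
    ei_labels
        Optional per-unit labels in ``{"E", "I", "unknown"}``.
    """

    unit_ids: list
    spikes: list
    duration_s: float
    positions_um: np.ndarray | None = None
    ei_labels: np.ndarray | None = None

    def __post_init__(self):
        self.unit_ids = [str(u) for u in self.unit_ids]
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValidationError("duplicate unit ids")
        self.duration_s = float(self.duration_s)
        if not self.duration_s > 0:
            raise ValidationError("duration_s must be > 0")
        if len(self.spikes) != len(self.unit_ids):
            raise ValidationError("spikes and unit_ids length mismatch")
        clean = []
        for uid, t in zip(self.unit_ids, self.spikes):
            t = np.asarray(t, dtype=np.float64)
            if t.ndim != 1:
                raise ValidationError(f"unit {uid}: spike times must be 1-D")
            if t.size:
                if np.any(~np.isfinite(t)):
                    raise ValidationError(f"unit {uid}: non-finite spike time")
                if t[0] < 0:
                    raise ValidationError(
                        f"unit {uid}: negative spike time {t[0]!r}")
                if t[-1] >= self.duration_s:
                    raise ValidationError(
                        f"unit {uid}: spike time {t[-1]!r} >= duration "
                        f"{self.duration_s!r}")
                if np.any(np.diff(t) <= 0):
                    k = int(np.argmax(np.diff(t) <= 0))
                    raise ValidationError(
                        f"unit {uid}: spike times not strictly increasing "
                        f"at index {k}")
            clean.append(t)
        self.spikes = clean
        if self.positions_um is not None:
            self.positions_um = np.asarray(self.positions_um, dtype=np.float64)
            if self.positions_um.shape != (self.n_units, 2):
                raise ValidationError("positions_um must be (n_units, 2)")
        if self.ei_labels is not None:
            self.ei_labels = np.asarray(self.ei_labels, dtype=object)
            if self.ei_labels.shape != (self.n_units,):
                raise ValidationError("ei_labels must cover every unit")
            bad = set(self.ei_labels) - {"E", "I", "unknown"}
            if bad:
                raise ValidationError(f"invalid ei labels: {sorted(bad)}")

    # -- convenience ------------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.spikes))

    def spike_counts(self) -> np.ndarray:
        return np.array([t.size for t in self.spikes], dtype=np.int64)

    def rates_hz(self) -> np.ndarray:
        return self.spike_counts() / self.duration_s

    def unit_index(self, unit_id) -> int:
        try:
            return self.unit_ids.index(str(unit_id))
        except ValueError:
            raise KeyError(f"unknown unit id {unit_id!r}") from None

    def truncate(self, duration_s: float) -> "SpikeTrainSet":
        """Restrict the recording to its first ``duration_s`` seconds."""
        if not 0 < duration_s <= self.duration_s:
            raise ValueError("truncation must be in (0, duration_s]")
        spikes = [t[t < duration_s] for t in self.spikes]
        return SpikeTrainSet(list(self.unit_ids), spikes, duration_s,
                             positions_um=self.positions_um,
                             ei_labels=self.ei_labels)

    @classmethod
    def from_unsorted(cls, unit_ids, spikes, duration_s, **kw):
        """Build a set from unsorted, possibly duplicated spike times."""
        clean = [np.unique(np.asarray(t, dtype=np.float64)) for t in spikes]
        return cls(list(unit_ids), clean, duration_s, **kw)


@dataclass
class BinnedSpikeMatrix:
    """Units x bins spike-count matrix at a fixed bin width."""

    bin_width_ms: float
    counts: np.ndarray  # (n_units, n_bins) non-negative integers
    unit_ids: list

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class InferenceResult:
    """One method's score graph S and weight graph W over all ordered pairs.

    ``S[i, j]`` is the detection-confidence score and ``W[i, j]`` the signed
    coupling-strength estimate for the putative connection ``i -> j``; both
    diagonals are NaN.
    """

    method: str
    S: np.ndarray
    W: np.ndarray
    unit_ids: list
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.method!r}")
        n = len(self.unit_ids)
        self.S = np.asarray(self.S, dtype=np.float64)
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.S.shape != (n, n) or self.W.shape != (n, n):
            raise ValueError("S/W shape must match unit count")
        np.fill_diagonal(self.S, np.nan)
        np.fill_diagonal(self.W, np.nan)

    def offdiag_mask(self) -> np.ndarray:
        n = len(self.unit_ids)
        return ~np.eye(n, dtype=bool)

    def save(self, path):
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("S", data=self.S)
            f.create_dataset("W", data=self.W)
            f.create_dataset(
                "unit_ids",
                data=np.array([str(u) for u in self.unit_ids], dtype="S"))
            f.attrs["method"] = self.method
            f.attrs["params"] = json.dumps(self.params, default=str)

    @classmethod
    def load(cls, path) -> "InferenceResult":
        with h5py.File(path, "r") as f:
            return cls(
                method=str(f.attrs["method"]),
                S=f["S"][()],
                W=f["W"][()],
                unit_ids=[u.decode() for u in f["unit_ids"][()]],
                params=json.loads(f.attrs.get("params", "{}")),
            )

    def save_csv(self, path_prefix):
        """Write S and W as CSVs (unit order in the index/header) plus a
        JSON sidecar with method and params."""
        prefix = Path(path_prefix)
        ids = [str(u) for u in self.unit_ids]
        for name, mat in (("S", self.S), ("W", self.W)):
            pd.DataFrame(mat, index=ids, columns=ids).to_csv(
                prefix.with_suffix(f".{name}.csv"))
        prefix.with_suffix(".meta.json").write_text(
            json.dumps(dict(method=self.method, params=self.params),
                       default=str))

    @classmethod
    def load_csv(cls, path_prefix) -> "InferenceResult":
        prefix = Path(path_prefix)
        meta = json.loads(prefix.with_suffix(".meta.json").read_text())
        S = pd.read_csv(prefix.with_suffix(".S.csv"), index_col=0)
        W = pd.read_csv(prefix.with_suffix(".W.csv"), index_col=0)
        return cls(method=meta["method"], S=S.to_numpy(), W=W.to_numpy(),
                   unit_ids=[str(c) for c in S.columns],
                   params=meta.get("params", {}))


def clip_scores(S: np.ndarray, lo_q: float = 0.001, hi_q: float = 0.999
                ) -> np.ndarray:
    """Clip a score matrix into its finite [lo_q, hi_q] quantile range.

    -log(p) style scores can overflow to inf; downstream consumers (and the
    ensemble classifier in particular) need finite inputs. Off-diagonal
    non-finite entries are mapped to the corresponding finite quantile bound
    (+inf and NaN-from-overflow to the upper bound is unsafe, so NaN maps to
    the lower bound: absence of evidence); the diagonal stays NaN.
    """
    S = np.asarray(S, dtype=np.float64).copy()
    n = S.shape[0]
    np.fill_diagonal(S, np.nan)
    off = ~np.eye(n, dtype=bool)
    vals = S[off]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        S[off] = 0.0
        return S
    lo, hi = np.quantile(finite, [lo_q, hi_q])
    vals = np.where(np.isposinf(vals), hi, vals)
    vals = np.where(np.isneginf(vals), lo, vals)
    vals = np.where(np.isnan(vals), lo, vals)
    S[off] = np.clip(vals, lo, hi)
    return S


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def bin_spikes(sts: SpikeTrainSet, bin_width_ms: float) -> BinnedSpikeMatrix:
    """Bin each unit's spikes into counts; bin k covers [k*D, (k+1)*D)."""
    if not bin_width_ms > 0:
        raise ValueError("bin_width_ms must be > 0")
    width_s = bin_width_ms / 1000.0
    n_bins = int(np.floor(sts.duration_s * 1000.0 / bin_width_ms))
    counts = np.zeros((sts.n_units, n_bins), dtype=np.int64)
    span = n_bins * width_s
    for k, t in enumerate(sts.spikes):
        t = t[t < span]
        if t.size:
            idx = np.floor(t / width_s).astype(np.int64)
            np.add.at(counts[k], idx, 1)
    return BinnedSpikeMatrix(bin_width_ms=float(bin_width_ms), counts=counts,
                             unit_ids=list(sts.unit_ids))


def jitter_surrogate(sts: SpikeTrainSet, half_width_ms: float,
                     seed: int) -> SpikeTrainSet:
    """Displace every spike independently by Uniform(-h, +h).

    Displaced times are reflected at the recording boundaries so that local
    rates near the edges are preserved; per-unit spike counts are conserved
    and each train is re-sorted. Millisecond-scale synaptic structure is
    destroyed while slow comodulation survives, which is what makes these
    surrogates a null model for short-latency coupling.
    """
    if half_width_ms < 0:
        raise ValueError("half_width_ms must be >= 0")
    if half_width_ms == 0:
        return SpikeTrainSet(list(sts.unit_ids),
                             [t.copy() for t in sts.spikes], sts.duration_s,
                             positions_um=sts.positions_um,
                             ei_labels=sts.ei_labels)
    rng = np.random.default_rng(seed)
    h = half_width_ms / 1000.0
    dur = sts.duration_s
    out = []
    for t in sts.spikes:
        tt = t + rng.uniform(-h, h, size=t.size)
        # reflect at [0, dur): fold into [0, 2*dur) then mirror
        tt = np.mod(tt, 2.0 * dur)
        tt = np.where(tt >= dur, 2.0 * dur - tt, tt)
        tt = np.clip(tt, 0.0, np.nextafter(dur, 0.0))
        tt.sort()
        # strict monotonicity: break exact ties by an ulp-scale nudge
        dup = np.flatnonzero(np.diff(tt) <= 0)
        for k in dup:
            tt[k + 1] = np.nextafter(tt[k], np.inf)
        out.append(tt)
    return SpikeTrainSet(list(sts.unit_ids), out, dur,
                         positions_um=sts.positions_um,
                         ei_labels=sts.ei_labels)


def subsample_units(sts: SpikeTrainSet, unit_subset) -> SpikeTrainSet:
    """Restrict a recording to a subset of units; duration is unchanged."""
    unit_subset = [str(u) for u in unit_subset]
    idx = [sts.unit_index(u) for u in unit_subset]
    pos = sts.positions_um[idx] if sts.positions_um is not None else None
    ei = sts.ei_labels[idx] if sts.ei_labels is not None else None
    if len(idx) == 0:
        # empty subset allowed: still a valid (unit-less) recording
        return SpikeTrainSet([], [], sts.duration_s)
    return SpikeTrainSet(unit_subset, [sts.spikes[k].copy() for k in idx],
                         sts.duration_s, positions_um=pos, ei_labels=ei)


# ---------------------------------------------------------------------------
# file round-tripping
# ---------------------------------------------------------------------------

def save_spike_trains(sts: SpikeTrainSet, path, format: str = "csv") -> None:
    """Write a SpikeTrainSet to disk (csv + JSON sidecar, or hdf5)."""
    path = Path(path)
    if format == "csv":
        rows = []
        for uid, t in zip(sts.unit_ids, sts.spikes):
            for x in t:
                rows.append((uid, x))
        df = pd.DataFrame(rows, columns=["unit_id", "time_s"])
        df.to_csv(path, index=False)
        sidecar = {"duration_s": sts.duration_s,
                   "unit_ids": list(sts.unit_ids)}
        if sts.positions_um is not None:
            sidecar["positions_um"] = sts.positions_um.tolist()
        if sts.ei_labels is not None:
            sidecar["ei_labels"] = list(sts.ei_labels)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar))
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["duration_s"] = sts.duration_s
            g = f.create_group("spikes")
            f.create_dataset(
                "unit_order",
                data=np.array([str(u) for u in sts.unit_ids], dtype="S"))
            for uid, t in zip(sts.unit_ids, sts.spikes):
                g.create_dataset(uid, data=t)
            if sts.positions_um is not None:
                f.create_dataset("positions_um", data=sts.positions_um)
            if sts.ei_labels is not None:
                f.create_dataset(
                    "ei_labels",
                    data=np.array([str(x) for x in sts.ei_labels], dtype="S"))
    else:
        raise ValueError(f"unknown format {format!r}")


def load_spike_trains(path, format: str = "csv") -> SpikeTrainSet:
    """Read a SpikeTrainSet written by :func:`save_spike_trains`.

    The csv dialect is two columns ``(unit_id, time_s)`` plus a header, with
    duration (and optional positions / E-I labels) in a ``<path>.json``
    sidecar. Validation errors name the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise FormatError(f"missing duration sidecar {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        if "duration_s" not in sidecar:
            raise FormatError("sidecar lacks duration_s")
        duration = float(sidecar["duration_s"])
        df = pd.read_csv(path, dtype={"unit_id": str})
        if list(df.columns) != ["unit_id", "time_s"]:
            raise FormatError(
                f"expected columns (unit_id, time_s), got {list(df.columns)}")
        bad = df.index[(df["time_s"] < 0) | (df["time_s"] >= duration)]
        if len(bad):
            r = int(bad[0])
            raise ValidationError(
                f"row {r}: time {df['time_s'].iloc[r]} outside "
                f"[0, {duration})")
        unit_ids = sidecar.get("unit_ids")
        if unit_ids is None:
            unit_ids = sorted(df["unit_id"].unique())
        unit_ids = [str(u) for u in unit_ids]
        groups = {uid: g["time_s"].to_numpy() for uid, g in
                  df.groupby("unit_id", sort=False)}
        spikes = [np.sort(groups.get(u, np.empty(0))) for u in unit_ids]
        pos = sidecar.get("positions_um")
        ei = sidecar.get("ei_labels")
        return SpikeTrainSet(unit_ids, spikes, duration,
                             positions_um=np.asarray(pos) if pos else None,
                             ei_labels=np.asarray(ei, dtype=object)
                             if ei else None)
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            if "duration_s" not in f.attrs:
                raise FormatError("hdf5 file lacks duration_s attribute")
            duration = float(f.attrs["duration_s"])
            unit_ids = [u.decode() for u in f["unit_order"][()]]
            spikes = [f["spikes"][u][()] for u in unit_ids]
            pos = f["positions_um"][()] if "positions_um" in f else None
            ei = (np.array([x.decode() for x in f["ei_labels"][()]],
                           dtype=object) if "ei_labels" in f else None)
        return SpikeTrainSet(unit_ids, spikes, duration, positions_um=pos,
                             ei_labels=ei)
    else:
        raise ValueError(f"unknown format {format!r}")
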