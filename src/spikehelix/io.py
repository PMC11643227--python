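"""CSV readers/writers, run configuration, and logging helpers.

File dialects
-------------
* Spike CSV: columns ``trial_id, neuron_id, time_s``, one row per spike,
  header required.  Arbitrary neuron labels are mapped to contiguous 1..N
  (sorted label order) and the mapping is returned/emitted.  Spikes outside
  the analysis window are dropped with a logged count.
* Fingerprint CSV: columns ``k, real, imag, magnitude, phase`` (round-trips
  through real/imag, lossless to float precision).
* Paths CSV: columns ``trial_id, step, x, y``.
* Labels CSV: columns ``trial_id, condition``.

Every run-level output can carry a config hash so that re-running with the
same configuration and seed reproduces deterministic outputs bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import SpikeFileError
from .geometry import SpikePattern
from .preprocess import Path2D
from .transform import Fingerprint

__all__ = [
    "RunConfig",
    "read_spike_csv",
    "write_spike_csv",
    "write_fingerprint_csv",
    "read_fingerprint_csv",
    "read_paths_csv",
    "write_paths_csv",
    "read_labels_csv",
]

log = logging.getLogger("spikehelix")

SPIKE_COLUMNS = ["trial_id", "neuron_id", "time_s"]


@dataclass(frozen=True)
class RunConfig:
    """Bag of run-level knobs; hashable for provenance stamping."""

    window: float = 1.0
    window_start: float = 0.0
    phase_offset: float = 0.0
    n_null: int = 1000
    n_boot: int = 1000
    embedding_dim: int = 2
    eigen_ordering: str = "modulus"
    cluster_method: str = "spectral"
    k_clusters: int = 3
    decoder: str = "nearest_centroid"
    k_folds: int = 10
    atol: float = 1e-10
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_json(self) -> str:
        d = asdict(self)
        d["config_hash"] = self.hash()
        return json.dumps(d, sort_keys=True, indent=2)


def _read_csv(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SpikeFileError(f"{path}: empty file") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SpikeFileError(f"{path}: missing columns {missing}")
    return df


def read_spike_csv(
    path,
    window: float,
    window_start: float = 0.0,
    n_neurons: int | None = None,
    half_open: bool = False,
):
    """Read per-trial spike patterns from a spike CSV.

    Times are shifted by ``window_start`` and spikes outside ``[0, T]``
    (or ``[0, T)`` with ``half_open``) are dropped with a logged count.
    Neuron labels are mapped to contiguous 1..N in sorted order; pass
    ``n_neurons`` to fix the population size when some neurons may be silent
    (then integer labels 1..n_neurons are used verbatim).

    Returns ``(patterns, neuron_map, n_dropped)`` where ``patterns`` maps
    trial_id to :class:`SpikePattern` and ``neuron_map`` maps the original
    neuron label to its 1-based ID.
    """
    df = _read_csv(path, SPIKE_COLUMNS)
    if len(df) and not pd.api.types.is_numeric_dtype(df["time_s"]):
        raise SpikeFileError(f"{path}: non-numeric spike times")
    times = df["time_s"].to_numpy(dtype=float) - window_start
    upper_ok = times < window if half_open else times <= window
    keep = (times >= 0.0) & upper_ok
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropped %d spike(s) outside window [0, %s]", n_dropped, window)
    df = df.loc[keep].assign(time_s=times[keep])
    if n_neurons is None:
        labels = sorted(pd.unique(df["neuron_id"]))
        neuron_map = {lab: i + 1 for i, lab in enumerate(labels)}
        n = max(len(labels), 1)
    else:
        n = int(n_neurons)
        neuron_map = {i: i for i in range(1, n + 1)}
    patterns = {}
    for trial_id, grp in df.groupby("trial_id", sort=True):
        ids = np.asarray([neuron_map[v] for v in grp["neuron_id"]], dtype=np.int64)
        patterns[trial_id] = SpikePattern(
            grp["time_s"].to_numpy(), ids, window, n
        )
    return patterns, neuron_map, n_dropped


def write_spike_csv(patterns: dict, path) -> None:
    """Write per-trial spike patterns in the spike CSV dialect."""
    rows = []
    for trial_id, p in patterns.items():
        rows.append(
            pd.DataFrame(
                {
                    "trial_id": trial_id,
                    "neuron_id": p.neuron_ids,
                    "time_s": p.times,
                }
            )
        )
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=SPIKE_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_fingerprint_csv(fp: Fingerprint, path, trial_id=None) -> None:
    df = fp.to_frame()
    if trial_id is not None:
        df.insert(0, "trial_id", trial_id)
    df.to_csv(path, index=False, float_format="%.17g")


def read_fingerprint_csv(path, window: float = 1.0, n_spikes: int = -1) -> Fingerprint:
    df = _read_csv(path, ["k", "real", "imag"])
    df = df.sort_values("k")
    mu = df["real"].to_numpy() + 1j * df["imag"].to_numpy()
    return Fingerprint(mu, n_neurons=len(df), n_spikes=n_spikes, window=window)


def read_paths_csv(path) -> dict:
    """Read per-trial 2-D paths; returns trial_id -> :class:`Path2D`."""
    df = _read_csv(path, ["trial_id", "step", "x", "y"])
    out = {}
    for trial_id, grp in df.groupby("trial_id", sort=True):
        grp = grp.sort_values("step")
        out[trial_id] = Path2D(grp[["x", "y"]].to_numpy(dtype=float))
    return out


def write_paths_csv(paths: dict, path) -> None:
    rows = []
    for trial_id, p in paths.items():
        v = p.vertices
        rows.append(
            pd.DataFrame(
                {"trial_id": trial_id, "step": np.arange(len(v)), "x": v[:, 0], "y": v[:, 1]}
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_labels_csv(path) -> dict:
    df = _read_csv(path, ["trial_id", "condition"])
    return dict(zip(df["trial_id"], df["condition"]))
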