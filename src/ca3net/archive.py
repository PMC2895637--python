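"""Run archives: self-describing directories of delimited text.

Layout::

    <dir>/
      meta.yaml             # config echo + seed + snapshot times
      raster.csv            # time_ms,neuron_id (header always present)
      delays.csv            # neuron_id,delay_ms
      conn.csv              # dense 0/1 matrix, row = presynaptic neuron
      weights_initial.csv   # dense float matrices, row = presynaptic neuron
      weights_final.csv
      weights_snap_XX.csv   # one per stored snapshot

Weights are written with 17 significant digits, so a round trip reproduces
them bit-for-bit and an archive can be re-analysed (or used to seed recall)
without the generating process.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .protocols import SimResult

__all__ = ["write_archive", "read_archive"]


def _write_matrix(path: Path, m: np.ndarray) -> None:
    np.savetxt(path, m, delimiter=",", fmt="%.17g")


def _read_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def write_archive(result: SimResult, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": result.config,
        "seed": int(result.seed),
        "snapshot_times": [int(t) for t in result.snapshot_times],
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    result.spikes.to_csv(d / "raster.csv", index=False)
    pd.DataFrame(
        {"neuron_id": np.arange(len(result.delays)), "delay_ms": result.delays}
    ).to_csv(d / "delays.csv", index=False)
    _write_matrix(d / "conn.csv", result.conn.astype(int))
    _write_matrix(d / "weights_initial.csv", result.w_initial)
    _write_matrix(d / "weights_final.csv", result.w_final)
    for k in range(result.snapshots.shape[0]):
        _write_matrix(d / f"weights_snap_{k:02d}.csv", result.snapshots[k])
    return d


def read_archive(directory: str | Path) -> SimResult:
    d = Path(directory)
    required = ["meta.yaml", "raster.csv", "delays.csv", "conn.csv",
                "weights_initial.csv", "weights_final.csv"]
    missing = [f for f in required if not (d / f).exists()]
    if missing:
        raise FileNotFoundError(f"partial archive {d}: missing {missing}")
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    spikes = pd.read_csv(d / "raster.csv", dtype={"time_ms": np.int64,
                                                  "neuron_id": np.int64})
    delays = pd.read_csv(d / "delays.csv")["delay_ms"].to_numpy(np.int64)
    conn = _read_matrix(d / "conn.csv").astype(bool)
    w_initial = _read_matrix(d / "weights_initial.csv")
    w_final = _read_matrix(d / "weights_final.csv")
    snap_times = np.array(meta.get("snapshot_times", []), dtype=np.int64)
    snaps = []
    for k in range(len(snap_times)):
        p = d / f"weights_snap_{k:02d}.csv"
        if p.exists():
            snaps.append(_read_matrix(p))
    snapshots = (
        np.stack(snaps) if snaps else np.zeros((0, *w_final.shape))
    )
    return SimResult(
        spikes=spikes, w_initial=w_initial, w_final=w_final,
        snapshots=snapshots,
        snapshot_times=snap_times[: len(snaps)] if snaps else snap_times,
        delays=delays, conn=conn, config=meta["config"], seed=meta["seed"],
    )
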