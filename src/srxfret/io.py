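"""Plain-text readers and writers for the pipeline's record types.

Transients are stored as CSV (``time_s,signal``) with a JSON sidecar
carrying the condition metadata; decays as ``channel_ns,counts``; EM
tallies as one row per preparation.  Everything round-trips through
pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import LifetimeDecay, Transient
from .em import EmTally

__all__ = [
    "write_transient_csv",
    "read_transient_csv",
    "write_decay_csv",
    "read_decay_csv",
    "write_tallies_csv",
    "read_tallies_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_transient_csv(tr: Transient, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": tr.time, "signal": tr.signal}).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps(tr.meta, sort_keys=True, default=str))
    return path


def read_transient_csv(path: str | Path) -> Transient:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    return Transient(
        time=df["time_s"].to_numpy(), signal=df["signal"].to_numpy(), meta=meta
    )


def write_decay_csv(decay: LifetimeDecay, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"channel_ns": decay.t_ns, "counts": decay.counts}).to_csv(
        path, index=False
    )
    _sidecar(path).write_text(json.dumps(decay.meta, sort_keys=True, default=str))
    return path


def read_decay_csv(path: str | Path) -> LifetimeDecay:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    counts = df["counts"].to_numpy(dtype=float)
    return LifetimeDecay(
        t_ns=df["channel_ns"].to_numpy(dtype=float),
        counts=counts,
        meta=meta,
        low_counts=counts.sum() < 1000,
    )


def write_tallies_csv(tallies: Sequence[EmTally], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"prep": t.prep, "closed": t.closed, "open": t.open, "unclear": t.unclear,
         **{k: v for k, v in t.meta.items() if np.isscalar(v)}}
        for t in tallies
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_tallies_csv(path: str | Path) -> list[EmTally]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        extra = {
            k: row[k] for k in df.columns if k not in {"prep", "closed", "open", "unclear"}
        }
        out.append(
            EmTally(
                prep=row["prep"],
                closed=int(row["closed"]),
                open=int(row["open"]),
                unclear=int(row.get("unclear", 0)),
                meta=extra,
            )
        )
    return out
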