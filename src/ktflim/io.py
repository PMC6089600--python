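"""Plain-text I/O for decay histograms, IRFs, tracks and fit reports.

Decay histograms and IRFs travel as CSV (bin_index, count|weight) with a JSON
sidecar of metadata (fine bin width, ADC ratio, seed, ground truth); movies
as multi-page TIFF plus CSV truth tables; curves and tables as CSV; fits as
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .flim import IRF, DecayHistogram

__all__ = [
    "write_irf",
    "read_irf",
    "write_histogram",
    "read_histogram",
    "write_json",
    "read_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_irf(path: str | Path, irf: IRF, meta: dict | None = None) -> None:
    path = Path(path)
    pd.DataFrame({"bin_index": np.arange(irf.n_fine), "weight": irf.weights}).to_csv(
        path, index=False
    )
    write_json(_sidecar(path), {"bin_width_ns": irf.bin_width,
                                "shift_support": list(irf.shift_support),
                                **(meta or {})})


def read_irf(path: str | Path) -> IRF:
    path = Path(path)
    df = pd.read_csv(path)
    meta = read_json(_sidecar(path))
    return IRF(weights=df["weight"].to_numpy(float),
               bin_width=float(meta["bin_width_ns"]),
               shift_support=tuple(meta.get("shift_support", (-10, 10))))


def write_histogram(
    path: str | Path, hist: DecayHistogram, irf_path: str | Path, meta: dict | None = None
) -> None:
    path = Path(path)
    pd.DataFrame({"bin_index": np.arange(hist.n_bins), "count": hist.counts}).to_csv(
        path, index=False
    )
    write_json(_sidecar(path), {"adc_ratio": hist.adc_ratio,
                                "fine_bin_width_ns": hist.irf.bin_width,
                                "irf": str(irf_path), **(meta or {})})


def read_histogram(path: str | Path, irf: IRF | None = None) -> DecayHistogram:
    path = Path(path)
    df = pd.read_csv(path)
    meta = read_json(_sidecar(path))
    if irf is None:
        irf_path = Path(meta["irf"])
        if not irf_path.is_absolute():
            irf_path = path.parent / irf_path
        irf = read_irf(irf_path)
    return DecayHistogram(counts=df["count"].to_numpy(), adc_ratio=int(meta["adc_ratio"]),
                          irf=irf)


def write_json(path: str | Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
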