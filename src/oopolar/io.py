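"""File-format plumbing: TIFF images, anchor CSVs, config YAML, result CSVs."""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import InvalidInputError
from .membrane_geometry import AnchorPoints, DomainPartition, MembraneTrace, \
    TracingConfig
from .quantification import QuantConfig


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-plane TIFF (or a stack) as float."""
    return tifffile.imread(str(path)).astype(float)


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image).astype(np.float32))


def read_anchors(path: str | Path) -> AnchorPoints:
    """Anchor CSV with header ``label,row,col`` and rows a1, a2, p."""
    df = pd.read_csv(path)
    required = {"label", "row", "col"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"anchor file needs columns {sorted(required)}")
    by_label = {str(r.label): (int(r.row), int(r.col))
                for r in df.itertuples()}
    missing = {"a1", "a2", "p"} - set(by_label)
    if missing:
        raise InvalidInputError(f"anchor file missing rows {sorted(missing)}")
    return AnchorPoints(a1=by_label["a1"], a2=by_label["a2"], p=by_label["p"])


def write_anchors(path: str | Path, anchors: AnchorPoints) -> None:
    rows = [(k, r, c) for k, (r, c) in anchors.as_dict().items()]
    pd.DataFrame(rows, columns=["label", "row", "col"]).to_csv(path,
                                                               index=False)


def write_trace(path: str | Path, trace: MembraneTrace) -> None:
    pd.DataFrame(trace.points, columns=["row", "col"]).to_csv(path,
                                                              index=False)


def write_partition(path: str | Path, partition: DomainPartition) -> None:
    rows = []
    px = partition.trace.pixel_size
    for label, (start, stop) in partition.segments.items():
        length = partition.lengths[label]
        rows.append((label, start, stop, length, length * px))
    pd.DataFrame(rows, columns=["domain", "start_index", "end_index",
                                "length_px", "length_um"]).to_csv(path,
                                                                  index=False)


def load_config(path: str | Path | None) -> QuantConfig:
    """Build a :class:`QuantConfig` from a YAML file (missing keys default)."""
    if path is None:
        return QuantConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    tracing_keys = {f.name for f in dc_fields(TracingConfig)}
    quant_keys = {f.name for f in dc_fields(QuantConfig)} - {"tracing"}
    unknown = set(raw) - tracing_keys - quant_keys
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    tracing = TracingConfig(**{k: v for k, v in raw.items()
                               if k in tracing_keys})
    return QuantConfig(**{k: v for k, v in raw.items() if k in quant_keys},
                       tracing=tracing)
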