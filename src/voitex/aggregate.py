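"""Per-scan aggregation: collapse 16 per-ROI feature records into one row
per scan and assemble the cohort feature table.

Each of the 107 features is aggregated over the 16 structures with one
of three statistics: sum for physically extensive quantities (volumes,
surfaces, energies), mean otherwise; mode is available but unassigned by
default.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IncompleteScanError
from .radiomics import EngineConfig, FeatureRecord, extract_all, manifest
from .roi import extract_roi_voxels, list_labels
from .volumes import load_labelmap, load_volume

__all__ = [
    "EXPECTED_LABELS",
    "AggregatorMap",
    "aggregate_features",
    "build_feature_table",
    "extract_scan_records",
]

logger = logging.getLogger(__name__)

#: The 16 structure labels every complete scan must carry.
EXPECTED_LABELS = tuple(range(1, 17))

_EXTENSIVE = frozenset(
    {
        "firstorder_Energy",
        "firstorder_TotalEnergy",
        "shape2d_MeshSurface",
        "shape2d_PixelSurface",
        "shape2d_Perimeter",
        "shape3d_MeshVolume",
        "shape3d_VoxelVolume",
        "shape3d_SurfaceArea",
    }
)


def _mode(values: np.ndarray) -> float:
    """Mode after rounding to 6 significant digits; ties -> smallest value."""
    with np.errstate(divide="ignore"):
        mags = np.where(values != 0, np.floor(np.log10(np.abs(values))), 0.0)
    rounded = np.array(
        [round(v, int(5 - m)) for v, m in zip(values, mags)], dtype=float
    )
    counts = Counter(rounded)
    best = max(counts.values())
    return float(min(v for v, c in counts.items() if c == best))


_AGGREGATORS = {
    "mean": lambda v: float(np.mean(v)),
    "sum": lambda v: float(np.sum(v)),
    "mode": _mode,
}


@dataclass
class AggregatorMap:
    """feature name -> one of {mean, mode, sum}, covering all 107 features."""

    assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = manifest.qualified_names()
        if not self.assignment:
            self.assignment = {
                n: ("sum" if n in _EXTENSIVE else "mean") for n in names
            }
        missing = set(names) - set(self.assignment)
        if missing:
            raise ValueError(f"aggregator map misses features: {sorted(missing)[:5]}")
        bad = {v for v in self.assignment.values()} - set(_AGGREGATORS)
        if bad:
            raise ValueError(f"unknown aggregators: {bad}")

    def aggregate(self, name: str, values: np.ndarray) -> float:
        return _AGGREGATORS[self.assignment[name]](values)

    def to_json(self) -> str:
        return json.dumps(self.assignment, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AggregatorMap":
        return cls(assignment=json.loads(text))

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def aggregate_features(
    records: list[FeatureRecord], agg_map: AggregatorMap | None = None
) -> dict[str, float]:
    """Collapse the 16 per-ROI records into one 107-value vector.

    Raises :class:`IncompleteScanError` unless the records carry exactly
    the labels 1-16 (order does not matter).
    """
    agg_map = agg_map or AggregatorMap()
    labels = sorted(r.roi_label for r in records)
    if labels != sorted(EXPECTED_LABELS):
        raise IncompleteScanError(
            f"expected one record per label 1-16, got labels {labels}"
        )
    ordered = sorted(records, key=lambda r: r.roi_label)  # order-independent result
    out: dict[str, float] = {}
    for name in manifest.qualified_names():
        values = np.array([r.values[name] for r in ordered])
        out[name] = agg_map.aggregate(name, values)
    return out


def extract_scan_records(
    volume_path: str | Path,
    labelmap_path: str | Path,
    config: EngineConfig | None = None,
) -> list[FeatureRecord]:
    """Load one scan and extract per-ROI feature records for labels 1-16."""
    config = config or EngineConfig()
    volume = load_volume(volume_path)
    labelmap = load_labelmap(labelmap_path)
    present = list_labels(labelmap)
    missing = [lb for lb in EXPECTED_LABELS if lb not in present]
    if missing:
        raise IncompleteScanError(f"labels missing from {labelmap_path}: {missing}")
    return [
        extract_all(extract_roi_voxels(volume, labelmap, lb), config)
        for lb in EXPECTED_LABELS
    ]


def build_feature_table(
    manifest_path: str | Path,
    config: EngineConfig | None = None,
    agg_map: AggregatorMap | None = None,
) -> pd.DataFrame:
    """Assemble the scans x 107 feature table from a cohort manifest CSV.

    Scans that fail to load or are missing labels are dropped with a
    logged warning. Columns: scan_id, class, then the 107 features in
    manifest order.
    """
    config = config or EngineConfig()
    agg_map = agg_map or AggregatorMap()
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    cohort = pd.read_csv(manifest_path)

    rows = []
    for rec in cohort.to_dict("records"):
        try:
            records = extract_scan_records(
                base / rec["volume_path"], base / rec["labelmap_path"], config
            )
            row = {"scan_id": rec["scan_id"], "class": rec["class"]}
            row.update(aggregate_features(records, agg_map))
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - drop-and-continue per scan
            logger.warning("dropping scan %s: %s", rec["scan_id"], exc)
    table = pd.DataFrame(rows)
    table.attrs["engine_config"] = config.to_json()
    table.attrs["aggregator_hash"] = agg_map.content_hash()
    return table
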