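"""Reading and writing cohort images, metadata and annotations.

Cohorts live on disk as one PNG/TIFF per case plus a sidecar metadata CSV
(columns ``case_id, path, mpp, label, menopause``).  Detected clusters are
serialized as GeoJSON FeatureCollections with Polygon geometries in
full-resolution pixel coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detect import ClusterAnnotation
from .synthetic import SlideCase

__all__ = [
    "write_cohort",
    "read_cohort",
    "annotations_to_geojson",
    "geojson_to_annotations",
    "write_annotations",
    "read_annotations",
]

META_COLUMNS = ["case_id", "path", "mpp", "label", "menopause"]


def write_cohort(cases: list[SlideCase], out_dir: str | Path) -> Path:
    """Write case images (PNG) and the metadata CSV; returns the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        path = out / f"{case.case_id}.png"
        iio.imwrite(path, case.image)
        rows.append(
            {
                "case_id": case.case_id,
                "path": path.name,
                "mpp": case.mpp,
                "label": case.label,
                "menopause": case.menopause,
            }
        )
    meta = out / "metadata.csv"
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(meta, index=False)
    return meta


def read_cohort(meta_csv: str | Path) -> list[SlideCase]:
    """Load a cohort from a metadata CSV; image paths resolve relative to it."""
    meta_csv = Path(meta_csv)
    df = pd.read_csv(meta_csv)
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    cases = []
    for row in df.itertuples(index=False):
        img = iio.imread(meta_csv.parent / row.path)
        cases.append(
            SlideCase(
                case_id=str(row.case_id),
                image=np.asarray(img)[..., :3],
                mpp=float(row.mpp),
                label=str(row.label),
                menopause=bool(row.menopause),
            )
        )
    return cases


def annotations_to_geojson(annotations: list[ClusterAnnotation]) -> dict:
    """GeoJSON FeatureCollection in full-resolution pixel coordinates."""
    features = []
    for ann in annotations:
        ring = ann.polygon.tolist()
        ring.append(ring[0])  # GeoJSON rings are explicitly closed
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "cluster_id": ann.cluster_id,
                    "area_px": ann.area_px,
                    "area_um2": ann.area_um2,
                    "excluded": ann.excluded,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def geojson_to_annotations(doc: dict) -> list[ClusterAnnotation]:
    out = []
    for feat in doc["features"]:
        ring = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)[:-1]
        props = feat["properties"]
        out.append(
            ClusterAnnotation(
                cluster_id=props["cluster_id"],
                polygon=ring,
                area_px=float(props["area_px"]),
                area_um2=float(props["area_um2"]),
                excluded=bool(props["excluded"]),
            )
        )
    return out


def write_annotations(annotations: list[ClusterAnnotation], path: str | Path) -> None:
    Path(path).write_text(json.dumps(annotations_to_geojson(annotations)))


def read_annotations(path: str | Path) -> list[ClusterAnnotation]:
    return geojson_to_annotations(json.loads(Path(path).read_text()))
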