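"""Field layouts: plot polygons with trial labels, plus bare-ground polygons.

A :class:`FieldLayout` holds one site's plot polygons (each labelled with
plot id, genotype, replicate block and site) together with the bare-ground
polygons sketched in the alleys, from which the terrain model is built.
Layouts round-trip through GeoJSON FeatureCollections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from shapely.geometry import Polygon, mapping, shape

__all__ = ["PlotFeature", "BareGroundFeature", "FieldLayout"]


@dataclass(frozen=True)
class PlotFeature:
    plot_id: str
    genotype_id: str
    rep: int
    site: str
    polygon: Polygon


@dataclass(frozen=True)
class BareGroundFeature:
    polygon_id: str
    polygon: Polygon


@dataclass
class FieldLayout:
    plots: list[PlotFeature] = field(default_factory=list)
    bare_ground: list[BareGroundFeature] = field(default_factory=list)
    crs: str = "EPSG:32650"

    def __post_init__(self) -> None:
        for p in self.plots:
            if not p.polygon.is_valid or p.polygon.area <= 0:
                raise ValueError(f"plot {p.plot_id} polygon is degenerate")
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            raise ValueError("plot_ids must be unique")

    def __len__(self) -> int:
        return len(self.plots)

    def for_site(self, site: str) -> "FieldLayout":
        return FieldLayout(
            plots=[p for p in self.plots if p.site == site],
            bare_ground=self.bare_ground,
            crs=self.crs,
        )

    @property
    def sites(self) -> list[str]:
        return sorted({p.site for p in self.plots})

    def bounds(self) -> tuple[float, float, float, float]:
        polys = [p.polygon for p in self.plots] + [b.polygon for b in self.bare_ground]
        if not polys:
            raise ValueError("empty layout has no bounds")
        xs0, ys0, xs1, ys1 = zip(*(g.bounds for g in polys))
        return min(xs0), min(ys0), max(xs1), max(ys1)

    # ------------------------------------------------------------- GeoJSON
    def plots_to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {
                    "plot_id": p.plot_id,
                    "genotype_id": p.genotype_id,
                    "rep": p.rep,
                    "site": p.site,
                },
            }
            for p in self.plots
        ]
        _write_collection(path, features, self.crs)

    def bare_ground_to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": mapping(b.polygon),
                "properties": {"polygon_id": b.polygon_id},
            }
            for b in self.bare_ground
        ]
        _write_collection(path, features, self.crs)

    @classmethod
    def from_geojson(
        cls, plots_path: str | Path, bare_path: str | Path | None = None
    ) -> "FieldLayout":
        plots_fc = json.loads(Path(plots_path).read_text())
        crs = _read_crs(plots_fc)
        plots = [
            PlotFeature(
                plot_id=str(f["properties"]["plot_id"]),
                genotype_id=str(f["properties"]["genotype_id"]),
                rep=int(f["properties"]["rep"]),
                site=str(f["properties"]["site"]),
                polygon=shape(f["geometry"]),
            )
            for f in plots_fc["features"]
        ]
        bare: list[BareGroundFeature] = []
        if bare_path is not None:
            bare_fc = json.loads(Path(bare_path).read_text())
            bare = [
                BareGroundFeature(
                    polygon_id=str(f["properties"]["polygon_id"]),
                    polygon=shape(f["geometry"]),
                )
                for f in bare_fc["features"]
            ]
        return cls(plots=plots, bare_ground=bare, crs=crs)


def _write_collection(path: str | Path, features: list[dict], crs: str) -> None:
    collection = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": f"urn:ogc:def:crs:{crs.replace(':', '::')}"}},
        "features": features,
    }
    Path(path).write_text(json.dumps(collection))


def _read_crs(fc: dict) -> str:
    name = fc.get("crs", {}).get("properties", {}).get("name", "")
    if "EPSG" in name:
        code = name.rsplit(":", 1)[-1]
        return f"EPSG:{code}"
    return "EPSG:32650"
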