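"""Sub-region geometry for the Northeast U.S. shelf.

The survey splits the shelf into four sub-regions: Gulf of Maine (GOM),
Georges Bank (GB), Southern New England (SNE) and the Mid-Atlantic Bight
(MAB).  Exact boundaries are a configuration concern — the shipped defaults
are simple rectangles chosen to tile the shelf without interior overlap —
and every output that depends on them records which definition was used.
Config order doubles as the tie-break priority for points that fall exactly
on a shared boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml
from shapely.geometry import Point, Polygon, box

REGION_NAMES = ("GOM", "GB", "SNE", "MAB")

# (lon_min, lat_min, lon_max, lat_max); order = tie-break priority
_DEFAULT_BOXES = {
    "GOM": (-70.0, 42.0, -66.0, 45.0),
    "GB": (-69.0, 40.5, -66.0, 42.0),
    "SNE": (-72.0, 39.0, -69.0, 41.0),
    "MAB": (-76.0, 35.0, -72.0, 39.0),
}


@dataclass
class RegionSpec:
    """An ordered set of named, non-overlapping region polygons."""

    names: list[str]
    polygons: list[Polygon]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("at least one region required")
        if len(self.names) != len(self.polygons):
            raise ValueError("names and polygons must align")
        self.validate()

    def validate(self) -> None:
        """Reject configurations where two region interiors overlap."""
        for i in range(len(self.names)):
            for j in range(i + 1, len(self.names)):
                inter = self.polygons[i].intersection(self.polygons[j])
                if not inter.is_empty and inter.area > 1e-12:
                    raise ValueError(
                        f"regions {self.names[i]} and {self.names[j]} overlap"
                    )

    def assign(self, lat: float, lon: float) -> str | None:
        """Region containing (lat, lon), or None if outside all.

        Boundary points go to the first region in config order (documented
        tie-break).
        """
        p = Point(lon, lat)
        for name, poly in zip(self.names, self.polygons):
            if poly.covers(p):
                return name
        return None

    def bounds(self, name: str) -> tuple[float, float, float, float]:
        return self.polygons[self.names.index(name)].bounds

    def to_dict(self) -> dict:
        return {
            "order": self.names,
            "polygons": {
                n: list(map(list, poly.exterior.coords))
                for n, poly in zip(self.names, self.polygons)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSpec":
        names = list(d["order"])
        polys = [Polygon(d["polygons"][n]) for n in names]
        return cls(names, polys)

    @classmethod
    def from_yaml(cls, path) -> "RegionSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "RegionSpec":
        names = list(_DEFAULT_BOXES)
        polys = [box(*_DEFAULT_BOXES[n]) for n in names]
        return cls(names, polys)


def bin_latitude(lat: float, width_deg: float = 2.0, lat0: float = 35.0,
                 lat1: float = 45.0) -> str | None:
    """Half-open latitude band label, e.g. 36.0 -> "35-37".

    Returns None outside [lat0, lat1).
    """
    if not (lat0 <= lat < lat1):
        return None
    k = int((lat - lat0) // width_deg)
    lo = lat0 + k * width_deg
    return f"{lo:g}-{lo + width_deg:g}"
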