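"""Capillary-domain morphometry of muscle sections.

Given digitized capillary coordinates and fiber boundary polygons from
a stained cross-section, computes the classic supply indices: the
capillary-to-fiber ratio (C:F), capillary density (CD, per mm^2), mean
fiber cross-sectional area (FCSA, um^2), and the Voronoi tessellation
of capillary domains — the region of tissue closer to one capillary
than any other — whose area heterogeneity is summarized as the standard
deviation of log-transformed domain areas (logSD). Natural log is used;
a different base would rescale logSD by a constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram

UM2_PER_MM2 = 1.0e6


@dataclass
class CapillarySection:
    """2-D capillary points and fiber outlines of one section (um units)."""

    capillary_points: np.ndarray  # (n, 2)
    fiber_polygons: list[np.ndarray]  # each (m_i, 2), closed rings
    region_boundary: np.ndarray  # (k, 2) simple ring

    def __post_init__(self) -> None:
        self.capillary_points = np.asarray(self.capillary_points, dtype=float).reshape(-1, 2)
        self.fiber_polygons = [np.asarray(p, dtype=float).reshape(-1, 2) for p in self.fiber_polygons]
        self.region_boundary = np.asarray(self.region_boundary, dtype=float).reshape(-1, 2)
        region = self.region_polygon()
        if not region.is_valid or region.area <= 0:
            raise ValueError("region boundary is not a simple polygon with positive area")
        for i, (x, y) in enumerate(self.capillary_points):
            if not region.covers(Point(x, y)):  # boundary points count as inside
                raise ValueError(f"capillary point {i} ({x}, {y}) lies outside the region")

    def region_polygon(self) -> Polygon:
        return Polygon(self.region_boundary)

    @property
    def n_capillaries(self) -> int:
        return len(self.capillary_points)

    @property
    def n_fibers(self) -> int:
        return len(self.fiber_polygons)


def cf_ratio(n_capillaries: int, n_fibers: int) -> float:
    """Capillaries per fiber."""
    if n_fibers <= 0:
        raise ValueError("capillary-to-fiber ratio needs at least one fiber")
    return n_capillaries / n_fibers


def capillary_density(section: CapillarySection) -> float:
    """Capillaries per mm^2 of section area (coordinates in um)."""
    area_um2 = section.region_polygon().area
    if area_um2 <= 0:
        raise ValueError("region area must be positive")
    return section.n_capillaries / (area_um2 / UM2_PER_MM2)


def fiber_csa(section: CapillarySection) -> float:
    """Mean fiber cross-sectional area in um^2 (shoelace; degenerate
    zero-area outlines are excluded with a warning)."""
    import warnings

    areas = []
    for i, ring in enumerate(section.fiber_polygons):
        poly = Polygon(ring)
        if poly.area == 0:
            warnings.warn(f"fiber polygon {i} has zero area; excluded")
            continue
        areas.append(poly.area)
    if not areas:
        raise ValueError("no fiber polygon with positive area")
    return float(np.mean(areas))


@dataclass
class DomainSummary:
    """Capillary domain polygons and the section-level supply indices."""

    domains: list[Polygon]  # one per capillary, input order
    areas: np.ndarray  # um^2
    cf_ratio: float
    capillary_density: float
    mean_fcsa: float
    logsd: float
    log_base: str = "natural"


def voronoi_domains(section: CapillarySection) -> DomainSummary:
    """Voronoi tessellation of the capillaries clipped to the region.

    Returns one domain polygon per capillary (in input order); domains
    are pairwise interior-disjoint and their areas sum to the region
    area. A single capillary owns the entire region.
    """
    pts = section.capillary_points
    if len(pts) == 0:
        raise ValueError("need at least one capillary point")
    uniq, counts = np.unique(pts, axis=0, return_counts=True)
    if (counts > 1).any():
        dupes = [tuple(p) for p in uniq[counts > 1][:5]]
        raise ValueError(f"duplicate capillary points: {dupes}")
    region = section.region_polygon()
    if len(pts) == 1:
        domains = [region]
    else:
        cells = voronoi_diagram(
            MultiPoint([tuple(p) for p in pts]), envelope=region.buffer(1.0)
        )
        # voronoi_diagram does not preserve input order: match cell to point
        domains_by_idx: dict[int, Polygon] = {}
        for cell in cells.geoms:
            for i, (x, y) in enumerate(pts):
                if i in domains_by_idx:
                    continue
                if cell.covers(Point(x, y)):
                    domains_by_idx[i] = cell.intersection(region)
                    break
        if len(domains_by_idx) != len(pts):
            raise RuntimeError("failed to match every capillary to a Voronoi cell")
        domains = [domains_by_idx[i] for i in range(len(pts))]
    areas = np.array([d.area for d in domains])
    return DomainSummary(
        domains=domains,
        areas=areas,
        cf_ratio=cf_ratio(section.n_capillaries, section.n_fibers)
        if section.n_fibers
        else float("nan"),
        capillary_density=capillary_density(section),
        mean_fcsa=fiber_csa(section) if section.n_fibers else float("nan"),
        logsd=domain_logsd(areas) if len(areas) >= 2 else 0.0,
    )


def domain_logsd(areas) -> float:
    """Sample SD (n-1 denominator) of natural-log domain areas.

    Scale invariant: multiplying all areas by a constant shifts the logs
    uniformly and leaves the SD unchanged.
    """
    a = np.asarray(areas, dtype=float)
    if a.size < 2:
        raise ValueError("logSD needs at least two domain areas")
    if (a <= 0).any():
        raise ValueError("domain areas must be positive for log transform")
    return float(np.std(np.log(a), ddof=1))


# ---------------------------------------------------------------------------
# file I/O


def read_points(path: str | Path) -> np.ndarray:
    """Tab-delimited x, y point file (header optional)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if "x" in cols and "y" in cols:
        return df[[df.columns[cols.index("x")], df.columns[cols.index("y")]]].to_numpy(float)
    return pd.read_csv(path, sep="\t", header=None).to_numpy(float)


def read_polygons(path: str | Path) -> list[np.ndarray]:
    """Tab-delimited polygon file: polygon_id, vertex_index, x, y."""
    df = pd.read_csv(path, sep="\t")
    need = {"polygon_id", "vertex_index", "x", "y"}
    if not need <= set(df.columns):
        raise ValueError(f"polygon file needs columns {sorted(need)}")
    out = []
    for _, grp in df.groupby("polygon_id", sort=True):
        grp = grp.sort_values("vertex_index")
        out.append(grp[["x", "y"]].to_numpy(float))
    return out


def write_domain_summary(summary: DomainSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"cf_ratio\t{summary.cf_ratio:.6g}\n")
        fh.write(f"capillary_density_per_mm2\t{summary.capillary_density:.6g}\n")
        fh.write(f"mean_fcsa_um2\t{summary.mean_fcsa:.6g}\n")
        fh.write(f"logsd\t{summary.logsd:.6g}\n")
        fh.write(f"log_base\t{summary.log_base}\n")


def write_domain_areas(summary: DomainSummary, path: str | Path) -> None:
    pd.DataFrame(
        {"capillary": np.arange(len(summary.areas)), "domain_area_um2": summary.areas}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
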