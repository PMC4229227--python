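"""Design-based stereology: optical fractionator and planar density counts.

The optical-fractionator design counts cells in systematically sampled
unbiased counting frames within a tissue section: a sampling grid is laid
over the ROI with a uniform random offset, an 85 x 85 um counting frame sits
in each grid cell, and cells are counted inside a virtual 3-D counting box
that starts 3 um below the section surface (guard zone) and extends 25 um
down (optical dissector).  Counting-frame edge rules make every cell
countable in exactly one frame: the left and bottom edges (and their
extensions) are forbidden, the right and top edges are inclusion edges.

Density is the total count over the sampled volume, and precision is
summarised by a coefficient of error (CE) computed as SEM/mean of the
per-site counts — the equal-sized-unit reduction of the
Scheaffer-Mendenhall-Ott survey-sampling CE.

Two simpler planar estimators are included: a random-fields density
(cells/mm^2 over n sampled fields) and an exhaustive-scan density (total
count over the full ROI area).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

from .synthetic import CellField3D

__all__ = [
    "SamplingDesign",
    "SiteCount",
    "DensityEstimate",
    "place_grid",
    "count_frame",
    "count_sites",
    "estimate_density",
    "schaffer_ce",
    "field_density",
    "exhaustive_density",
    "write_site_counts_csv",
    "read_site_counts_csv",
    "write_design_yaml",
    "read_design_yaml",
]

UM3_PER_MM3 = 1e9
UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class SamplingDesign:
    """Optical-fractionator geometry (defaults: the published design)."""

    grid_dx_um: float = 296.6
    grid_dy_um: float = 277.2
    frame_w_um: float = 85.0
    frame_h_um: float = 85.0
    guard_um: float = 3.0
    dissector_h_um: float = 25.0
    thickness_every: int = 5

    def __post_init__(self) -> None:
        for name in ("grid_dx_um", "grid_dy_um", "frame_w_um", "frame_h_um",
                     "dissector_h_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.guard_um < 0:
            raise ValueError("guard_um must be >= 0")
        if self.thickness_every < 1:
            raise ValueError("thickness_every must be >= 1")
        if self.frame_w_um > self.grid_dx_um or self.frame_h_um > self.grid_dy_um:
            raise ValueError("counting frame must fit inside one grid cell")

    @property
    def frame_area_um2(self) -> float:
        return self.frame_w_um * self.frame_h_um

    @property
    def box_volume_um3(self) -> float:
        return self.frame_area_um2 * self.dissector_h_um

    @property
    def min_thickness_um(self) -> float:
        """QC bound: section must hold guard zone plus dissector."""
        return self.guard_um + self.dissector_h_um


@dataclass(frozen=True)
class SiteCount:
    site_index: int
    site_origin: tuple[float, float]  # (x_um, y_um), frame lower-left corner
    q_intact: int
    q_pyknotic: int
    thickness_um: float | None = None

    def __post_init__(self) -> None:
        if self.q_intact < 0 or self.q_pyknotic < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def q_total(self) -> int:
        return self.q_intact + self.q_pyknotic


@dataclass(frozen=True)
class DensityEstimate:
    density_per_mm3: float
    ce: float | None
    n_sites: int
    sum_q: int
    pyknotic_pct: float | None = None


def _as_polygon(roi) -> Polygon:
    if isinstance(roi, Polygon):
        return roi
    arr = np.asarray(roi, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
        raise ValueError("ROI must be a shapely Polygon or an (n>=3, 2) vertex array")
    return Polygon(arr)


def place_grid(roi_polygon, design: SamplingDesign, seed: int | None = None,
               offset: tuple[float, float] | None = None) -> list[tuple[float, float]]:
    """Systematic-uniform-random counting-site placement over an ROI.

    A grid with the design spacing is shifted by a uniform random offset in
    ``[0, dx) x [0, dy)`` (or by ``offset`` if given, e.g. ``(0, 0)`` for a
    deterministic tiling); a site is retained when its frame-associated
    point (the frame's lower-left corner) falls inside the ROI.
    """
    poly = _as_polygon(roi_polygon)
    if poly.area <= 0:
        raise ValueError("ROI polygon has zero area")
    dx, dy = design.grid_dx_um, design.grid_dy_um
    if offset is None:
        rng = np.random.default_rng(seed)
        ox = float(rng.uniform(0.0, dx))
        oy = float(rng.uniform(0.0, dy))
    else:
        ox, oy = float(offset[0]) % dx, float(offset[1]) % dy
    minx, miny, maxx, maxy = poly.bounds
    i0 = math.floor((minx - ox) / dx)
    i1 = math.ceil((maxx - ox) / dx)
    j0 = math.floor((miny - oy) / dy)
    j1 = math.ceil((maxy - oy) / dy)
    sites = []
    for j in range(j0, j1 + 1):
        y = oy + j * dy
        for i in range(i0, i1 + 1):
            x = ox + i * dx
            if poly.covers(Point(x, y)):
                sites.append((x, y))
    if not sites:
        warnings.warn("sampling grid produced no counting sites "
                      "(ROI smaller than one grid cell?)", stacklevel=2)
    return sites


def count_frame(field: CellField3D, site: tuple[float, float],
                design: SamplingDesign, site_index: int = 0,
                thickness_um: float | None = None) -> SiteCount:
    """Count cells in one unbiased counting frame / optical dissector.

    A cell at ``(x, y, z)`` is counted when ``x0 < x <= x0 + w`` and
    ``y0 < y <= y0 + h`` (left/bottom forbidden, right/top inclusive) and
    its depth satisfies ``guard <= z < guard + dissector`` (half-open to
    avoid double counting at the box floor).
    """
    if field.slab_extent[2] < design.min_thickness_um:
        raise ValueError(
            "slab thinner than guard zone plus dissector height "
            f"({field.slab_extent[2]} < {design.min_thickness_um} um)")
    x0, y0 = float(site[0]), float(site[1])
    xyz = field.xyz
    if xyz.shape[0] == 0:
        return SiteCount(site_index, (x0, y0), 0, 0, thickness_um)
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    in_frame = ((x > x0) & (x <= x0 + design.frame_w_um)
                & (y > y0) & (y <= y0 + design.frame_h_um))
    z_lo = design.guard_um
    in_box = in_frame & (z >= z_lo) & (z < z_lo + design.dissector_h_um)
    pyk = field.pyknotic[in_box]
    return SiteCount(
        site_index=site_index,
        site_origin=(x0, y0),
        q_intact=int(np.count_nonzero(~pyk)),
        q_pyknotic=int(np.count_nonzero(pyk)),
        thickness_um=thickness_um,
    )


def count_sites(field: CellField3D, sites: Sequence[tuple[float, float]],
                design: SamplingDesign) -> list[SiteCount]:
    """Count every site; section thickness is recorded at every
    ``thickness_every``-th site (here: the slab thickness itself)."""
    out = []
    for idx, site in enumerate(sites):
        thick = field.slab_extent[2] if idx % design.thickness_every == 0 else None
        out.append(count_frame(field, site, design, site_index=idx,
                               thickness_um=thick))
    return out


def schaffer_ce(per_site_counts: Sequence[float]) -> float | None:
    """Coefficient of error of the site mean: (SD/sqrt(n)) / mean.

    Returns ``None`` (flagged undefined) when the mean count is zero.
    """
    q = np.asarray(per_site_counts, dtype=float)
    if q.size < 2:
        raise ValueError("CE needs at least two sites")
    mean = q.mean()
    if mean == 0:
        return None
    sem = q.std(ddof=1) / math.sqrt(q.size)
    return float(sem / mean)


def estimate_density(site_counts: Sequence[SiteCount], design: SamplingDesign,
                     which: str = "total") -> DensityEstimate:
    """Density (cells/mm^3) from per-site dissector counts.

    ``which`` selects the counted class: ``"total"``, ``"intact"`` or
    ``"pyknotic"``.  Density is sum(Q) over the total sampled box volume
    (n_sites x frame area x dissector height); the CE is attached from the
    per-site counts of the same class, and the pyknotic percentage is
    always derived from both classes together.
    """
    if not site_counts:
        raise ValueError("no counting sites")
    getter = {"total": lambda s: s.q_total,
              "intact": lambda s: s.q_intact,
              "pyknotic": lambda s: s.q_pyknotic}
    if which not in getter:
        raise ValueError("which must be 'total', 'intact' or 'pyknotic'")
    q = np.array([getter[which](s) for s in site_counts], dtype=int)
    n_sites = len(site_counts)
    sum_q = int(q.sum())
    density = sum_q / (n_sites * design.box_volume_um3) * UM3_PER_MM3
    ce = schaffer_ce(q) if n_sites >= 2 else None
    n_int = sum(s.q_intact for s in site_counts)
    n_pyk = sum(s.q_pyknotic for s in site_counts)
    pyk_pct = 100.0 * n_pyk / (n_int + n_pyk) if (n_int + n_pyk) > 0 else None
    return DensityEstimate(density_per_mm3=float(density), ce=ce,
                           n_sites=n_sites, sum_q=sum_q, pyknotic_pct=pyk_pct)


def field_density(field_counts: Sequence[float], field_area_um2: float,
                  n_fields: int | None = None) -> float:
    """Planar density (cells/mm^2) from counts in n sampled fields."""
    counts = np.asarray(field_counts, dtype=float)
    if n_fields is None:
        n_fields = counts.size
    if n_fields < 1:
        raise ValueError("need at least one field")
    if field_area_um2 <= 0:
        raise ValueError("field area must be positive")
    return float(counts.sum() / (n_fields * field_area_um2) * UM2_PER_MM2)


def exhaustive_density(total_count: float, roi_area_um2: float) -> float:
    """Planar density (cells/mm^2) from an exhaustive scan of the ROI."""
    if roi_area_um2 <= 0:
        raise ValueError("ROI area must be positive")
    return float(total_count / roi_area_um2 * UM2_PER_MM2)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def write_site_counts_csv(site_counts: Sequence[SiteCount], path) -> None:
    rows = [{
        "site_index": s.site_index,
        "x_um": s.site_origin[0],
        "y_um": s.site_origin[1],
        "q_intact": s.q_intact,
        "q_pyknotic": s.q_pyknotic,
        "thickness_um": s.thickness_um if s.thickness_um is not None else "",
    } for s in site_counts]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_site_counts_csv(path) -> list[SiteCount]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        thick = r.get("thickness_um")
        thick = None if pd.isna(thick) else float(thick)
        out.append(SiteCount(
            site_index=int(r["site_index"]),
            site_origin=(float(r["x_um"]), float(r["y_um"])),
            q_intact=int(r["q_intact"]),
            q_pyknotic=int(r["q_pyknotic"]),
            thickness_um=thick,
        ))
    return out


def write_design_yaml(design: SamplingDesign, path) -> None:
    from dataclasses import asdict
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(design), fh, sort_keys=True)


def read_design_yaml(path) -> SamplingDesign:
    with open(path) as fh:
        return SamplingDesign(**yaml.safe_load(fh))
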