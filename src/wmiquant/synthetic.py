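"""Synthetic ground-truth generators for the quantification pipeline.

Three families of inputs are produced, each with a known answer attached so
that every downstream estimator can be validated against truth:

* fluorescence-like micrographs with a spatially varying background, additive
  noise, and bright stained structures occupying a controlled area fraction
  (:func:`generate_image`);
* three-dimensional slabs of cells drawn from a homogeneous Poisson point
  process, with a small "pyknotic" (degenerating) subpopulation
  (:func:`generate_cell_field`);
* a twin-structured four-group cohort of animals whose per-endpoint group
  means and SDs default to the reported group summaries of the original study
  (:func:`simulate_cohort`).

All generators are deterministic for a fixed seed; sub-streams are derived
with :class:`numpy.random.SeedSequence` so per-animal / per-shape draws do
not interact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from skimage.draw import disk as _draw_disk

__all__ = [
    "ImageSpec",
    "SyntheticImage",
    "CellField3D",
    "GroupSpec",
    "CohortSpec",
    "AnimalRecord",
    "generate_image",
    "generate_cell_field",
    "simulate_cohort",
    "default_cohort_spec",
    "cohort_to_frame",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_image_tiff",
    "write_mask_png",
    "write_spec_yaml",
    "GROUPS",
]

#: canonical group ordering used throughout the package
GROUPS = ("control", "early_hi", "late_hi", "rhi")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic immunofluorescence tile.

    Intensities are on a 16-bit scale.  ``fg_contrast`` is the intensity step
    of stained structures above the local background; ``bg_gradient_amp`` is
    the amplitude of a smooth low-frequency illumination field.  The default
    pixel size (0.645 um) corresponds to a 10X objective on a CCD with
    6.45 um photosites.
    """

    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 0.645
    bg_level: float = 2000.0
    bg_gradient_amp: float = 300.0
    noise_sd: float = 120.0
    fg_fraction: float = 0.2
    fg_contrast: float = 600.0
    fg_shape: str = "blob"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0.0 <= self.fg_fraction <= 1.0:
            raise ValueError("fg_fraction must lie in [0, 1]")
        if self.fg_contrast <= 0:
            raise ValueError("fg_contrast must be positive")
        if self.noise_sd < 0 or self.bg_gradient_amp < 0:
            raise ValueError("noise_sd and bg_gradient_amp must be >= 0")
        if self.fg_shape not in ("blob", "filament"):
            raise ValueError("fg_shape must be 'blob' or 'filament'")


@dataclass(frozen=True)
class SyntheticImage:
    """Rendered tile plus its ground-truth foreground mask."""

    intensities: np.ndarray  # uint16, (H, W)
    truth_mask: np.ndarray   # bool,   (H, W)
    achieved_fraction: float
    spec: ImageSpec

    def __post_init__(self) -> None:
        if self.intensities.shape != self.truth_mask.shape:
            raise ValueError("mask and image dimensions differ")


def _blob_pixels(shape: tuple[int, int], rng: np.random.Generator,
                 r_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of one random disk clipped to the image."""
    h, w = shape
    r = rng.uniform(2.0, max(2.0, r_max))
    cy = rng.uniform(0, h)
    cx = rng.uniform(0, w)
    return _draw_disk((cy, cx), r, shape=shape)


def _filament_pixels(shape: tuple[int, int], rng: np.random.Generator,
                     max_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of one random thick polyline (process-like)."""
    h, w = shape
    thickness = 1.5
    # length chosen so the stamped area stays under the per-shape budget
    length = max(6.0, max_px / (2.0 * thickness + 1.0))
    n_steps = max(3, int(length / 2.0))
    y = rng.uniform(0, h)
    x = rng.uniform(0, w)
    theta = rng.uniform(0, 2 * np.pi)
    stamp = np.zeros(shape, dtype=bool)
    for _ in range(n_steps):
        theta += rng.normal(0.0, 0.35)
        y += 2.0 * math.sin(theta)
        x += 2.0 * math.cos(theta)
        rr, cc = _draw_disk((y, x), thickness, shape=shape)
        stamp[rr, cc] = True
    return np.nonzero(stamp)


def generate_image(spec: ImageSpec) -> SyntheticImage:
    """Render a synthetic stained tile hitting a target area fraction.

    Foreground structures (disks for somata-like "blob" staining, thick
    random polylines for process-like "filament" staining) are added until
    the true mask fraction is within 0.004 of ``spec.fg_fraction``; each
    shape's area is capped so the final fraction cannot overshoot by more
    than the same margin.

    Raises
    ------
    ValueError
        If the target fraction cannot be reached with the shape budget
        (pathologically small images).
    """
    shape = (spec.height_px, spec.width_px)
    n_total = shape[0] * shape[1]
    rng = np.random.default_rng(spec.seed)

    mask = np.zeros(shape, dtype=bool)
    target_px = spec.fg_fraction * n_total
    cap = max(4, int(0.008 * n_total))  # max pixels added by one shape
    if spec.fg_fraction > 0:
        r_max = math.sqrt(0.9 * cap / math.pi)
        stop = target_px - cap / 2.0
        max_iter = 200_000
        it = 0
        while mask.sum() < stop:
            it += 1
            if it > max_iter:
                raise ValueError(
                    "could not reach fg_fraction=%g with the configured "
                    "shape parameters" % spec.fg_fraction)
            if spec.fg_shape == "blob":
                rr, cc = _blob_pixels(shape, rng, r_max)
            else:
                rr, cc = _filament_pixels(shape, rng, cap)
            mask[rr, cc] = True

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, spec.bg_level, dtype=float)
    if spec.bg_gradient_amp > 0:
        # two low-frequency sinusoids with random orientation and phase
        for _ in range(2):
            fy = rng.uniform(-1.2, 1.2) / shape[0]
            fx = rng.uniform(-1.2, 1.2) / shape[1]
            phase = rng.uniform(0, 2 * np.pi)
            img += 0.5 * spec.bg_gradient_amp * np.sin(
                2 * np.pi * (fy * yy + fx * xx) + phase)
    img[mask] += spec.fg_contrast
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    return SyntheticImage(
        intensities=img,
        truth_mask=mask,
        achieved_fraction=float(mask.mean()),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# 3-D cell fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellField3D:
    """Homogeneous Poisson field of cells inside a tissue slab.

    Coordinates are in micrometres with the origin at the slab's lower-left
    top corner; ``z`` measures depth from the slab surface.  ``true_density``
    is the realised count divided by slab volume (cells/mm^3).
    """

    slab_extent: tuple[float, float, float]  # (x_um, y_um, z_um)
    xyz: np.ndarray                          # (n, 3) float
    pyknotic: np.ndarray                     # (n,) bool
    true_density: float
    true_pyknotic_fraction: float
    seed: int

    @property
    def n_cells(self) -> int:
        return int(self.xyz.shape[0])

    @property
    def cells(self) -> list[tuple[float, float, float, str]]:
        lab = np.where(self.pyknotic, "pyknotic", "intact")
        return [(float(x), float(y), float(z), str(s))
                for (x, y, z), s in zip(self.xyz, lab)]


def generate_cell_field(extent_um: Sequence[float],
                        density_per_mm3: float,
                        pyknotic_fraction: float,
                        seed: int = 0) -> CellField3D:
    """Draw a homogeneous Poisson point process of cells in a slab.

    Parameters
    ----------
    extent_um:
        ``(x, y, z)`` slab dimensions in micrometres.
    density_per_mm3:
        Poisson intensity in cells per cubic millimetre.
    pyknotic_fraction:
        Probability that a cell is independently labelled degenerating.
    """
    extent = tuple(float(v) for v in extent_um)
    if len(extent) != 3 or any(not math.isfinite(v) or v <= 0 for v in extent):
        raise ValueError("extent_um must be three positive finite lengths")
    if not math.isfinite(density_per_mm3) or density_per_mm3 < 0:
        raise ValueError("density_per_mm3 must be finite and >= 0")
    if not 0.0 <= pyknotic_fraction <= 1.0:
        raise ValueError("pyknotic_fraction must lie in [0, 1]")

    volume_mm3 = extent[0] * extent[1] * extent[2] * 1e-9
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(density_per_mm3 * volume_mm3))
    xyz = rng.uniform(0.0, 1.0, size=(n, 3)) * np.asarray(extent)
    pyk = rng.uniform(size=n) < pyknotic_fraction
    return CellField3D(
        slab_extent=extent,
        xyz=xyz,
        pyknotic=pyk,
        true_density=n / volume_mm3,
        true_pyknotic_fraction=float(pyk.mean()) if n else 0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    name: str
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated four-group twin cohort.

    ``endpoints`` maps endpoint name -> {group -> (mean, sd)}.  ``ewe_sd``
    is the between-ewe random-intercept SD expressed as a fraction of each
    endpoint's total SD (0 disables the ewe effect; values > 1 would imply
    more between-ewe variance than the endpoint has and raise an error).
    ``latent_loading`` (lambda in [0, 1]) is the loading of a per-animal
    shared severity factor on every endpoint's residual, inducing positive
    cross-endpoint correlation of roughly lambda^2 within groups.
    ``score_latents`` maps region -> {group -> (latent mean, latent sd)} for
    the discretised ordinal injury scores.
    """

    groups: tuple[GroupSpec, ...]
    endpoints: dict[str, dict[str, tuple[float, float]]]
    score_latents: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    ewe_sd: float = 0.0
    latent_loading: float = 0.7
    sections_per_region: int = 3
    section_jitter_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if self.ewe_sd < 0:
            raise ValueError("ewe_sd must be >= 0")
        if self.ewe_sd > 1:
            raise ValueError("ewe variance would exceed endpoint variance "
                             "(ewe_sd is a fraction of the endpoint SD)")
        if not 0.0 <= self.latent_loading <= 1.0:
            raise ValueError("latent_loading must lie in [0, 1]")
        names = {g.name for g in self.groups}
        for ep, per_group in self.endpoints.items():
            for gname, (mu, sd) in per_group.items():
                if gname not in names:
                    raise ValueError(f"endpoint {ep} refers to unknown group {gname}")
                if sd < 0:
                    raise ValueError(f"endpoint {ep}, group {gname}: sd < 0")


@dataclass
class AnimalRecord:
    """One animal: its group, its ewe, and all endpoint observations."""

    animal_id: str
    ewe_id: str
    group: str
    endpoints: dict[str, float]
    section_scores: dict[str, list[int]] = field(default_factory=dict)


# reported group means and SDs of the original study: the default conditions
_DEFAULT_ENDPOINTS: dict[str, dict[str, tuple[float, float]]] = {
    "gfap_af": {
        "control": (0.20, 0.06), "early_hi": (0.33, 0.05),
        "late_hi": (0.25, 0.05), "rhi": (0.37, 0.04),
    },
    "iba1_af": {
        "control": (0.06, 0.05), "early_hi": (0.18, 0.13),
        "late_hi": (0.08, 0.06), "rhi": (0.33, 0.17),
    },
    "olig2_density": {  # cells/mm^2
        "control": (117.2, 18.9), "early_hi": (154.6, 15.5),
        "late_hi": (105.1, 23.0), "rhi": (151.5, 48.5),
    },
    "o4_density": {  # cells/mm^3
        "control": (16854.0, 4752.0), "early_hi": (16430.0, 7182.0),
        "late_hi": (22855.0, 3210.0), "rhi": (29917.0, 11254.0),
    },
    "pyknotic_pct": {
        "control": (0.9, 0.4), "early_hi": (1.2, 0.9),
        "late_hi": (5.0, 2.4), "rhi": (1.7, 1.8),
    },
    "ac3_density": {  # cells/mm^2
        "control": (1.62, 0.76), "early_hi": (0.92, 0.21),
        "late_hi": (6.30, 5.40), "rhi": (1.73, 1.33),
    },
}

# ordinal-score latent means mirror the reported H&E score means per region
_DEFAULT_SCORE_LATENTS: dict[str, dict[str, tuple[float, float]]] = {
    "frontal_wm": {
        "control": (0.20, 0.45), "early_hi": (0.80, 0.84),
        "late_hi": (0.28, 0.44), "rhi": (2.0, 1.3),
    },
    "parietal_wm": {
        "control": (0.60, 0.89), "early_hi": (1.4, 0.89),
        "late_hi": (1.00, 0.30), "rhi": (2.3, 0.82),
    },
}


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The published cohort: Control n=5, Early HI n=5, Late HI n=6, rHI n=6."""
    kwargs = dict(
        groups=(GroupSpec("control", 5), GroupSpec("early_hi", 5),
                GroupSpec("late_hi", 6), GroupSpec("rhi", 6)),
        endpoints=_DEFAULT_ENDPOINTS,
        score_latents=_DEFAULT_SCORE_LATENTS,
        ewe_sd=0.0,
        latent_loading=0.7,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def _twin_map(groups: Sequence[GroupSpec]) -> dict[str, list[tuple[str, str]]]:
    """Assign animals to ewes, pairing twins across treatment arms.

    Mirrors the experimental design: each ewe carried one fetus of the
    control + early-HI pair or of the late-HI + rHI pair.  Unpairable
    animals (unequal group sizes) get singleton ewes.
    """
    by_group = {g.name: [f"{g.name}_{i+1}" for i in range(g.n)] for g in groups}
    pairs = [("control", "early_hi"), ("late_hi", "rhi")]
    ewes: dict[str, list[tuple[str, str]]] = {}
    ewe_counter = 0
    used: set[str] = set()
    for ga, gb in pairs:
        if ga in by_group and gb in by_group:
            for a, b in zip(by_group[ga], by_group[gb]):
                ewe_counter += 1
                ewes[f"ewe_{ewe_counter:02d}"] = [(a, ga), (b, gb)]
                used.update((a, b))
    for g in groups:
        for aid in by_group[g.name]:
            if aid not in used:
                ewe_counter += 1
                ewes[f"ewe_{ewe_counter:02d}"] = [(aid, g.name)]
    return ewes


def simulate_cohort(spec: CohortSpec) -> list[AnimalRecord]:
    """Simulate one cohort of animals under the given design.

    Each endpoint value is ``group mean + ewe intercept + residual`` where
    the ewe intercept has SD ``ewe_sd * sd`` and the residual SD is chosen
    so the total SD equals the specified ``sd``.  The residual itself mixes
    a per-animal shared severity factor (loading ``latent_loading``) with an
    endpoint-specific deviate, so endpoints correlate within animals.
    Ordinal section scores come from a per-region latent severity value,
    jittered per section, rounded and clipped to 0..3.
    """
    rng = np.random.default_rng(spec.seed)
    ewes = _twin_map(spec.groups)

    ewe_u = {ewe: rng.standard_normal() for ewe in ewes}
    records: list[AnimalRecord] = []
    for ewe_id, members in ewes.items():
        for animal_id, group in members:
            z_shared = rng.standard_normal()
            lam = spec.latent_loading
            endpoints: dict[str, float] = {}
            for ep, per_group in spec.endpoints.items():
                if group not in per_group:
                    continue
                mu, sd = per_group[group]
                ewe_part = spec.ewe_sd * sd * ewe_u[ewe_id]
                resid_sd = sd * math.sqrt(max(0.0, 1.0 - spec.ewe_sd ** 2))
                eps = rng.standard_normal()
                resid = resid_sd * (lam * z_shared + math.sqrt(1 - lam ** 2) * eps)
                endpoints[ep] = mu + ewe_part + resid
            section_scores: dict[str, list[int]] = {}
            for region, per_group in spec.score_latents.items():
                if group not in per_group:
                    continue
                mu, sd = per_group[group]
                latent = mu + sd * (lam * z_shared
                                    + math.sqrt(1 - lam ** 2) * rng.standard_normal())
                scores = []
                for _ in range(spec.sections_per_region):
                    s = latent + rng.normal(0.0, spec.section_jitter_sd)
                    scores.append(int(np.clip(round(s), 0, 3)))
                section_scores[region] = scores
            records.append(AnimalRecord(
                animal_id=animal_id, ewe_id=ewe_id, group=group,
                endpoints=endpoints, section_scores=section_scores))
    return records


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def cohort_to_frame(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    """Cohort as a tidy table: one row per animal, one column per endpoint.

    Section scores are flattened into ``score_<region>_s<i>`` columns.
    """
    rows = []
    for r in records:
        row: dict[str, object] = {
            "animal_id": r.animal_id, "ewe_id": r.ewe_id, "group": r.group}
        row.update(r.endpoints)
        for region, scores in r.section_scores.items():
            for i, s in enumerate(scores, start=1):
                row[f"score_{region}_s{i}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: Sequence[AnimalRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[AnimalRecord]:
    df = pd.read_csv(path)
    score_cols = [c for c in df.columns if c.startswith("score_")]
    regions: dict[str, list[str]] = {}
    for c in score_cols:
        region = c[len("score_"):c.rindex("_s")]
        regions.setdefault(region, []).append(c)
    endpoint_cols = [c for c in df.columns
                     if c not in ("animal_id", "ewe_id", "group")
                     and c not in score_cols]
    records = []
    for _, row in df.iterrows():
        records.append(AnimalRecord(
            animal_id=str(row["animal_id"]),
            ewe_id=str(row["ewe_id"]),
            group=str(row["group"]),
            endpoints={c: float(row[c]) for c in endpoint_cols},
            section_scores={
                region: [int(row[c]) for c in sorted(cols)]
                for region, cols in regions.items()},
        ))
    return records


def write_image_tiff(image: SyntheticImage | np.ndarray, path) -> None:
    import tifffile
    arr = image.intensities if isinstance(image, SyntheticImage) else np.asarray(image)
    tifffile.imwrite(path, arr.astype(np.uint16))


def write_mask_png(mask: np.ndarray, path) -> None:
    import imageio.v3 as iio
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_spec_yaml(spec, path) -> None:
    from dataclasses import asdict
    with open(path, "w") as fh:
        yaml.safe_dump(_yamlable(asdict(spec)), fh, sort_keys=True)


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
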