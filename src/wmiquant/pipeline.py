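"""End-to-end orchestration: simulate -> quantify -> score -> test -> report.

``run_all`` drives the whole desk-scale analysis from one YAML-able config:
it simulates a twin cohort at the published group means, renders one
synthetic stained tile per group at that group's astrogliosis level and
re-estimates its area fraction, simulates one cell slab per group at the
group's preOL density and runs the optical fractionator over it, assembles
the ordinal-score report, and runs the statistical battery.  Every stage
writes plain CSV/JSON so each can also be consumed standalone, and the
whole run is byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import image_quant, scoring, stats, stereology, synthetic

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("wmiquant")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration for one full pipeline run.

    Image parameters intentionally default to a desk-scale tile (256 px,
    ball radius 50 px ~ 4x the largest structure) rather than the
    full-montage geometry; both are plain numbers here and can be raised
    for full-size runs.
    """

    seed: int = 0
    alpha: float = 0.05
    bonferroni_m: int | None = None
    ewe_sd: float = 0.0
    latent_loading: float = 0.7
    image_size_px: int = 256
    ball_radius_px: float = 50.0
    n_bins: int = 256
    image_noise_sd: float = 120.0
    image_contrast: float = 600.0
    slab_extent_um: tuple[float, float, float] = (1200.0, 1200.0, 40.0)
    pyknotic_fraction: float = 0.02
    write_images: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "slab_extent_um" in data:
            data["slab_extent_um"] = tuple(data["slab_extent_um"])
        return cls(**data)


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_all(config: RunConfig, outdir) -> Path:
    """Run every stage; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _subseeds(config.seed, 4)
    timings: dict[str, float] = {}

    # ---- stage 1: cohort -------------------------------------------------
    t0 = time.perf_counter()
    cohort_spec = synthetic.default_cohort_spec(
        seed=seeds[0], ewe_sd=config.ewe_sd,
        latent_loading=config.latent_loading)
    records = synthetic.simulate_cohort(cohort_spec)
    synthetic.write_cohort_csv(records, out / "cohort.csv")
    timings["cohort"] = time.perf_counter() - t0
    log.info("cohort: %d animals -> cohort.csv (%.2fs)",
             len(records), timings["cohort"])

    # ---- stage 2: images + area fractions --------------------------------
    t0 = time.perf_counter()
    af_results = {}
    gfap = cohort_spec.endpoints["gfap_af"]
    img_seeds = _subseeds(seeds[1], len(synthetic.GROUPS))
    for gname, iseed in zip(synthetic.GROUPS, img_seeds):
        mean_af = gfap[gname][0]
        spec = synthetic.ImageSpec(
            width_px=config.image_size_px, height_px=config.image_size_px,
            noise_sd=config.image_noise_sd, fg_contrast=config.image_contrast,
            fg_fraction=mean_af, fg_shape="filament", seed=iseed)
        img = synthetic.generate_image(spec)
        res = image_quant.area_fraction(
            img.intensities, ball_radius_px=config.ball_radius_px,
            n_bins=config.n_bins)
        af_results[gname] = {
            **res.to_dict(),
            "true_fraction": img.achieved_fraction,
            "abs_error": abs(res.area_fraction - img.achieved_fraction),
        }
        if config.write_images:
            synthetic.write_image_tiff(img, out / f"gfap_{gname}.tif")
            synthetic.write_mask_png(img.truth_mask, out / f"gfap_{gname}_mask.png")
    _json_dump(af_results, out / "area_fractions.json")
    timings["area_fractions"] = time.perf_counter() - t0
    log.info("area fractions for %d groups (%.2fs)",
             len(af_results), timings["area_fractions"])

    # ---- stage 3: stereology ---------------------------------------------
    t0 = time.perf_counter()
    design = stereology.SamplingDesign()
    o4 = cohort_spec.endpoints["o4_density"]
    stereo_results = {}
    field_seeds = _subseeds(seeds[2], len(synthetic.GROUPS))
    ex, ey, _ = config.slab_extent_um
    roi = [(0.0, 0.0), (ex - design.frame_w_um, 0.0),
           (ex - design.frame_w_um, ey - design.frame_h_um),
           (0.0, ey - design.frame_h_um)]
    for gname, fseed in zip(synthetic.GROUPS, field_seeds):
        field = synthetic.generate_cell_field(
            config.slab_extent_um, o4[gname][0],
            config.pyknotic_fraction, seed=fseed)
        sites = stereology.place_grid(roi, design, seed=fseed)
        counts = stereology.count_sites(field, sites, design)
        stereology.write_site_counts_csv(counts, out / f"o4_sites_{gname}.csv")
        est = stereology.estimate_density(counts, design)
        stereo_results[gname] = {
            "density_per_mm3": est.density_per_mm3,
            "ce": est.ce,
            "n_sites": est.n_sites,
            "sum_q": est.sum_q,
            "pyknotic_pct": est.pyknotic_pct,
            "true_density_per_mm3": field.true_density,
        }
    stereology.write_design_yaml(design, out / "design.yaml")
    _json_dump(stereo_results, out / "stereology.json")
    timings["stereology"] = time.perf_counter() - t0
    log.info("stereology for %d groups (%.2fs)",
             len(stereo_results), timings["stereology"])

    # ---- stage 4: scoring ------------------------------------------------
    t0 = time.perf_counter()
    _json_dump(scoring.score_report(records), out / "scoring.json")
    timings["scoring"] = time.perf_counter() - t0

    # ---- stage 5: statistics --------------------------------------------
    t0 = time.perf_counter()
    battery = stats.run_full_battery(records, stats.BatteryConfig(
        alpha=config.alpha, bonferroni_m=config.bonferroni_m))
    _json_dump(battery, out / "stats.json")
    timings["stats"] = time.perf_counter() - t0

    # ---- stage 6: summary table ------------------------------------------
    rows = ["endpoint,group,n,mean,sd"]
    for ep, entry in sorted(battery["endpoints"].items()):
        for gname in synthetic.GROUPS:
            if gname in entry["groups"]:
                g = entry["groups"][gname]
                rows.append(f"{ep},{gname},{g['n']},{g['mean']:.6g},{g['sd']:.6g}")
    (out / "summary.csv").write_text("\n".join(rows) + "\n")

    log.info("run complete: %s", out)
    return out
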