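"""Ordinal neuropathology scales and their aggregation rules.

White-matter injury is graded per section by the percentage of white matter
showing necrosis (0: none; 1: 1-25%; 2: 26-50%; 3: >50%).  Gray-matter
injury uses a 4-point composite scale (0 normal .. 3 extensive injury or
translaminar cortical necrosis) combined across H&E and Iba-1 stains.
Scores from the three near-adjacent sections of a region are averaged, and
severe pathology is defined as an average score of 2 or greater.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .synthetic import AnimalRecord

__all__ = [
    "WHITE_MATTER_REGIONS",
    "GRAY_MATTER_REGIONS",
    "RegionAssessment",
    "necrosis_percent_to_score",
    "gray_matter_composite",
    "aggregate_region",
    "severe_group_share",
    "score_report",
]

WHITE_MATTER_REGIONS = ("frontal_wm", "parietal_wm")
GRAY_MATTER_REGIONS = ("frontal_ctx", "parietal_ctx", "thalamus")
SEVERE_THRESHOLD = 2.0


@dataclass(frozen=True)
class RegionAssessment:
    region: str
    section_scores: tuple[int, ...]
    mean_score: float
    severe: bool


def necrosis_percent_to_score(percent: float) -> int:
    """Map percent necrotic white matter to the 0-3 ordinal score.

    Bands are 0 -> 0; (0, 25] -> 1; (25, 50] -> 2; (50, 100] -> 3.  Exactly
    zero necrosis scores 0; the band edges at 25 and 50 belong to the lower
    band so that "greater than 50%" starts strictly above 50.
    """
    p = float(percent)
    if not 0.0 <= p <= 100.0:
        raise ValueError("percent must lie in [0, 100]")
    if p == 0.0:
        return 0
    if p <= 25.0:
        return 1
    if p <= 50.0:
        return 2
    return 3


def gray_matter_composite(stain_scores: dict[str, int], rule: str = "max") -> int:
    """Combine per-stain (H&E, Iba-1) gray-matter scores into one composite.

    ``rule='max'`` (default) takes the worse of the two stains;
    ``rule='mean'`` rounds the stain average to the nearest integer.
    """
    vals = [int(v) for v in stain_scores.values()]
    if not vals:
        raise ValueError("no stain scores given")
    if any(v not in (0, 1, 2, 3) for v in vals):
        raise ValueError("scores must be integers in 0..3")
    if rule == "max":
        return max(vals)
    if rule == "mean":
        return int(np.clip(round(float(np.mean(vals))), 0, 3))
    raise ValueError("rule must be 'max' or 'mean'")


def aggregate_region(scores: Sequence[int], region: str = "frontal_wm") -> RegionAssessment:
    """Average section scores and flag severe pathology (mean >= 2)."""
    vals = [int(s) for s in scores]
    if not vals:
        raise ValueError("no section scores")
    if any(v not in (0, 1, 2, 3) for v in vals):
        raise ValueError("scores must be integers in 0..3")
    mean = float(np.mean(vals))
    return RegionAssessment(
        region=region,
        section_scores=tuple(vals),
        mean_score=mean,
        severe=mean >= SEVERE_THRESHOLD,
    )


def severe_group_share(records: Sequence[AnimalRecord],
                       region: str) -> dict[str, float] | None:
    """Per-group percentage of the severely injured animals.

    For each treatment group the share is (severe animals in the group) /
    (severe animals overall) x 100, so the shares sum to 100.  Returns
    ``None`` when no animal is severe (the share is undefined).
    """
    severe_groups = []
    for r in records:
        scores = r.section_scores.get(region)
        if scores is None:
            continue
        if aggregate_region(scores, region).severe:
            severe_groups.append(r.group)
    if not severe_groups:
        return None
    total = len(severe_groups)
    groups = sorted({r.group for r in records})
    return {g: 100.0 * severe_groups.count(g) / total for g in groups}


def score_report(records: Sequence[AnimalRecord]) -> dict:
    """Per-animal region assessments plus per-region severe-group shares."""
    regions = sorted({reg for r in records for reg in r.section_scores})
    animals = {}
    for r in records:
        animals[r.animal_id] = {
            reg: {
                "section_scores": list(map(int, r.section_scores[reg])),
                "mean_score": aggregate_region(r.section_scores[reg], reg).mean_score,
                "severe": aggregate_region(r.section_scores[reg], reg).severe,
            }
            for reg in r.section_scores
        }
    shares = {reg: severe_group_share(records, reg) for reg in regions}
    return {"animals": animals, "severe_group_share_pct": shares}
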