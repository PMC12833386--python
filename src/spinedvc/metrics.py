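"""Landmark-based clinical measures of disc geometry and sagittal alignment.

All measures operate on explicit mid-sagittal landmark coordinates (mm), the
way a clinician would place calipers in a viewer:

* disc heights — distances between paired endplate rim points, measured
  orthogonal to the mid-disc plane (the bisector of the two bounding
  endplate lines), at the anterior, central and posterior sites; the
  anterior:posterior ratio divides anterior by posterior height;
* segmental lordosis — Cobb angle between the superior endplate of the
  superior vertebra and the inferior endplate of the inferior vertebra,
  positive when the lines converge posteriorly (lordotic);
* lumbar lordosis — angle between the superior endplates of L1 and S1;
* lumbar height — distance from the most anterior point of the superior L1
  endplate to the corresponding point of the superior S1 endplate;
* sacral angle — tilt of the superior S1 endplate against the horizontal
  reference, positive for the usual anterior-up slope;
* Pfirrmann consensus — rounded average of three ratings, binned as
  non-degenerated (1–2), degenerated (3), severely degenerated (4–5).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkSet

__all__ = [
    "DiscHeights",
    "SpineMetrics",
    "disc_heights",
    "segmental_lordosis",
    "global_metrics",
    "pfirrmann_consensus",
    "measure_all",
]


class GeometryError(ValueError):
    pass


class MissingLandmarkError(KeyError):
    pass


@dataclass(frozen=True)
class DiscHeights:
    anterior: float
    central: float
    posterior: float

    @property
    def ap_ratio(self) -> float:
        return self.anterior / self.posterior

    @property
    def average(self) -> float:
        """Mean of the three measurement sites (the regression predictor)."""
        return (self.anterior + self.central + self.posterior) / 3.0


def _split_level(level: str) -> tuple[str, str]:
    try:
        sup, inf = level.split("-")
    except ValueError:
        raise ValueError(f"disc level must look like 'L4-L5', got {level!r}") from None
    return sup, inf


def _line_angle(anterior: np.ndarray, posterior: np.ndarray,
                horizontal: np.ndarray) -> float:
    """Signed angle (rad) of the anterior→posterior direction vs horizontal."""
    d = posterior - anterior
    if np.linalg.norm(d) < 1e-9:
        raise GeometryError("coincident endplate rim points")
    h = horizontal
    return float(np.arctan2(d[0] * h[1] - d[1] * h[0], d @ h)) * -1.0


def disc_heights(landmarks: LandmarkSet, level: str) -> DiscHeights:
    """Anterior/central/posterior disc heights (mm), orthogonal to the
    mid-disc plane."""
    sup_v, inf_v = _split_level(level)
    for v in (sup_v, inf_v):
        if not landmarks.has_endplates(v):
            raise MissingLandmarkError(f"endplate landmarks missing for {v!r}")
    ua, up = landmarks.endplate(sup_v, "inf")    # lower endplate of upper vertebra
    la, lp = landmarks.endplate(inf_v, "sup")    # upper endplate of lower vertebra

    def unit(v: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise GeometryError("degenerate endplate line")
        return v / n

    d_sup = unit(up - ua)
    d_inf = unit(lp - la)
    if d_sup @ d_inf < 0:
        d_inf = -d_inf
    bisector = unit(d_sup + d_inf)               # mid-disc plane direction
    normal = np.array([-bisector[1], bisector[0]])
    heights = []
    for upper, lower in ((ua, la), (0.5 * (ua + up), 0.5 * (la + lp)), (up, lp)):
        heights.append(abs(float((upper - lower) @ normal)))
    ant, cent, post = heights
    if post <= 0 or ant <= 0:
        raise GeometryError(f"non-positive disc height at level {level}")
    return DiscHeights(ant, cent, post)


def segmental_lordosis(landmarks: LandmarkSet, level: str) -> float:
    """Cobb angle of a segment in degrees, positive = lordotic.

    Uses the superior endplate of the superior vertebra and the inferior
    endplate of the inferior vertebra; for concave endplates the rims are by
    construction the line through the anterior and posterior extremities.
    """
    sup_v, inf_v = _split_level(level)
    a_sup = _line_angle(*landmarks.endplate(sup_v, "sup"), landmarks.horizontal)
    a_inf = _line_angle(*landmarks.endplate(inf_v, "inf"), landmarks.horizontal)
    return float(np.degrees(a_inf - a_sup))


def global_metrics(landmarks: LandmarkSet, top: str = "L1", bottom: str = "S1",
                   ) -> "SpineMetricsGlobal":
    """Lumbar lordosis (deg), lumbar height (mm) and sacral angle (deg)."""
    for name in (f"{top}:sup_ant", f"{top}:sup_post",
                 f"{bottom}:sup_ant", f"{bottom}:sup_post"):
        if name not in landmarks:
            raise MissingLandmarkError(name)
    a_top = _line_angle(*landmarks.endplate(top, "sup"), landmarks.horizontal)
    a_bot = _line_angle(*landmarks.endplate(bottom, "sup"), landmarks.horizontal)
    lordosis = float(np.degrees(a_bot - a_top))
    height = float(np.linalg.norm(landmarks[f"{top}:sup_ant"]
                                  - landmarks[f"{bottom}:sup_ant"]))
    sacral = float(np.degrees(a_bot))
    return SpineMetricsGlobal(lordosis, height, sacral)


@dataclass(frozen=True)
class SpineMetricsGlobal:
    lumbar_lordosis_deg: float
    lumbar_height_mm: float
    sacral_angle_deg: float


_BINS = {1: "ND", 2: "ND", 3: "D", 4: "SD", 5: "SD"}


def pfirrmann_consensus(grades) -> tuple[int, str]:
    """Consensus of three Pfirrmann ratings: rounded average, then bin.

    Averages are rounded half away from zero (a 2.5 consensus, possible only
    with even rater counts, becomes 3); with three integer raters the mean
    only hits thirds, which round unambiguously.
    """
    grades = list(grades)
    if any(g not in (1, 2, 3, 4, 5) for g in grades):
        raise ValueError(f"Pfirrmann ratings must be integers 1-5, got {grades}")
    mean = sum(grades) / len(grades)
    grade = int(np.floor(mean + 0.5))
    return grade, _BINS[grade]


@dataclass
class SpineMetrics:
    """All clinical measures for one landmark set."""

    levels: dict[str, dict[str, float]]
    lumbar_lordosis_deg: float
    lumbar_height_mm: float
    sacral_angle_deg: float


def measure_all(landmarks: LandmarkSet, levels: list[str],
                top: str = "L1", bottom: str = "S1") -> SpineMetrics:
    """Per-level heights/ratio/lordosis plus the global alignment measures."""
    out: dict[str, dict[str, float]] = {}
    for level in levels:
        h = disc_heights(landmarks, level)
        out[level] = {
            "anterior_height": h.anterior,
            "central_height": h.central,
            "posterior_height": h.posterior,
            "ap_ratio": h.ap_ratio,
            "avg_disc_height": h.average,
            "segmental_lordosis_deg": segmental_lordosis(landmarks, level),
        }
    g = global_metrics(landmarks, top=top, bottom=bottom)
    return SpineMetrics(out, g.lumbar_lordosis_deg, g.lumbar_height_mm,
                        g.sacral_angle_deg)
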