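"""Mid-sagittal landmark sets for clinical spine measurements.

Landmarks are 2-D points (mm) in the sagittal plane with the package axis
convention: first coordinate anterior–posterior (+posterior), second
cranial–caudal (+cranial).  Point names follow the pattern

* ``<vertebra>:sup_ant`` / ``sup_post`` — superior-endplate anterior/posterior rim,
* ``<vertebra>:inf_ant`` / ``inf_post`` — inferior-endplate rim,
* ``<disc>:ant`` / ``cent`` / ``post``  — disc measurement sites.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["LandmarkSet"]

_ENDPLATE_KEYS = ("sup_ant", "sup_post", "inf_ant", "inf_post")


@dataclass
class LandmarkSet:
    """Named mid-sagittal points plus the horizontal reference direction."""

    points: dict[str, np.ndarray]
    horizontal: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        self.horizontal = np.asarray(self.horizontal, dtype=float)
        for name, p in self.points.items():
            if p.shape != (2,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} must be a finite 2-vector")
        n = np.linalg.norm(self.horizontal)
        if n == 0:
            raise ValueError("horizontal reference must be non-zero")
        self.horizontal = self.horizontal / n

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise KeyError(f"missing landmark {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def endplate(self, vertebra: str, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(anterior, posterior) rim points of ``sup`` or ``inf`` endplate."""
        if which not in ("sup", "inf"):
            raise ValueError("which must be 'sup' or 'inf'")
        return self[f"{vertebra}:{which}_ant"], self[f"{vertebra}:{which}_post"]

    def has_endplates(self, vertebra: str) -> bool:
        return all(f"{vertebra}:{k}" in self.points for k in _ENDPLATE_KEYS)

    def transformed(self, rotation_deg: float = 0.0,
                    translation: tuple[float, float] = (0.0, 0.0),
                    rotate_horizontal: bool = False) -> "LandmarkSet":
        """Rigidly transformed copy (rotation about the origin, then shift)."""
        a = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        pts = {k: rot @ v + np.asarray(translation, float)
               for k, v in self.points.items()}
        horiz = rot @ self.horizontal if rotate_horizontal else self.horizontal
        return LandmarkSet(pts, horiz)

    def save(self, path: str | Path) -> None:
        payload = {
            "horizontal": self.horizontal.tolist(),
            "points": {k: v.tolist() for k, v in self.points.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkSet":
        payload = json.loads(Path(path).read_text())
        return cls({k: np.asarray(v) for k, v in payload["points"].items()},
                   np.asarray(payload["horizontal"]))
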