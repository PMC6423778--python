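"""Cytokine-array membrane densitometry.

A membrane carries a grid of antibody spots, each capturing one analyte,
plus reference spots at three positions (upper-left, lower-left and
lower-right corners) that define the 100% intensity scale.  Spot density
is the background-subtracted integrated pixel intensity inside the spot
disc; analytes are reported as percent of the mean reference density and
classified as abundant (> 20%), secreted (> 5%) or not secreted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NOT_SECRETED = "not_secreted"
SECRETED = "secreted"
ABUNDANT = "abundant"
CLASS_ORDER = {NOT_SECRETED: 0, SECRETED: 1, ABUNDANT: 2}

SECRETED_THRESHOLD = 5.0  # percent of reference, strict
ABUNDANT_THRESHOLD = 20.0  # percent of reference, strict


class LayoutError(ValueError):
    """Raised for inconsistent membrane layouts."""


class MembraneError(ValueError):
    """Raised when a membrane cannot be quantified (e.g. dead references)."""


@dataclass(frozen=True)
class Spot:
    analyte: str
    row: int
    col: int
    x: float
    y: float
    radius: float
    is_reference: bool = False


@dataclass
class MembraneLayout:
    """Spot layout of one membrane.

    Reference spots must occupy exactly three positions, identified by
    distinct analyte labels (duplicate spots of one position share a
    label and are averaged at the raw-density stage).  Spot discs must be
    pairwise disjoint.
    """

    spots: list[Spot]

    def __post_init__(self) -> None:
        ref_labels = {s.analyte for s in self.spots if s.is_reference}
        if len(ref_labels) != 3:
            raise LayoutError(
                f"expected reference spots at 3 positions, got {len(ref_labels)}"
            )
        for i, a in enumerate(self.spots):
            for b in self.spots[i + 1 :]:
                d = np.hypot(a.x - b.x, a.y - b.y)
                if d < a.radius + b.radius:
                    raise LayoutError(
                        f"overlapping spot discs: {a.analyte} and {b.analyte}"
                    )

    @property
    def reference_labels(self) -> set[str]:
        return {s.analyte for s in self.spots if s.is_reference}

    @property
    def analytes(self) -> list[str]:
        """Non-reference analyte labels in layout order, deduplicated."""
        seen: dict[str, None] = {}
        for s in self.spots:
            if not s.is_reference:
                seen.setdefault(s.analyte, None)
        return list(seen)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                (s.analyte, s.row, s.col, s.x, s.y, s.radius, int(s.is_reference))
                for s in self.spots
            ],
            columns=["analyte", "row", "col", "x", "y", "radius", "is_reference"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MembraneLayout":
        df = pd.read_csv(path)
        spots = [
            Spot(
                str(r.analyte),
                int(r.row),
                int(r.col),
                float(r.x),
                float(r.y),
                float(r.radius),
                bool(r.is_reference),
            )
            for r in df.itertuples()
        ]
        return cls(spots)


@dataclass
class CytokineProfile:
    """Per-analyte densitometry result for one membrane."""

    raw_density: dict[str, float]
    percent_of_reference: dict[str, float]
    classes: dict[str, str]
    reference_percent: dict[str, float] = field(default_factory=dict)

    @property
    def analytes(self) -> list[str]:
        return list(self.percent_of_reference)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "raw_density": self.raw_density,
                "percent_of_reference": self.percent_of_reference,
                "class": self.classes,
            }
        )


def quantify_spots(
    image: np.ndarray, layout: MembraneLayout
) -> dict[str, float]:
    """Background-subtracted integrated density per analyte.

    For each spot the density is the pixel sum inside the disc minus the
    disc area times the local background, estimated as the median in an
    annulus of inner radius r and outer radius 2r.  If a spot's annulus
    overlaps another spot's disc, its background falls back to the global
    image median (with a warning).  Negative densities are clipped to 0;
    duplicate spots of one analyte are averaged.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    global_median = float(np.median(img))

    per_spot: dict[str, list[float]] = {}
    for spot in layout.spots:
        if not (0 <= spot.x < w and 0 <= spot.y < h):
            raise LayoutError(f"spot {spot.analyte} outside image bounds")
        r2 = (xx - spot.x) ** 2 + (yy - spot.y) ** 2
        disc = r2 <= spot.radius**2
        annulus = (r2 > spot.radius**2) & (r2 <= (2 * spot.radius) ** 2)
        if _annulus_hits_other_disc(spot, layout):
            warnings.warn(
                f"annulus of {spot.analyte} overlaps another spot; "
                "using global median background",
                stacklevel=2,
            )
            bg = global_median
        else:
            bg = float(np.median(img[annulus]))
        density = float(img[disc].sum() - disc.sum() * bg)
        per_spot.setdefault(spot.analyte, []).append(max(density, 0.0))
    return {a: float(np.mean(v)) for a, v in per_spot.items()}


def _annulus_hits_other_disc(spot: Spot, layout: MembraneLayout) -> bool:
    for other in layout.spots:
        if other is spot:
            continue
        d = np.hypot(other.x - spot.x, other.y - spot.y)
        if d < 2 * spot.radius + other.radius:
            return True
    return False


def percent_of_reference(
    raw: dict[str, float], layout: MembraneLayout
) -> dict[str, float]:
    """Express densities as percent of the mean reference density.

    The three reference positions are averaged (duplicates within each
    position were already averaged at the raw-density stage).  Reference
    spots themselves therefore report close to 100.
    """
    refs = [raw[a] for a in layout.reference_labels if a in raw]
    if not refs:
        raise MembraneError("no reference spot densities available")
    ref_mean = float(np.mean(refs))
    if ref_mean <= 0:
        raise MembraneError("all reference densities <= 0: failed membrane")
    return {a: 100.0 * d / ref_mean for a, d in raw.items()}


def classify(percent: float) -> str:
    """Class from percent-of-reference; bounds strict as published."""
    if percent < 0:
        raise ValueError("percent must be nonnegative")
    if percent > ABUNDANT_THRESHOLD:
        return ABUNDANT
    if percent > SECRETED_THRESHOLD:
        return SECRETED
    return NOT_SECRETED


def quantify_membrane(
    image: np.ndarray, layout: MembraneLayout
) -> CytokineProfile:
    """Full per-membrane pipeline: densitometry, normalization, classes."""
    raw = quantify_spots(image, layout)
    percent = percent_of_reference(raw, layout)
    ref_labels = layout.reference_labels
    analyte_percent = {a: p for a, p in percent.items() if a not in ref_labels}
    return CytokineProfile(
        raw_density={a: raw[a] for a in analyte_percent},
        percent_of_reference=analyte_percent,
        classes={a: classify(p) for a, p in analyte_percent.items()},
        reference_percent={a: percent[a] for a in ref_labels},
    )


@dataclass
class ProfileComparison:
    shared: set[str]
    exclusive: dict[str, set[str]]
    class_floor: str


def compare_profiles(
    profiles: dict[str, CytokineProfile], class_floor: str = ABUNDANT
) -> ProfileComparison:
    """Shared and exclusive analytes at or above a class floor.

    ``shared`` holds analytes whose class reaches ``class_floor`` in every
    preparation; each preparation's ``exclusive`` set holds analytes
    reaching the floor only there.
    """
    if class_floor not in CLASS_ORDER:
        raise ValueError(f"unknown class {class_floor!r}")
    preps = list(profiles)
    if not preps:
        raise ValueError("no profiles to compare")
    analyte_sets = [set(profiles[p].analytes) for p in preps]
    if any(s != analyte_sets[0] for s in analyte_sets):
        raise LayoutError("profiles do not share a layout")
    floor = CLASS_ORDER[class_floor]
    above = {
        p: {
            a
            for a in profiles[p].analytes
            if CLASS_ORDER[profiles[p].classes[a]] >= floor
        }
        for p in preps
    }
    shared = set.intersection(*above.values())
    exclusive = {
        p: above[p] - set.union(set(), *(above[q] for q in preps if q != p))
        for p in preps
    }
    return ProfileComparison(shared=shared, exclusive=exclusive, class_floor=class_floor)
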