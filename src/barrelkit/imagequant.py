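"""Barrel–septa contrast and puncta-per-cell quantification.

A tangential barrel-cortex section is measured through three ROI groups:
5–6 hand-drawn barrel ROIs, one enclosing ROI covering those barrels plus
the surrounding septa up to the edges of adjacent barrels, and 0–3
background ROIs in low-signal territory.  Septa intensity is the
enclosing ROI's *integrated* intensity minus the summed barrel integrated
intensities, divided by the septa pixel area (subtracting mean
intensities directly would be dimensionally inconsistent when areas
differ).  The segregation statistic is the contrast index

    contrast = (barrel - septa) / (barrel + septa)

on mean intensities, which needs no background correction because it is a
ratio; absolute barrel/septa intensities are reported normalized to the
mean of the background ROI means.  Section values are averaged per animal
(typically two sections).

For RNAscope data, each RNA punctum is associated with the nearest cell
centroid (Euclidean distance, ties broken by smallest cell id), counts
are tallied per cell (zero-count cells included), and means are taken per
layer per image, then per animal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.draw import polygon2mask

__all__ = [
    "RoiSet",
    "SectionMeasurement",
    "measure_rois",
    "septa_mean",
    "contrast_index",
    "normalize_to_background",
    "quantify_section",
    "aggregate_per_animal",
    "assign_puncta",
    "tally_puncta",
    "roi_set_from_polygons",
]


@dataclass
class RoiSet:
    """Barrel / enclosing / background ROI masks for one tissue section.

    Masks are boolean arrays of the image shape.  Every barrel ROI must
    lie inside the enclosing ROI, barrel ROIs are pairwise disjoint, and
    background ROIs must not touch the enclosing ROI.
    """

    barrel_rois: list[np.ndarray]
    enclosing_roi: np.ndarray
    background_rois: list[np.ndarray] = field(default_factory=list)
    section_id: str = ""
    animal_id: str = ""
    genotype: str = ""
    age: str = ""

    def __post_init__(self) -> None:
        shape = self.enclosing_roi.shape
        for m in [*self.barrel_rois, *self.background_rois]:
            if m.shape != shape:
                raise ValueError("all ROI masks must share one image shape")
        acc = np.zeros(shape, dtype=int)
        for m in self.barrel_rois:
            if not m.any():
                raise ValueError("empty barrel ROI")
            if (m & ~self.enclosing_roi).any():
                raise ValueError("barrel ROI extends outside the enclosing ROI")
            acc += m
        if (acc > 1).any():
            raise ValueError("barrel ROIs overlap")
        for m in self.background_rois:
            if not m.any():
                raise ValueError("empty background ROI")
            if (m & self.enclosing_roi).any():
                raise ValueError("background ROI overlaps the enclosing ROI")
        if not self.enclosing_roi.any():
            raise ValueError("empty enclosing ROI")


@dataclass(frozen=True)
class SectionMeasurement:
    """Derived intensities and contrast for one section, one channel."""

    section_id: str
    animal_id: str
    genotype: str
    age: str
    channel: str
    barrel_mean: float
    septa_mean: float
    contrast: float
    barrel_norm: float | None = None
    septa_norm: float | None = None


def measure_rois(image: np.ndarray, rois: Sequence[np.ndarray]) -> pd.DataFrame:
    """Per-ROI mean, integrated sum and pixel area.

    Mean is defined as integrated sum / area; an empty ROI or one that
    does not match the image shape is rejected.
    """
    image = np.asarray(image, dtype=float)
    rows = []
    for i, m in enumerate(rois):
        if m.shape != image.shape:
            raise ValueError(f"ROI {i} shape {m.shape} does not match image {image.shape}")
        area = int(m.sum())
        if area == 0:
            raise ValueError(f"ROI {i} is empty")
        total = float(image[m].sum())
        rows.append({"roi": i, "mean": total / area, "sum": total, "area": area})
    return pd.DataFrame(rows)


def septa_mean(
    enclosing_sum: float,
    enclosing_area: float,
    barrel_sums: Sequence[float],
    barrel_areas: Sequence[float],
) -> float:
    """Mean septa intensity: (enclosing sum - sum of barrel sums) over the septa area.

    The septa territory is the enclosing ROI minus the barrel ROIs, so the
    septa integrated intensity is the enclosing integrated intensity minus
    the barrel integrated intensities, and its mean divides by the
    remaining pixel area.
    """
    s = enclosing_sum - float(np.sum(barrel_sums))
    area = enclosing_area - float(np.sum(barrel_areas))
    if area <= 0:
        raise ValueError("barrel ROIs tile the entire enclosing ROI (zero septa area)")
    return s / area


def contrast_index(barrel_mean: float, septa_mean: float) -> float:
    """(barrel - septa) / (barrel + septa); in [-1, 1] for non-negative means."""
    denom = barrel_mean + septa_mean
    if denom == 0:
        raise ValueError("undefined contrast: barrel + septa = 0")
    return (barrel_mean - septa_mean) / denom


def normalize_to_background(value: float, background_means: Sequence[float]) -> float:
    """Divide by the arithmetic mean of the background-ROI means."""
    bg = np.asarray(background_means, dtype=float)
    if bg.size == 0:
        raise ValueError("at least one background ROI is required")
    m = float(bg.mean())
    if m <= 0:
        raise ValueError("background mean must be positive")
    return value / m


def quantify_section(
    image: np.ndarray,
    roiset: RoiSet,
    channel: str = "",
    background_subtract_contrast: bool = False,
) -> SectionMeasurement:
    """Full per-section quantification from an image and its ROI set.

    Contrast is computed on raw means (it is a ratio and needs no
    background correction); the optional ``background_subtract_contrast``
    extension subtracts the background mean from both terms first.
    Normalized intensities are reported only when background ROIs exist.
    """
    barrels = measure_rois(image, roiset.barrel_rois) if roiset.barrel_rois else pd.DataFrame(columns=["mean", "sum", "area"])
    enc = measure_rois(image, [roiset.enclosing_roi]).iloc[0]
    area_w_mean = float(barrels["sum"].sum() / barrels["area"].sum()) if len(barrels) else float("nan")
    s_mean = septa_mean(enc["sum"], enc["area"], barrels["sum"].to_list(), barrels["area"].to_list())

    bg_means: list[float] = []
    if roiset.background_rois:
        bg_means = measure_rois(image, roiset.background_rois)["mean"].to_list()

    b, s = area_w_mean, s_mean
    if background_subtract_contrast:
        if not bg_means:
            raise ValueError("background-subtracted contrast needs background ROIs")
        bg = float(np.mean(bg_means))
        b, s = b - bg, s - bg
    return SectionMeasurement(
        section_id=roiset.section_id,
        animal_id=roiset.animal_id,
        genotype=roiset.genotype,
        age=roiset.age,
        channel=channel,
        barrel_mean=area_w_mean,
        septa_mean=s_mean,
        contrast=contrast_index(b, s),
        barrel_norm=normalize_to_background(area_w_mean, bg_means)
        if bg_means and np.mean(bg_means) > 0
        else None,
        septa_norm=normalize_to_background(s_mean, bg_means)
        if bg_means and np.mean(bg_means) > 0
        else None,
    )


def aggregate_per_animal(sections: pd.DataFrame) -> pd.DataFrame:
    """Average section measurements per animal (and channel, if present).

    Expects one row per section with at least ``animal_id`` plus numeric
    measurement columns; ``genotype`` and ``age`` are carried through as
    grouping keys.  Warns when an animal contributes a number of sections
    other than two (the study's convention).
    """
    keys = [k for k in ("animal_id", "genotype", "age", "channel") if k in sections.columns]
    if "animal_id" not in keys:
        raise ValueError("sections table needs an animal_id column")
    num_cols = [c for c in sections.columns if c not in keys and pd.api.types.is_numeric_dtype(sections[c])]
    grouped = sections.groupby(keys, dropna=False)
    counts = grouped.size()
    odd = counts[counts != 2]
    if len(odd):
        warnings.warn(
            f"{len(odd)} animal group(s) do not have exactly two sections", stacklevel=2
        )
    out = grouped[num_cols].mean().reset_index()
    out["n_sections"] = counts.to_numpy()
    return out


def assign_puncta(
    cells: pd.DataFrame,
    puncta: pd.DataFrame,
    max_distance: float | None = None,
) -> np.ndarray:
    """Nearest-cell assignment of RNA puncta by centroid distance.

    ``cells`` needs columns cell_id, x, y; ``puncta`` needs x, y.  Each
    punctum is assigned the cell with minimum Euclidean distance; exact
    ties go to the smallest cell_id.  With ``max_distance`` set, puncta
    farther than the cap from every cell get -1 (off by default: the
    quantification has no distance cap).  Returns an array of cell ids.
    """
    if len(cells) == 0:
        raise ValueError("no cells to assign puncta to")
    order = cells.sort_values("cell_id").reset_index(drop=True)
    xy = order[["x", "y"]].to_numpy(dtype=float)
    pxy = puncta[["x", "y"]].to_numpy(dtype=float)
    if not (np.isfinite(xy).all() and np.isfinite(pxy).all()):
        raise ValueError("coordinates must be finite")
    ids = order["cell_id"].to_numpy()
    if len(pxy) == 0:
        return np.array([], dtype=ids.dtype)
    tree = cKDTree(xy)
    dist, idx = tree.query(pxy)
    out = ids[idx].copy()
    # resolve exact ties deterministically toward the smallest cell_id
    for i, p in enumerate(pxy):
        cands = tree.query_ball_point(p, r=dist[i] * (1 + 1e-9) + 1e-12)
        if len(cands) > 1:
            d2 = ((xy[cands] - p) ** 2).sum(axis=1)
            best = d2.min()
            winners = [ids[cands[j]] for j in np.nonzero(d2 == best)[0]]
            out[i] = min(winners)
    if max_distance is not None:
        out = np.where(dist <= max_distance, out, -1)
    return out


def tally_puncta(
    cells: pd.DataFrame,
    assignments: np.ndarray,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Puncta-per-cell counts and layer means per image, then per animal.

    ``cells`` needs cell_id, layer and, optionally, image_id/animal_id
    label columns.  Cells receiving no punctum count as zero.  Returns
    ``(per_cell_counts, per_image_means, per_animal_means)``.
    """
    counts = pd.Series(0, index=cells["cell_id"], name="n_puncta", dtype=int)
    assigned = pd.Series(assignments)
    assigned = assigned[assigned != -1]
    vc = assigned.value_counts()
    counts.loc[vc.index] = vc.to_numpy()

    tab = cells.copy()
    tab["n_puncta"] = counts.to_numpy()
    img_keys = [k for k in ("animal_id", "genotype", "image_id", "layer") if k in tab.columns]
    if "layer" not in img_keys:
        raise ValueError("cells table needs a layer column")
    per_image = tab.groupby(img_keys, dropna=False)["n_puncta"].mean().reset_index()
    per_image = per_image.rename(columns={"n_puncta": "mean_puncta_per_cell"})
    animal_keys = [k for k in ("animal_id", "genotype", "layer") if k in per_image.columns]
    per_animal = (
        per_image.groupby(animal_keys, dropna=False)["mean_puncta_per_cell"].mean().reset_index()
        if animal_keys
        else per_image
    )
    return counts, per_image, per_animal


def roi_set_from_polygons(
    spec: dict,
    image_shape: tuple[int, int],
    **labels,
) -> RoiSet:
    """Build an RoiSet from JSON-style polygons.

    ``spec`` maps {"barrels": [poly, ...], "enclosing": poly,
    "background": [poly, ...]} where each polygon is a list of (row, col)
    vertices.  Polygons are rasterized with scikit-image's polygon fill,
    which includes pixels whose centers fall inside the polygon.
    """
    def rast(poly):
        return polygon2mask(image_shape, np.asarray(poly, dtype=float))

    return RoiSet(
        barrel_rois=[rast(p) for p in spec.get("barrels", [])],
        enclosing_roi=rast(spec["enclosing"]),
        background_rois=[rast(p) for p in spec.get("background", [])],
        **labels,
    )
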