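"""Length-normalized T2 distribution profiling of a masked tendon.

Given a voxelwise T2 map and a tendon mask running from the lateral
(footprint) insertion to the medial musculotendinous junction, this module

1. filters the map to suppress noise and partial-volume voxels (bone has
   very short T2 and low signal; bursal fluid very long T2),
2. assigns every mask voxel a normalized along-tendon coordinate in
   [0, 100] percent of tendon length via geodesic distance inside the mask,
3. bins mean T2 against that coordinate (the T2 distribution profile), and
4. splits the tendon into lateral / middle / medial thirds and summarizes
   mean +/- SD T2 per segment.

Because profiles live on the normalized coordinate, tendons of different
physical length — or the same tendon at two visits — are directly
comparable without image registration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .relaxometry import T2Map

__all__ = [
    "SEGMENT_NAMES",
    "TendonMask",
    "LengthField",
    "T2Profile",
    "SegmentSummary",
    "FilterReport",
    "filter_t2_map",
    "parameterize_length",
    "bin_profile",
    "split_segments",
    "segment_means",
]

logger = logging.getLogger(__name__)

SEGMENT_NAMES = ("lateral", "middle", "medial")
_THIRD = 100.0 / 3.0

DEFAULT_T2_BOUNDS = (5.0, 120.0)
DEFAULT_R2_MIN = 0.7


@dataclass
class TendonMask:
    """Binary tendon mask with its two anatomical end seeds.

    ``lateral_seed`` marks the footprint (insertion) end, ``medial_seed``
    the musculotendinous junction.  The mask must be one 8-connected
    component containing both seeds.
    """

    voxels: np.ndarray
    lateral_seed: tuple[int, int]
    medial_seed: tuple[int, int]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        for name in ("lateral_seed", "medial_seed"):
            r, c = getattr(self, name)
            if not self.voxels[r, c]:
                raise ValueError(f"{name} ({r}, {c}) lies outside the mask")


@dataclass
class LengthField:
    """Normalized along-tendon coordinate for every mask voxel.

    ``position`` is in percent of tendon length: 0 at the lateral seed,
    100 at the medial seed, NaN off the mask.  ``tendon_length_mm`` is the
    geodesic footprint-to-junction distance.
    """

    position: np.ndarray
    tendon_length_mm: float
    mask: np.ndarray


@dataclass
class T2Profile:
    """Binned T2 distribution profile: mean T2 vs normalized position."""

    bin_centers: np.ndarray  #: percent
    bin_means: np.ndarray  #: ms; NaN for empty bins
    bin_counts: np.ndarray

    @property
    def nonempty(self) -> np.ndarray:
        return self.bin_counts > 0


@dataclass
class SegmentSummary:
    """Mean +/- SD of T2 over one tendon third."""

    segment: str
    mean_t2: float
    sd_t2: float
    n_voxels: int


@dataclass
class FilterReport:
    """Bookkeeping of the partial-volume/noise filter."""

    n_mask: int
    n_kept: int
    n_invalid: int
    n_out_of_bounds: int
    n_low_r2: int


def filter_t2_map(
    t2map: T2Map,
    mask: TendonMask,
    t2_bounds: tuple[float, float] = DEFAULT_T2_BOUNDS,
    r2_min: float = DEFAULT_R2_MIN,
) -> tuple[np.ndarray, FilterReport]:
    """Keep mask voxels with a valid decay fit, in-range T2 and good R^2.

    Criteria are applied in order (validity, then T2 bounds, then R^2), and
    the report counts removals per criterion.  Removing more than half of
    the mask triggers a logged warning, not an error — heavily degenerate
    tendons legitimately lose many voxels.

    Returns the boolean array of surviving voxels plus a
    :class:`FilterReport`.
    """
    lo, hi = t2_bounds
    if not lo < hi:
        raise ValueError("t2_bounds must satisfy lo < hi")
    if not 0 <= r2_min <= 1:
        raise ValueError("r2_min must lie in [0, 1]")
    m = mask.voxels
    if m.shape != t2map.shape:
        raise ValueError("mask grid does not match the T2 map")

    ok_valid = m & t2map.valid
    with np.errstate(invalid="ignore"):
        ok_bounds = ok_valid & (t2map.t2 >= lo) & (t2map.t2 <= hi)
    ok_r2 = ok_bounds & (t2map.r2 >= r2_min)

    n_mask = int(m.sum())
    report = FilterReport(
        n_mask=n_mask,
        n_kept=int(ok_r2.sum()),
        n_invalid=n_mask - int(ok_valid.sum()),
        n_out_of_bounds=int(ok_valid.sum()) - int(ok_bounds.sum()),
        n_low_r2=int(ok_bounds.sum()) - int(ok_r2.sum()),
    )
    if n_mask and report.n_kept < 0.5 * n_mask:
        msg = (
            f"T2 filter removed {n_mask - report.n_kept}/{n_mask} mask voxels "
            f"(invalid={report.n_invalid}, out-of-bounds={report.n_out_of_bounds}, "
            f"low-r2={report.n_low_r2})"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return ok_r2, report


def _mask_graph(mask: np.ndarray, spacing: tuple[float, float]) -> tuple[coo_matrix, np.ndarray]:
    """8-connected adjacency of mask voxels, edges weighted by mm step length."""
    nr, nc = mask.shape
    idx = -np.ones((nr, nc), dtype=np.int64)
    coords = np.argwhere(mask)
    idx[mask] = np.arange(len(coords))
    dr, dc = spacing
    rows, cols, weights = [], [], []
    for sr, sc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        w = float(np.hypot(sr * dr, sc * dc))
        r0 = slice(max(0, -sr), nr - max(0, sr))
        c0 = slice(max(0, -sc), nc - max(0, sc))
        r1 = slice(max(0, sr), nr - max(0, -sr))
        c1 = slice(max(0, sc), nc - max(0, -sc))
        both = mask[r0, c0] & mask[r1, c1]
        a = idx[r0, c0][both]
        b = idx[r1, c1][both]
        rows.append(a)
        cols.append(b)
        weights.append(np.full(a.size, w))
    row = np.concatenate(rows)
    col = np.concatenate(cols)
    dat = np.concatenate(weights)
    n = len(coords)
    graph = coo_matrix((dat, (row, col)), shape=(n, n))
    return graph, coords


def parameterize_length(
    mask: TendonMask, voxel_spacing: tuple[float, float]
) -> LengthField:
    """Assign each mask voxel a normalized along-tendon coordinate.

    Computes the spacing-weighted geodesic distance from the lateral seed
    to every mask voxel (Dijkstra on the 8-connected voxel graph, edge
    weights the Euclidean step length in mm), then divides by the distance
    at the medial seed and scales to percent.  Voxels geodesically slightly
    beyond the medial seed (e.g. the far edge of the insertion) are clipped
    to 100; the coordinate reduces to the axis coordinate for straight
    bands and follows arc length for curved ones.

    Raises if the mask is disconnected between the seeds.
    """
    graph, coords = _mask_graph(mask.voxels, voxel_spacing)
    n_comp, labels = connected_components(graph, directed=False)
    flat = {tuple(rc): i for i, rc in enumerate(map(tuple, coords))}
    i_lat = flat[tuple(mask.lateral_seed)]
    i_med = flat[tuple(mask.medial_seed)]
    if n_comp > 1 and not np.all(labels == labels[i_lat]):
        raise ValueError("tendon mask is not a single connected component")

    dist = dijkstra(graph, directed=False, indices=i_lat)
    length_mm = float(dist[i_med])
    if not np.isfinite(length_mm) or length_mm <= 0:
        raise ValueError("medial seed unreachable from lateral seed within mask")

    position = np.full(mask.voxels.shape, np.nan)
    position[mask.voxels] = np.clip(100.0 * dist / length_mm, 0.0, 100.0)
    return LengthField(
        position=position, tendon_length_mm=length_mm, mask=mask.voxels.copy()
    )


def bin_profile(
    t2map: T2Map,
    filtered: np.ndarray,
    length: LengthField,
    n_bins: int = 100,
) -> T2Profile:
    """Bin mean T2 of the filtered voxels against normalized position.

    Uses ``n_bins`` (>= 1) equal-width bins on [0, 100]; bins are half-open with
    the last bin closed (a voxel at exactly 100% lands in the last bin).
    Empty bins carry a NaN mean and zero count and are excluded from any
    downstream regression rather than interpolated.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    sel = np.asarray(filtered, dtype=bool)
    if not sel.any():
        raise ValueError("no filtered voxels to profile")
    pos = length.position[sel]
    t2 = t2map.t2[sel]
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    which = np.minimum(np.digitize(pos, edges[1:-1]), n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=t2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.any(counts == 0):
        logger.info("profile has %d empty bins of %d", int((counts == 0).sum()), n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return T2Profile(bin_centers=centers, bin_means=means, bin_counts=counts)


def split_segments(length: LengthField) -> np.ndarray:
    """Label every mask voxel lateral (0) / middle (1) / medial (2).

    Thirds of normalized length with half-open boundaries: lateral is
    [0, 33.3), middle [33.3, 66.7), medial [66.7, 100].  Off-mask voxels
    get label -1.
    """
    labels = np.full(length.position.shape, -1, dtype=np.int8)
    pos = length.position
    on = length.mask
    labels[on & (pos < _THIRD)] = 0
    labels[on & (pos >= _THIRD) & (pos < 2 * _THIRD)] = 1
    labels[on & (pos >= 2 * _THIRD)] = 2
    return labels


def segment_means(
    t2map: T2Map, filtered: np.ndarray, labels: np.ndarray
) -> list[SegmentSummary]:
    """Mean, SD (n-1 denominator) and voxel count of T2 per tendon third.

    An empty segment yields a summary with NaN statistics and count 0 so
    that partition bookkeeping still holds.
    """
    sel = np.asarray(filtered, dtype=bool)
    out: list[SegmentSummary] = []
    for code, name in enumerate(SEGMENT_NAMES):
        vox = t2map.t2[sel & (labels == code)]
        if vox.size == 0:
            logger.warning("segment %s has no filtered voxels", name)
            out.append(SegmentSummary(name, float("nan"), float("nan"), 0))
            continue
        sd = float(np.std(vox, ddof=1)) if vox.size > 1 else 0.0
        out.append(SegmentSummary(name, float(np.mean(vox)), sd, int(vox.size)))
    return out
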