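"""The three scalar vessel biomarkers: mvFD, Murray's deviation, bifurcation angle.

* **mvFD** — box-counting fractal dimension of the binary vessel image:
  pad to a power-of-two square, halve the box size from the full image down
  to one pixel, count occupied boxes at each scale, and take the slope of the
  first-order fit of log N_S against log(1/S). A space-filling image reads
  2, a straight line 1.
* **MD** — Murray's deviation at a junction: ``|D_m^3 - sum(D_d^3)| / D_m^3``
  where the mother vessel is the incident segment with the largest diameter
  and the rest are daughters. Murray's law (mother cube equals sum of
  daughter cubes) gives MD = 0; tumor networks deviate upward.
* **BA** — bifurcation angle at junctions with exactly three sub-vessels:
  the angle between the two daughter centerlines, each obtained by a total
  least squares line fit to the near-junction portion of the daughter path.
  The portion length follows the daughter-length rule: whole daughter when
  its length L_D <= 3 px, half when 3 < L_D <= VL-bar (the mean segment
  length), and the first fifth when L_D > VL-bar. Junction-blob pixels are
  excluded from the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateDataError, NoVesselsError
from .image import as_binary
from .vessel_graph import BranchPoint, VesselGraph

__all__ = [
    "BoxCountSeries",
    "BifurcationRecord",
    "MorphometrySummary",
    "compute_mvfd",
    "murray_deviation",
    "compute_md",
    "compute_ba",
    "summarize",
]


# ---------------------------------------------------------------------------
# microvessel fractal dimension
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxCountSeries:
    """Box sizes (descending powers of two), occupied-box counts, fitted slope."""

    box_sizes: tuple[int, ...]
    counts: tuple[int, ...]
    mvfd: float
    degenerate: bool = False  # single-pixel image: flat counts, slope forced to 0


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def compute_mvfd(image) -> BoxCountSeries:
    """Box-counting fractal dimension of a binary vessel image.

    The image is zero-padded (bottom/right) to the next power-of-two square,
    the grid is anchored at the origin, and every dyadic box size from the
    padded size down to 1 px enters the fit.
    """
    arr = as_binary(image).astype(bool)
    n_pixels = int(arr.sum())
    if n_pixels == 0:
        raise NoVesselsError("no vessels: cannot compute mvFD of an empty image")
    size = _next_pow2(max(arr.shape))
    padded = np.zeros((size, size), dtype=bool)
    padded[: arr.shape[0], : arr.shape[1]] = arr

    sizes: list[int] = []
    counts: list[int] = []
    cur = padded
    s = 1
    while True:
        sizes.append(s)
        counts.append(int(cur.sum()))
        if s >= size:
            break
        h = cur.shape[0] // 2
        cur = cur.reshape(h, 2, h, 2).any(axis=(1, 3))
        s *= 2
    sizes.reverse()  # descending S: padded size ... 1
    counts.reverse()

    if n_pixels == 1:
        warnings.warn("single-pixel image: mvFD fit is degenerate, returning 0", stacklevel=2)
        return BoxCountSeries(tuple(sizes), tuple(counts), 0.0, degenerate=True)

    x = np.log(1.0 / np.array(sizes, dtype=float))
    y = np.log(np.array(counts, dtype=float))
    slope = float(np.polyfit(x, y, 1)[0])
    return BoxCountSeries(tuple(sizes), tuple(counts), slope)


# ---------------------------------------------------------------------------
# Murray's deviation
# ---------------------------------------------------------------------------

@dataclass
class BifurcationRecord:
    """Mother/daughter assignment and metrics at one branch point."""

    branch: BranchPoint
    mother_label: int
    mother_diameter_px: float
    daughter_labels: tuple[int, ...]
    daughter_diameters_px: tuple[float, ...]
    md: float
    ba_deg: float | None = None
    ba_degenerate: bool = False

    @property
    def n_sv(self) -> int:
        return self.branch.n_sv


def murray_deviation(mother_diameter: float, daughter_diameters) -> float:
    """``|D_m^3 - sum(D_d^3)| / D_m^3`` — zero when Murray's law holds exactly.

    Homogeneous of degree zero: rescaling every diameter by the same factor
    leaves the value unchanged.
    """
    dm3 = float(mother_diameter) ** 3
    if dm3 <= 0:
        raise ValueError("mother diameter must be positive")
    dd3 = sum(float(d) ** 3 for d in daughter_diameters)
    return abs(dm3 - dd3) / dm3


def _segment_diameter(seg) -> float:
    if seg.caliber_px is not None:
        return seg.caliber_px
    if seg.mean_diameter_px is not None:
        return seg.mean_diameter_px
    raise DegenerateDataError("diameters not estimated; run estimate_diameters first")


def _assign_mother(graph: VesselGraph, bp: BranchPoint):
    """Mother = largest diameter; ties broken by longer segment, then lowest label."""
    segs = [graph.segments[lbl] for lbl in bp.incident_labels if lbl in graph.segments]
    if len(segs) < 2:
        return None, []
    mother = max(segs, key=lambda s: (_segment_diameter(s), s.length_px, -s.label))
    daughters = [s for s in segs if s.label != mother.label]
    return mother, daughters


def compute_md(graph: VesselGraph) -> list[BifurcationRecord]:
    """Murray's deviation at every non-degenerate branch point (n_sv >= 2)."""
    records: list[BifurcationRecord] = []
    for bp in graph.branch_points:
        if bp.degenerate:
            continue
        mother, daughters = _assign_mother(graph, bp)
        if mother is None:
            continue
        dm = _segment_diameter(mother)
        dds = [_segment_diameter(s) for s in daughters]
        if dm <= 0 or any(d <= 0 for d in dds):
            warnings.warn(
                f"branch at ({bp.row},{bp.col}) has a nonpositive diameter; excluded",
                stacklevel=2,
            )
            continue
        records.append(
            BifurcationRecord(
                branch=bp,
                mother_label=mother.label,
                mother_diameter_px=dm,
                daughter_labels=tuple(s.label for s in daughters),
                daughter_diameters_px=tuple(dds),
                md=murray_deviation(dm, dds),
            )
        )
    return records


# ---------------------------------------------------------------------------
# bifurcation angle
# ---------------------------------------------------------------------------

def _oriented_path(seg, branch_rc: np.ndarray) -> np.ndarray:
    """Segment path ordered so index 0 is the end nearest the branch point."""
    path = seg.path
    d_first = np.hypot(*(path[0] - branch_rc))
    d_last = np.hypot(*(path[-1] - branch_rc))
    return path if d_first <= d_last else path[::-1]


def _portion_fraction(l_d: float, vl_bar: float) -> float:
    if l_d <= 3.0:
        return 1.0
    if l_d <= vl_bar:
        return 0.5
    return 0.2


def _window_flesh(points: np.ndarray, flesh, pad: int) -> np.ndarray:
    """Vessel pixels whose nearest labeled skeleton pixel lies in the window."""
    arr, ir, ic = flesh
    h, w = arr.shape
    r0 = max(int(points[:, 0].min()) - pad, 0)
    r1 = min(int(points[:, 0].max()) + pad + 1, h)
    c0 = max(int(points[:, 1].min()) - pad, 0)
    c1 = min(int(points[:, 1].max()) + pad + 1, w)
    keys = points[:, 0].astype(np.int64) * w + points[:, 1]
    sub_keys = ir[r0:r1, c0:c1].astype(np.int64) * w + ic[r0:r1, c0:c1]
    mask = arr[r0:r1, c0:c1] & np.isin(sub_keys, keys)
    return np.argwhere(mask) + np.array([r0, c0])


def _fit_direction(
    points: np.ndarray,
    origin: np.ndarray,
    far: np.ndarray | None = None,
    ordered: bool = True,
) -> np.ndarray | None:
    """Total-least-squares direction of a pixel set, oriented away from origin.

    Ordered runs are smoothed with a short moving average first; digitized
    straight lines carry +-0.5 px staircase noise that otherwise tilts short
    fits. ``far`` fixes the orientation (defaults to the last point).
    """
    if len(points) < 2:
        return None
    pts = points.astype(float)
    if far is None:
        far = pts[-1]
    if ordered and len(pts) >= 5:
        kernel = np.ones(5) / 5.0
        pts = np.column_stack(
            [np.convolve(pts[:, 0], kernel, mode="valid"),
             np.convolve(pts[:, 1], kernel, mode="valid")]
        )
        if len(pts) < 2:
            pts = points.astype(float)
    centered = pts - pts.mean(axis=0)
    # principal axis via SVD of the centered coordinates
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 0:
        return None
    direction = vt[0]
    if np.dot(direction, np.asarray(far, dtype=float) - origin) < 0:
        direction = -direction
    norm = np.linalg.norm(direction)
    return direction / norm if norm > 0 else None


def compute_ba(
    graph: VesselGraph,
    image=None,
    records: list[BifurcationRecord] | None = None,
    blob_margin_px: float = 1.0,
    min_fit_px: int = 5,
) -> list[BifurcationRecord]:
    """Fill ``ba_deg`` for every record whose branch point has exactly 3 sub-vessels.

    For each daughter the near-branch portion of the path is selected by the
    daughter-length rule (whole / half / first fifth of the chain length,
    measured from the branch end), junction-blob pixels are dropped, the
    portion is extended along the path if fewer than ``min_fit_px`` pixels
    survive, and a total-least-squares line gives the daughter direction
    (oriented away from the branch point). The angle between the two daughter
    directions is reported in degrees in (0, 180].
    """
    if records is None:
        records = compute_md(graph)
    vl_bar = graph.mean_vessel_length_px
    edt = None
    flesh = None
    if image is not None:
        arr = as_binary(image).astype(bool)
        edt = ndi.distance_transform_edt(arr)
        labeled_mask = graph.label_image > 0
        if labeled_mask.any():
            # nearest labeled skeleton pixel for every canvas pixel: lets the
            # fit use the daughter's full vessel cross-section, whose wall
            # quantization averages out far better than the 1-px centerline
            _, (ir, ic) = ndi.distance_transform_edt(~labeled_mask, return_indices=True)
            flesh = (arr, ir, ic)

    for rec in records:
        if rec.n_sv != 3 or len(rec.daughter_labels) != 2:
            continue
        bp = rec.branch
        branch_rc = np.array(bp.rc, dtype=float)
        blob_core = blob_margin_px + (float(edt[bp.row, bp.col]) if edt is not None else 0.0)
        calibers = [graph.segments[lbl].caliber_px or 0.0 for lbl in rec.daughter_labels]

        def fit_pair(extra_radius: float):
            dirs = []
            for lbl, cal in zip(rec.daughter_labels, calibers):
                seg = graph.segments[lbl]
                # the daughter centerline stays bent until the strokes
                # separate, about one daughter caliber past the blob
                blob_radius = max(blob_core + cal, extra_radius)
                path = _oriented_path(seg, branch_rc)
                frac = _portion_fraction(seg.length_px, vl_bar)
                steps = (
                    np.hypot(*(np.diff(path, axis=0).T)) if len(path) > 1 else np.zeros(0)
                )
                arc = np.concatenate([[0.0], np.cumsum(steps)])
                dist_to_branch = np.hypot(*((path - branch_rc).T))
                outside = dist_to_branch > blob_radius
                if outside.any():
                    # the portion window opens where the path leaves the
                    # junction blob, so exclusion never shrinks the fit length
                    s0 = arc[np.nonzero(outside)[0][0]]
                    keep = outside & (arc >= s0) & (arc <= s0 + frac * seg.length_px + 1e-9)
                else:
                    keep = np.zeros(len(path), dtype=bool)
                if keep.sum() < min_fit_px:
                    # extend along the path, nearest-first, skipping blob pixels
                    for idx in range(len(path)):
                        if keep.sum() >= min_fit_px:
                            break
                        if outside[idx]:
                            keep[idx] = True
                    if keep.sum() < 2:
                        keep[:] = arc <= frac * seg.length_px + 1e-9
                        keep[:2] = True
                window = path[keep]
                far_pt = window[-1]
                points, ordered = window, True
                if flesh is not None and keep.sum() >= 2:
                    flesh_pts = _window_flesh(window, flesh, pad=int(np.ceil(cal)) + 2)
                    if len(flesh_pts):
                        # junction-side cross-section pixels can belong to the
                        # wedge shared with the sibling daughter; drop them
                        fd = np.hypot(*((flesh_pts - branch_rc).T))
                        flesh_pts = flesh_pts[fd > blob_radius + cal / 2.0]
                    if len(flesh_pts) >= 2 * len(window):
                        points, ordered = flesh_pts, False
                dirs.append(_fit_direction(points, branch_rc, far=far_pt, ordered=ordered))
            return dirs

        def pair_angle(dirs):
            if any(v is None for v in dirs):
                return None
            cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
            return float(np.degrees(np.arccos(cosang)))

        angle = pair_angle(fit_pair(0.0))
        if angle is not None and angle > 1e-6 and flesh is None:
            # skeleton-only fallback, second pass: at narrow angles the
            # daughters hug each other past the mother blob; exclude up to
            # their geometric separation radius (the cross-section fit is
            # insensitive to this and keeps its longer window)
            half = np.radians(max(angle, 10.0) / 2.0)
            sep_radius = (calibers[0] + calibers[1]) / (2.0 * np.sin(half)) + blob_margin_px
            refined = pair_angle(fit_pair(sep_radius))
            if refined is not None and refined > 1e-6:
                angle = refined
        if angle is None:
            rec.ba_degenerate = True
            warnings.warn(
                f"degenerate daughter fit at branch ({bp.row},{bp.col}); BA excluded",
                stacklevel=2,
            )
            continue
        if angle <= 1e-6:
            rec.ba_degenerate = True
            warnings.warn(
                f"daughters collinear along the same ray at ({bp.row},{bp.col}); BA excluded",
                stacklevel=2,
            )
            continue
        rec.ba_deg = angle
    return records


# ---------------------------------------------------------------------------
# per-lesion summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphometrySummary:
    """Per-lesion summary: mvFD plus MD/BA mean, median, max, min."""

    mvfd: float | None
    md_mean: float | None
    md_median: float | None
    md_max: float | None
    md_min: float | None
    ba_mean: float | None
    ba_median: float | None
    ba_max: float | None
    ba_min: float | None
    n_bifurcations: int

    def to_dict(self) -> dict:
        return {
            "mvfd": self.mvfd,
            "md_mean": self.md_mean,
            "md_median": self.md_median,
            "md_max": self.md_max,
            "md_min": self.md_min,
            "ba_mean": self.ba_mean,
            "ba_median": self.ba_median,
            "ba_max": self.ba_max,
            "ba_min": self.ba_min,
            "n_bifurcations": self.n_bifurcations,
        }


def _stats(values: list[float]):
    if not values:
        return (None, None, None, None)
    a = np.asarray(values, dtype=float)
    return (float(a.mean()), float(np.median(a)), float(a.max()), float(a.min()))


def summarize(
    records: list[BifurcationRecord],
    box_series: BoxCountSeries | None = None,
) -> MorphometrySummary:
    """Aggregate per-bifurcation MD and BA values; missing stays missing, never 0."""
    md_values = [r.md for r in records]
    ba_values = [r.ba_deg for r in records if r.ba_deg is not None and not r.ba_degenerate]
    md_mean, md_median, md_max, md_min = _stats(md_values)
    ba_mean, ba_median, ba_max, ba_min = _stats(ba_values)
    return MorphometrySummary(
        mvfd=box_series.mvfd if box_series is not None else None,
        md_mean=md_mean,
        md_median=md_median,
        md_max=md_max,
        md_min=md_min,
        ba_mean=ba_mean,
        ba_median=ba_median,
        ba_max=ba_max,
        ba_min=ba_min,
        n_bifurcations=len(records),
    )
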