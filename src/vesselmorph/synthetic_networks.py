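"""Synthetic vessel networks with known ground truth.

The validation study needs binary vessel images whose morphometric parameters
are known exactly: models with a preset mean bifurcation angle, models whose
junction diameters are solved so Murray's deviation hits a preset mean,
lesion-shaped models with a designated (central or peripheral) vessel
distribution, and models of increasing structural complexity. Each model is a
:class:`SyntheticNetworkSpec` — polylines with stroke widths on a pixel
canvas — that is rasterized to a binary image and pushed through the same
measurement pipeline as real data.

Preset means are met *exactly at spec level*: per-junction values are drawn
around the preset and the last junction solves the mean constraint, so every
discrepancy measured downstream is rasterization/estimation error, not model
error.

``make_cohort`` draws benign/malignant per-lesion parameter vectors from
truncated normal distributions with the published group means and standard
deviations, for power/direction checks of the statistics machinery (the draws
are independent across parameters; real covariance is unknown).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import InputError

__all__ = [
    "Stroke",
    "LesionMaskSpec",
    "JunctionTruth",
    "SyntheticNetworkSpec",
    "rasterize",
    "render_lesion_mask",
    "make_ba_model",
    "make_md_model",
    "make_pattern_model",
    "make_complexity_models",
    "make_cohort",
    "COHORT_DISTRIBUTIONS",
]


# ---------------------------------------------------------------------------
# spec containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stroke:
    """A polyline drawn with a constant stroke width (>= 2 px)."""

    points: tuple[tuple[float, float], ...]  # (row, col) control points
    width_px: float

    def __post_init__(self):
        if self.width_px < 2.0:
            raise InputError(f"stroke width {self.width_px:.2f} px < 2 px")
        if len(self.points) < 2:
            raise InputError("a stroke needs at least two control points")


@dataclass(frozen=True)
class LesionMaskSpec:
    """A disk lesion mask (center + radius, pixels)."""

    center_rc: tuple[float, float]
    radius_px: float


@dataclass(frozen=True)
class JunctionTruth:
    """Ground truth at one simulated bifurcation."""

    center_rc: tuple[float, float]
    angle_deg: float | None = None
    md: float | None = None
    mother_width_px: float | None = None
    daughter_widths_px: tuple[float, ...] = ()


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Polylines + widths + preset ground truth for one simulated model."""

    strokes: tuple[Stroke, ...]
    canvas_px: tuple[int, int] = (1024, 1024)
    junctions: tuple[JunctionTruth, ...] = ()
    lesion_mask_spec: LesionMaskSpec | None = None
    seed: int = 0
    ground_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize(spec: SyntheticNetworkSpec) -> np.ndarray:
    """Draw every stroke onto a binary canvas (union of strokes).

    A pixel is on iff its center lies within ``width/2`` of the stroke's
    polyline (no anti-aliasing; deterministic for a given spec). Geometry
    reaching outside the canvas is clipped with a warning.
    """
    if not spec.strokes:
        raise InputError("empty spec: no strokes to rasterize")
    h, w = spec.canvas_px
    canvas = np.zeros((h, w), dtype=bool)
    clipped = False
    for stroke in spec.strokes:
        half = stroke.width_px / 2.0
        pts = np.asarray(stroke.points, dtype=float)
        if (pts - half < 0).any() or (pts[:, 0] + half > h - 1).any() or (
            pts[:, 1] + half > w - 1
        ).any():
            clipped = True
        for p, q in zip(pts[:-1], pts[1:]):
            r0 = max(int(np.floor(min(p[0], q[0]) - half - 1)), 0)
            r1 = min(int(np.ceil(max(p[0], q[0]) + half + 1)) + 1, h)
            c0 = max(int(np.floor(min(p[1], q[1]) - half - 1)), 0)
            c1 = min(int(np.ceil(max(p[1], q[1]) + half + 1)) + 1, w)
            if r0 >= r1 or c0 >= c1:
                continue
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            v = q - p
            vv = float(v @ v)
            if vv == 0:
                d2 = (rr - p[0]) ** 2 + (cc - p[1]) ** 2
            else:
                t = ((rr - p[0]) * v[0] + (cc - p[1]) * v[1]) / vv
                t = np.clip(t, 0.0, 1.0)
                d2 = (rr - (p[0] + t * v[0])) ** 2 + (cc - (p[1] + t * v[1])) ** 2
            canvas[r0:r1, c0:c1] |= d2 <= half * half
    if clipped:
        warnings.warn("stroke geometry extends beyond the canvas; clipped", stacklevel=2)
    return canvas.astype(np.uint8)


def render_lesion_mask(spec: SyntheticNetworkSpec) -> np.ndarray:
    """Rasterize the spec's disk lesion mask."""
    if spec.lesion_mask_spec is None:
        raise InputError("spec has no lesion_mask_spec")
    h, w = spec.canvas_px
    cr, cc = spec.lesion_mask_spec.center_rc
    rr, cc_grid = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d2 = (rr - cr) ** 2 + (cc_grid - cc) ** 2
    return (d2 <= spec.lesion_mask_spec.radius_px ** 2).astype(np.uint8)


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------

def _unit(theta_rad: float) -> np.ndarray:
    return np.array([np.sin(theta_rad), np.cos(theta_rad)])


_CRITICAL_DIRECTIONS_DEG = (0.0, 26.565, 45.0, 63.435, 90.0)  # slopes 0, 1/2, 1, 2, inf


def _lattice_aligned(theta_rad: float, margin_deg: float = 6.0) -> bool:
    """True when a direction is near a low-order lattice-rational slope.

    A constant-width stroke rasterized along such a direction quantizes with
    a short period, so its fractional width rounds systematically instead of
    dithering out along the length. Preset-parameter models keep their
    strokes in general position, as a CAD drawing in general orientation
    would be.
    """
    deg = np.degrees(theta_rad) % 90.0
    return any(abs(deg - c) < margin_deg for c in _CRITICAL_DIRECTIONS_DEG)


def _generic_junction_orientation(
    rng: np.random.Generator,
    offsets_rad: list[float],
    max_tries: int = 200,
) -> float:
    """Base direction phi such that phi + each offset avoids lattice angles."""
    for _ in range(max_tries):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        if not any(_lattice_aligned(phi + off) for off in offsets_rad):
            return phi
    return rng.uniform(0.0, 2.0 * np.pi)  # best effort


def _junction_sites(n: int, canvas: int, margin: float, rng: np.random.Generator):
    """Non-overlapping junction centers on a jittered grid."""
    g = int(np.ceil(np.sqrt(n)))
    usable = canvas - 2.0 * margin
    cell = usable / g
    jitter = min(15.0, cell / 8.0)
    sites = []
    for i in range(g):
        for j in range(g):
            if len(sites) >= n:
                break
            r = margin + (i + 0.5) * cell + rng.uniform(-jitter, jitter)
            c = margin + (j + 0.5) * cell + rng.uniform(-jitter, jitter)
            sites.append((r, c))
    return sites[:n]


def _solve_mean_constraint(
    preset: float,
    n: int,
    jitter: float,
    lo: float,
    hi: float,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> np.ndarray:
    """Draw n values around the preset whose arithmetic mean is the preset exactly."""
    if not (lo < preset < hi):
        raise InputError(f"preset {preset} outside feasible range ({lo}, {hi})")
    for _ in range(max_tries):
        head = np.clip(rng.normal(preset, jitter, size=n - 1), lo, hi)
        last = n * preset - head.sum()
        if lo < last < hi:
            values = np.append(head, last)
            return values
    raise InputError(
        f"could not satisfy mean constraint {preset} within ({lo}, {hi}) after {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# preset-parameter models
# ---------------------------------------------------------------------------

def make_ba_model(
    preset_mean_deg: float,
    n_junctions: int = 9,
    seed: int = 0,
    canvas_px: int = 1024,
    mother_width_px: float = 6.0,
    daughter_width_px: float = 4.0,
    mother_length_px: float = 90.0,
    daughter_length_px: float = 60.0,
    angle_jitter_deg: float = 6.0,
) -> SyntheticNetworkSpec:
    """Y-junction battery whose per-junction angles average to the preset exactly.

    Each junction is a straight mother stroke running into the junction and
    two straight daughter strokes leaving it symmetrically about the mother's
    continuation, separated by the assigned angle. The mother is drawn wider
    than the daughters so largest-diameter mother selection is unambiguous.
    """
    if not (10.0 < preset_mean_deg < 170.0):
        raise InputError("preset mean angle must lie in (10, 170) degrees")
    if n_junctions < 3:
        raise InputError("need at least 3 junctions")
    rng = np.random.default_rng(seed)
    angles = _solve_mean_constraint(
        preset_mean_deg, n_junctions, angle_jitter_deg, 15.0, 165.0, rng
    )
    margin = mother_length_px + max(daughter_length_px, 20.0) + 10.0
    sites = _junction_sites(n_junctions, canvas_px, margin, rng)
    strokes: list[Stroke] = []
    junctions: list[JunctionTruth] = []
    for (jr, jc), angle in zip(sites, angles):
        j = np.array([jr, jc])
        a = np.radians(angle)
        phi = _generic_junction_orientation(rng, [np.pi, a / 2.0, -a / 2.0])
        mother_start = j - mother_length_px * _unit(phi)
        d1 = j + daughter_length_px * _unit(phi + a / 2.0)
        d2 = j + daughter_length_px * _unit(phi - a / 2.0)
        strokes.append(Stroke((tuple(mother_start), tuple(j)), mother_width_px))
        strokes.append(Stroke((tuple(j), tuple(d1)), daughter_width_px))
        strokes.append(Stroke((tuple(j), tuple(d2)), daughter_width_px))
        junctions.append(
            JunctionTruth(
                center_rc=(jr, jc),
                angle_deg=float(angle),
                mother_width_px=mother_width_px,
                daughter_widths_px=(daughter_width_px, daughter_width_px),
            )
        )
    return SyntheticNetworkSpec(
        strokes=tuple(strokes),
        canvas_px=(canvas_px, canvas_px),
        junctions=tuple(junctions),
        seed=seed,
        ground_truth={
            "mean_ba_deg": float(preset_mean_deg),
            "per_junction_ba_deg": [float(a) for a in angles],
        },
    )


def make_md_model(
    preset_mean_md: float,
    n_junctions: int = 9,
    seed: int = 0,
    canvas_px: int = 1024,
    mother_width_px: float = 10.0,
    mother_length_px: float = 100.0,
    daughter_length_px: float = 70.0,
    md_jitter: float = 0.05,
) -> SyntheticNetworkSpec:
    """Y-junction battery whose per-junction Murray deviations average to the preset.

    Daughter widths are symmetric and solved from the junction's assigned MD
    target ``m``: ``w_d = w_m * ((1 - m) / 2)^(1/3)`` (daughters narrower than
    Murray's law predicts), so the cube relation gives exactly ``m`` at spec
    level. Daughter directions are dithered so diameter quantization averages
    out along the paths.
    """
    if not (0.0 <= preset_mean_md < 1.0):
        raise InputError("preset mean MD must lie in [0, 1)")
    if n_junctions < 3:
        raise InputError("need at least 3 junctions")
    rng = np.random.default_rng(seed)
    if preset_mean_md == 0.0:
        targets = np.zeros(n_junctions)
    else:
        targets = _solve_mean_constraint(
            preset_mean_md, n_junctions, md_jitter, 0.02, 0.95, rng
        )
    margin = mother_length_px + daughter_length_px + 10.0
    sites = _junction_sites(n_junctions, canvas_px, margin, rng)
    strokes: list[Stroke] = []
    junctions: list[JunctionTruth] = []
    for (jr, jc), m in zip(sites, targets):
        w_d = mother_width_px * ((1.0 - m) / 2.0) ** (1.0 / 3.0)
        if w_d < 2.0:
            raise InputError("resolution too low for preset: daughter width < 2 px")
        j = np.array([jr, jc])
        half1 = np.radians(rng.uniform(45.0, 75.0))
        half2 = np.radians(rng.uniform(45.0, 75.0))
        phi = _generic_junction_orientation(rng, [np.pi, half1, -half2])
        mother_start = j - mother_length_px * _unit(phi)
        d1 = j + daughter_length_px * _unit(phi + half1)
        d2 = j + daughter_length_px * _unit(phi - half2)
        strokes.append(Stroke((tuple(mother_start), tuple(j)), mother_width_px))
        strokes.append(Stroke((tuple(j), tuple(d1)), w_d))
        strokes.append(Stroke((tuple(j), tuple(d2)), w_d))
        junctions.append(
            JunctionTruth(
                center_rc=(jr, jc),
                md=float(m),
                mother_width_px=mother_width_px,
                daughter_widths_px=(w_d, w_d),
            )
        )
    return SyntheticNetworkSpec(
        strokes=tuple(strokes),
        canvas_px=(canvas_px, canvas_px),
        junctions=tuple(junctions),
        seed=seed,
        ground_truth={
            "mean_md": float(preset_mean_md),
            "per_junction_md": [float(m) for m in targets],
        },
    )


def _wavy_points(
    start: np.ndarray,
    direction_rad: float,
    length: float,
    amplitude: float,
    cycles: float,
    n_samples: int = 40,
) -> tuple[tuple[float, float], ...]:
    t = np.linspace(0.0, 1.0, n_samples)
    axis = _unit(direction_rad)
    normal = np.array([-axis[1], axis[0]])
    pts = (
        start[None, :]
        + t[:, None] * length * axis[None, :]
        + (amplitude * np.sin(2.0 * np.pi * cycles * t))[:, None] * normal[None, :]
    )
    return tuple(map(tuple, pts))


def make_pattern_model(
    pattern: str,
    seed: int = 0,
    canvas_px: int = 1024,
    lesion_radius_px: float = 320.0,
    n_strokes: int = 10,
    stroke_width_px: float = 4.0,
) -> SyntheticNetworkSpec:
    """Disk lesion with vessels confined to the central or peripheral region.

    With erosion radius 3 px and center fraction 0.5 the center/periphery
    boundary sits at ~0.5 * (lesion_radius - 3); central strokes stay well
    inside it and peripheral strokes well outside, so >= 90% (in practice
    100%) of vessel pixels land in the designated region.
    """
    if pattern not in ("central", "peripheral"):
        raise InputError("pattern must be 'central' or 'peripheral'")
    rng = np.random.default_rng(seed)
    center = np.array([canvas_px / 2.0, canvas_px / 2.0])
    r_boundary = 0.5 * (lesion_radius_px - 3.0)
    strokes: list[Stroke] = []
    if pattern == "central":
        inner = r_boundary - stroke_width_px - 25.0
        for _ in range(n_strokes):
            rho = rng.uniform(0.0, inner * 0.5)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            start = center + rho * _unit(theta)
            direction = rng.uniform(0.0, 2.0 * np.pi)
            length = min(rng.uniform(50.0, 80.0), inner - rho)
            strokes.append(
                Stroke(
                    _wavy_points(start, direction, length, rng.uniform(2.0, 6.0), 1.5),
                    stroke_width_px,
                )
            )
    else:
        lo = r_boundary + stroke_width_px + 25.0
        hi = lesion_radius_px - 3.0 - stroke_width_px - 15.0
        for _ in range(n_strokes):
            rho = rng.uniform(lo, hi)
            theta0 = rng.uniform(0.0, 2.0 * np.pi)
            span = rng.uniform(0.4, 0.8)  # radians of arc
            t = np.linspace(0.0, 1.0, 20)
            pts = center[None, :] + rho * np.stack(
                [np.sin(theta0 + span * t), np.cos(theta0 + span * t)], axis=1
            )
            strokes.append(Stroke(tuple(map(tuple, pts)), stroke_width_px))
    return SyntheticNetworkSpec(
        strokes=tuple(strokes),
        canvas_px=(canvas_px, canvas_px),
        lesion_mask_spec=LesionMaskSpec(tuple(center), lesion_radius_px),
        seed=seed,
        ground_truth={"pattern": pattern, "svp": 1 if pattern == "central" else 0},
    )


def make_complexity_models(
    seed: int = 0,
    canvas_px: int = 1024,
) -> list[SyntheticNetworkSpec]:
    """Three networks of strictly increasing structural complexity.

    Low: a few long straight vessels. Medium: more vessels with gentle
    waviness and some side branches. High: a dense bed of strongly wavy
    vessels with many side branches. Box-counting dimension increases along
    the series.
    """
    rng = np.random.default_rng(seed)
    specs = []
    configs = [
        {"n": 4, "amp": 0.0, "cycles": 0.0, "branches": 0, "rank": 1},
        {"n": 10, "amp": 10.0, "cycles": 2.0, "branches": 5, "rank": 2},
        {"n": 24, "amp": 18.0, "cycles": 4.0, "branches": 12, "rank": 3},
    ]
    for cfg in configs:
        strokes: list[Stroke] = []
        margin = 60.0
        for _ in range(cfg["n"]):
            start = np.array(
                [
                    rng.uniform(margin, canvas_px - margin),
                    rng.uniform(margin, canvas_px - margin),
                ]
            )
            direction = rng.uniform(0.0, 2.0 * np.pi)
            length = rng.uniform(250.0, 450.0)
            end = start + length * _unit(direction)
            end = np.clip(end, margin, canvas_px - margin)
            length = float(np.linalg.norm(end - start))
            if length < 50:
                length = 50.0
            direction = float(np.arctan2(*(end - start))) if length > 0 else direction
            strokes.append(
                Stroke(
                    _wavy_points(start, direction, length, cfg["amp"], cfg["cycles"]),
                    4.0,
                )
            )
        for _ in range(cfg["branches"]):
            base = strokes[int(rng.integers(0, cfg["n"]))]
            pts = np.asarray(base.points)
            anchor = pts[int(rng.integers(5, len(pts) - 5))]
            direction = rng.uniform(0.0, 2.0 * np.pi)
            length = rng.uniform(60.0, 140.0)
            end = np.clip(anchor + length * _unit(direction), margin, canvas_px - margin)
            strokes.append(Stroke((tuple(anchor), tuple(end)), 3.0))
        specs.append(
            SyntheticNetworkSpec(
                strokes=tuple(strokes),
                canvas_px=(canvas_px, canvas_px),
                seed=seed,
                ground_truth={"complexity_rank": cfg["rank"]},
            )
        )
    return specs


# ---------------------------------------------------------------------------
# synthetic benign/malignant cohorts
# ---------------------------------------------------------------------------

# per-parameter (benign mean, benign sd, malignant mean, malignant sd, lower, upper)
COHORT_DISTRIBUTIONS: dict[str, tuple[float, float, float, float, float, float]] = {
    "mvfd": (1.13, 0.09, 1.28, 0.03, 1.0, 2.0),
    "md_mean": (0.29, 0.13, 0.40, 0.12, 0.0, np.inf),
    "md_median": (0.28, 0.15, 0.41, 0.18, 0.0, np.inf),
    "md_max": (0.42, 0.19, 0.68, 0.20, 0.0, np.inf),
    "md_min": (0.19, 0.16, 0.13, 0.16, 0.0, np.inf),
    "ba_mean": (110.28, 24.21, 95.86, 10.37, 1e-6, 180.0),
    "ba_median": (108.70, 20.33, 94.28, 12.38, 1e-6, 180.0),
    "ba_max": (127.36, 25.90, 128.43, 22.99, 1e-6, 180.0),
    "ba_min": (95.84, 23.42, 65.99, 18.13, 1e-6, 180.0),
    "vdr": (0.70, 0.38, 1.95, 0.62, 1e-6, np.inf),
}

# P(SVP = 1 | group), read from the 30/35 vs 21/25 concordance counts
_P_SVP1 = {"benign": 5.0 / 35.0, "malignant": 21.0 / 25.0}
_SIZE_MEAN_MM, _SIZE_SD_MM, _SIZE_LO_MM, _SIZE_HI_MM = 15.86, 7.81, 5.0, 40.0


def _draw_truncnorm(
    mean: float, sd: float, lo: float, hi: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd if np.isfinite(hi) else np.inf
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def make_cohort(n_benign: int = 35, n_malignant: int = 25, seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic benign/malignant cohort of per-lesion parameter summaries.

    Each parameter is drawn independently from the group's truncated normal;
    the (min, median, max) order statistics of MD and BA are then sorted and
    the mean clipped into [min, max] so each row is internally consistent.
    """
    if n_benign < 2 or n_malignant < 2:
        raise InputError("need at least 2 lesions per group")
    rng = np.random.default_rng(seed)
    frames = []
    for label, n in (("benign", n_benign), ("malignant", n_malignant)):
        cols: dict[str, np.ndarray] = {}
        for name, (mb, sb, mm, sm, lo, hi) in COHORT_DISTRIBUTIONS.items():
            mean, sd = (mb, sb) if label == "benign" else (mm, sm)
            cols[name] = _draw_truncnorm(mean, sd, lo, hi, n, rng)
        for fam in ("md", "ba"):
            order = np.sort(
                np.stack([cols[f"{fam}_min"], cols[f"{fam}_median"], cols[f"{fam}_max"]]),
                axis=0,
            )
            cols[f"{fam}_min"], cols[f"{fam}_median"], cols[f"{fam}_max"] = order
            cols[f"{fam}_mean"] = np.clip(
                cols[f"{fam}_mean"], cols[f"{fam}_min"], cols[f"{fam}_max"]
            )
        cols["svp"] = (rng.random(n) < _P_SVP1[label]).astype(int)
        cols["size_mm"] = _draw_truncnorm(
            _SIZE_MEAN_MM, _SIZE_SD_MM, _SIZE_LO_MM, _SIZE_HI_MM, n, rng
        )
        df = pd.DataFrame(cols)
        df.insert(0, "label", label)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", [f"L{i:03d}" for i in range(len(out))])
    column_order = [
        "id", "label", "size_mm", "mvfd",
        "md_mean", "md_median", "md_max", "md_min",
        "ba_mean", "ba_median", "ba_max", "ba_min",
        "vdr", "svp",
    ]
    return out[column_order]
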