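"""Synthetic NIRF lymphangiography data with full ground truth.

Everything downstream of the camera is testable against these generators:
1-D ROI-intensity traces with known contraction (trough) times, image
stacks of a pulsating conducting vessel with a known pixel mask, wound
series with a known reconnection day, multi-genotype cohorts with known
per-animal pumping rates, and IHC-like phantoms with a known positive-stain
fraction.

All generators are pure functions of their parameters and an integer seed:
the same call is bit-identical on re-run. Timing noise (inter-pulse jitter)
and camera noise draw from independent child streams of the seed, so
switching camera noise off never changes the contraction times.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks

from .pumping import ImageStack, IntensityTrace

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "ContractionParams",
    "CameraParams",
    "VesselGeometry",
    "GenotypePreset",
    "WoundSpec",
    "GENOTYPE_PRESETS",
    "simulate_trace",
    "simulate_stack",
    "simulate_cohort",
    "simulate_wound_series",
    "make_ihc_phantom",
    "load_presets",
]


class InvalidParameterError(ValueError):
    """Raised when a generator is called with out-of-range parameters."""


@dataclass(frozen=True)
class ContractionParams:
    """Phasic contraction model of a collecting lymphatic vessel.

    true_rate
        Ground-truth pumping rate in pumps/min (0 = quiescent vessel).
    amplitude_fraction
        Depth of each intensity trough relative to baseline, in [0, 1].
    rate_jitter_cv
        Coefficient of variation of the inter-pulse intervals (gamma
        distributed, so intervals are strictly positive).
    drift_slope
        Slow ICG washin/washout drift, intensity units per frame.
    """

    true_rate: float
    amplitude_fraction: float = 0.3
    rate_jitter_cv: float = 0.1
    drift_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.true_rate < 0:
            raise InvalidParameterError("true_rate must be >= 0")
        if not 0.0 <= self.amplitude_fraction <= 1.0:
            raise InvalidParameterError("amplitude_fraction must be in [0, 1]")
        if self.rate_jitter_cv < 0:
            raise InvalidParameterError("rate_jitter_cv must be >= 0")


@dataclass(frozen=True)
class CameraParams:
    """EMCCD acquisition model; defaults reproduce 5 frames/s imaging."""

    fps: float = 5.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    background_level: float = 100.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidParameterError("fps must be > 0")
        if self.read_noise_sd < 0:
            raise InvalidParameterError("read_noise_sd must be >= 0")
        if self.background_level < 0:
            raise InvalidParameterError("background_level must be >= 0")
        if self.bit_depth not in (8, 16):
            raise InvalidParameterError("bit_depth must be 8 or 16")

    @property
    def max_intensity(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass(frozen=True)
class VesselGeometry:
    """A tube in the image plane: centerline polyline plus half-width."""

    centerline: tuple[tuple[float, float], ...]
    radius_px: float
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise InvalidParameterError("radius_px must be > 0")
        if len(self.centerline) < 2:
            raise InvalidParameterError("centerline needs >= 2 points")
        h, w = self.image_shape
        for r, c in self.centerline:
            if not (0 <= r < h and 0 <= c < w):
                raise InvalidParameterError(
                    f"centerline point ({r}, {c}) outside image {self.image_shape}"
                )


@dataclass(frozen=True)
class GenotypePreset:
    """Between-animal pumping-rate distribution for one mouse line."""

    name: str
    mean_rate: float
    sd_rate: float
    n_default: int = 6

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise InvalidParameterError("mean_rate must be > 0")
        if self.sd_rate < 0:
            raise InvalidParameterError("sd_rate must be >= 0")


#: Baseline pumping-rate presets (pumps/min, mean and between-animal SD) for
#: the growth-hormone mouse lines: bGH overexpressors pump fastest, GH
#: receptor knockouts slowest.
GENOTYPE_PRESETS: dict[str, GenotypePreset] = {
    "bGH": GenotypePreset("bGH", 8.6, 0.7),
    "WT": GenotypePreset("WT", 6.8, 1.0),
    "GHA": GenotypePreset("GHA", 6.4, 1.5),
    "GHRKO": GenotypePreset("GHRKO", 4.7, 1.1),
}

#: Schedule used for baseline measurement: both flanks on two separate days.
DEFAULT_SCHEDULE: tuple[tuple[str, int], ...] = (
    ("left", 1),
    ("right", 1),
    ("left", 2),
    ("right", 2),
)


@dataclass(frozen=True)
class WoundSpec:
    """Ground truth for a vessel-transection wound series.

    node_roi_a / node_roi_b are (row, col, radius) circles over the two
    lymph-node regions. Before ``truth_reconnection_day`` the main vessel
    mask has a gap at the transection site and no path joins the nodes;
    from that day on a continuous path exists. ``collateral_paths`` detour
    vessels may be present on any day but never bridge the gap early.
    """

    node_roi_a: tuple[float, float, float]
    node_roi_b: tuple[float, float, float]
    truth_reconnection_day: int | str = 12
    collateral_paths: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.truth_reconnection_day, str):
            if self.truth_reconnection_day != "never":
                raise InvalidParameterError(
                    'truth_reconnection_day must be an int >= 1 or "never"'
                )
        elif self.truth_reconnection_day < 1:
            raise InvalidParameterError("truth_reconnection_day must be >= 1")
        if self.collateral_paths < 0:
            raise InvalidParameterError("collateral_paths must be >= 0")
        ra, rb = self.node_roi_a, self.node_roi_b
        d = np.hypot(ra[0] - rb[0], ra[1] - rb[1])
        if d <= ra[2] + rb[2]:
            raise InvalidParameterError("node ROIs must be disjoint")


# ---------------------------------------------------------------------------
# trace / stack generators
# ---------------------------------------------------------------------------


def _pulse_times(
    contraction: ContractionParams, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Trough center times in seconds, first pulse half an interval in."""
    if contraction.true_rate == 0 or contraction.amplitude_fraction == 0:
        return np.empty(0)
    mean_iv = 60.0 / contraction.true_rate
    cv = contraction.rate_jitter_cv
    # generous upper bound on the number of intervals needed
    n_max = int(duration_s / mean_iv * 3) + 20
    if cv == 0:
        intervals = np.full(n_max, mean_iv)
    else:
        shape = 1.0 / cv**2
        intervals = rng.gamma(shape, mean_iv / shape, size=n_max)
    times = np.cumsum(intervals) - 0.5 * intervals[0]
    return times[times < duration_s]


def _pulse_waveform(
    t: np.ndarray, times: np.ndarray, width_s: float
) -> np.ndarray:
    """Sum of unit-depth raised-cosine dips centered on ``times``."""
    dip = np.zeros_like(t)
    for t0 in times:
        u = (t - t0) / width_s
        sel = np.abs(u) <= 0.5
        dip[sel] += 0.5 * (1.0 + np.cos(2.0 * np.pi * u[sel]))
    return dip


def _clean_pulsation(
    contraction: ContractionParams,
    camera: CameraParams,
    duration_s: float,
    rng_time: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless modulation: (per-frame dip in [0,1], truth frames, times)."""
    n = int(round(duration_s * camera.fps))
    t = np.arange(n) / camera.fps
    times = _pulse_times(contraction, duration_s, rng_time)
    if times.size == 0:
        return np.zeros(n), np.empty(0, dtype=int), times
    width_s = 0.5 * 60.0 / contraction.true_rate
    dip = _pulse_waveform(t, times, width_s)
    # ground truth = observable minima of the noiseless component; jittered
    # dips that overlap merge into a single observable trough
    minima, _ = find_peaks(dip, prominence=1e-9)
    truth = minima[(minima >= 1) & (minima <= n - 2)]
    return dip, truth.astype(int), times


def _apply_camera_noise(
    clean: np.ndarray, camera: CameraParams, rng: np.random.Generator
) -> np.ndarray:
    out = np.clip(clean, 0.0, None)
    if camera.shot_noise:
        out = rng.poisson(out).astype(float)
    if camera.read_noise_sd > 0:
        out = out + rng.normal(0.0, camera.read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, camera.max_intensity)


def simulate_trace(
    contraction: ContractionParams,
    camera: CameraParams,
    duration_s: float,
    seed: int,
) -> tuple[IntensityTrace, np.ndarray]:
    """Simulate a mean-ROI intensity trace of a pumping vessel.

    Returns the trace and the ground-truth trough frame indices (interior
    local minima of the noiseless pulsation component).
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be > 0")
    rng_time, rng_noise = np.random.default_rng(seed).spawn(2)
    n = int(round(duration_s * camera.fps))
    dip, truth, _ = _clean_pulsation(contraction, camera, duration_s, rng_time)
    base = camera.background_level
    clean = base * (1.0 - contraction.amplitude_fraction * dip)
    clean = clean + contraction.drift_slope * np.arange(n)
    noisy = clean
    if camera.shot_noise or camera.read_noise_sd > 0:
        noisy = _apply_camera_noise(clean, camera, rng_noise)
    return IntensityTrace(values=noisy, fps=camera.fps), truth


def distance_to_polyline(
    shape: tuple[int, int], polyline: tuple[tuple[float, float], ...]
) -> np.ndarray:
    """Per-pixel Euclidean distance to a polyline (min over segments)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dmin = np.full(pts.shape[0], np.inf)
    poly = np.asarray(polyline, dtype=float)
    for p0, p1 in zip(poly[:-1], poly[1:]):
        seg = p1 - p0
        L2 = seg @ seg
        if L2 == 0:
            d = np.linalg.norm(pts - p0, axis=1)
        else:
            u = np.clip((pts - p0) @ seg / L2, 0.0, 1.0)
            proj = p0 + u[:, None] * seg
            d = np.linalg.norm(pts - proj, axis=1)
        dmin = np.minimum(dmin, d)
    return dmin.reshape(shape)


def vessel_mask(geometry: VesselGeometry) -> np.ndarray:
    """Ground-truth vessel mask: pixels within radius_px of the centerline."""
    return distance_to_polyline(geometry.image_shape, geometry.centerline) <= (
        geometry.radius_px
    )


def simulate_stack(
    geometry: VesselGeometry,
    contraction: ContractionParams,
    camera: CameraParams,
    duration_s: float,
    seed: int,
    vessel_contrast: float = 150.0,
    psf_sigma_px: float = 0.8,
) -> tuple[ImageStack, np.ndarray, np.ndarray]:
    """Simulate a NIRF movie of one pulsating vessel.

    Vessel pixels carry ``vessel_contrast`` intensity above background,
    modulated by the contraction model; the whole frame sits on the camera
    background with shot/read noise. Returns (stack, truth mask, truth
    trough frames).
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be > 0")
    rng_time, rng_noise = np.random.default_rng(seed).spawn(2)
    n = int(round(duration_s * camera.fps))
    dip, truth, _ = _clean_pulsation(contraction, camera, duration_s, rng_time)
    mask = vessel_mask(geometry)
    profile = mask.astype(float)
    if psf_sigma_px > 0:  # mild optical blur; truth mask stays crisp
        profile = gaussian_filter(profile, psf_sigma_px)
    mod = 1.0 - contraction.amplitude_fraction * dip  # per-frame, in [0,1]
    frames = camera.background_level + (
        vessel_contrast * mod[:, None, None] * profile[None, :, :]
    )
    if camera.shot_noise or camera.read_noise_sd > 0:
        frames = _apply_camera_noise(frames, camera, rng_noise)
    stack = ImageStack(frames=frames, fps=camera.fps)
    return stack, mask, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Per-animal rates below this are not physiological; draws are resampled.
RATE_FLOOR = 0.5


def _truncated_rate(
    preset: GenotypePreset, rng: np.random.Generator
) -> float:
    for _ in range(1000):
        r = rng.normal(preset.mean_rate, preset.sd_rate)
        if r >= RATE_FLOOR:
            return float(r)
    raise RuntimeError("truncated sampling failed; preset far below floor")


def simulate_cohort(
    presets: list[GenotypePreset],
    n_per_genotype: int,
    schedule: tuple[tuple[str, int], ...] = DEFAULT_SCHEDULE,
    seed: int = 0,
    duration_s: float = 180.0,
    contraction_template: ContractionParams | None = None,
    camera: CameraParams | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Simulate a multi-genotype baseline cohort.

    Each animal's true rate is drawn Normal(mean, sd) truncated at
    0.5 pumps/min; every (side, day) in ``schedule`` yields one noisy trace
    at that rate. Returns a dict keyed (genotype, animal, side, day) ->
    (IntensityTrace, truth trough frames) and a truth table with one row
    per animal.
    """
    if not presets:
        raise InvalidParameterError("presets must be non-empty")
    if n_per_genotype < 1:
        raise InvalidParameterError("n_per_genotype must be >= 1")
    if not schedule:
        raise InvalidParameterError("schedule must be non-empty")
    camera = camera or CameraParams()
    template = contraction_template or ContractionParams(true_rate=1.0)
    master = np.random.default_rng(seed)
    rate_rng = master.spawn(1)[0]
    traces: dict = {}
    rows = []
    trace_seed = 0
    # child seeds derived deterministically from the master stream
    seed_stream = master.spawn(1)[0]
    for preset in presets:
        for animal in range(n_per_genotype):
            rate = (
                preset.mean_rate
                if preset.sd_rate == 0
                else _truncated_rate(preset, rate_rng)
            )
            rows.append(
                {
                    "genotype": preset.name,
                    "animal": animal,
                    "true_rate": rate,
                }
            )
            contraction = ContractionParams(
                true_rate=rate,
                amplitude_fraction=template.amplitude_fraction,
                rate_jitter_cv=template.rate_jitter_cv,
                drift_slope=template.drift_slope,
            )
            for side, day in schedule:
                trace_seed = int(seed_stream.integers(0, 2**31 - 1))
                trace, truth = simulate_trace(
                    contraction, camera, duration_s, trace_seed
                )
                traces[(preset.name, animal, side, day)] = (trace, truth)
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# wound series
# ---------------------------------------------------------------------------


def _collateral_polyline(
    start: np.ndarray, end: np.ndarray, bulge: float, n_pts: int = 8
) -> tuple[tuple[float, float], ...]:
    """Arc from start to end bowed sideways by ``bulge`` pixels."""
    u = np.linspace(0.0, 1.0, n_pts)
    seg = end - start
    normal = np.array([-seg[1], seg[0]])
    nrm = np.linalg.norm(normal)
    if nrm > 0:
        normal = normal / nrm
    pts = start[None, :] + u[:, None] * seg[None, :]
    pts = pts + (np.sin(np.pi * u) * bulge)[:, None] * normal[None, :]
    return tuple((float(r), float(c)) for r, c in pts)


def simulate_wound_series(
    spec: WoundSpec,
    geometry: VesselGeometry,
    days: list[int],
    seed: int,
    duration_s: float = 10.0,
    camera: CameraParams | None = None,
    gap_halfwidth_px: float = 6.0,
) -> dict[int, tuple[ImageStack, np.ndarray]]:
    """Simulate repeated post-transection imaging of the wounded vessel.

    The main vessel (``geometry``) runs node A -> node B. On days before
    the truth reconnection day its mask has a gap of 2*gap_halfwidth_px
    centered at the transection site (polyline midpoint by arc length);
    from the truth day on the vessel is continuous. Collateral detours, if
    requested, sit entirely on the node-A side and never reach node B.
    """
    if sorted(days) != list(days):
        raise InvalidParameterError("days must be sorted ascending")
    camera = camera or CameraParams()
    poly = np.asarray(geometry.centerline, dtype=float)
    seglen = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]

    def point_at(s: float) -> np.ndarray:
        s = np.clip(s, 0.0, total)
        i = int(np.searchsorted(arclen, s, side="right") - 1)
        i = min(i, len(seglen) - 1)
        f = (s - arclen[i]) / seglen[i] if seglen[i] > 0 else 0.0
        return poly[i] + f * (poly[i + 1] - poly[i])

    def sub_polyline(s0: float, s1: float) -> tuple[tuple[float, float], ...]:
        ss = [s0] + [s for s in arclen if s0 < s < s1] + [s1]
        return tuple((float(p[0]), float(p[1])) for p in (point_at(s) for s in ss))

    mid = total / 2.0
    cut_a = sub_polyline(0.0, mid - gap_halfwidth_px)
    cut_b = sub_polyline(mid + gap_halfwidth_px, total)

    rng = np.random.default_rng(seed)
    collaterals = []
    for _ in range(spec.collateral_paths):
        # detour on the A side only: between two points upstream of the cut
        s0 = rng.uniform(0.05, 0.35) * (mid - gap_halfwidth_px)
        s1 = rng.uniform(0.55, 0.95) * (mid - gap_halfwidth_px)
        bulge = rng.uniform(6.0, 12.0) * rng.choice([-1.0, 1.0])
        pts = _collateral_polyline(point_at(s0), point_at(s1), bulge)
        h, w = geometry.image_shape
        pts = tuple(
            (min(max(r, 0.0), h - 1.0), min(max(c, 0.0), w - 1.0)) for r, c in pts
        )
        collaterals.append(pts)

    day_seeds = rng.integers(0, 2**31 - 1, size=len(days))
    truth_day = spec.truth_reconnection_day
    out: dict[int, tuple[ImageStack, np.ndarray]] = {}
    for day, dseed in zip(days, day_seeds):
        connected = truth_day != "never" and day >= truth_day
        polylines = (
            [tuple((float(r), float(c)) for r, c in poly)]
            if connected
            else [cut_a, cut_b]
        )
        polylines += collaterals
        mask = np.zeros(geometry.image_shape, dtype=bool)
        for pl in polylines:
            if len(pl) >= 2:
                mask |= (
                    distance_to_polyline(geometry.image_shape, pl)
                    <= geometry.radius_px
                )
        profile = gaussian_filter(mask.astype(float), 0.8)
        n = int(round(duration_s * camera.fps))
        frames = camera.background_level + 150.0 * profile[None, :, :] * np.ones(
            (n, 1, 1)
        )
        frames = _apply_camera_noise(
            frames, camera, np.random.default_rng(int(dseed))
        )
        out[day] = (ImageStack(frames=frames, fps=camera.fps), mask)
    return out


# ---------------------------------------------------------------------------
# IHC phantom
# ---------------------------------------------------------------------------


def make_ihc_phantom(
    positive_fraction: float,
    texture_scale: float = 4.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
) -> tuple[np.ndarray, np.ndarray]:
    """IHC-like image with a known positive-stain area fraction.

    A smooth random field is thresholded at the matching quantile, so the
    truth-mask fraction equals ``positive_fraction`` to within 2%. Positive
    pixels are drawn brighter than background.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise InvalidParameterError("positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    field = gaussian_filter(rng.standard_normal(shape), texture_scale)
    if positive_fraction <= 0.0:
        mask = np.zeros(shape, dtype=bool)
    elif positive_fraction >= 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        thr = np.quantile(field, 1.0 - positive_fraction)
        mask = field > thr
    image = 80.0 + 12.0 * rng.standard_normal(shape)
    image[mask] = 160.0 + 18.0 * rng.standard_normal(int(mask.sum()))
    return np.clip(image, 0.0, 255.0), mask


def load_presets(path) -> dict[str, GenotypePreset]:
    """Read genotype presets from a TOML table ``[presets.<name>]``."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    out = {}
    for name, entry in doc.get("presets", {}).items():
        out[name] = GenotypePreset(
            name=name,
            mean_rate=float(entry["mean_rate"]),
            sd_rate=float(entry["sd_rate"]),
            n_default=int(entry.get("n_default", 6)),
        )
    return out
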