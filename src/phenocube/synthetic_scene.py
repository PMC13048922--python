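"""Seeded synthetic arid-zone scenes for exercising the mapping pipeline.

Real field waypoints and the full Sentinel-2 archive are not distributable,
so tests and benchmarks run on simulated landscapes that reproduce the
statistical structure the method exploits: irregular acquisition dates,
rainfall-pulse greenness dynamics in which buffel grass greens up faster,
peaks higher and senesces more slowly than native grasses, fire events that
depress NBR, cloud/nodata dropout, and a blocky land-cover mosaic with
landscape strata.

All randomness flows through one ``numpy.random.Generator`` derived from the
scene seed; identical config + seed yields a bit-identical scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .indices_cube import (
    BANDS,
    DegenerateConfigError,
    GridGeoreference,
    ReflectanceCube,
    as_day_array,
)

LN2 = float(np.log(2.0))

# fixed 5-band endmembers (BLUE, GREEN, RED, NIR, SWIR1); simulator constants
SOIL_ENDMEMBER = np.array([0.14, 0.18, 0.24, 0.30, 0.38])
GREEN_ENDMEMBER = np.array([0.03, 0.07, 0.05, 0.42, 0.19])
CHAR_ENDMEMBER = np.array([0.04, 0.05, 0.06, 0.08, 0.24])

#: e-folding-style half-life (days) of the char signal after a fire
CHAR_FADE_HALFLIFE = 240.0

COVER_NAMES = ("buffel", "native_tussock", "spinifex", "shrub_canopy", "bare",
               "riparian_woodland")
STRATUM_NAMES = ("alluvial_plain", "granite_range", "dunefield")


@dataclass(frozen=True)
class PhenologyParams:
    """Rain-response parameters of one cover class.

    The response to a rain pulse rises linearly at ``rise_rate`` per day
    (after ``lag_days``), peaks, then decays exponentially with half-life
    ``decay_halflife_days``.  ``amplitude`` is peak fractional green cover
    per mm of rain; ``baseline`` is the dry-season green fraction.
    """

    lag_days: float
    rise_rate: float
    decay_halflife_days: float
    amplitude: float
    baseline: float

    def __post_init__(self):
        for name in ("lag_days", "rise_rate", "decay_halflife_days", "amplitude",
                     "baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class CoverClass:
    name: str
    phenology: PhenologyParams
    endmember: np.ndarray = field(default_factory=lambda: GREEN_ENDMEMBER.copy())

    def __post_init__(self):
        if self.name not in COVER_NAMES:
            raise ValueError(f"unknown cover class {self.name!r}")
        e = np.asarray(self.endmember, dtype=float)
        if e.shape != (5,) or e.min() < 0 or e.max() > 1:
            raise ValueError("endmember must be 5 reflectances in [0, 1]")
        object.__setattr__(self, "endmember", e)


def default_cover_classes() -> list[CoverClass]:
    """The six default cover classes.

    Buffel has a strictly shorter lag, larger amplitude and longer decay
    half-life than either native grass class (tussock grasses and spinifex),
    encoding its faster, higher, longer-lasting green-up.
    """
    p = PhenologyParams
    return [
        CoverClass("buffel", p(2, 0.25, 60, 0.035, 0.15)),
        CoverClass("native_tussock", p(6, 0.10, 25, 0.015, 0.05)),
        CoverClass("spinifex", p(10, 0.06, 40, 0.008, 0.12)),
        CoverClass("shrub_canopy", p(12, 0.05, 90, 0.006, 0.30)),
        CoverClass("bare", p(0, 0.0, 30, 0.0, 0.02)),
        CoverClass("riparian_woodland", p(8, 0.08, 120, 0.010, 0.45)),
    ]


def _check_buffel_contrast(classes):
    by = {c.name: c.phenology for c in classes}
    b = by["buffel"]
    for other in ("native_tussock", "spinifex"):
        if other not in by:
            continue
        o = by[other]
        if not (b.lag_days < o.lag_days and b.amplitude > o.amplitude
                and b.decay_halflife_days > o.decay_halflife_days):
            raise ValueError(
                f"buffel phenology must green faster, higher and longer than {other}"
            )


@dataclass(frozen=True)
class RainfallSeries:
    event_dates: np.ndarray
    event_magnitudes: np.ndarray

    def __post_init__(self):
        d = as_day_array(self.event_dates)
        m = np.asarray(self.event_magnitudes, dtype=float)
        if d.size != m.size:
            raise ValueError("event dates and magnitudes differ in length")
        if d.size and np.any(np.diff(d) <= np.timedelta64(0, "D")):
            raise ValueError("event dates must be strictly increasing")
        if np.any(m < 0):
            raise ValueError("event magnitudes must be nonnegative")
        object.__setattr__(self, "event_dates", d)
        object.__setattr__(self, "event_magnitudes", m)

    @property
    def n_events(self) -> int:
        return self.event_dates.size


@dataclass(frozen=True)
class FireSchedule:
    """List of (date, burned-pixel mask, severity in [0, 1]) events."""

    events: tuple = ()

    def __post_init__(self):
        evs = []
        for d, mask, sev in self.events:
            if not 0.0 <= sev <= 1.0:
                raise ValueError(f"fire severity {sev} outside [0, 1]")
            evs.append((np.datetime64(d, "D"), np.asarray(mask, dtype=bool), float(sev)))
        object.__setattr__(self, "events", tuple(evs))


@dataclass(frozen=True)
class SceneConfig:
    grid_rows: int = 64
    grid_cols: int = 64
    start_date: date = date(2016, 1, 1)
    end_date: date = date(2025, 1, 1)
    revisit_days: int = 5
    dropout_prob: float = 0.70
    cloud_prob: float = 0.25
    cloud_beta_params: tuple = (1.5, 30.0)
    nodata_prob: float = 0.05
    noise_sd: float = 0.02
    noise_mode: str = "additive"
    rain_rate_per_year: float = 4.0
    rain_magnitude_mean: float = 20.0
    fire_rate_per_year: float = 0.35
    riparian_infest_prob: float = 0.5
    seed: int = 42

    def __post_init__(self):
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise DegenerateConfigError("grid dimensions must be >= 1")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise DegenerateConfigError("dropout_prob must lie in [0, 1)")
        if self.noise_sd < 0:
            raise DegenerateConfigError("noise_sd must be nonnegative")
        if self.noise_mode not in ("additive", "multiplicative"):
            raise DegenerateConfigError(f"unknown noise_mode {self.noise_mode!r}")
        if self.start_date >= self.end_date:
            raise DegenerateConfigError("start_date must precede end_date")


@dataclass
class SyntheticScene:
    cube: ReflectanceCube
    truth_labels: np.ndarray          # bool (rows, cols): buffel present
    strata: np.ndarray                # int (rows, cols): stratum id
    cover_map: np.ndarray             # int (rows, cols): index into classes
    classes: list
    rainfall: RainfallSeries
    fires: FireSchedule
    config: SceneConfig
    green_traces: np.ndarray | None = None   # noise-free (n_classes, n_dates)


# ---------------------------------------------------------------------------
# acquisition dates and drivers

def generate_dates(config: SceneConfig, rng: np.random.Generator | None = None):
    """Nominal revisit-interval dates with seeded random dropout."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    start = np.datetime64(config.start_date, "D")
    end = np.datetime64(config.end_date, "D")
    nominal = np.arange(start, end + np.timedelta64(1, "D"),
                        np.timedelta64(config.revisit_days, "D"))
    if nominal.size == 0:
        raise DegenerateConfigError("date span shorter than the revisit interval")
    keep = rng.random(nominal.size) >= config.dropout_prob
    dates = nominal[keep]
    if dates.size == 0:
        raise DegenerateConfigError("all acquisition dates dropped; lower dropout_prob")
    return dates


def simulate_rainfall(dates, rate_per_year: float, magnitude_mean: float,
                      seed=None, rng: np.random.Generator | None = None) -> RainfallSeries:
    """Homogeneous-Poisson rain events with exponential magnitudes (mm)."""
    if rate_per_year <= 0:
        raise ValueError("rate_per_year must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    dates = as_day_array(dates)
    span_days = float((dates[-1] - dates[0]).astype(int))
    n = rng.poisson(rate_per_year * span_days / 365.25)
    offsets = np.sort(rng.uniform(0.0, span_days, size=n))
    mags = rng.exponential(magnitude_mean, size=n)
    days = dates[0] + np.round(offsets).astype(int).astype("timedelta64[D]")
    # merge events that round onto the same day to keep dates strictly increasing
    uniq, inv = np.unique(days, return_inverse=True)
    merged = np.zeros(uniq.size)
    np.add.at(merged, inv, mags)
    return RainfallSeries(event_dates=uniq, event_magnitudes=merged)


def response_kernel(tau_days: np.ndarray, rise_rate: float,
                    decay_halflife_days: float) -> np.ndarray:
    """Rise-then-decay pulse response, K(0)=0, peak value 1.

    Linear rise reaching 1 at tau = 1/rise_rate, then exponential decay with
    the given half-life.  rise_rate = 0 means no response at all.
    """
    tau = np.asarray(tau_days, dtype=float)
    if rise_rate <= 0:
        return np.zeros_like(tau)
    t_peak = 1.0 / rise_rate
    rising = np.clip(tau * rise_rate, 0.0, 1.0)
    decaying = np.exp(-LN2 * np.maximum(tau - t_peak, 0.0) / decay_halflife_days)
    return np.where(tau <= 0, 0.0, rising * decaying)


def fire_factor(tau_days: np.ndarray, severity: float, rise_rate: float) -> np.ndarray:
    """Multiplicative green-cover suppression after a fire.

    Drops to (1 - severity) at the fire date and recovers along the rise
    limb of the class response kernel.
    """
    tau = np.asarray(tau_days, dtype=float)
    recovery = np.clip(tau * rise_rate, 0.0, 1.0) if rise_rate > 0 else 0.0
    factor = 1.0 - severity * (1.0 - recovery)
    return np.where(tau < 0, 1.0, factor)


def greenness_trace(params: PhenologyParams, rain: RainfallSeries,
                    fire: FireSchedule, dates) -> np.ndarray:
    """Per-date fractional green cover for one cover class.

    Every fire event in the schedule is applied; spatial burn masks are the
    renderer's concern.
    """
    dates = as_day_array(dates)
    if dates.size == 0:
        raise ValueError("dates must be nonempty")
    t = (dates - dates[0]).astype(float)
    g = np.full(t.shape, params.baseline, dtype=float)
    for ev_date, mag in zip(rain.event_dates, rain.event_magnitudes):
        tau = t - float((ev_date - dates[0]).astype(int)) - params.lag_days
        g += params.amplitude * mag * response_kernel(
            tau, params.rise_rate, params.decay_halflife_days)
    for ev_date, _mask, sev in fire.events:
        tau = t - float((np.datetime64(ev_date, "D") - dates[0]).astype(int))
        g *= fire_factor(tau, sev, params.rise_rate)
    return np.clip(g, 0.0, 1.0)


# ---------------------------------------------------------------------------
# landscape layout

#: per-stratum cover-class mixture (order follows COVER_NAMES)
_STRATUM_MIX = {
    0: (0.35, 0.25, 0.10, 0.15, 0.10, 0.05),   # alluvial plain: buffel-rich
    1: (0.15, 0.30, 0.30, 0.15, 0.10, 0.00),   # granite range: intermediate
    2: (0.00, 0.20, 0.55, 0.05, 0.20, 0.00),   # dunefield: buffel-free
}
_STRATUM_SPLITS = (0.40, 0.75)   # row fractions separating the three bands
_BLOCK = 8                       # cover patches are BLOCK x BLOCK pixel blocks


def build_landscape(config: SceneConfig, rng: np.random.Generator):
    """Blocky cover-class mosaic in three horizontal strata plus a riparian
    corridor; returns (cover_map, strata, infested_mask)."""
    rows, cols = config.grid_rows, config.grid_cols
    strata = np.zeros((rows, cols), dtype=int)
    r1 = int(round(rows * _STRATUM_SPLITS[0]))
    r2 = int(round(rows * _STRATUM_SPLITS[1]))
    strata[r1:r2] = 1
    strata[r2:] = 2

    cover = np.zeros((rows, cols), dtype=int)
    for br in range(0, rows, _BLOCK):
        for bc in range(0, cols, _BLOCK):
            sid = int(strata[br, bc])
            cover[br:br + _BLOCK, bc:bc + _BLOCK] = rng.choice(
                len(COVER_NAMES), p=_STRATUM_MIX[sid])

    # riparian corridor: a meandering vertical strip through every stratum
    rip = COVER_NAMES.index("riparian_woodland")
    center = cols * 0.5
    rr = np.arange(rows)
    mid = center + 0.15 * cols * np.sin(2 * np.pi * rr / max(rows, 1) * 1.5)
    half_w = max(1, cols // 42)
    corridor = np.abs(np.arange(cols)[None, :] - mid[:, None]) <= half_w
    cover[corridor] = rip

    # a seeded fraction of riparian pixels carry a buffel understory
    infested = corridor & (rng.random((rows, cols)) < config.riparian_infest_prob)
    return cover, strata, infested


def simulate_fires(config: SceneConfig, dates, strata, rng: np.random.Generator) -> FireSchedule:
    """Poisson-count fire events, each burning a random rectangle."""
    dates = as_day_array(dates)
    span_years = float((dates[-1] - dates[0]).astype(int)) / 365.25
    n = rng.poisson(config.fire_rate_per_year * span_years)
    rows, cols = strata.shape
    events = []
    for _ in range(n):
        day = dates[0] + np.timedelta64(int(rng.integers(30, max(31, int(span_years * 365.25)))), "D")
        h = int(rng.integers(rows // 6 + 1, rows // 2 + 1))
        w = int(rng.integers(cols // 6 + 1, cols // 2 + 1))
        r0 = int(rng.integers(0, rows - h + 1))
        c0 = int(rng.integers(0, cols - w + 1))
        mask = np.zeros((rows, cols), dtype=bool)
        mask[r0:r0 + h, c0:c0 + w] = True
        severity = float(rng.uniform(0.5, 1.0))
        events.append((day, mask, severity))
    events.sort(key=lambda e: e[0])
    return FireSchedule(events=tuple(events))


# ---------------------------------------------------------------------------
# rendering

def render_reflectance(
    dates,
    cover_map: np.ndarray,
    classes,
    rain: RainfallSeries,
    fires: FireSchedule,
    config: SceneConfig,
    rng: np.random.Generator,
    understory_weight: np.ndarray | None = None,
    geo: GridGeoreference | None = None,
):
    """Linear-mixture rendering of the scene into a ReflectanceCube.

    Per pixel and date: reflectance = g * vegetation endmember +
    (1 - g) * soil endmember, with the green fraction g from the pixel's
    cover-class trace (optionally blended with the buffel trace through
    ``understory_weight``).  Burned pixels blend toward a char endmember
    with exponentially fading weight.  Gaussian noise is added (or applied
    multiplicatively) and everything is clipped to [0, 1].  Cloud patches
    are contiguous rectangles; occasional nodata strips emulate partial
    mosaics.

    Returns (cube, green_traces) with green_traces the noise-free per-class
    (n_classes, n_dates) green fractions.
    """
    dates = as_day_array(dates)
    rows, cols = cover_map.shape
    n_t = dates.size
    name_to_i = {c.name: i for i, c in enumerate(classes)}

    # noise-free fire-free per-class traces; fires are applied per pixel
    no_fire = FireSchedule()
    traces = np.stack([greenness_trace(c.phenology, rain, no_fire, dates)
                       for c in classes])                       # (C, T)

    g = traces[cover_map]                                        # (rows, cols, T)
    g = np.moveaxis(g, -1, 0)                                    # (T, rows, cols)
    if understory_weight is not None:
        gb = traces[name_to_i["buffel"]]
        w = understory_weight[None, :, :]
        g = (1.0 - w) * g + w * gb[:, None, None]

    t = (dates - dates[0]).astype(float)
    char_weight = np.zeros((n_t, rows, cols))
    for ev_date, mask, sev in fires.events:
        tau = t - float((ev_date - dates[0]).astype(int))
        rise = np.stack([fire_factor(tau, sev, c.phenology.rise_rate) for c in classes])
        factor = np.moveaxis(rise[cover_map], -1, 0)             # (T, rows, cols)
        g = np.where(mask[None, :, :], g * factor, g)
        cw = np.where(tau < 0, 0.0, sev * np.exp(-LN2 * np.maximum(tau, 0.0)
                                                 / CHAR_FADE_HALFLIFE))
        char_weight = np.where(mask[None, :, :],
                               np.maximum(char_weight, cw[:, None, None]), char_weight)
    g = np.clip(g, 0.0, 1.0)

    veg = np.stack([c.endmember for c in classes])               # (C, 5)
    band_arrays = {}
    for bi, band in enumerate(BANDS):
        veg_b = veg[cover_map, bi]                               # (rows, cols)
        refl = g * veg_b[None, :, :] + (1.0 - g) * SOIL_ENDMEMBER[bi]
        refl = (1.0 - char_weight) * refl + char_weight * CHAR_ENDMEMBER[bi]
        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, size=refl.shape)
            refl = refl * (1.0 + noise) if config.noise_mode == "multiplicative" \
                else refl + noise
        band_arrays[band] = np.clip(refl, 0.0, 1.0)

    valid = np.ones((n_t, rows, cols), dtype=bool)
    cloud = np.zeros((n_t, rows, cols), dtype=bool)
    a, b = config.cloud_beta_params
    for i in range(n_t):
        if config.cloud_prob > 0 and rng.random() < config.cloud_prob:
            frac = float(rng.beta(a, b))
            area = frac * rows * cols
            h = min(rows, max(1, int(round(np.sqrt(area)))))
            w = min(cols, max(1, int(round(area / h))))
            r0 = int(rng.integers(0, rows - h + 1))
            c0 = int(rng.integers(0, cols - w + 1))
            cloud[i, r0:r0 + h, c0:c0 + w] = True
        if config.nodata_prob > 0 and rng.random() < config.nodata_prob:
            # partial mosaic: a missing edge strip covering 5-35% of the rows
            strip = max(1, int(round(rows * rng.uniform(0.05, 0.35))))
            if rng.random() < 0.5:
                valid[i, :strip, :] = False
            else:
                valid[i, -strip:, :] = False
    valid &= ~cloud

    cube = ReflectanceCube(
        dates=dates,
        bands=band_arrays,
        valid_mask=valid,
        cloud_mask=cloud,
        geo=geo or GridGeoreference(),
    )
    return cube, traces


def build_scene(config: SceneConfig, classes=None) -> SyntheticScene:
    """Generate a full synthetic scene from one seeded config."""
    rng = np.random.default_rng(config.seed)
    classes = list(classes) if classes is not None else default_cover_classes()
    _check_buffel_contrast(classes)

    dates = generate_dates(config, rng)
    rain = simulate_rainfall(dates, config.rain_rate_per_year,
                             config.rain_magnitude_mean, rng=rng)
    cover, strata, infested = build_landscape(config, rng)
    fires = (simulate_fires(config, dates, strata, rng)
             if config.fire_rate_per_year > 0 else FireSchedule())

    understory = infested.astype(float) * 0.6
    cube, traces = render_reflectance(dates, cover, classes, rain, fires,
                                      config, rng, understory_weight=understory)
    buffel_idx = next(i for i, c in enumerate(classes) if c.name == "buffel")
    truth = (cover == buffel_idx) | infested
    return SyntheticScene(
        cube=cube, truth_labels=truth, strata=strata, cover_map=cover,
        classes=classes, rainfall=rain, fires=fires, config=config,
        green_traces=traces,
    )


# ---------------------------------------------------------------------------
# waypoints

def sample_waypoints(scene: SyntheticScene, n: int, stratified: bool = True,
                     seed=None, per_stratum: bool = False) -> pd.DataFrame:
    """Without-replacement ground-truth waypoint sample.

    Stratified sampling allocates ``n`` across strata proportionally to
    stratum area (largest-remainder rounding); with ``per_stratum`` the
    count ``n`` applies to every stratum.  Returns a DataFrame with columns
    x, y, label ('buffel'/'buffel_free'), stratum, row, col.
    """
    rng = np.random.default_rng(scene.config.seed if seed is None else seed)
    rows, cols = scene.truth_labels.shape
    flat_strata = scene.strata.ravel()
    n_px = rows * cols
    if not stratified:
        if n > n_px:
            raise ValueError(f"n={n} exceeds pixel count {n_px}")
        picks = rng.choice(n_px, size=n, replace=False)
    else:
        sids = np.unique(flat_strata)
        if per_stratum:
            alloc = {int(s): n for s in sids}
        else:
            sizes = np.array([(flat_strata == s).sum() for s in sids])
            raw = n * sizes / sizes.sum()
            base = np.floor(raw).astype(int)
            rem = n - base.sum()
            order = np.argsort(-(raw - base))
            base[order[:rem]] += 1
            alloc = {int(s): int(k) for s, k in zip(sids, base)}
        picks = []
        for s, k in alloc.items():
            pool = np.flatnonzero(flat_strata == s)
            if k > pool.size:
                raise ValueError(
                    f"requested {k} waypoints from stratum {s} "
                    f"({STRATUM_NAMES[s] if s < len(STRATUM_NAMES) else s}) "
                    f"but it has only {pool.size} pixels")
            picks.append(rng.choice(pool, size=k, replace=False))
        picks = np.concatenate(picks)
    r, c = np.divmod(picks, cols)
    x, y = scene.cube.geo.pixel_center(r, c)
    labels = np.where(scene.truth_labels.ravel()[picks], "buffel", "buffel_free")
    return pd.DataFrame({
        "x": x, "y": y, "label": labels,
        "stratum": flat_strata[picks], "row": r, "col": c,
    })


# ---------------------------------------------------------------------------
# benchmark configurations

def default_benchmark_config(seed: int = 42) -> SceneConfig:
    """The default 64 x 64, ~9-year benchmark scene (about 180-200
    acquisitions surviving dropout, before mosaic QC)."""
    return SceneConfig(seed=seed)


def rank6_benchmark_config(seed: int = 7) -> SceneConfig:
    """A scene whose noise-free greenness spans six temporal patterns.

    One phenology trace per cover class, no fires, no riparian understory
    blending, no cloud/nodata masking: every noise-free index matrix then
    has at most six distinct column types, hence rank <= 6.  Reflectance
    noise is 5% multiplicative.
    """
    return SceneConfig(
        grid_rows=48, grid_cols=48,
        start_date=date(2018, 1, 1), end_date=date(2022, 1, 1),
        revisit_days=10, dropout_prob=0.30,
        cloud_prob=0.0, nodata_prob=0.0,
        noise_sd=0.05, noise_mode="multiplicative",
        fire_rate_per_year=0.0, riparian_infest_prob=0.0,
        seed=seed,
    )
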