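"""Synthetic time-lapse generator with per-cell ground truth.

Emulates the statistical structure of time-lapse recordings of *C. elegans*
touch neurons undergoing excitotoxic necrosis, so that every analysis stage
(ROI quantification, event detection, integration, cohort statistics) can be
tested against known truth without microscopy data:

* cytoplasmic Ca2+ traces: baseline ~1 fold plus transient peaks that rise
  smoothly and decay back to baseline; necrotic cells reach 1.4-5x
  background, ER-store-deficient (*crt-1*-like) cells are capped at 1.2x;
* cell swelling once the running integral of the Ca2+ enrichment crosses a
  threshold, with linear radius growth afterwards;
* a surface-PS ring appearing a fixed delay after swelling and rising
  sigmoidally, with the integrated PS enrichment log-linearly coupled to the
  integrated Ca2+ enrichment (the coupling the cohort regression recovers);
* cohort-level pharmacology: a dantrolene-like dose lowers the ER release
  gain, a thapsigargin-like dose raises baseline cytoplasmic Ca2+.

The generator is phenomenological: it reproduces trace shapes, event
ordering, and cohort scaling, not ER/cytosol Ca2+ kinetics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .events import (
    FULL_WINDOW,
    RECORD_END,
    IntensityTrace,
    EventTimes,
    default_time_grid,
    integrate_trace,
)

__all__ = [
    "TraceParams",
    "ScenarioConfig",
    "GroundTruthRow",
    "CellRecord",
    "FrameStack",
    "RenderGeometry",
    "simulate_ca_trace",
    "simulate_cell",
    "simulate_cohort",
    "render_frames",
    "scenario_config",
    "coupled_ps_integral",
]

# Calibrated so that the default necrotic cohort's mean swelling time sits
# near the boundary between the fast and slow acquisition epochs (~695 min),
# the mean time at which swelling becomes visible in recordings.
DEFAULT_SWELLING_THRESHOLD = 80.0

# Fold range of necrotic Ca2+ peak amplitudes over background.
NECROTIC_PEAK_RANGE = (1.4, 5.0)
CRT1_PEAK_CAP = 1.2


@dataclass(frozen=True)
class TraceParams:
    """Shape parameters of one cell's Ca2+ trace.

    Amplitudes and the cap are folds over background; a peak is a smooth
    bump (half-Gaussian rise of width ``peak_rise_width``, exponential decay
    of time constant ``peak_decay_width``) added to the baseline.
    """

    baseline_level: float = 1.0
    peak_amplitudes: tuple[float, ...] = ()
    peak_times: tuple[float, ...] = ()
    peak_rise_width: float = 7.0
    peak_decay_width: float = 20.0
    peak_cap: float = math.inf
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be positive")
        if self.peak_rise_width <= 0 or self.peak_decay_width <= 0:
            raise ValueError("peak widths must be positive")
        if len(self.peak_amplitudes) != len(self.peak_times):
            raise ValueError("peak_amplitudes and peak_times must have equal length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def simulate_ca_trace(
    params: TraceParams, times: np.ndarray, cell_id: str = "", channel: str = "Ca"
) -> IntensityTrace:
    """Render a relative-intensity Ca2+ trace on the given time grid."""
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be nonempty and strictly increasing")
    v = np.full_like(times, params.baseline_level)
    for amp, t0 in zip(params.peak_amplitudes, params.peak_times):
        rise = np.exp(-((times - t0) ** 2) / (2.0 * params.peak_rise_width**2))
        decay = np.exp(-(times - t0) / params.peak_decay_width)
        bump = np.where(times < t0, rise, decay)
        v = v + (amp - 1.0) * bump
    v = np.minimum(v, params.peak_cap)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        v = np.clip(v * rng.normal(1.0, params.noise_sd, size=v.shape), 0.0, None)
    return IntensityTrace(times=times, values=v, cell_id=cell_id, channel=channel)


@dataclass(frozen=True)
class ScenarioConfig:
    """Genotype/drug parameterization of a simulated cohort.

    ``channel_leak`` scales the Ca2+ influx driving the transients,
    ``er_release_gain`` multiplies peak amplitudes (a dantrolene-like dose
    lowers it; *crt-1*-like loss of the ER store sets it near 0),
    ``reuptake_block`` raises the baseline fold (thapsigargin-like).
    ``ps_coupling_slope`` and ``ps_coupling_intercept`` define the
    log-linear map from the integrated Ca2+ enrichment to the integrated PS
    enrichment (both in fold*minutes over the 560-800 min analysis window).
    """

    scenario_name: str
    n_cells: int = 4
    channel_leak: float = 1.0
    er_release_gain: float = 1.0
    reuptake_block: float = 0.0
    swelling_threshold: float = DEFAULT_SWELLING_THRESHOLD
    ps_coupling_slope: float = 1.0
    ps_coupling_intercept: float = 0.3
    ps_delay: float = 40.0
    ps_ramp: float = 30.0
    peak_cap: float = math.inf
    noise_sd: float = 0.0
    n_peaks_range: tuple[int, int] = (2, 4)
    peak_time_range: tuple[float, float] = (590.0, 740.0)
    rise_width_range: tuple[float, float] = (5.0, 10.0)
    decay_width_range: tuple[float, float] = (12.0, 28.0)
    initial_radius: float = 4.0
    swell_factor: float = 2.5
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("channel_leak", "er_release_gain", "reuptake_block"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.swelling_threshold <= 0:
            raise ValueError("swelling_threshold must be positive")
        if self.ps_delay < 0 or self.ps_ramp <= 0:
            raise ValueError("ps_delay must be >= 0 and ps_ramp > 0")
        if self.initial_radius <= 0 or self.swell_factor < 1:
            raise ValueError("initial_radius > 0 and swell_factor >= 1 required")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    def to_json(self) -> str:
        return json.dumps({"schema_version": 1, **asdict(self)}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        data = json.loads(text)
        data.pop("schema_version", None)
        for key in ("n_peaks_range", "peak_time_range", "rise_width_range", "decay_width_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class GroundTruthRow:
    """True events, integrals, and geometry for one simulated cell."""

    scenario: str
    cell_id: str
    ca_onset: float | None
    swelling_onset: float | None
    ps_onset: float | None
    ca_integral: float  # enrichment integral, fold*min over 560-800
    ps_integral: float
    ps_plateau: float  # plateau enrichment (RPS - 1)
    initial_radius: float
    final_radius: float

    @property
    def events(self) -> EventTimes:
        return EventTimes(self.ca_onset, self.swelling_onset, self.ps_onset)


@dataclass(frozen=True)
class CellRecord:
    """One simulated cell: observed traces, radius track, and ground truth."""

    ca: IntensityTrace
    ps: IntensityTrace
    times: np.ndarray
    radii: np.ndarray
    truth: GroundTruthRow


def coupled_ps_integral(ca_integral: float, slope: float, intercept: float) -> float:
    """Log-linear coupling: integrated PS enrichment as a function of the
    integrated Ca2+ enrichment (natural log)."""
    if ca_integral <= 0:
        return 0.0
    return math.exp(intercept + slope * math.log(ca_integral))


def _smoothstep(t: np.ndarray, start: float, ramp: float) -> np.ndarray:
    """0 before ``start``, cubic smoothstep over ``ramp`` minutes, then 1."""
    x = np.clip((t - start) / ramp, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _enrichment_integral(times: np.ndarray, values: np.ndarray) -> float:
    trace = IntensityTrace(times=times, values=np.clip(values - 1.0, 0.0, None))
    return integrate_trace(trace, FULL_WINDOW, require_qualified=False)


def simulate_cell(
    config: ScenarioConfig, cell_index: int, times: np.ndarray | None = None
) -> CellRecord:
    """Simulate one cell of a scenario; deterministic given (seed, index)."""
    if times is None:
        times = default_time_grid()
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng([config.seed % (2**31), cell_index])
    cell_id = f"{config.scenario_name}/c{cell_index}"

    baseline = 1.0 + config.reuptake_block * rng.uniform(0.5, 1.5)
    n_peaks = int(rng.integers(config.n_peaks_range[0], config.n_peaks_range[1] + 1))
    drive = config.channel_leak * config.er_release_gain
    amplitudes = 1.0 + drive * rng.uniform(
        NECROTIC_PEAK_RANGE[0] - 1.0, NECROTIC_PEAK_RANGE[1] - 1.0, size=n_peaks
    )
    peak_times = np.sort(rng.uniform(*config.peak_time_range, size=n_peaks))
    rise_w = rng.uniform(*config.rise_width_range)
    decay_w = rng.uniform(*config.decay_width_range)

    clean_params = TraceParams(
        baseline_level=baseline,
        peak_amplitudes=tuple(amplitudes),
        peak_times=tuple(peak_times),
        peak_rise_width=rise_w,
        peak_decay_width=decay_w,
        peak_cap=config.peak_cap,
        noise_sd=0.0,
    )
    ca_clean = simulate_ca_trace(clean_params, times, cell_id=cell_id).values

    # --- ground-truth events from the noise-free signal ---
    onset_level = max(CRT1_PEAK_CAP, baseline + 0.2)
    above = np.nonzero(ca_clean > onset_level)[0]
    ca_onset = float(times[above[0]]) if above.size else None

    running = np.concatenate([[0.0], cumulative_trapezoid(ca_clean - 1.0, times)])
    crossed = np.nonzero(running > config.swelling_threshold)[0]
    swelling_onset = float(times[crossed[0]]) if crossed.size else None

    radii = np.full_like(times, config.initial_radius)
    ps_clean = np.ones_like(times)
    ps_onset: float | None = None
    ps_integral = 0.0
    plateau = 0.0
    if swelling_onset is not None:
        grow = times > swelling_onset
        frac = (times[grow] - swelling_onset) / (RECORD_END - swelling_onset)
        radii[grow] = config.initial_radius * (1.0 + (config.swell_factor - 1.0) * frac)

        ps_onset = swelling_onset + config.ps_delay
        ca_integral = _enrichment_integral(times, ca_clean)
        target = coupled_ps_integral(
            ca_integral, config.ps_coupling_slope, config.ps_coupling_intercept
        )
        shape = _smoothstep(times, ps_onset, config.ps_ramp)
        shape_integral = _enrichment_integral(times, 1.0 + shape)
        if target > 0 and shape_integral > 0:
            plateau = target / shape_integral
            ps_clean = 1.0 + plateau * shape
            ps_integral = target
    ca_integral = _enrichment_integral(times, ca_clean)

    # --- observation noise and optional frame dropout ---
    ca_obs, ps_obs = ca_clean, ps_clean
    if config.noise_sd > 0:
        ca_obs = np.clip(ca_clean * rng.normal(1.0, config.noise_sd, times.shape), 0.0, None)
        ps_obs = np.clip(ps_clean * rng.normal(1.0, config.noise_sd, times.shape), 0.0, None)
    keep = np.ones(times.shape, dtype=bool)
    if config.dropout_rate > 0:
        keep = rng.uniform(size=times.shape) > config.dropout_rate
        keep[0] = keep[-1] = True  # preserve the trace support

    truth = GroundTruthRow(
        scenario=config.scenario_name,
        cell_id=cell_id,
        ca_onset=ca_onset,
        swelling_onset=swelling_onset,
        ps_onset=ps_onset,
        ca_integral=ca_integral,
        ps_integral=ps_integral,
        ps_plateau=plateau,
        initial_radius=config.initial_radius,
        final_radius=float(radii[-1]),
    )
    return CellRecord(
        ca=IntensityTrace(times[keep], ca_obs[keep], cell_id=cell_id, channel="Ca"),
        ps=IntensityTrace(times[keep], ps_obs[keep], cell_id=cell_id, channel="PS"),
        times=times[keep],
        radii=radii[keep],
        truth=truth,
    )


def simulate_cohort(
    configs: list[ScenarioConfig], times: np.ndarray | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[CellRecord]]:
    """Simulate every scenario and return (long table, ground truth, cells).

    The long table has one row per cell and time point with columns
    ``scenario, cell_id, time_min, ca_r, rps, radius_px, seed``.
    """
    if not configs:
        raise ValueError("at least one scenario is required")
    names = [c.scenario_name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate scenario names")
    rows, truth_rows, cells = [], [], []
    for config in configs:
        for i in range(config.n_cells):
            rec = simulate_cell(config, i, times=times)
            cells.append(rec)
            truth_rows.append(asdict(rec.truth))
            rows.append(
                pd.DataFrame(
                    {
                        "scenario": config.scenario_name,
                        "cell_id": rec.truth.cell_id,
                        "time_min": rec.times,
                        "ca_r": rec.ca.values,
                        "rps": rec.ps.values,
                        "radius_px": rec.radii,
                        "seed": config.seed,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True), pd.DataFrame(truth_rows), cells


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderGeometry:
    """Image geometry for rendering a cohort into 2-D frames."""

    shape: tuple[int, int] = (96, 96)
    centers: tuple[tuple[float, float], ...] = ((48.0, 48.0),)
    background_unit: float = 100.0
    ring_width: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_unit <= 0:
            raise ValueError("background_unit must be positive")
        if not 2.0 <= self.ring_width <= 4.0:
            raise ValueError("ring_width must be within 2-4 pixels")


@dataclass(frozen=True)
class FrameStack:
    """Rendered two-channel time-lapse with per-frame cell geometry."""

    frames: dict[str, np.ndarray]  # channel -> (T, H, W)
    times: np.ndarray
    centers: tuple[tuple[float, float], ...]
    radii: np.ndarray  # (n_cells, T)
    background_unit: float
    ring_width: float

    def save(self, directory) -> dict[str, str]:
        """Write one multi-page TIFF per channel plus a geometry CSV."""
        import tifffile
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = {}
        for channel, stack in self.frames.items():
            path = directory / f"{channel.lower()}_stack.tif"
            tifffile.imwrite(path, stack.astype(np.float32))
            written[channel] = str(path)
        rows = []
        for ci, (cr, cc) in enumerate(self.centers):
            for ti, t in enumerate(self.times):
                rows.append(
                    {"cell": ci, "time_min": t, "row": cr, "col": cc, "radius_px": self.radii[ci, ti]}
                )
        geom_path = directory / "geometry.csv"
        pd.DataFrame(rows).to_csv(geom_path, index=False)
        written["geometry"] = str(geom_path)
        return written


def render_frames(cells: list[CellRecord], geometry: RenderGeometry) -> FrameStack:
    """Rasterize a cohort into two-channel grayscale frames.

    Each frame starts as a flat background plane of known unit intensity.
    The Ca channel paints the cell disk at ``Ca_R x background``; the PS
    channel paints a ring of ``ring_width`` pixels just outside the cell
    boundary at ``RPS x background``. Pixel membership uses the same
    center-inside rule as quantification.
    """
    if len(cells) != len(geometry.centers):
        raise ValueError("one center per cell is required")
    times = cells[0].times
    for rec in cells[1:]:
        if not np.array_equal(rec.times, times):
            raise ValueError("all cells must share the same time grid")
    h, w = geometry.shape
    radii = np.stack([rec.radii for rec in cells])
    max_extent = radii.max(axis=1) + geometry.ring_width
    for (cr, cc), ext in zip(geometry.centers, max_extent):
        if cr - ext < 0 or cc - ext < 0 or cr + ext > h - 1 or cc + ext > w - 1:
            raise ValueError("cell (incl. PS ring) overlaps the image border")

    rr, cc_grid = np.mgrid[0:h, 0:w]
    rng = np.random.default_rng(geometry.seed)
    n_t = times.size
    ca_stack = np.full((n_t, h, w), geometry.background_unit, dtype=float)
    ps_stack = np.full((n_t, h, w), geometry.background_unit, dtype=float)
    for ti in range(n_t):
        for ci, rec in enumerate(cells):
            cr, ccol = geometry.centers[ci]
            dist = np.hypot(rr - cr, cc_grid - ccol)
            r = radii[ci, ti]
            disk = dist <= r
            ring = (dist > r) & (dist <= r + geometry.ring_width)
            ca_stack[ti][disk] = rec.ca.values[ti] * geometry.background_unit
            ps_stack[ti][ring] = rec.ps.values[ti] * geometry.background_unit
        if geometry.noise_sd > 0:
            ca_stack[ti] = np.clip(
                ca_stack[ti] * rng.normal(1.0, geometry.noise_sd, (h, w)), 0.0, None
            )
            ps_stack[ti] = np.clip(
                ps_stack[ti] * rng.normal(1.0, geometry.noise_sd, (h, w)), 0.0, None
            )
    return FrameStack(
        frames={"Ca": ca_stack, "PS": ps_stack},
        times=times,
        centers=geometry.centers,
        radii=radii,
        background_unit=geometry.background_unit,
        ring_width=geometry.ring_width,
    )


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------


def scenario_config(
    name: str, *, dose: float = 0.0, n_cells: int = 4, seed: int = 0, noise_sd: float = 0.0
) -> ScenarioConfig:
    """Preset scenario configurations.

    ``"mec-4(d)"``
        Necrotic touch neurons: full channel leak and ER release; peaks span
        1.4-5x background and every cell swells.
    ``"wild-type"``
        Live neurons: weak, short fluctuations, no swelling.
    ``"crt-1"``
        ER store absent: release gain near zero, trace capped at 1.2x.
    ``"dantrolene"``
        Necrotic background with ER release reduced by ``dose`` (uM).
    ``"thapsigargin"``
        Wild-type background with reuptake blocked by ``dose`` (ug/ml),
        which raises baseline cytoplasmic Ca2+ and can push cells over the
        swelling threshold.
    """
    common = dict(n_cells=n_cells, seed=seed, noise_sd=noise_sd)
    if name == "mec-4(d)":
        return ScenarioConfig(scenario_name=f"mec-4(d)" if dose == 0 else f"mec-4(d)@{dose}", **common)
    if name == "wild-type":
        return ScenarioConfig(
            scenario_name="wild-type",
            er_release_gain=0.4,
            decay_width_range=(5.0, 12.0),
            **common,
        )
    if name == "crt-1":
        return ScenarioConfig(
            scenario_name="crt-1",
            er_release_gain=0.05,
            peak_cap=CRT1_PEAK_CAP,
            **common,
        )
    if name == "dantrolene":
        return ScenarioConfig(
            scenario_name=f"dantrolene@{dose:g}uM",
            er_release_gain=1.0 / (1.0 + 0.35 * dose),
            **common,
        )
    if name == "thapsigargin":
        return ScenarioConfig(
            scenario_name=f"thapsigargin@{dose:g}ug/ml",
            er_release_gain=0.4,
            reuptake_block=0.04 * dose,
            decay_width_range=(5.0, 12.0),
            **common,
        )
    raise ValueError(f"unknown scenario preset: {name!r}")
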