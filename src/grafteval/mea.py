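"""Multielectrode-array flash-response analysis.

Implements the quantification applied to retinal ganglion cell (RGC) spike
trains recorded on a 60-electrode array over a transplanted retina:

* peri-stimulus time histograms (PSTHs) at 20-ms resolution, smoothed with an
  order-4 binomial filter;
* rule-based classification of each unit's response to a 2-s full-field flash
  into ON / OFF / ON-OFF / low-signal / not-classified, using a detection
  threshold of mean + 4 SD of the dark firing rate;
* baseline-corrected peak firing rates per flash intensity and a
  Naka-Rushton intensity-response fit (half-saturation ``I50``, slope ``n``);
* assignment of electrodes to graft-centric areas 1-5 by morphological
  dilation of the graft mask.

All rates are in spikes/s, times in seconds, intensities in R*/rod/s and
lengths in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

__all__ = [
    "StimulusProtocol",
    "SpikeDataset",
    "UnitRecording",
    "PSTH",
    "BaselineStats",
    "ResponseLabel",
    "ResponseClass",
    "IRPoint",
    "IRFit",
    "ElectrodeLayout",
    "AreaMap",
    "naka_rushton",
    "compute_psth",
    "binomial_smooth",
    "baseline_stats",
    "peak_response",
    "classify_rgc",
    "fit_intensity_response",
    "assign_electrode_areas",
    "summarize_responses",
]

# Flash intensity ladder used throughout (R*/rod/s); the top step is the
# reference intensity at which units are classified.
DEFAULT_INTENSITIES = (0.83, 1.49, 4.32, 15.32, 49.38, 95.23)


@dataclass(frozen=True)
class StimulusProtocol:
    """Full-field flash protocol: light on during ``[t_on, t_off]``.

    ``dark_window`` is a 10-s stretch of each trial with no stimulus, used to
    estimate the spontaneous (dark) firing rate; it must not overlap the flash
    or the post-offset response window.
    """

    trial_duration: float = 15.0
    t_on: float = 2.0
    t_off: float = 4.0
    intensities: tuple[float, ...] = DEFAULT_INTENSITIES
    trials_per_intensity: int = 20
    dark_window: tuple[float, float] = (5.0, 15.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_on < self.t_off <= self.trial_duration):
            raise ValueError("require 0 <= t_on < t_off <= trial_duration")
        ints = tuple(float(i) for i in self.intensities)
        if any(i <= 0 for i in ints):
            raise ValueError("intensities must be strictly positive")
        if any(b <= a for a, b in zip(ints, ints[1:])):
            raise ValueError("intensities must be strictly increasing")
        object.__setattr__(self, "intensities", ints)
        lo, hi = self.dark_window
        if hi <= lo or lo < 0 or hi > self.trial_duration:
            raise ValueError("dark_window must lie within the trial")
        # the offset response window extends 0.3 s past light-off
        if lo < self.t_off + 0.3 and hi > self.t_on:
            raise ValueError("dark_window overlaps the stimulus/response epoch")
        if self.trials_per_intensity < 1:
            raise ValueError("need at least one trial per intensity")

    @property
    def reference_intensity(self) -> float:
        """Intensity at which the response type is determined (top of ladder)."""
        return self.intensities[-1]


@dataclass
class UnitRecording:
    """Spike times of one sorted unit, keyed by (intensity, trial index)."""

    electrode_id: str
    spikes: dict[tuple[float, int], np.ndarray] = field(default_factory=dict)

    def trials_at(self, intensity: float) -> list[np.ndarray]:
        out = [v for (i, _), v in sorted(self.spikes.items()) if i == intensity]
        if not out:
            raise KeyError(f"no trials at intensity {intensity}")
        return out


@dataclass
class SpikeDataset:
    """All sorted units of one recording plus the protocol they were run under."""

    protocol: StimulusProtocol
    units: dict[str, UnitRecording] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for uid, rec in self.units.items():
            for (intensity, trial), times in sorted(rec.spikes.items()):
                for t in times:
                    rows.append((uid, intensity, trial, float(t)))
        return pd.DataFrame(rows, columns=["unit_id", "intensity", "trial", "t_spike_s"])

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        protocol: StimulusProtocol,
        electrodes: Mapping[str, str] | None = None,
    ) -> "SpikeDataset":
        ds = cls(protocol=protocol)
        electrodes = electrodes or {}
        for (uid, intensity, trial), grp in frame.groupby(
            ["unit_id", "intensity", "trial"], sort=True
        ):
            uid = str(uid)
            rec = ds.units.setdefault(
                uid, UnitRecording(electrode_id=str(electrodes.get(uid, "")))
            )
            rec.spikes[(float(intensity), int(trial))] = np.sort(
                grp["t_spike_s"].to_numpy(float)
            )
        return ds


@dataclass
class PSTH:
    """Trial-pooled firing rate versus time.

    ``rates[k]`` is the pooled spike count in bin ``k`` divided by
    ``bin_width * n_trials`` — so before smoothing
    ``sum(rates) * bin_width * n_trials`` reconstructs the total spike count.
    """

    bin_edges: np.ndarray
    rates: np.ndarray
    bin_width: float
    n_trials: int
    smoothed: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def total_spikes(self) -> float:
        return float(np.sum(self.rates) * self.bin_width * self.n_trials)


@dataclass(frozen=True)
class BaselineStats:
    """Spontaneous-activity statistics; detection threshold = mean + k*SD."""

    mean_rate: float
    sd_rate: float
    threshold: float


class ResponseLabel(str, Enum):
    ON = "ON"
    OFF = "OFF"
    ON_OFF = "ON_OFF"
    LOW_SIGNAL = "LOW_SIGNAL"
    NOT_CLASSIFIED = "NOT_CLASSIFIED"


@dataclass(frozen=True)
class ResponseClass:
    label: ResponseLabel
    onset_peak: float
    offset_peak: float
    onset_peak_time: float | None = None
    offset_peak_time: float | None = None


@dataclass(frozen=True)
class IRPoint:
    intensity: float
    corrected_peak: float  # spikes/s; 0 if subthreshold


@dataclass(frozen=True)
class IRFit:
    """Naka-Rushton fit R(I) = Rmin + (Rmax - Rmin) * I^n / (I^n + I50^n)."""

    rmin: float
    rmax: float
    i50: float
    n: float
    sse: float
    degenerate: bool = False

    def __call__(self, intensity) -> np.ndarray:
        if self.degenerate:
            return np.full_like(np.asarray(intensity, float), self.rmin)
        return naka_rushton(intensity, self.rmin, self.rmax, self.i50, self.n)


def naka_rushton(intensity, rmin: float, rmax: float, i50: float, n: float):
    """Saturating intensity-response curve; R(I50) = (Rmin + Rmax) / 2."""
    i = np.asarray(intensity, dtype=float)
    ipow = np.power(i, n)
    return rmin + (rmax - rmin) * ipow / (ipow + i50**n)


# ---------------------------------------------------------------------------
# PSTH computation and smoothing
# ---------------------------------------------------------------------------

def compute_psth(
    trials: Sequence[np.ndarray],
    trial_duration: float,
    bin_width: float = 0.020,
) -> PSTH:
    """Pool spike times over trials into a firing-rate histogram.

    Parameters
    ----------
    trials : sequence of arrays of spike times (s), one per trial.
    trial_duration : length of each trial (s).
    bin_width : histogram resolution (s); 20 ms by default.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    if bin_width <= 0 or trial_duration <= 0:
        raise ValueError("bin_width and trial_duration must be positive")
    n_bins = int(round(trial_duration / bin_width))
    if abs(n_bins * bin_width - trial_duration) > 1e-9 * max(1.0, trial_duration):
        raise ValueError("bin_width must divide trial_duration")
    edges = np.arange(n_bins + 1) * bin_width
    pooled = np.concatenate([np.asarray(t, float) for t in trials]) if trials else np.array([])
    if pooled.size and (pooled.min() < 0 or pooled.max() > trial_duration):
        raise ValueError("spike time outside [0, trial_duration]")
    counts, _ = np.histogram(pooled, bins=edges)
    rates = counts / (bin_width * len(trials))
    return PSTH(bin_edges=edges, rates=rates, bin_width=bin_width,
                n_trials=len(trials), smoothed=False)


def binomial_kernel(order: int) -> np.ndarray:
    """Order-n binomial kernel C(n, k) / 2^n, k = 0..n; sums to 1."""
    if order < 1:
        raise ValueError("order must be >= 1")
    k = np.arange(order + 1)
    coef = np.array([math.comb(order, int(j)) for j in k], dtype=float)
    return coef / 2.0**order


def binomial_smooth(psth: PSTH, order: int = 4) -> PSTH:
    """Smooth a PSTH with the order-n binomial filter (reflect padding).

    The default order 4 gives the kernel [1, 4, 6, 4, 1] / 16.
    """
    kernel = binomial_kernel(order)
    pad_left = (len(kernel) - 1) // 2
    pad_right = len(kernel) - 1 - pad_left
    padded = np.pad(psth.rates, (pad_left, pad_right), mode="reflect")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return PSTH(bin_edges=psth.bin_edges.copy(), rates=smoothed,
                bin_width=psth.bin_width, n_trials=psth.n_trials, smoothed=True)


# ---------------------------------------------------------------------------
# Baseline, peaks and classification
# ---------------------------------------------------------------------------

def _window_mask(psth: PSTH, lo: float, hi: float,
                 closed_left: bool, closed_right: bool) -> np.ndarray:
    c = psth.bin_centers
    left = c >= lo if closed_left else c > lo
    right = c <= hi if closed_right else c < hi
    return left & right


def baseline_stats(
    psth: PSTH,
    dark_window: tuple[float, float],
    sd_multiplier: float = 4.0,
    min_duration: float = 10.0,
) -> BaselineStats:
    """Mean, sample SD and detection threshold of the dark firing rate.

    Computed over the unsmoothed PSTH bins whose centers fall in
    ``dark_window`` (closed on both sides); threshold = mean + sd_multiplier*SD.
    """
    lo, hi = dark_window
    if hi - lo < min_duration - 1e-9:
        raise ValueError(f"dark window must cover at least {min_duration} s")
    mask = _window_mask(psth, lo, hi, True, True)
    vals = psth.rates[mask]
    if vals.size < 2:
        raise ValueError("dark window contains fewer than two bins")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return BaselineStats(mean_rate=mean, sd_rate=sd,
                         threshold=mean + sd_multiplier * sd)


def _window_peak(psth: PSTH, lo: float, hi: float,
                 closed_left: bool, closed_right: bool) -> tuple[float, float]:
    """(max rate, time of earliest maximal bin) within a window."""
    mask = _window_mask(psth, lo, hi, closed_left, closed_right)
    if not mask.any():
        raise ValueError("window contains no bins")
    idx = np.flatnonzero(mask)
    rates = psth.rates[idx]
    k = int(idx[int(np.argmax(rates))])  # argmax -> earliest bin on ties
    return float(psth.rates[k]), float(psth.bin_centers[k])


def peak_response(
    psth: PSTH,
    baseline: BaselineStats,
    window: tuple[float, float],
    closed_left: bool = True,
    closed_right: bool = True,
) -> float:
    """Baseline-corrected peak rate in a window; 0 if the peak is subthreshold.

    Returns ``max(rate) - mean_rate`` when the window maximum strictly exceeds
    the mean+4SD threshold, otherwise 0 (subthreshold peaks count as 0 Hz).
    Never negative.
    """
    peak, _ = _window_peak(psth, window[0], window[1], closed_left, closed_right)
    if peak > baseline.threshold:
        return max(0.0, peak - baseline.mean_rate)
    return 0.0


def classify_rgc(
    psth: PSTH,
    baseline: BaselineStats,
    protocol: StimulusProtocol,
    onset_window: float = 0.5,
    offset_window: tuple[float, float] = (0.05, 0.3),
    low_signal_cutoff: float = 10.0,
) -> ResponseClass:
    """Classify a flash response as ON / OFF / ON-OFF / low-signal / not-classified.

    A window "responds" when its maximum smoothed rate strictly exceeds the
    mean+4SD threshold. The onset window is ``(t_on, t_on + 0.5 s]`` and the
    offset window ``[t_off + 0.05 s, t_off + 0.3 s]`` (a bin belongs to a
    window when its center does). If at least one window responds but the
    largest baseline-corrected peak is below ``low_signal_cutoff`` (10 Hz),
    the unit is labelled LOW_SIGNAL; if neither responds, NOT_CLASSIFIED.
    """
    if not psth.smoothed:
        raise ValueError("classification operates on the smoothed PSTH")
    on_lo, on_hi = protocol.t_on, protocol.t_on + onset_window
    off_lo = protocol.t_off + offset_window[0]
    off_hi = protocol.t_off + offset_window[1]
    if off_hi > psth.bin_edges[-1] + 1e-9:
        raise ValueError("offset window extends past the trial end")

    on_peak, on_t = _window_peak(psth, on_lo, on_hi, False, True)
    off_peak, off_t = _window_peak(psth, off_lo, off_hi, True, True)
    on_resp = on_peak > baseline.threshold
    off_resp = off_peak > baseline.threshold

    on_corr = max(0.0, on_peak - baseline.mean_rate) if on_resp else 0.0
    off_corr = max(0.0, off_peak - baseline.mean_rate) if off_resp else 0.0

    if not on_resp and not off_resp:
        label = ResponseLabel.NOT_CLASSIFIED
    elif max(on_corr, off_corr) < low_signal_cutoff:
        label = ResponseLabel.LOW_SIGNAL
    elif on_resp and off_resp:
        label = ResponseLabel.ON_OFF
    elif on_resp:
        label = ResponseLabel.ON
    else:
        label = ResponseLabel.OFF

    return ResponseClass(
        label=label,
        onset_peak=on_corr,
        offset_peak=off_corr,
        onset_peak_time=on_t if on_resp else None,
        offset_peak_time=off_t if off_resp else None,
    )


# ---------------------------------------------------------------------------
# Intensity-response fitting
# ---------------------------------------------------------------------------

def fit_intensity_response(
    points: Sequence[IRPoint],
    i50_bounds: tuple[float, float] | None = None,
    n_bounds: tuple[float, float] = (0.1, 10.0),
    grid_shape: tuple[int, int] = (80, 60),
) -> IRFit:
    """Fit the Naka-Rushton curve to corrected peak rates.

    ``Rmin`` and ``Rmax`` are fixed to the smallest and largest observed
    corrected peaks; ``(I50, n)`` minimise the summed squared error, found by
    a log-spaced grid search followed by Nelder-Mead refinement from the best
    grid node.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 intensity-response points")
    intens = np.array([p.intensity for p in pts], float)
    peaks = np.array([p.corrected_peak for p in pts], float)
    if np.any(intens <= 0):
        raise ValueError("intensities must be positive")
    rmin = float(peaks.min())
    rmax = float(peaks.max())
    if rmax == rmin:
        return IRFit(rmin=rmin, rmax=rmax, i50=float("nan"), n=float("nan"),
                     sse=0.0, degenerate=True)
    if i50_bounds is None:
        i50_bounds = (intens.min() / 10.0, intens.max() * 10.0)

    i50_grid = np.geomspace(i50_bounds[0], i50_bounds[1], grid_shape[0])
    n_grid = np.geomspace(n_bounds[0], n_bounds[1], grid_shape[1])
    # sse over the (i50, n) grid, vectorised over points
    ipow = np.power(intens[None, None, :], n_grid[None, :, None])
    i50pow = np.power(i50_grid[:, None, None], n_grid[None, :, None])
    pred = rmin + (rmax - rmin) * ipow / (ipow + i50pow)
    sse_grid = np.sum((pred - peaks[None, None, :]) ** 2, axis=-1)
    gi, gn = np.unravel_index(int(np.argmin(sse_grid)), sse_grid.shape)

    log_bounds = (np.log(i50_bounds), np.log(n_bounds))

    def objective(theta: np.ndarray) -> float:
        li = float(np.clip(theta[0], *log_bounds[0]))
        ln = float(np.clip(theta[1], *log_bounds[1]))
        resid = naka_rushton(intens, rmin, rmax, np.exp(li), np.exp(ln)) - peaks
        return float(resid @ resid)

    x0 = np.array([np.log(i50_grid[gi]), np.log(n_grid[gn])])
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 4000})
    best = res.x if res.fun <= sse_grid[gi, gn] else x0
    i50 = float(np.exp(np.clip(best[0], *log_bounds[0])))
    n = float(np.exp(np.clip(best[1], *log_bounds[1])))
    sse = min(float(res.fun), float(sse_grid[gi, gn]))
    return IRFit(rmin=rmin, rmax=rmax, i50=i50, n=n, sse=sse)


# ---------------------------------------------------------------------------
# Electrode layout and graft-centric areas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeLayout:
    """8x8 electrode grid with the four corners absent (60 electrodes).

    ``pitch`` is the inter-electrode distance and ``electrode_size`` the pad
    side length, both in micrometres. Electrode (row r, column c) sits at
    ``(x, y) = (c * pitch, r * pitch)``; ids are ``"r{r}c{c}"``.
    """

    n_rows: int = 8
    n_cols: int = 8
    pitch: float = 200.0
    electrode_size: float = 30.0

    def positions(self) -> dict[str, tuple[float, float]]:
        corners = {(0, 0), (0, self.n_cols - 1),
                   (self.n_rows - 1, 0), (self.n_rows - 1, self.n_cols - 1)}
        out: dict[str, tuple[float, float]] = {}
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                if (r, c) in corners:
                    continue
                out[f"r{r}c{c}"] = (c * self.pitch, r * self.pitch)
        return out


@dataclass
class AreaMap:
    """Partition of electrodes into graft-centric areas 1-5."""

    assignment: dict[str, int]

    def electrodes_in(self, area: int) -> list[str]:
        return sorted(e for e, a in self.assignment.items() if a == area)


def assign_electrode_areas(
    mask: np.ndarray,
    pixel_size: float | tuple[float, float],
    layout: ElectrodeLayout | Mapping[str, tuple[float, float]],
    base_radius: float = 200.0,
    magnifications: Sequence[float] = (1, 5, 10, 15),
    origin: tuple[float, float] = (0.0, 0.0),
) -> AreaMap:
    """Assign each electrode to an area by dilating the graft mask.

    The mask (a (rows, cols) boolean raster, rows along y) is dilated by discs
    of radius ``m * base_radius`` for each magnification m; area 1 is the
    graft and its border (the 1x dilation), areas 2-4 the successive rings,
    and area 5 everything beyond the outermost dilation. Dilation by a
    Euclidean disc is evaluated exactly via the Euclidean distance transform:
    an electrode lies inside the m-fold dilation iff its distance to the mask
    is <= m * base_radius.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("graft mask is empty")
    if np.isscalar(pixel_size):
        sampling = (float(pixel_size), float(pixel_size))
    else:
        sampling = (float(pixel_size[0]), float(pixel_size[1]))  # (dy, dx)
    if sampling[0] <= 0 or sampling[1] <= 0 or base_radius <= 0:
        raise ValueError("pixel size and base_radius must be positive")
    mags = sorted(float(m) for m in magnifications)
    if len(mags) != 4 or mags[0] <= 0:
        raise ValueError("expected four positive dilation magnifications")

    # distance from every background pixel to the nearest mask pixel (um)
    dist = ndimage.distance_transform_edt(~mask, sampling=sampling)

    positions = layout.positions() if isinstance(layout, ElectrodeLayout) else dict(layout)
    thresholds = [m * base_radius for m in mags]
    assignment: dict[str, int] = {}
    ny, nx = mask.shape
    for eid, (x, y) in positions.items():
        row = int(round((y - origin[1]) / sampling[0]))
        col = int(round((x - origin[0]) / sampling[1]))
        if not (0 <= row < ny and 0 <= col < nx):
            raise ValueError(f"electrode {eid} lies outside the raster extent")
        d = float(dist[row, col])
        area = 5
        for k, thr in enumerate(thresholds):
            if d <= thr:
                area = k + 1
                break
        assignment[eid] = area
    return AreaMap(assignment=assignment)


def summarize_responses(
    classes: Mapping[str, ResponseClass],
    electrodes: Mapping[str, str],
    areas: AreaMap,
) -> pd.DataFrame:
    """Tabulate response-type counts and fractions per area and pooled.

    Returns a tidy table with columns (area, label, count, fraction); the
    pooled rows carry area "all". Fractions sum to 1 within each group.
    """
    labels = [l.value for l in ResponseLabel]
    rows: list[tuple[str, str, int]] = []
    per_area: dict[int, list[str]] = {}
    for uid, rc in classes.items():
        if uid not in electrodes:
            raise KeyError(f"unit {uid} has no electrode")
        eid = electrodes[uid]
        if eid not in areas.assignment:
            raise KeyError(f"electrode {eid} has no area")
        per_area.setdefault(areas.assignment[eid], []).append(rc.label.value)

    def _count(group: str, members: Iterable[str]) -> None:
        members = list(members)
        total = len(members)
        for lab in labels:
            cnt = sum(1 for m in members if m == lab)
            if total:
                rows.append((group, lab, cnt, cnt / total))

    for area in sorted(per_area):
        _count(str(area), per_area[area])
    _count("all", [l for ls in per_area.values() for l in ls])
    return pd.DataFrame(rows, columns=["area", "label", "count", "fraction"])
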