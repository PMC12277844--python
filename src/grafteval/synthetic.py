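"""Synthetic data with known ground truth for the three analysis stages.

Three generators emulate the statistical structure the analyses assume:

* ``gen_spike_trains`` — inhomogeneous-Poisson RGC spike trains under a
  flash protocol. Each cell fires at
  ``lambda(t) = baseline + A_on * g(t - t_on) + A_off * g(t - t_off)`` where
  ``g`` is a unit-peak half-cosine bump of width ``transient_width`` and the
  transient amplitudes follow the cell's Naka-Rushton curve at the trial
  intensity (ON cells drive the onset bump, OFF the offset, ON-OFF both,
  low-signal cells a small onset bump, unresponsive cells none).
* ``gen_hc_pattern`` — hard-core (minimum-distance) horizontal-cell mosaics
  in a circular field with an optic-disc hole, optionally thinned inside
  patches to mimic the spatially uneven cell loss of degenerating retinas.
* ``gen_puncta_scene`` — 3D scenes of planted CtBP2/mGluR6/dendrite triplets
  satisfying the 1.5-um synapse rule, plus distractor spots placed far
  enough from everything to violate it.

All randomness flows from the explicit ``seed`` of each call; identical
arguments and seed reproduce outputs exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .hc import PointPattern
from .mea import (
    ResponseLabel,
    SpikeDataset,
    StimulusProtocol,
    UnitRecording,
    naka_rushton,
)
from .synapse import DendriteSkeleton, PunctaScene

__all__ = [
    "IRParams",
    "default_cell_population",
    "CellSpec",
    "FieldSpec",
    "ThinningPatch",
    "SceneSpec",
    "GroundTruth",
    "gen_spike_trains",
    "gen_hc_pattern",
    "gen_puncta_scene",
]

# label a generated cell maps to under the classification rules
LABEL_FOR_TYPE = {
    "ON": ResponseLabel.ON,
    "OFF": ResponseLabel.OFF,
    "ON_OFF": ResponseLabel.ON_OFF,
    "LOW": ResponseLabel.LOW_SIGNAL,
    "NONE": ResponseLabel.NOT_CLASSIFIED,
}


class IRParams(NamedTuple):
    """Naka-Rushton ground-truth parameters of one cell."""

    rmin: float  # spikes/s
    rmax: float  # spikes/s
    i50: float   # R*/rod/s
    n: float     # dimensionless


@dataclass(frozen=True)
class CellSpec:
    """Generative description of one simulated RGC."""

    cell_id: str
    response_type: str  # ON | OFF | ON_OFF | LOW | NONE
    baseline_rate: float = 3.0
    ir_params: IRParams = IRParams(0.0, 25.0, 10.0, 1.0)
    transient_width: float = 0.3
    low_amplitude: tuple[float, float] = (5.0, 9.0)  # corrected-peak band for LOW cells

    def __post_init__(self) -> None:
        if self.response_type not in LABEL_FOR_TYPE:
            raise ValueError(f"unknown response_type {self.response_type!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        rmin, rmax, i50, n = self.ir_params
        if not (rmax >= rmin >= 0):
            raise ValueError("require Rmax >= Rmin >= 0")
        if i50 <= 0 or n <= 0:
            raise ValueError("I50 and n must be positive")
        if self.transient_width <= 0:
            raise ValueError("transient_width must be positive")


@dataclass(frozen=True)
class ThinningPatch:
    center: tuple[float, float]  # um
    radius: float                # um
    deletion_prob: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.deletion_prob <= 1.0):
            raise ValueError("deletion_prob must be in [0, 1]")
        if self.radius <= 0:
            raise ValueError("patch radius must be positive")


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and target statistics of a horizontal-cell mosaic."""

    field_radius: float = 1000.0          # um
    disc_center: tuple[float, float] = (0.0, 0.0)
    disc_diameter: float = 150.0          # um, usually 100-200
    target_density: float = 800.0         # cells/mm^2
    hardcore_radius: float = 15.0         # um, minimum pairwise distance
    thinning_patches: tuple[ThinningPatch, ...] = ()

    def __post_init__(self) -> None:
        if self.target_density <= 0 or self.field_radius <= 0:
            raise ValueError("field_radius and target_density must be positive")
        if self.hardcore_radius < 0:
            raise ValueError("hardcore_radius must be >= 0")
        object.__setattr__(self, "thinning_patches",
                           tuple(self.thinning_patches))

    @property
    def usable_area_mm2(self) -> float:
        full = math.pi * (self.field_radius / 1000.0) ** 2
        disc = math.pi * (self.disc_diameter / 2000.0) ** 2
        return full - disc


@dataclass(frozen=True)
class SceneSpec:
    """Layout of a planted 3D puncta scene."""

    volume_extent: tuple[float, float, float] = (60.0, 60.0, 30.0)  # x, y, z um
    n_true_synapses: int = 20
    n_distractor_ctbp2: int = 50
    n_distractor_mglur6: int = 50
    n_rbc: int = 10
    min_separation: float = 4.0  # um, must exceed twice the detection radius
    jitter_sd: float = 0.5       # um, CtBP2->mGluR6 displacement scale

    def __post_init__(self) -> None:
        if min(self.n_true_synapses, self.n_distractor_ctbp2,
               self.n_distractor_mglur6) < 0 or self.n_rbc < 0:
            raise ValueError("counts must be >= 0")
        if self.min_separation <= 3.0:
            raise ValueError("min_separation must exceed twice the 1.5-um radius")
        if self.n_true_synapses > 0 and self.n_rbc == 0:
            raise ValueError("planted synapses require at least one RBC")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring downstream recovery."""

    planted_synapses: list[tuple[object, object, str]] = field(default_factory=list)
    true_labels: dict[str, ResponseLabel] = field(default_factory=dict)
    true_ir_params: dict[str, IRParams] = field(default_factory=dict)


def default_cell_population(
    n_cells: int,
    seed: int,
    baseline_rate: float = 3.0,
    proportions: dict[str, float] | None = None,
    rmax_range: tuple[float, float] = (25.0, 35.0),
    i50_range: tuple[float, float] = (2.0, 15.0),
    n_range: tuple[float, float] = (0.8, 1.5),
) -> list[CellSpec]:
    """A mixed RGC population with randomised Naka-Rushton parameters.

    The default mix (35% ON, 20% OFF, 20% ON-OFF, 25% unresponsive) operates
    in a high-signal regime: transient amplitudes at the reference flash
    comfortably exceed the mean+4SD detection threshold, so the generated
    labels are recoverable by the classifier. Low-signal cells are omitted
    here because at a 3 spikes/s baseline the 4SD threshold already exceeds
    the 10-Hz cutoff (the low-signal band is empty); populations exercising
    that band use lower baselines and more trials.
    """
    rng = np.random.default_rng(seed)
    props = proportions or {"ON": 0.35, "OFF": 0.20, "ON_OFF": 0.20, "NONE": 0.25}
    types = list(props)
    counts = [int(round(props[t] * n_cells)) for t in types]
    while sum(counts) < n_cells:
        counts[0] += 1
    while sum(counts) > n_cells:
        counts[int(np.argmax(counts))] -= 1
    cells = []
    k = 0
    for t, cnt in zip(types, counts):
        for _ in range(cnt):
            params = IRParams(
                rmin=0.0,
                rmax=float(rng.uniform(*rmax_range)),
                i50=float(np.exp(rng.uniform(*np.log(i50_range)))),
                n=float(rng.uniform(*n_range)),
            )
            cells.append(CellSpec(cell_id=f"u{k:04d}", response_type=t,
                                  baseline_rate=baseline_rate, ir_params=params))
            k += 1
    return cells


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def _transient_amplitudes(cell: CellSpec, intensity: float,
                          low_amp: float | None) -> tuple[float, float]:
    amp = float(naka_rushton(intensity, *cell.ir_params))
    if cell.response_type == "ON":
        return amp, 0.0
    if cell.response_type == "OFF":
        return 0.0, amp
    if cell.response_type == "ON_OFF":
        return amp, amp
    if cell.response_type == "LOW":
        return float(low_amp), 0.0
    return 0.0, 0.0


def _bump(t: np.ndarray, start: float, width: float) -> np.ndarray:
    """Unit-peak half-cosine bump supported on [start, start + width]."""
    u = (t - start) / width
    out = np.sin(np.pi * np.clip(u, 0.0, 1.0))
    out[(u < 0) | (u > 1)] = 0.0
    return out


def gen_spike_trains(
    protocol: StimulusProtocol,
    cells: Sequence[CellSpec],
    seed: int,
    n_electrodes: int = 60,
) -> tuple[SpikeDataset, GroundTruth]:
    """Simulate per-trial spike trains for a population of cells.

    Spikes are drawn from an inhomogeneous Poisson process by thinning a
    homogeneous process at the rate ceiling. Trials are independent (the
    protocol makes no generative claim about inter-trial adaptation).
    Electrodes are assigned cyclically from an 8x8-minus-corners layout.
    """
    if protocol.trial_duration <= 0:
        raise ValueError("trial duration must be positive")
    rng = np.random.default_rng(seed)
    ds = SpikeDataset(protocol=protocol)
    truth = GroundTruth()
    from .mea import ElectrodeLayout

    eids = sorted(ElectrodeLayout().positions())
    T = protocol.trial_duration
    w = None
    for ci, cell in enumerate(cells):
        w = cell.transient_width
        # the LOW amplitude is drawn once per cell so all trials agree
        low_amp = float(rng.uniform(*cell.low_amplitude)) if cell.response_type == "LOW" else None
        rec = UnitRecording(electrode_id=eids[ci % len(eids)])
        for intensity in protocol.intensities:
            a_on, a_off = _transient_amplitudes(cell, intensity, low_amp)
            lam_max = cell.baseline_rate + a_on + a_off
            for trial in range(protocol.trials_per_intensity):
                if lam_max <= 0:
                    rec.spikes[(intensity, trial)] = np.empty(0)
                    continue
                n_cand = rng.poisson(lam_max * T)
                t = np.sort(rng.uniform(0.0, T, size=n_cand))
                lam = (cell.baseline_rate
                       + a_on * _bump(t, protocol.t_on, w)
                       + a_off * _bump(t, protocol.t_off, w))
                keep = rng.uniform(0.0, 1.0, size=n_cand) < lam / lam_max
                rec.spikes[(intensity, trial)] = t[keep]
        ds.units[cell.cell_id] = rec
        truth.true_labels[cell.cell_id] = LABEL_FOR_TYPE[cell.response_type]
        truth.true_ir_params[cell.cell_id] = cell.ir_params
    return ds, truth


# ---------------------------------------------------------------------------
# Horizontal-cell mosaics
# ---------------------------------------------------------------------------

def gen_hc_pattern(fieldspec: FieldSpec, seed: int,
                   attempt_factor: int = 10_000) -> PointPattern:
    """Hard-core mosaic by dart throwing, then patchy thinning.

    Points are drawn uniformly in the annular field (disc excluded) and
    accepted when at least ``hardcore_radius`` from every accepted point;
    the target count is ``target_density * usable area``. Each accepted
    point lying inside thinning patches is then deleted independently with
    the combined patch deletion probability.
    """
    rng = np.random.default_rng(seed)
    n_target = int(round(fieldspec.target_density * fieldspec.usable_area_mm2))
    r = fieldspec.hardcore_radius
    # random-sequential-adsorption feasibility: discs of radius r/2 jam near
    # 54.7% coverage; refuse clearly infeasible requests up front
    if r > 0:
        area_um2 = fieldspec.usable_area_mm2 * 1e6
        if n_target * math.pi * (r / 2.0) ** 2 > 0.547 * area_um2:
            raise ValueError("hardcore_radius infeasible at the target density")
    disc_r = fieldspec.disc_diameter / 2.0
    dc = np.asarray(fieldspec.disc_center)
    pts: list[np.ndarray] = []
    max_attempts = attempt_factor * max(1, n_target)
    attempts = 0
    arr = np.empty((0, 2))
    while len(pts) < n_target:
        if attempts >= max_attempts:
            raise RuntimeError("hard-core sampling failed within the attempt cap")
        attempts += 1
        # uniform in the field disc via radius sqrt transform
        rad = fieldspec.field_radius * math.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * math.pi)
        p = np.array([rad * math.cos(ang), rad * math.sin(ang)])
        if np.linalg.norm(p - dc) <= disc_r:
            continue
        if pts and r > 0:
            if np.min(np.linalg.norm(arr - p, axis=1)) < r:
                continue
        pts.append(p)
        arr = np.vstack([arr, p])

    if fieldspec.thinning_patches and len(pts):
        u = rng.uniform(size=len(arr))
        p_keep = np.ones(len(arr))
        for patch in fieldspec.thinning_patches:
            inside = np.linalg.norm(arr - np.asarray(patch.center), axis=1) <= patch.radius
            p_keep[inside] *= 1.0 - patch.deletion_prob
        arr = arr[u >= 1.0 - p_keep]

    return PointPattern(points=arr, field_radius=fieldspec.field_radius,
                        disc_center=fieldspec.disc_center,
                        disc_diameter=fieldspec.disc_diameter)


# ---------------------------------------------------------------------------
# Puncta scenes
# ---------------------------------------------------------------------------

def _min_dist_to_points(p: np.ndarray, keep_out: np.ndarray) -> float:
    if len(keep_out) == 0:
        return math.inf
    return float(np.min(np.linalg.norm(keep_out - p, axis=1)))


def gen_puncta_scene(
    spec: SceneSpec, seed: int, max_attempts: int = 200_000
) -> tuple[PunctaScene, GroundTruth]:
    """Plant synapse triplets and distractors in a 3D volume.

    Each planted synapse is a CtBP2 spot, an mGluR6 spot jittered at most
    1.45 um away, and a short dendrite branch of its RBC passing within
    1 um of the CtBP2 spot. Every other structure (other planted spots,
    dendrite sample points, distractors) is kept at least ``min_separation``
    away, so with min_separation > 2 * 1.5 um the planted triplets are
    exactly the structures satisfying the detection rule.
    """
    rng = np.random.default_rng(seed)
    ex = np.asarray(spec.volume_extent, float)
    margin = 2.0
    lo, hi = margin, ex - margin
    if np.any(hi <= lo):
        raise ValueError("volume too small for the placement margin")

    keep_out = np.empty((0, 3))
    ctbp2: list[np.ndarray] = []
    mglur6: list[np.ndarray] = []
    branch_by_rbc: dict[int, list[np.ndarray]] = {}
    planted: list[tuple[int, int, str]] = []
    attempts = 0

    def _try_place() -> np.ndarray:
        nonlocal attempts
        while True:
            if attempts >= max_attempts:
                raise RuntimeError("scene placement failed within the attempt cap")
            attempts += 1
            p = rng.uniform(lo, hi)
            if _min_dist_to_points(p, keep_out) >= spec.min_separation:
                return p

    for k in range(spec.n_true_synapses):
        while True:
            c = _try_place()
            # mGluR6 within the detection radius (Gaussian jitter, capped)
            while True:
                off = rng.normal(0.0, spec.jitter_sd, size=3)
                if 0.0 < np.linalg.norm(off) <= 1.45:
                    break
            m = np.clip(c + off, lo, hi)
            # dendrite branch: short vertical segment whose top passes
            # within 1 um of the CtBP2 spot
            near = c + _unit(rng) * rng.uniform(0.3, 1.0)
            soma = near + np.array([0.0, 0.0, -5.0])
            seg_samples = _sample_segment(soma, near, 0.5)
            # the branch must stay clear of every other planted structure
            others = keep_out
            if len(others) and np.min(
                np.linalg.norm(others[:, None, :] - seg_samples[None, :, :], axis=2)
            ) < spec.min_separation:
                continue  # resample this synapse's position entirely
            break
        rbc = k % spec.n_rbc
        ctbp2.append(c)
        mglur6.append(m)
        branch_by_rbc.setdefault(rbc, []).append(np.stack([soma, near]))
        planted.append((k, k, f"rbc{rbc:03d}"))
        keep_out = np.vstack([keep_out, c[None, :], m[None, :], seg_samples])

    for _ in range(spec.n_distractor_ctbp2):
        p = _try_place()
        ctbp2.append(p)
        keep_out = np.vstack([keep_out, p[None, :]])
    for _ in range(spec.n_distractor_mglur6):
        p = _try_place()
        mglur6.append(p)
        keep_out = np.vstack([keep_out, p[None, :]])

    dendrites = [
        DendriteSkeleton(cell_id=f"rbc{rbc:03d}", polylines=polys)
        for rbc, polys in sorted(branch_by_rbc.items())
    ]
    scene = PunctaScene(
        ctbp2=PunctaScene.spots_frame(np.array(ctbp2).reshape(-1, 3)),
        mglur6=PunctaScene.spots_frame(np.array(mglur6).reshape(-1, 3)),
        dendrites=dendrites,
    )
    truth = GroundTruth(planted_synapses=[(c, m, r) for c, m, r in planted])
    return scene, truth


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _sample_segment(a: np.ndarray, b: np.ndarray, step: float) -> np.ndarray:
    n = max(2, int(np.ceil(np.linalg.norm(b - a) / step)) + 1)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return a[None, :] * (1 - t) + b[None, :] * t
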