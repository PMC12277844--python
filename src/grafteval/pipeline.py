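"""Pipeline orchestration: per-unit MEA analysis and multi-stage runs.

``analyze_spike_dataset`` turns a spike dataset into one row per unit with
its response label, baseline-corrected peak rates per flash intensity and
the Naka-Rushton fit; ``run_pipeline`` chains whichever stages the provided
inputs support (MEA, horizontal-cell mosaics, synapse detection) and writes
their tables plus a manifest and run log into an output directory.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .config import RunConfig
from .hc import PointPattern, circle_density, compare_groups, nnd, place_sampling_circles
from .mea import (
    AreaMap,
    ElectrodeLayout,
    IRPoint,
    PSTH,
    ResponseLabel,
    SpikeDataset,
    StimulusProtocol,
    UnitRecording,
    assign_electrode_areas,
    baseline_stats,
    binomial_smooth,
    classify_rgc,
    compute_psth,
    fit_intensity_response,
    peak_response,
    summarize_responses,
)
from .synapse import (
    PunctaScene,
    RosetteSurface,
    detect_synapses,
    forming_rbc_density,
    select_rbcs_near_rosette,
    synapses_per_rbc,
)

__all__ = ["RunLog", "analyze_unit", "analyze_spike_dataset", "run_pipeline"]


@dataclass
class RunLog:
    """One record per invocation: stages run, row counts, config identity."""

    config_digest: str
    seed: int
    started: float = dc_field(default_factory=time.time)
    stages: list[dict] = dc_field(default_factory=list)

    def add(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, "t": time.time(), **counts})

    def to_dict(self) -> dict:
        return {"config_digest": self.config_digest, "seed": self.seed,
                "started": self.started, "stages": self.stages}


def _unit_psths(
    rec: UnitRecording, protocol: StimulusProtocol, config: RunConfig
) -> dict[float, tuple[PSTH, PSTH]]:
    """(raw, smoothed) PSTH per intensity for one unit."""
    out = {}
    for intensity in protocol.intensities:
        raw = compute_psth(rec.trials_at(intensity), protocol.trial_duration,
                           config.bin_width)
        out[intensity] = (raw, binomial_smooth(raw, config.filter_order))
    return out


def analyze_unit(
    rec: UnitRecording, protocol: StimulusProtocol, config: RunConfig
) -> dict:
    """Classify one unit and fit its intensity-response curve.

    The label is determined from the reference (top) intensity; peaks at
    every intensity are taken from the window matching the label's polarity
    (onset for ON, offset for OFF, onset for ON-OFF, whose intensity-response
    analysis follows its ON component). Baseline statistics are computed per
    intensity from that intensity's own unsmoothed PSTH, so the mean+4SD
    threshold reflects the noise level of the very histogram it gates.
    """
    psths = _unit_psths(rec, protocol, config)
    ref = protocol.reference_intensity
    raw_ref, smooth_ref = psths[ref]
    base_ref = baseline_stats(raw_ref, protocol.dark_window,
                              config.sd_multiplier, config.dark_duration)
    rc = classify_rgc(smooth_ref, base_ref, protocol, config.onset_window,
                      config.offset_window, config.low_signal_cutoff)

    on_window = (protocol.t_on, protocol.t_on + config.onset_window)
    off_window = (protocol.t_off + config.offset_window[0],
                  protocol.t_off + config.offset_window[1])
    peaks: dict[float, float] = {}
    use_onset = rc.label in (ResponseLabel.ON, ResponseLabel.ON_OFF)
    window = on_window if use_onset else off_window
    closed_left = not use_onset  # onset window is open on the left
    for intensity, (raw, smooth) in psths.items():
        base = baseline_stats(raw, protocol.dark_window,
                              config.sd_multiplier, config.dark_duration)
        peaks[intensity] = peak_response(smooth, base, window,
                                         closed_left=closed_left)

    row = {
        "unit_id": None,
        "electrode_id": rec.electrode_id,
        "label": rc.label.value,
        "onset_peak": rc.onset_peak,
        "offset_peak": rc.offset_peak,
    }
    for intensity in protocol.intensities:
        row[f"peak_{intensity:g}"] = peaks[intensity]
    if rc.label in (ResponseLabel.ON, ResponseLabel.OFF, ResponseLabel.ON_OFF):
        pts = [IRPoint(i, peaks[i]) for i in protocol.intensities]
        if len({p.corrected_peak for p in pts}) >= 2:
            fit = fit_intensity_response(pts, config.ir_i50_bounds,
                                         config.ir_n_bounds)
            row.update(i50=fit.i50, n=fit.n, sse=fit.sse,
                       rmin=fit.rmin, rmax=fit.rmax)
    row.setdefault("i50", np.nan)
    row.setdefault("n", np.nan)
    row.setdefault("sse", np.nan)
    return row


def analyze_spike_dataset(
    ds: SpikeDataset, config: RunConfig, areas: AreaMap | None = None
) -> pd.DataFrame:
    rows = []
    for uid in sorted(ds.units):
        row = analyze_unit(ds.units[uid], ds.protocol, config)
        row["unit_id"] = uid
        if areas is not None:
            row["area"] = areas.assignment.get(row["electrode_id"])
        rows.append(row)
    frame = pd.DataFrame(rows)
    if len(frame):
        lead = ["unit_id", "electrode_id"] + (["area"] if areas is not None else [])
        frame = frame[lead + [c for c in frame.columns if c not in lead]]
    return frame


# ---------------------------------------------------------------------------
# Multi-stage run
# ---------------------------------------------------------------------------

def run_pipeline(
    config: RunConfig, inputs: Mapping[str, object], out_dir: str | Path
) -> Path:
    """Run every stage the inputs support and write its artifacts.

    Recognised input keys (objects or file paths):

    * ``spikes`` (SpikeDataset) with optional ``graft_mask``
      ((mask, pixel_size) pair) for electrode areas;
    * ``hc_patterns`` (mapping group name -> list of PointPattern);
    * ``scene`` (PunctaScene) with optional ``rosette``
      ((mask, voxel_size)) and ``graft_area_mm2``.

    Outputs are deterministic for a fixed config + seed; a manifest lists
    every file written, and a run log records stage row counts. A stage
    failure aborts the run but leaves the partial manifest on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(config_digest=config.digest(), seed=config.seed)
    manifest: dict[str, str] = {}

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        manifest[name] = str(path)

    try:
        if "spikes" in inputs:
            ds: SpikeDataset = inputs["spikes"]  # type: ignore[assignment]
            areas = None
            if "graft_mask" in inputs:
                mask, pixel_size = inputs["graft_mask"]  # type: ignore[misc]
                areas = assign_electrode_areas(
                    mask, pixel_size, ElectrodeLayout(),
                    config.dilation_base_radius, config.dilation_magnifications)
                _write(pd.DataFrame(sorted(areas.assignment.items()),
                                    columns=["electrode_id", "area"]),
                       "electrode_areas.csv")
            units = analyze_spike_dataset(ds, config, areas)
            _write(units, "units.csv")
            log.add("mea", n_units=len(units))
            if areas is not None and len(units):
                classes = {
                    r.unit_id: classify_stub(r.label) for r in units.itertuples()
                }
                electrodes = dict(zip(units["unit_id"], units["electrode_id"]))
                _write(summarize_responses(classes, electrodes, areas),
                       "response_summary.csv")

        if "hc_patterns" in inputs:
            groups: Mapping[str, Sequence[PointPattern]] = inputs["hc_patterns"]  # type: ignore[assignment]
            dens_rows, nnd_rows = [], []
            densities_by_group: dict[str, list[float]] = {}
            for group, patterns in groups.items():
                for ri, pattern in enumerate(patterns):
                    circles = place_sampling_circles(
                        pattern.disc_center, pattern.disc_diameter,
                        config.circle_diameter)
                    for c in circles:
                        d = circle_density(pattern, c)
                        dens_rows.append((group, ri, c.region, c.direction, d))
                        if d is not None:
                            densities_by_group.setdefault(group, []).append(d)
                    res = nnd(pattern, config.nnd_bin_width, config.nnd_range)
                    for d in res.distances:
                        nnd_rows.append((group, ri, float(d)))
            _write(pd.DataFrame(dens_rows, columns=[
                "group", "retina", "region", "direction", "density_mm2"]),
                "hc_density.csv")
            _write(pd.DataFrame(nnd_rows, columns=["group", "retina", "nnd_um"]),
                   "hc_nnd.csv")
            stats: dict[str, float] = {}
            names = sorted(densities_by_group)
            if len(names) == 2:
                u, p = compare_groups(densities_by_group[names[0]],
                                      densities_by_group[names[1]])
                stats = {"groups": names, "U": u, "p_value": p}
                gio.write_json(stats, out / "hc_comparison.json")
                manifest["hc_comparison.json"] = str(out / "hc_comparison.json")
            log.add("hc", n_density_rows=len(dens_rows), n_nnd=len(nnd_rows))

        if "scene" in inputs:
            scene: PunctaScene = inputs["scene"]  # type: ignore[assignment]
            records = detect_synapses(scene, config.synapse_radius)
            _write(pd.DataFrame(
                [(r.ctbp2_id, r.mglur6_id, r.rbc_id,
                  r.d_ctbp2_mglur6, r.d_ctbp2_dendrite) for r in records],
                columns=["ctbp2_id", "mglur6_id", "rbc_id",
                         "d_ctbp2_mglur6", "d_ctbp2_dendrite"]),
                "synapses.csv")
            if "rosette" in inputs:
                mask, voxel_size = inputs["rosette"]  # type: ignore[misc]
                surface = RosetteSurface(mask, voxel_size)
                selected = select_rbcs_near_rosette(
                    scene.dendrites, surface, config.rbc_reach)
            else:
                selected = {str(d.cell_id) for d in scene.dendrites}
            summary = synapses_per_rbc(records, selected)
            _write(pd.DataFrame(sorted(summary.counts.items()),
                                columns=["rbc_id", "n_synapses"]),
                   "rbc_counts.csv")
            result = {
                "n_synapses": len(records),
                "n_rbc_selected": len(selected),
                "n_rbc_forming": len(summary.forming),
                "mean_synapses_per_rbc": summary.mean_per_rbc,
            }
            if "graft_area_mm2" in inputs:
                result["forming_rbc_density_mm2"] = forming_rbc_density(
                    summary.forming, float(inputs["graft_area_mm2"]))  # type: ignore[arg-type]
            gio.write_json(result, out / "synapse_summary.json")
            manifest["synapse_summary.json"] = str(out / "synapse_summary.json")
            log.add("synapse", n_records=len(records))
    finally:
        gio.write_json(manifest, out / "manifest.json")
        gio.write_json(log.to_dict(), out / "run_log.json")
    return out


def classify_stub(label: str):
    """Wrap a bare label string as a ResponseClass for summarisation."""
    from .mea import ResponseClass

    return ResponseClass(label=ResponseLabel(label), onset_peak=0.0, offset_peak=0.0)
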