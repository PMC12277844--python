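# Methods

`grafteval` quantifies how well a transplanted retinal-organoid sheet
integrates into a degenerated host retina, using three independent readouts:
flash-evoked retinal ganglion cell (RGC) activity on a multielectrode array
(MEA), the spatial statistics of the host horizontal-cell (HC) mosaic, and
geometric detection of host-graft ribbon synapses in 3D immunofluorescence
data. Each analysis stage has a matched synthetic-data generator with known
ground truth, so every rule in the pipeline can be validated end to end.

## 1. MEA flash-response analysis

**PSTH.** Spike times of each sorted unit are pooled over trials into a
peri-stimulus time histogram with 20-ms bins; the rate in a bin is the
pooled count divided by `bin_width x n_trials`, so the unsmoothed PSTH
conserves the total spike count exactly. PSTHs are smoothed with an order-4
binomial filter (kernel `[1, 4, 6, 4, 1]/16`, reflect padding); the kernel
is nonnegative and sums to one, so constant inputs are invariant.

**Threshold.** The spontaneous rate is estimated from a 10-s dark segment of
each trial: the mean and sample SD of the unsmoothed 20-ms dark-bin rates
give a detection threshold of `mean + 4 SD`. Baseline statistics are
computed per intensity from that intensity's own PSTH, so the threshold
reflects the counting noise of the histogram it gates (a pooled
across-intensity baseline was evaluated and rejected: it drops the threshold
below the single-intensity PSTH's own noise floor and creates false
detections).

**Classification.** At the reference flash (95.23 R\*/rod/s, 2 s,
full-field) a unit is scored in two windows: onset `(t_on, t_on + 0.5 s]`
and offset `[t_off + 0.05 s, t_off + 0.3 s]`; a bin belongs to a window when
its center does, and a window "responds" when its maximum smoothed rate
strictly exceeds the threshold. Labels: both windows → ON-OFF, onset only →
ON, offset only → OFF, neither → not classified. If at least one window
responds but the largest baseline-corrected peak is below 10 spikes/s the
unit is labelled low-signal; the 10-Hz rule is applied to the corrected peak
and the boundary is strict (`< 10`). Peak ties across bins resolve to the
earliest bin.

**Intensity-response fit.** Per intensity, the corrected peak is
`max(smoothed rate in window) − dark mean` when the maximum exceeds
threshold, else 0 (subthreshold peaks count as 0 Hz; the peak is never
negative). The resulting points are fitted with the Naka-Rushton function

    R(I) = Rmin + (Rmax − Rmin) · I^n / (I^n + I50^n)

where `Rmin`/`Rmax` are fixed to the smallest/largest observed corrected
peaks and `(I50, n)` minimise the summed squared error, via a log-spaced
80x60 grid over `I50 ∈ [Imin/10, Imax·10]`, `n ∈ [0.1, 10]` followed by
Nelder-Mead refinement in log space (sse tolerance 1e-12, parameters clipped
to the bounds). The fitted curve always satisfies
`R(I50) = (Rmin + Rmax)/2`. If all peaks are equal the fit is flagged
degenerate and `I50`/`n` are undefined (NaN).

*Known estimator limitation.* Pinning `Rmin`/`Rmax` to the observed extremes
means the family cannot contain a generating curve whose asymptotes are not
reached by the intensity ladder, and the subthreshold→0 rule removes the
low-intensity limb at realistic noise levels. On simulated ON cells
(baseline 3 spikes/s, Rmax 25, I50 10, n 1, six-step ladder) the median
relative I50 error is ~0.35 at 20 trials/intensity and plateaus near ~0.18
at 500 trials — a bias floor, not counting noise. The estimator remains
strongly rank-sensitive (populations with I50 = 3 vs 30 separate cleanly at
20 trials), which is what the sensitivity comparisons between preparations
rely on. Classification is far more robust: label recovery is 100% at 20
trials under the default generator conditions.

**Graft-centric areas.** The graft footprint (a binary raster, pixel size in
um) is dilated by Euclidean discs of radius `m x base_radius` for
magnifications `m ∈ {1, 5, 10, 15}`; area 1 is the 1x dilation (graft and
border), areas 2-4 the successive rings, area 5 everything beyond. Dilation
by a disc is evaluated exactly through the Euclidean distance transform
(per-axis pixel spacing supported): an electrode is inside the m-fold
dilation iff its distance to the mask is `<= m x base_radius`. The default
`base_radius` is one electrode pitch (200 um) and is configurable, since the
magnification unit is a free choice. The 60-electrode layout is an 8x8 grid
with absent corners, 200-um pitch, 30-um pads.

## 2. Horizontal-cell mosaic statistics

**Sampling geometry.** The optic disc is enclosed in a circle of diameter
100-200 um. In each of the four cardinal directions a chain of three 500-um
circles is laid out tangentially: center distances `disc_radius + 250`,
`+750`, `+1250` um, labelled proximal / middle / distal — 12 circles per
retina. Circles over damaged tissue are excluded by the caller (flagged, no
number reported); there is no automatic damage detection.

**Density.** Cells whose centroid lies within the circle (boundary
inclusive, `distance <= radius`) are counted and divided by the circle area
(~0.196 mm^2); densities are reported in cells/mm^2.

**NND.** Each cell's Euclidean distance to its nearest neighbour (excluding
itself) is computed with a k-d tree; the reported distance is recomputed
from the neighbour index with the plain Euclidean formula so results are
bit-identical to a definitional all-pairs scan. No edge correction is
applied. The distribution is summarised as a relative-frequency histogram
(default 5-um bins from 0 um; the range extends beyond 100 um if needed so
frequencies always sum to 1).

**Group comparison.** Two-sided Mann-Whitney U; exact null for untied
samples with combined n <= 16, tie-corrected normal approximation otherwise
(scipy implementation, validated against full permutation enumeration).

## 3. Host-graft synapse detection

A synapse is a CtBP2 spot (photoreceptor ribbon) lying within 1.5 um of both
an mGluR6 spot (ON-bipolar postsynaptic tip) and a rod-bipolar-cell dendrite.
"Within" is inclusive (`<=`). For each CtBP2 spot the nearest mGluR6 spot
and the nearest point on any dendrite polyline (exact point-to-segment
distance, no voxelisation) are found; a record is emitted iff both distances
pass, at most one per CtBP2 spot, with exact ties broken toward the
lexicographically smaller id. The dendrite realising the minimum distance
assigns the synapse to its RBC.

RBCs are pre-selected by proximity to the photoreceptor-rosette surface:
a cell qualifies when any point of its skeleton (segments sampled at half
the smallest voxel spacing, not only vertices) lies within 10 um of the
rosette mask. Distances to the mask interpolate the anisotropic Euclidean
distance transform; queries outside the raster fall back to an exact
nearest-voxel search. Per selected RBC the synapse count is reported; cells
with >= 1 synapse are "RBCs with forming synapse", and their number divided
by the grafted area (2D projected area, mm^2) gives the forming-RBC density.

Spot detection from raster volumes (a stand-in for interactive spot tracing)
uses a scale-normalised Laplacian-of-Gaussian at a physical scale sigma
(converted to per-axis voxel sigmas, so anisotropic stacks are handled) and
reports local maxima above an intensity floor as centroids in um.

## 4. Synthetic data generators

All generators draw every random number from a single `numpy` generator
seeded per call; identical inputs and seed reproduce outputs exactly.

**Spike trains.** Inhomogeneous Poisson processes (thinning algorithm) with
rate `lambda(t) = baseline + A_on·g(t − t_on) + A_off·g(t − t_off)`, where
`g` is a unit-peak half-cosine bump of width 0.3 s (smooth, compactly
supported, unambiguous peak time). The transient amplitude at each intensity
is the cell's Naka-Rushton value: ON cells drive the onset bump, OFF the
offset, ON-OFF both; unresponsive cells have none. Low-signal cells receive
a per-cell amplitude drawn uniformly from 5-9 spikes/s so their corrected
peak falls below 10 Hz. Trials are independent — no adaptation or
inter-trial structure is modelled. The default protocol uses 15-s trials
with the flash at 2-4 s, a 10-s dark window at 5-15 s, and the six-step
intensity ladder 0.83-95.23 R\*/rod/s.

Default population conditions (used by the end-to-end checks and the
acceptance script): baseline 3 spikes/s, 20 trials/intensity, mix 35% ON /
20% OFF / 20% ON-OFF / 25% unresponsive, `Rmax ~ U(25, 35)`,
`I50 ~ logU(2, 15)`, `n ~ U(0.8, 1.5)`. Low-signal cells are excluded from
this mix for an arithmetic reason: at baseline 3 spikes/s and 20 trials the
mean+4SD threshold is ~14 spikes/s, which already exceeds the 10-Hz
low-signal cutoff, so no PSTH can respond yet stay below 10 Hz — the band is
empty. Low-signal recovery is exercised at baseline 1 spikes/s with 100
trials, where the threshold (~4 Hz) leaves the band open.

**HC mosaics.** Hard-core point processes by dart throwing (uniform
candidates in the annular field outside the optic disc, accepted when at
least `hardcore_radius` from all accepted points; attempt cap 10^4 x N,
and requests beyond the random-sequential-adsorption jamming coverage
(~54.7%) are rejected up front). Spatially uneven degeneration is emulated
by thinning patches: points inside a patch are deleted independently with
the patch's probability (probabilities of overlapping patches compose).
Defaults: 1000-um field, 150-um disc, 800 cells/mm^2, 15-um hard core —
thinning lowers density and shifts the NND distribution upward while the
minimum NND stays at the hard-core floor, the signature the mosaic
statistics are designed to detect.

**Puncta scenes.** Planted triplets: a CtBP2 spot, an mGluR6 spot jittered
at most 1.45 um away (Gaussian jitter, resampled until inside the cap), and
a short dedicated dendrite branch of the owning RBC passing within 1 um of
the CtBP2 spot. Every other structure — other planted spots, dendrite sample
points, distractor spots of both channels — is kept at least
`min_separation` (default 4 um, required > 2 x 1.5 um) from everything else,
so the planted triplets are by construction exactly the structures
satisfying the detection rule and every distractor violates it. This is what
makes precision = recall = 1 a meaningful end-to-end check rather than a
tautology: the detector must find all planted geometry and nothing else.

## 5. What the synthetic data does and does not show

The generators carry the statistical structure the analyses assume — Poisson
counting noise, saturating intensity-response transients, hard-core mosaic
geometry with patchy loss, and sub-resolution synaptic apposition — but not
the full complexity of real recordings: no spike-sorting errors or
electrode crosstalk, no adaptation or oscillatory retinal activity, no
segmentation errors in cell detection, and no anisotropic optical blur or
background in the puncta scenes. Passing tests therefore demonstrate that
the analysis rules are implemented exactly and that they recover ground
truth under their own assumptions; they do not certify performance on
degraded real data.

## 6. Numerical and design choices

* Windows: onset half-open left, offset closed; bin membership by center —
  deterministic and testable boundary behaviour.
* `> threshold` is strict everywhere; `<= radius`/`<= reach` inclusive.
* Sample SD (ddof = 1) over dark bins; the SD's averaging basis is a free
  choice the configuration records.
* Degenerate fits (all peaks equal) are flagged rather than fitted.
* Problem sizes in the test suite and acceptance script (200 units x 20
  trials, 5 retinas per group, 20 puncta scenes) were chosen as the smallest
  populations at which the end-to-end statistics are stable.
* Exit codes of the CLI: 0 success, 2 validation error, 3 stage error;
  tables are UTF-8 CSV, rasters TIFF with JSON voxel-size sidecars, and all
  randomness flows from the configured seed.
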