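# octavg

Registration, averaging and quantification of **radial peripapillary
capillaries (RPCs)** on en-face optical coherence tomography angiography
(OCTA).

The RPCs form a distinctive network inside the retinal nerve fibre layer
around the optic disc: long, near-parallel capillaries of ~9 µm diameter
spaced 30–40 µm apart, with few anastomoses. They are thought to be
selectively vulnerable in glaucoma, but single OCTA en-face frames are too
noisy for reliable capillary-level quantification. Registering several
scans from one session and averaging them is a simple, device-agnostic way
to enhance the network — and the number of frames worth acquiring depends
on which metric you care about. This package implements that entire
workflow for researchers working with 10×10° (304×304 px) en-face slabs,
plus a synthetic scene generator so every stage is testable without
patient data.

## What it computes

For each peripapillary region of interest (~2×2°, placed superior,
superotemporal, temporal, inferotemporal and inferior to the disc, 1°
outside the fitted disc-margin ellipse) and each number of averaged frames
n = 1…10:

- **SNR** — mask-based: `SNR = (μ_signal − μ_background) / √(σ²_signal +
  σ²_background)`, where the signal region is the vessel skeleton of the
  10-frame average dilated to ~15 µm (9 µm anatomical diameter + ~6 µm
  apparent broadening on OCTA) and the background is its complement; the
  same mask is applied at every n.
- **Skeleton endpoints** — count of one-neighbour pixels of the vessel
  skeleton (binarise at 6× bicubic upsampling with a ~50 px adaptive
  threshold, then thin); spurious endpoints are a fragmentation/noise
  proxy.
- **Mean capillary segment length** — total skeleton length divided by the
  number of segments between endpoints/branch points, in µm.
- **Capillary length density** — skeleton length / ROI area, mm⁻¹
  (convertible to an area-coverage % by assuming a uniform 9 µm diameter).
- **Intercapillary distance (ICD)** — mean peak-to-peak distance of an
  intensity profile averaged over a 0.1×1° box oriented perpendicular to
  the vessels, in µm.

The statistics stage then asks, per region and metric: is there a
frame-count effect at all (one-way repeated-measures ANOVA with the
Greenhouse–Geisser sphericity correction), where does it stop
(Bonferroni-corrected paired t-tests on the nine sequential comparisons
1v2 … 9v10), and hence what is the **optimal number of averaged frames**
(the smallest n after which no sequential gain is significant, α = 0.05).
A normative module places individual eyes on healthy-control box plots and
flags densities below the lower whisker.

## Worked example

`examples/04_quantify_one_roi.py` simulates a 10-frame stack (default
noise model, true spacing 38 µm ≈ density 27.9 mm⁻¹), registers it and
quantifies the temporal ROI:

```
ground truth: density 27.88 mm^-1, spacing 38.0 um
 n   SNR  endpoints  seg-len(um)  density(mm^-1)  ICD(um)
 1   2.21         76        189.7           26.45     36.7
 2   2.44         44        257.4           27.31     36.7
 5   2.68         35        403.8           26.93     36.7
10   2.79         31        441.2           26.75     36.7
```

Reading: averaging raises SNR and removes more than half the spurious
skeleton endpoints (76 → 31) while fusing fragments into longer segments;
density and ICD barely move and stay near the ground truth — the
single-frame-robust metrics. The other examples cover simulation,
registration accuracy, ROI placement, the frame-count statistics and the
normative comparison; each prints what the numbers mean.

A thin CLI wraps the same library:

```sh
octavg simulate --seed 1 --out stack.tiff
octavg register stack.tiff --out registered.tiff
octavg run-all --out results_dir          # bundled synthetic config
octavg stats metrics.csv --out stats_dir  # statistics stage only
```

`octavg stats` also accepts an XLSX workbook with one long-format sheet
per metric (subject, region, n_frames, value), the layout used for
per-subject supplementary data.

## Layout

- `src/octavg/` — `synthetic` (scene generator), `register` (rigid
  registration), `geometry` (disc ellipse + ROIs), `quantify` (the five
  metrics), `stats` (RM-ANOVA/post hoc/normative), `pipeline` + `cli`
  (orchestration), `io` (TIFF/CSV/XLSX), `plots` (QC figures).
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
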