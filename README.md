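# granulemotion

Analysis of intracellular secretory-granule mobility from live-cell
fluorescence imaging, built for the workflows used to study insulin and
glucagon granule trafficking in pancreatic β- and α-cell models: dense
fields of point-like vesicles imaged by confocal time-lapse (~200 ms/frame,
~500 frames), tracked with TrackMate, and sized by single-molecule
localization microscopy.

The package provides three complementary analyses plus the synthetic
ground-truth generator that makes each of them testable end to end:

1. **SPT motion classification** (`granulemotion.spt`). Each trajectory is
   segmented in two steps and every frame is assigned to one of three
   motion classes. Step 1 ("stop-and-go") thresholds a moving 5-frame
   windowed speed at *v*<sub>t</sub> = 0.2 μm/s: sustained fast runs become
   *drifted* segments. Step 2 (MSS–TAD) scans the remaining mixed segments
   for transient arrests of diffusion — intervals where a Simson–Sheetz
   confinement likelihood says the local diffusivity is improbably low
   relative to the segment average — using a seed-and-threshold rule
   (seed at *L*<sub>c1</sub> = 1.8 over ≥ 5 frames, grow at
   *L*<sub>c2</sub> = 1.4, keep zones ≥ 7 frames). Every resulting
   (sub)trajectory is then classified from its displacement-moment
   spectrum (orders 1–6): *blocked* if the short-lag diffusivity
   D<sub>12</sub> < 2×10⁻³ μm²/s, otherwise *drifted* if the anomalous
   parameter γ (half the MSD log–log exponent) ≥ 0.75, otherwise
   *diffusive* (slow below 10⁻² μm²/s, fast above). Results are reported
   as length percentages — the fraction of all classified spots per class.
2. **iMSD correlation spectroscopy** (`granulemotion.imsd`). The
   spatiotemporal correlation of the raw image stack is computed by FFT,
   its width per time lag extracted by an isotropic Gaussian fit, and the
   resulting curve fit with σ²(τ) = σ₀² + 4 D<sub>m</sub> τ^α, giving the
   ensemble diffusivity D<sub>m</sub>, the anomalous exponent α (< 1
   sub-diffusive, ≈ 1 Brownian, > 1 super-diffusive) and the offset σ₀², a
   squared apparent-size metric that grows with granule dimension.
3. **SMLM granule sizing** (`granulemotion.storm`). ThunderSTORM-style
   localization tables are quality-filtered (first 500 frames dropped,
   sigma > 130 nm or uncertainty > 40 nm removed), clustered with DBSCAN
   (ε = 50 nm, minPts = 8), and each cluster sized by the
   equivalent-circle diameter 2√(area/π) of its occupied-bin contour.

`granulemotion.synthetic` generates trajectories (immobile, confined,
Brownian, drifted, and switching mixtures with per-frame ground-truth
labels), renders them into Poisson-noise TIFF stacks, and simulates
disc-shaped localization clusters, so every stage above can be verified
against known truth. `granulemotion.report` aggregates per-acquisition
summaries into condition tables and runs the gated statistics
(Shapiro–Wilk normality, Welch t-test or Mann–Whitney, Holm–Šidák
correction across the three categories).

## Worked example

Simulate the reference three-way mixture (30 immobile + 30 Brownian at
D = 5×10⁻³ μm²/s + 30 drifted at 0.5 μm/s tracks, 100 frames at 204 ms)
and classify it:

```sh
granulemotion demo --seed 1 --out demo/
```

prints

```
blocked 34.0% / diffusive 29.6% / drifted 36.4%
```

and writes `demo/segments.csv` (one row per classified (sub)trajectory
with its label, D₁₂ and γ) plus `demo/summary.csv`:

```
acquisition_id,blocked,diffusive,drifted,n_tracks,n_spots
demo,34,29.5556,36.4444,90,9000
```

Each class was designed at 33.3% of the spots; the immobile and drifted
populations are recovered almost exactly, while a few percent of the
Brownian spots land in the drifted class because at D = 5×10⁻³ μm²/s a
5-frame windowed speed occasionally sustains excursions above the
0.2 μm/s threshold — the same ambiguity a real diffusing granule
presents. Per-track majority labels are 100% correct in all three
classes here.

The other stages run the same way: `granulemotion render` writes a
synthetic Brownian stack, `granulemotion imsd --stack stack.tif --out r/`
fits D<sub>m</sub>, α and the offset, `granulemotion storm --locs
locs.csv --out s/` sizes localization clusters, and
`granulemotion classify --tracks spots.csv --dt 0.204 --out c/` ingests a
TrackMate spots-statistics export. `--help` on any subcommand lists every
threshold with its default.

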