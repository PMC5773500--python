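# carpetfcs

Line-scan image correlation spectroscopy for nuclear-envelope transport:
pair-correlation (pCF) carpets, single-component FCS diffusion fitting,
number & brightness (N&B) moment analysis, zone statistics around the
nuclear lamina, two-channel cross-correlated image pCF, and 3D particle
segmentation — driven end-to-end by a Brownian-dynamics simulator with
known ground truth.

## The problem

Tracking how a virus-sized particle moves through a cell — diffusing in
the cytoplasm, pausing at the nuclear envelope (NE), occasionally slipping
through a nuclear pore — requires statistics that work at millisecond
resolution on rare, dim, single particles. Confocal *line scans* across
the NE provide that: scanning one line every ~1.5 ms for 32,000 lines
yields a **carpet** F(t, r), a time × position intensity matrix in which
every pixel column is a fluctuation time trace.

This package implements the analysis chain such experiments use:

* **ACF / pCF.** The pair correlation function between two pixels a
  distance d apart,

  ```
  pCF(τ, d) = ⟨F(t, r) · F(t + τ, r + d)⟩ / (⟨F(t, r)⟩ ⟨F(t, r + d)⟩) − 1,
  ```

  is the probability signature of molecules traveling from r to r + d in
  time τ. With d = 0 it is the autocorrelation (ACF); computed between two
  spectral channels it scores the co-transport of two labeled species. A
  delayed positive pCF peak across the lamina is a single-particle
  translocation event; its absence marks an impermeable barrier.
* **FCS fitting.** Column ACFs are fitted to the single-component model
  G(τ) = G₀ / ((1 + τ/τ_D)·√(1 + τ/(κ²τ_D))) (κ = ∞ gives the 2D form),
  with D = w₀²/(4τ_D); fits are χ²-validated, restricted to D ∈ [0, 100]
  µm²/s, and classified *fast* (D > 2 µm²/s) or *slow*.
* **N&B.** Apparent number N = ⟨k⟩²/σ² and brightness B = σ²/⟨k⟩ per
  column, under a fast scheme (300-line segments) and a slow scheme
  (100-line averages), which separate rapid diffusers from slow bright
  aggregates.
* **Zones.** The lamin-marker channel locates the lamina; columns are
  partitioned into cytoplasm / NE / nucleoplasm (NE = ±11 px band).
* **Image pCF.** Per-pixel pCF amplitude maps at offset d on 2D
  two-channel time series, overlay colocalization, cross-correlated pCF,
  and normalized profiles across the NE.
* **3D segmentation.** Distance-transform-seeded watershed on confocal
  stacks; per-object volume/intensity/centroid and signed distance to the
  nucleus surface, binned in 0.5 µm shells.

Because live-cell recordings of this kind are rarely public, the
`simcarpet` module generates the inputs with full ground truth — Brownian
species with configurable D, brightness and channel weights, a
semi-permeable (optionally thick) NE barrier, drift, immobile fractions, a
static lamin stripe, Gaussian-PSF sampling and Poisson noise — so every
stage is validated by parameter recovery.

## Worked example

```bash
python analysis/01_simulate_linescan.py
python analysis/02_correlation_carpets.py
python analysis/03_fit_diffusion_zones.py
```

simulates a two-channel scan across the NE (fast capsid-like species at
D = 3.5 µm²/s confined by a 30%-permeable barrier on the lamina, slow
pore-docked particles at the envelope, bright near-immobile endosome-like
aggregates 1 µm into the cytoplasm, static lamin stripe) and prints:

```
pCF distance 20 px = 820 nm
same-side pCF amplitude (cytoplasm bulk): 0.0461, transit peak at 52 ms
controlled barrier comparison (96 seeds, single species):
  impermeable: cross/same amplitude = +2.7% (no transport signature beyond estimator noise)
  30% permeable: cross amplitude +0.295 (positive: single-particle transits across the envelope)

lamina at column 150.0; cytoplasm on the left
     cytoplasm: n=139  D = 2.12 ± 0.12 µm²/s (median 2.41)
            NE: n= 23  D = 0.01 ± 0.00 µm²/s (median 0.02)
   nucleoplasm: n= 94  D = 2.90 ± 0.12 µm²/s (median 3.39)
fast (D > 2 µm²/s): 173/256 columns (68%)
```

Movement stalls in the NE band (the docked population), an impermeable
envelope shows no pair correlation across it while a 30%-permeable one
does, and a 20-pixel pair at 41 nm pixels is correctly reported as an
820 nm separation. The remaining drivers run N&B (`04` — the slow-scheme
brightness peaks ~1 µm on the cytoplasmic side, where the aggregates
were planted), 3D segmentation (`05`) and two-channel image pCF (`06`);
each writes its tables under `results/`.

The same machinery is scriptable through one YAML config:

```bash
carpetfcs carpet --config pipeline.yaml --seed 7 --outdir run1
carpetfcs report run1
```

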