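# mitoqpi

Macrophages in the tumor microenvironment occasionally hand whole
mitochondria to neighboring cancer cells, and the recipient cells divide
faster.  `mitoqpi` packages the two computational halves of that story:

1. **An agent-based model (ABM)** of tumor population growth under rare
   mitochondrial transfer.  Each cell agent carries a dry mass *m* that
   grows per time step Δt as

   m(t+Δt) = m(t) · (1 + k·Δt),

   with k = k₀ for ordinary cells and k = k₀·r for cells carrying
   transferred mitochondria.  Per step, a transfer-negative cell becomes a
   carrier with probability f·Δt/T_d (f = overall transfer fraction per
   doubling time T_d).  A cell divides into two half-mass daughters when it
   exceeds twice its birth mass; exactly one daughter of a carrier keeps
   the mitochondria, so half the carrier population loses the growth
   advantage at every division.  The population mass m_P = Σᵢ mᵢ is
   compared against the pure-exponential baseline m_B = m₀·e^(d·ln2) after
   d doublings.

2. **A quantitative-phase-imaging (QPI) pipeline** that turns phase-shift
   time-lapse movies into single-cell dry-mass tracks: sixth-order
   polynomial background correction, phase→mass conversion
   (m = Σ φ·λ·A/α with λ = 0.623 µm, α = 0.185 µm³/pg, A = 0.36 µm²/px),
   Sobel segmentation, greedy nearest-centroid tracking with division
   detection, specific growth rate (least-squares mass-vs-time slope ÷ mean
   mass), cytokinesis fractions and daughter-lineage mass curves.
   Fluorescence channels are overlaid to classify cells (recipient-marker
   ≥ 1.5× background → cancer cell; donor-marker ≥ 2× background →
   macrophage) and a rolling-ball filter (ball 4.8–9 µm) isolates the
   punctate donor-mitochondria signal that marks recipient cancer cells.

A fully ground-truthed synthetic-movie generator (`mitoqpi.synthetic`)
emulates the imaging regime — 40 h doubling time, one frame per 15 min for
48 h, ~5% recipients growing 15% faster, polynomial phase background,
additive noise, division with single-daughter punctae inheritance — so
every stage is testable without microscope data.  Small reporter utilities
(`mitoqpi.reporters`) implement Livak ΔΔCT percent knockdown and ERK-KTR
cytoplasm:nucleus ratio series.

## Worked example

```python
from mitoqpi.abm import ABMParams, mean_relative_increase

params = ABMParams(n0=1000, f=0.05, r=1.15, Td=40.0, dt=0.4, d_target=20.0, seed=1)
mean_pct, sd = mean_relative_increase(params, n_seeds=10)
print(f"population mass increase at 20 doublings: {mean_pct:.1f} +/- {sd:.1f} %")
```

prints

```
population mass increase at 20 doublings: 14.4 +/- 0.3 %
```

i.e. even though only ~5% of cells carry donor mitochondria at any moment
(carriers keep losing them at division), the compounding 15% growth-rate
advantage leaves the population ~15% more massive than pure exponential
growth after 20 doublings.

The same thing from the shell, plus a synthetic movie analyzed end to end:

```bash
mitoqpi simulate --f 0.05 --r 1.15 --doublings 20 --n0 1000 --seed 1 --reps 10
mitoqpi synth --preset fast --seed 4 --out movie/
mitoqpi analyze --phase movie/phase.tif --rfp movie/recipient_marker.tif \
    --mito movie/donor_mito.tif --out analysis/
```

`analyze` writes per-cell tracks (`tracks.csv`), lineages, growth rates
per class and a `summary.json` whose `growth_rate_increase_pct` field is
the recovered recipient-vs-non-recipient growth advantage.

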