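# Methods

## Agent-based model of growth under rare mitochondrial transfer

Each agent is a cell with dry mass *m* (pg), a birth ("baseline") mass and
a boolean carrier flag.  Per time step Δt:

1. **Growth** (Euler step): m ← m·(1 + k·Δt), with k = k₀ for
   non-carriers and k₀·r for carriers.
2. **Transfer lottery**: each non-carrier becomes a carrier with
   probability f·Δt/T_d, so over one doubling time a fraction ≈ f of the
   population gains mitochondria.  Gaining them again is a no-op; carriers
   only change their growth constant, nothing else.
3. **Division**: an agent whose mass exceeds twice its birth mass is
   replaced by two daughters at exactly half its mass, whose baseline is
   reset to that half (so the next division requires another full
   doubling).  For a carrier parent exactly one daughter keeps the flag
   (`loss_rule="deterministic"`, the default, matching the imaging
   observation that usually a single daughter inherits the transferred
   mitochondria); a Bernoulli(1/2)-per-daughter variant is selectable.

Division conserves mass exactly: m/2 is exact in binary floating point.

**Growth-constant calibration.**  With k₀ = ln2/T_d the discrete Euler
update compounds to slightly more than a doubling per T_d.  The default
(`calibration="discrete"`) instead sets k₀ = (2^(Δt/T_d) − 1)/Δt, which
makes one mass doubling take exactly T_d at the discrete level, so "d
doublings" and "elapsed time d·T_d" coincide for the baseline population.
The continuous convention remains available (`calibration="continuous"`).

**Baseline and readout.**  The reference is pure exponential growth,
m_B = m₀·2^d.  `relative_increase(traj, d)` evaluates the simulated
population mass at *elapsed time* d·T_d (the epoch at which the baseline
has doubled d times) — not at the simulation's own realized doubling
count, which a transfer-boosted population reaches earlier.

**Population cap.**  Simulating 2^20 doublings agent-by-agent is
impossible; the model is mass-homogeneous, so relative quantities are
independent of agent count up to Monte-Carlo error.  The simulator keeps
n₀ agents (default 1000): whenever the count exceeds 4·n₀ it uniformly
subsamples back to n₀ and carries a scalar scale factor
(total-before / total-kept) so the reported population mass stays
unbiased.  The reported carrier fraction is that of the sample.

**Defaults.**  n₀ = 1000, m₀ = 250 pg, f = 0.05, r = 1.15, T_d = 40 h,
Δt = T_d/100, 20 doublings.  Δt = T_d/100 keeps the Euler discretization
error far below the ~15% effect size; Δt > T_d/20 is rejected.  At these
settings the predicted excess population mass at 20 doublings is ≈14–15%,
with seed-to-seed scatter well under one percentage point when averaged
over ≥10 seeds.

A rough steady-state argument explains the size of the effect: carriers
are created at rate f/T_d per cell and their number is conserved at
division (one daughter keeps, one loses, while the population doubles), so
the carrier fraction settles near f/ln2 ≈ 7%; the population growth
exponent gains a factor (1 + p·(r−1)), compounding to
2^(20·p·0.15) ≈ 1.15 over 20 doublings.

## QPI dry-mass pipeline

**Phase → mass.**  With phase shift φ in fractions of a wavelength, the
per-pixel dry mass is φ·λ·A/α (λ = 0.623 µm, α = 0.185 µm³/pg,
A = 0.36 µm²/pixel by default); region mass is the sum over member pixels.

**Background correction.**  A degree-6 2-D polynomial surface (28 terms,
coordinates normalized to [−1,1]² for conditioning) is fitted robustly:
fit to all pixels, exclude pixels more than 2σ *above* the surface (cells
add positive phase), refit, three iterations.  Fitting subsamples to at
most ~50k pixels on a regular grid; the surface is evaluated and
subtracted on the full grid.  The design matrix is cached per image shape.

**Segmentation.**  Sobel gradient magnitude → Otsu threshold →
morphological closing (disk radius 3 px) → hole filling → removal of
regions below `min_area` (default 200 px) → 8-connected labeling.  Labels
are then expanded by 3 px (boundary-respecting) because the edge-based
mask systematically misses the faint outer skirt of a cell; without the
expansion region masses are biased low by ~10%.  Constant images yield
zero regions.

**Tracking.**  Greedy nearest-centroid linking under a per-frame
displacement cap (default 20 µm at 15-min frames).  Robustness rules, in
order: (i) unmatched regions first try to *resume* a track that ended
within the last 8 frames at compatible position and mass (±30%) — this
absorbs transient merge/split events when two touching cells segment as
one blob; (ii) a division is called when a remaining new region and a
matched region both lie within the displacement cap of a track with ≥3
frames of history and their masses are each 50±20% of, and sum to within
20% of, the parent's last mass; (iii) a matched region whose mass jumps
above 1.5× or drops below 0.6× the track's last mass ends the track
(missed division or merge) instead of corrupting its growth fit.  Tracks
ending mid-movie near the border are `left_frame`; all other
non-dividing ends are `censored`.

**Growth rate.**  Specific growth rate = least-squares slope of mass vs
time divided by mean mass (1/h); for an exponential track with k·T ≤ 0.3
this linearized estimate is within 2% of k.  Tracks need ≥3 frames;
class-level summaries additionally require ≥5 h of observation, below
which single-frame noise dominates the fit.

**Cytokinesis fraction.**  Denominator: tracks that divided or were
observed ≥30 h (earlier leavers are omitted); numerator: divisions within
40 h of first observation.

**Classification.**  Per-channel background = median intensity over
non-cell pixels.  Whole-cell gates: recipient-marker mean ≥ 1.5×
background → cancer; donor-marker mean ≥ 2× background → macrophage;
passing both gates is treated as a cancer/macrophage fusion and excluded
(`other`).  Donor punctae are isolated by a rolling-ball filter —
grayscale opening with a ball-shaped (non-flat) structuring element,
default diameter 6 µm within the allowed 4.8–9 µm window — and detected
where the residual exceeds 5× its robust σ (scaled MAD, with a tiny floor
so noise-free images threshold sensibly).  A cell is punctae-positive in a
frame if ≥2 detected pixels fall inside it; a track is punctae-positive if
detection persists for ≥2 consecutive frames; a daughter inherits if
punctae are detected in any of its first 3 frames.  Recipient cancer cell
= cancer gate ∧ punctae ∧ not macrophage.

## Synthetic data

The generator emulates the statistical structure the analysis relies on,
not microscope physics: circular truncated-Gaussian phase profiles
(σ = radius/2, truncated at the radius, radius 10–15 µm) whose integrated
phase is scaled so the rendered mass is exact; exponential mass growth
between divisions with division at the first frame ≥2× birth mass;
daughters placed on opposite sides of the parent; Gaussian random-walk
motility (0.3 µm/frame) with reflecting margins; a gentle random degree-6
phase background; additive Gaussian phase noise (default 2% of a typical
peak cell phase); uniform recipient-marker fluorescence over cell
footprints (3× background) and 1.5-µm donor punctae (10× background, 3 per
recipient) that move with their cell and pass to exactly one daughter.
Founders start partway through their cycle (uniform 0–0.7 doublings) so
divisions are staggered.

What it does *not* model — irregular cell shapes, shot noise, optical
point-spread functions, cell death, contact-dependent transfer, realistic
densities and motility — bounds what passing tests show: they validate the
algorithms against their own stated operators on data satisfying the
model's assumptions, not equivalence with any particular microscope or
the original acquisition software.

## Reporter quantifications

Livak ΔΔCT: technical replicates averaged per (sample, condition, gene);
ΔCT = CT_target − CT_reference; ΔΔCT per biological sample when sample
names pair across conditions, otherwise from condition means; percent
knockdown = (1 − 2^−ΔΔCT)·100 (negative ΔΔCT reported as negative).  The
opposite sign convention is available via `convention=
"reference_minus_target"`.  ERK-KTR: cytoplasm:nucleus MFI ratio per time
point, normalized to exactly 1 at the first time point.

## Numerical choices and limitations

- All times in hours, masses in pg, lengths in µm; pixel size =
  √(pixel area); (row, col) pixel coordinates, 0-based.
- Greedy tracking is adequate for the sparse fields tested here; it is not
  a globally optimal assignment and will fail at high density or with
  displacement > the cap per frame.
- Division detection requires the daughters to be segmented separately
  within the resume window; daughters that stay merged longer are picked
  up late or censored.
- The end-to-end recovery test uses a 768×768 px canvas with 32 founder
  cells — enough cells for stable class means while keeping the field
  sparse enough for the greedy tracker and a few minutes of runtime.
- The ABM ignores space, death and contact structure by design; it is a
  bookkeeping model for how a small, continuously re-seeded fast-growing
  subpopulation compounds into population-level excess mass.
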