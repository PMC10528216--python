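# Methods

## The measurement model

`secmp` quantifies adeno-associated virus (AAV) preparations from two
orthogonal measurements of the same sample:

1. **SEC-UV.** Size-exclusion chromatography separates monomeric virions
   from aggregates (eluting earlier) and small contaminants (eluting
   later). Within the analyst-chosen monomer peak window, the
   baseline-corrected 280 nm and 260 nm absorbance traces are integrated
   and normalized by path length and injected volume. The resulting pair
   of absorbances is a linear mixture of two absorbers — the protein
   capsid shell and the encapsidated single-stranded DNA:

       A280 = ε_cap,280 · c_cap + ε_DNA,280 · w_DNA
       A260 = ε_cap,260 · c_cap + ε_DNA,260 · w_DNA

   Inverting this 2×2 system yields the capsid molar concentration
   `c_cap` (mol/L) and the DNA mass concentration `w_DNA` (mg/mL). From
   these follow the total capsid number concentration `N_A · c_cap`
   (reported per mL), the mean DNA mass per capsid `w_DNA / c_cap` (Da),
   and the genome size in kilo-nucleotides through the standard ssDNA
   mass formula `M = n_nt × 303.7 + 79.0` Da.

2. **Mass photometry (MP).** A single-particle technique that yields one
   mass estimate per landing particle. The mass histogram of the
   monomeric virion range (3–6 MDa) is used to (a) classify sample
   homogeneity through Gaussian peak fits and (b) count particles in mass
   windows.

The two are combined through a three-branch decision:

- **Scenario 1** — one homogeneous MP peak (fitted σ ≤ 150 kDa): a single
  species; titer and genome size come from the UV branch alone. Zero
  genome size means empty capsids (effective titer 0); otherwise every
  capsid is packaged and the effective titer equals the total capsid
  titer.
- **Scenario 2** — exactly two homogeneous peaks (empty + full): `%full =
  w_DNA / (c_cap · M_genome)`, with the genome mass taken from the vector
  sequence or from the spacing of the two MP peaks. Values above 100% are
  reported with a warning, never clamped: they diagnose integration or
  baseline error.
- **Scenario 3** — anything broader (partially packaged populations):
  `%full = n_full / n_total`, counting raw events in a window of
  half-width 150 kDa around the theoretical fully packaged virion mass
  against all events in 3–6 MDa. The scenario-2 mass-balance ratio is
  still reported, labelled **DNA occupancy**, because for heterogeneous
  samples it is the total DNA relative to full loading — not a particle
  fraction — and is explicitly marked non-interpretable.

In every branch, `effective titer = (N_A · c_cap / mL) × %full`.

## Conventions and numerical choices

- **Volume windows are half-open** `[v_start, v_end)`; **mass windows are
  closed** `[lo, hi]` (an event exactly at 5.40 MDa counts as full).
- **Baseline** is a straight line through two user-supplied anchors per
  channel (or a constant). This is the simplest model consistent with
  manual baseline placement; subtraction is pointwise and linear.
- **Integration** is trapezoidal on the native volume grid with linear
  interpolation at window edges that fall between grid points — no
  resampling. Integration is additive over adjacent windows to 1e-12
  relative, and a warning is logged when the trace exceeds 1 mAU at the
  window edges (a mis-set baseline symptom).
- **Deconvolution conditioning**: the extinction matrix must have a
  condition number below 1e6 (configurable). A solution component that is
  negative but within 2% of the magnitude it would take at a 260/280
  ratio of 0.6 is clamped to zero and flagged (so clean empty-capsid
  samples report exactly 0 genome); larger negative values raise an
  inconsistency error rather than silently producing unphysical output.
- **Peak fitting**: modes are detected on a 3-bin moving average of a
  25 kDa-bin histogram (≥ 4 bins per σ for 110–150 kDa peaks); a
  candidate mode must rise above its surroundings by at least
  `5·sqrt(height)` counts, which rejects Poisson fluctuations of flat
  distributions. Each accepted mode is refined by least-squares Gaussian
  fit (lmfit) on the raw histogram within mode ± 3 provisional σ
  (provisional σ from the half-maximum width). Fits are returned sorted
  by mass; a non-converging fit is flagged per peak, not fatal.
- **Homogeneity** uses σ ≤ 150 kDa inclusive (a fit at exactly 150 kDa
  passes).
- **Counting** always operates on raw events, never on fitted areas; the
  histogram directly enumerates particles.
- **Display rounding** is round-half-even at the stated significant
  figures and is purely a reporting concern; internal values keep full
  precision.

## Default extinction coefficients

The coefficients are configuration, not constants, because DNA extinction
is sequence-independent and capsid-protein extinction varies only mildly
across serotypes. The packaged defaults are literature values: intact
capsid ε280 = 6.61×10⁶ M⁻¹cm⁻¹ with a protein 260/280 ratio of 0.563
(ε260 = 3.72×10⁶), and ssDNA ε260 = 27 mL·mg⁻¹cm⁻¹ (A260 of 1 at
≈ 37 µg/mL) with a 280/260 ratio of 0.53 (ε280 = 14.3). Every report
echoes the coefficient set used. All validation in this package is
closed-loop — the simulator and the inversion share one coefficient set —
so no test outcome depends on these defaults.

## The forward simulator

The simulator is the package's answer key: it generates both input kinds
from a ground-truth species mixture using exactly the physics the
analysis inverts.

- **Chromatogram**: each species contributes a Gaussian elution peak
  whose integrated channel area is `1000 · l · V_inj · (ε_cap,ch · c +
  ε_DNA,ch · w)` mAU·mL; free-DNA species carry only DNA terms,
  free-protein contaminants only (scaled) protein terms. Linear baseline
  drift and white noise are added last, from a seeded generator.
- **MP events**: drawn among capsid-bearing species with probability
  proportional to number concentration — the instrument dilutes every
  sample to a common working concentration (~10¹¹ particles/mL), so the
  event count is an acquisition setting and only species proportions
  matter. Each event mass is the species mass plus Gaussian error.

Default conditions: chromatogram noise SD 0.1 mAU on an 0.002 mL grid,
drift 0.05 mAU/mL, MP per-event mass error SD 120 kDa (which reproduces
the 110–135 kDa fitted widths of homogeneous capsid preparations),
10,000 MP events, 10 µL injection, 1 cm path length. The reference
demo mixes use an empty capsid shell of 3.76 MDa; the heterogeneous demo
mix is 30% empty, 35% partial (0.35·genome), 25% partial (0.78·genome),
10% full monomers, plus an early-eluting aggregate (mass above the 6 MDa
counting ceiling), free DNA and free protein.

Two aspects of that composition are deliberate:

- **Aggregates** perturb UV integration if the peak window is set badly
  but never enter the 3–6 MDa counting range — the method's dominant
  real-world failure mode.
- **Window-capture bias.** With per-event noise of 120 kDa, a ±150 kDa
  counting window captures only ~79% of genuinely full particles. Raw
  windowed counting is therefore unbiased only when the underlying mass
  distribution is locally flat near the window edges, so that leak-in
  from neighbouring partial species offsets the leak-out of full ones.
  Real partially packaged preparations form a near-continuum below the
  full mass, and the default mix emulates that regime (the 0.78·genome
  species sits just below the window). For well-separated empty/full
  mixtures the same bias argues for a wider counting window, which is why
  the window half-width is configurable.

## What the simulator does not model

Physical chromatography (plate theory, peak tailing, column overload),
MP optics and contrast-to-mass calibration, mass-dependent MP detection
efficiency (assumed uniform across 3–6 MDa), absorbance flow-cell
saturation, and light-scattering contributions to UV absorbance. Passing
closed-loop tests therefore demonstrates the correctness of the analysis
chain under the stated signal model, not robustness to every instrument
artifact; on real exports the manual choices (baseline anchors, peak
boundaries) remain the dominant error source.

## Validation problem sizes

Closed-loop validation uses 10,000 MP events per run and 20 seeded
replicates for the recovery and loading-volume studies; the
deconvolution round-trip property is checked over ~1,000 randomized
well-conditioned coefficient sets. These sizes give binomial counting
errors (≈0.3 percentage points SE at %full = 10%) well inside the
asserted tolerances while keeping the whole suite fast.

## Known limitations

- Scenario classification keys on fitted peak count and width; species
  separated by less than about two noise SDs merge into one broad peak
  and are classified (correctly, but uninformatively) as scenario 3.
- The advisory boundary suggester walks to the nearest flanking valleys
  of the summed channels; on noisy traces a plateau can stop the walk
  early. It is advisory only — integration always uses the configured
  window.
- Negative-clamping references a 260/280 ratio of 0.6; for extinction
  sets whose protein ratio is far from typical capsids the 2% tolerance
  may need adjusting.
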