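# redoxmap

Multivariate imaging analysis of tumor metabolism: co-registration and
regional comparison of optical redox ratio maps, IHC-derived hypoxia and
HIF-1α maps, and NAD(P)H lifetime (FLIM phasor) endpoints.

## The problem

Tumor oxygenation, HIF-1α signalling, and cell metabolism vary together
across a tumor section at the scale of the oxygen diffusion limit
(~100 μm). Bulk per-section means wash these relationships out; this
package implements a pipeline that preserves them:

1. **Calibration** — raw two-photon intensities are normalized by laser
   power and PMT gain against fluorescein standards
   (`I = c · Pᵃ · Gᵇ · c_day`, fitted in log space), so images from
   different acquisitions are comparable in fluorescein-equivalent μM.
2. **Optical redox ratio** — per pixel,
   `ORR = I_FAD / (I_NAD(P)H + I_FAD)` ∈ [0, 1]; higher values indicate a
   more oxidized cofactor pool.
3. **IHC masking** — pimonidazole (hypoxia) pixels are intensity above a
   cutoff in the red channel at 755 nm excitation; HIF-1α pixels from the
   red×green *product* at 950 nm (suppresses single-channel background).
   Low-signal pixels and manually traced polygon regions (necrosis,
   non-tumor) are masked out.
4. **Registration** — the IHC modality is aligned onto the
   autofluorescence frame by the unique similarity transform mapping one
   two-point landmark line onto the other (scale, then rotation, then an
   integer-rounded translation); binary maps are resampled
   nearest-neighbour. Masks are intersected.
5. **Regional analysis** — each layer of the {ORR, pimo+, HIF-1α+} stack
   is averaged over a 100 μm-radius disk around every pixel (a pillbox
   kernel with exact fractional rim coverage, divided by the convolved
   mask so borders and masked-out pixels don't bias the average).
6. **FLIM phasor** — per-pixel decays (80 MHz, 256 × 0.0390625 ns bins)
   map to `G = Σc·cos(ωt)/Σc`, `S = Σc·sin(ωt)/Σc`. A line fitted to the
   pixel cloud intersects the universal circle `(G−½)² + S² = ¼` at the
   two species lifetimes (free ≈ 0.4 ns, bound 1.9–5.7 ns); chord
   projection gives each pixel's bound fraction α₂ and
   `τ_m = α₁τ₁ + α₂τ₂`.
7. **Histograms & statistics** — uni/bi/trivariate histograms normalized
   to percent of pixels (the trivariate colors each 2-D bin by the mean of
   a third variable, e.g. ORR), median/Otsu/mean low–high cutoffs,
   χ² homogeneity between binned groups, OLS regression, ANCOVA slope
   comparison, and Holm–Bonferroni adjustment.

A first-class synthetic-section generator (`redoxmap.synthetic`) produces
ground-truthed inputs for every stage — correlated stained foci with known
redox offsets, Poisson photon noise, two-exponential decay cubes, and a
known misregistration — so the whole pipeline is testable end to end
without any imaging data.

## Worked example

`examples/04_phasor_lifetimes.py` simulates a TCSPC cube with three bound
fraction bands and recovers the lifetime decomposition:

```
decay cube: (48, 48, 256), 2.30e+07 photons total
phasor line: S = -0.5331 G + 0.7056  (R^2 = 0.9994, 2304 px)
two-species adequacy: 0.0% of pixels farther than 0.05 from the line
universal-circle lifetimes: tau1 = 0.400 ns (true 0.4), tau2 = 2.419 ns (true 2.5)
  band alpha2 = 0.2: recovered 0.207, mean lifetime 0.818 ns
  band alpha2 = 0.5: recovered 0.517, mean lifetime 1.443 ns
  band alpha2 = 0.8: recovered 0.827, mean lifetime 2.071 ns
```

The recovered τ₂ is biased ~3% low because the 10 ns acquisition window is
shorter than the 12.5 ns repetition period (see `docs/methods.md`); the
bound-fraction bands are recovered within 0.03.

`examples/03_register_and_regional.py` runs the full section pipeline and
detects an implanted pimo−/HIF+/high-ORR subpopulation:

```
estimated similarity: scale 1.0300 (true 1.03), rotation 5.00 deg (true 5.0), ...
registered pimo map agrees with ground truth on 99.98% of in-mask pixels
majority-HIF / minority-pimo regions: mean regional ORR 0.684 over 18295 px
stain-free bulk: mean regional ORR 0.414
detected ORR offset 0.270 (implanted 0.30)
```

The other examples cover generation/IO (`01`), intensity calibration
(`02`), and histogram statistics (`05`).

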