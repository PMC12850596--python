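# Methods

## Physical model and assumptions

The model treats the transmit RF field as quasi-static: at 64–123 MHz the
wavelength in tissue is far larger than the wire spacing of a stent, so
induction dominates, retardation and standing waves are neglected, and the
harmonic carrier factors out — currents are real amplitudes per unit
incident B1. Stent struts are perfect electric conductors (the skin depth
in NiTi at these frequencies is 1–20 µm against strut radii of 50–200 µm),
which has two consequences: the resistive term in the circuit equations is
dropped, and all self-inductances are the *external* (surface-current)
closed forms — the ring formula µ0 R (ln(8R/ρ) − 2) and the matching
external Grover/Rosa rectangle formula

    L = (µ0/π) [ L ln(2Lw/(ρ(L+b))) + w ln(2Lw/(ρ(w+b))) + 2b − 2(L+w) + 2ρ ],
    b = √(L² + w²).

Variants of this formula in the literature differ only in the constant:
−7/4 (L+w) when the internal inductance of a uniform volume current is
included, −2 (L+w) for a surface current. The surface form is the one
consistent with the PEC assumption and with the ring constant −2; it is
certified in the tests against a Neumann-integral oracle (below).

## Loop decomposition and geometry conventions

The stent long axis lies along +x of the model frame. The circular family
is a stack of m = floor(L/l2) + 1 rings spaced by l2, centred on the
mid-plane; when l2 divides L exactly this is the convention
L = (m − 1) l2. The rectangular family pairs the N longitudinal bars at
azimuths ±γ_i from the shielded-component direction, γ_i = (i − ½)(2π/N),
i = 1..floor(N/2). Each pair is represented by the planar *chord rectangle*
through its two bars: length L, width w_i = 2R sin γ_i, lying in the plane
y_i = R cos γ_i. This one representation serves all three uses
consistently:

* flux — the rectangle's normal is parallel to the shielded B1 component
  and its area w_i L is exactly the projected area of the bent loop;
* inductance — the Neumann integral between chord rectangles is
  well-defined for every N (translating all projections onto the central
  plane, a reading the figure-level description permits, would make loops
  with equal w_i coincident and the integral divergent — e.g. both loops
  of an N = 4 cage);
* Biot–Savart — the bars sit at their true distance R from the axis, which
  controls the centre field.

For odd N the unpaired middle bar (index ceil(N/2)) is omitted: closing it
against a neighbouring bar would share wire with an existing loop and the
1/|r1 − r2| kernel diverges on shared segments. The omission is a known
≈1% effect on β.

Orientation relative to B0 is handled entirely by combination weights
(sin²δ on the circular flux, never by rotating geometry): each family is
computed once in its canonical orientation and combined as
β = ½ [β_rect + cos²δ β_rect + sin²δ β_circ].

## Numerical choices

* **Discretization** — 100 segments per wire piece (ring, rectangle side)
  by default, configurable. Rings use polygonal quadrature of the exact
  finite-segment field; straight bars are exact per segment, so the only
  discretization error is the 100-gon approximation of a ring (< 0.1% on
  perimeter and centre field).
* **Neumann integrals** — midpoint double sums over segment pairs;
  halving/doubling the segment count moves rectangle–rectangle couplings
  by < 0.2%.
* **Self-inductance oracle** — the closed forms are cross-checked against
  the mutual inductance between a loop and a copy displaced by the wire's
  geometric mean distance (ρ for a surface current). A naive per-segment
  GMD cutoff misses the adjacent-segment logarithmic contribution by ~10%
  and is not used.
* **Elliptic integrals** — `scipy.special.ellipk/ellipe` are parametrized
  by m = k²; the wrapper accepts the modulus k of the coaxial-ring formula
  and squares it internally (a classic silent-error trap, covered by the
  Neumann equivalence test at < 0.5% over separations of 2–100 mm).
* **Linear solve** — `numpy.linalg.solve` with a relative-residual
  contract of 1e−10 and rejection above condition number 1e12.
* **β extraction** — rectangular family: the value at the stent centre
  (the measured analogue is a small centre ROI; the calculated field is
  flat there). Circular family: the on-axis mean over x ∈ [0, l2/2]
  (51 samples) — the paper-style window "from the central loop to the
  midpoint of its nearest neighbour", which by mirror symmetry is the same
  interval for odd and even ring counts. Axis-only averaging, not a volume
  mean.
* **Masking** — map points closer than 2ρ to a wire are flagged; the
  thin-wire field legitimately exceeds 100% shielding near bars, so
  masking is cosmetic and never applied on the axis where β is read.
* **Degenerate inputs** — l2 ≥ L (fewer than two rings), N < 3, ρ ≥ R,
  coincident loops and out-of-domain magnitude ratios are rejected or, for
  noise-driven ratio pixels, clamped and flagged in a quality mask.

## Flip-angle mapping module

The double-angle method inverts the FLASH ratio
I1/I2 = (1 − cos 2α E1) / (2 cos α (1 − cos α E1)) per pixel through a
lookup table on α ∈ (0°, 90°) at 0.01° resolution; the table construction
verifies strict monotonicity for the given E1 and fails loudly otherwise.
The inversion is restricted below 90° because applied background angles in
the double-angle protocol stay ≤ 81.2°. E1 comes from a mono-exponential
saturation-recovery fit A(t) = A0 (1 − e^(−t/T1)) over the TI series (the
fit is a function of the recovery time, not TR). Shielding maps follow
either β = 1 − α/α_BG (both components shielded) or
β = 1 − (2α − α_BG)/α_BG (single component, stent orthogonal to B0).
Protocol adaptation computes FA/(1 − β) (also rounded to integer degrees
for protocol entry) and averages/(1 − β)²; the formulas, not any rounded
printed values, are authoritative.

## Synthetic data

`synthesize_image_pair` emulates the double-angle acquisition: per-pixel
true flip angle (1 − β) α_BG (or (1 − β/2) α_BG in single-component mode),
FLASH steady-state magnitudes at TR = 200 ms, T1 = 100 ms (the
contrast-doped water-bath regime, E1 ≈ 0.135) and nominal α1 = 40.6°, with
Rician noise (Gaussian on both quadrature channels before magnitude) of
absolute scale σ, deterministic under a fixed seed. A smooth quadratic
background-shading option emulates coil inhomogeneity. The generator does
not model receive-coil structure beyond shading, susceptibility artefacts,
slice-profile effects or motion — recovery tests therefore demonstrate the
correctness of the inversion chain, not robustness to every scanner
confound.

## Study conditions and problem sizes

The model catalogue mirrors the analytical sweeps: R = 8 mm, ρ = 0.2 mm,
circular stacks with l2 ∈ {0.6, 1, 2, 4, …, 30} mm (the measured models'
2-mm grid plus the sub-millimetre endpoints; the source states only the
range 0.6–30 mm), rectangular cages with N = 3…30, each at stent lengths
60, 80 and 100 mm. The commercial reference geometry is
[N, l2] = [4, 6 mm], L = 120 mm, ρ = 0.05 mm. Cell width l1 is labelled by
the chord 2R sin(π/N) (which reproduces the catalogue's N = 8 ↔ 6.1 mm
label); the arc 2πR/N is reported alongside.

## Known limitations

* The calculated centre shielding of the commercial N = 4 geometry is
  32.8%, a little below the ~35% reference value for that stent; the
  residual is within the documented systematic offset between this class
  of analytical model and full-wave simulation for rectangular loops, and
  is sensitive to the strut radius (36.6% at ρ = 0.1 mm vs 32.8% at
  0.05 mm).
* No finite-resistance or skin-effect corrections: measured shielding of
  real (resistive) stents is expected below the PEC prediction.
* Straight, non-overlapping stents only; single-cell designs; round wire.
* No E-field/SAR computation and no standing-wave effects (the dominant
  source of 3 T inhomogeneity in measurements).
* β can exceed 1 in the tight-coupling regime l2 < 1 mm on the axis
  average; physical catalogue geometries stay below 1 at the centre.
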