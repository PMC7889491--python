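# Methods

`prftherm` implements the measurement-and-simulation chain used to
validate RF-heating predictions of a parallel-transmit (pTx) MRI coil
against proton-resonance-frequency (PRF) shift thermometry in a gel
phantom. This note records the models, the parameter choices that
matter, and the design decisions taken where more than one reasonable
implementation exists.

## PRF thermometry model

The water proton resonance frequency shifts with temperature by
`alpha = -0.00988 ppm/degC` (the value appropriate for 1-2% agar gels).
In a gradient-echo acquisition at static field `B0 = 7 T` this appears
as image phase accruing linearly with echo time,

    dphi = 2*pi * gamma * alpha * B0 * dT * TE,      gamma = 42.576 MHz/T,

so heating winds phase *backwards*. `phase_to_temperature` inverts this
relation; the `2*pi` is explicit because gamma is carried in Hz/T and
phase in radians.

### Reconstruction chain

1. **k-space conditioning.** A separable 3D Hann window (unity at the
   k-space centre) and symmetric zero-padding to twice the acquisition
   matrix (64x64x30 -> 128x128x60 at protocol scale). FFTs are unitary,
   so image energy equals windowed k-space energy exactly.
2. **Coil combination.** The receive channels of the two interleaved RF
   shim modes are concatenated (2 x 8 = 16 channels). Per voxel, the
   channel x (echo*repetition) data matrix is reduced to one complex
   series by projecting onto its principal left singular vector
   (computed from the 16x16 channel covariance over all echoes and
   repetitions). For rank-1 noiseless data this preserves
   inter-repetition phase differences exactly. The per-voxel rather
   than global choice of combination weights is a design decision; the
   eigenvector's arbitrary phase is fixed per voxel and cancels in the
   later phase differencing.
3. **First-echo phasing.** Each later echo is multiplied by the unit
   conjugate phase of echo 1 of the same repetition. Any phase common
   to all echoes of a repetition — transmit/receive chain drift,
   per-repetition jitter — cancels identically. The residual thermal
   phase of echo `e` is then proportional to `TE_e - TE_1`.
4. **TE convention.** Because of step 3, temperature conversion uses
   the *effective* echo time `TE_e - TE_1` by default; the nominal-TE
   variant is selectable (`ReconConfig.te_convention="nominal"`) for
   comparison but is biased low by the ratio `(TE_e - TE_1)/TE_e`.
5. **Reference repetition.** Phase differences are taken against a
   configurable reference repetition (default 20, matching a ~14-min
   stabilisation pre-scan) by conjugate multiplication followed by
   angle extraction; no unwrapping beyond +/-pi is attempted, since at
   these echo times |dphi| stays far below pi for the few-degC changes
   of interest.
6. **Echo combination.** Per-echo temperature maps are averaged with
   weights `TE_e * |I_e|` (nominal TE times image intensity),
   normalised per voxel — a convex combination, so the output is
   bracketed by the per-echo inputs.
7. **Drift correction.** Either (a) `probe`: subtract the scalar mean
   offset between map ROI means (default ~4-voxel ROIs) and fibre-optic
   probe readings — with one probe the corrected ROI mean equals the
   probe exactly; or (b) `plane`: per repetition, an OLS fit of
   `a0 + ax*x + ay*y + az*z` over a mask, subtracted from the map. The
   scalar-mean-offset reading of the two-probe correction is a design
   decision (spatial interpolation between two points is
   under-determined).

`stability_report` differentiates the fitted plane coefficients over a
sliding window (default 10 min) and reports the first repetition after
which the largest axis gradient rate stays below a threshold (default
0.001 degC/mm per window) for the rest of the series. The bulk offset
is reported but not thresholded, since on real systems it keeps
growing after the spatial gradients settle.

## Synthetic acquisition generator

The generator renders complex images voxel-by-voxel in image space:
magnitude `|mode| * |coil| * exp(-TE/T2*)`, phase equal to the coil and
mode phase plus per-repetition jitter plus the PRF phase of the true
(heating + drift) field. Because every k-space step of the
reconstruction is linear, image-space generation is exact — no
separate k-space simulator is needed; apodisation tests transform the
same data.

Defaults mirror the 7 T protocol: 64x64x30 matrix over a 300 mm^3
field of view, 8 channels, shim-mode phase increments of 45 deg (mode
1) and 0 deg (mode 2), echo times 1.44/3.62/5.5/7.38/9.26 ms, 41 s
dynamic interval. Coil sensitivities are smooth complex profiles
peaked at 8 equally spaced azimuthal positions; with equal spacing the
45-degree mode cancels identically on the cylinder axis, reproducing
the B1 void that motivates the two-mode acquisition, while the 0-degree
mode peaks there (complementary coverage).

Choices where the protocol gives no number:

- **T2\* = 9 ms.** Echo trains for PRF thermometry are designed with
  `TE_max ~ T2*` (the phase-SNR optimum); the protocol's longest echo
  is 9.26 ms. This matters: the benefit of multi-echo combination over
  the single best echo comes from signal decay across the train. With
  an unrealistically long T2* the last echo alone would be optimal.
- **Hotspot**: a 3D Gaussian (sigma 25 mm) centred 30 mm inside the
  phantom edge — the scale of a single dipole's deposition pattern and
  the position of the edge probe — with amplitude ramping linearly
  over repetitions. It is a stand-in, not a claim of equivalence to
  any simulated field pattern.
- **Drift**: the bulk offset grows linearly for the whole scan; each
  spatial-gradient coefficient settles exponentially with a 14-min
  time constant. The default asymptotic gradient amplitude
  (0.005 degC/mm on x, from a rate of 2.44e-4 degC/mm per repetition)
  is chosen so the drift rate crosses the 0.001 degC/mm-per-10-min
  stability threshold around the settling time, reproducing the
  qualitative stabilisation behaviour of the real system.
- **Noise** is circular complex Gaussian, total sd `noise_sd` per
  channel sample; **seeding** uses one global seed with a named
  sub-stream per component (noise, jitter), so regenerating one stage
  never perturbs another and identical configurations are
  bit-identical.

What the generator deliberately omits: electromagnetic field
simulation, susceptibility and chemical-shift effects, gradient
nonlinearity, T1 saturation, k-space-segmented (elliptical) sampling,
and the temporal interleaving of the two shim modes (both modes are
rendered at every repetition index). Tests passing on synthetic data
therefore validate the *reconstruction algebra and statistics*, not
scanner-specific artefact behaviour.

## Thermal model

A gel phantom has no perfusion or metabolism, so the bioheat equation
reduces to conduction plus the RF source:

    rho*Cp * dT/dt = div(kappa grad T) + rho*SAR,
    -kappa dT/dn = h (T - T_ambient)   on the gel surface.

The solver is explicit forward-time central-space on a regular voxel
grid restricted to the gel interior. Fluxes are accumulated per face,
which makes the insulated scheme conservative to round-off; Robin
losses are applied per exposed voxel face with the face's area. The
PMMA shell is excluded from the conductive domain entirely (the
interior mask stops at the gel surface): the shell is invisible to
thermometry and its thermal properties are not characterised, so
treating the gel surface as the Robin boundary is the cleanest
defensible choice.

Numerics: `dt` defaults to half the explicit stability bound
`min(dx^2,dy^2,dz^2)/(6K)` and is then shrunk so an integer number of
steps spans the requested duration exactly (this also keeps closed-form
checks such as the adiabatic law exact). A user-supplied `dt` above
the bound is rejected before any stepping. Sensors are nearest-voxel
lookups; an energy ledger (SAR input, boundary loss) is accumulated
step-synchronously so the balance check is exact for the scheme.

Grid default for desk-scale work is 5 mm (a 21-minute phantom run in
seconds on one CPU); 1 mm is supported but slow. Test and demo runs
use 10-20 mm grids and matrices of ~16-25 voxels per axis, chosen as
the smallest sizes at which the geometric and statistical properties
under test are well resolved.

## Phantom characterisation

- `thermal_conductivity`: `kappa = K * rho * Cp`. The characterised
  diffusivity is stored as `K = 1.26e-7 m^2/s` (0.126 mm^2/s);
  together with rho = 1022.22 kg/m^3 and Cp = 3776.3 J/kg/degC it
  gives kappa = 0.4864 W/m/degC.
- `specific_heat_from_recipe`: mass-weighted mean over the gel recipe
  components (agar, polyethylene powder, NaCl, TX-151, benzoic acid,
  water). The per-litre-of-water recipe evaluates to 0.877 kcal/kg/degC
  ~ 3672 J/kg/degC with the thermochemical 4186.8 J/kcal. Note this
  differs from the 3776.3 J/kg/degC used in the published simulations;
  both are representable, and table reproductions use the published
  value.
- `percent_difference`: signed `100*(m - r)/r`, displayed half-up at
  1 decimal (so the phantom permittivity 47.76 vs 51.00 reads -6.4%).
- `fit_heat_transfer_coefficient`: sweeps candidate h values (default
  1 to 10 W/m^2/degC in 0.5 steps), simulating the cooling scenario for
  each and minimising the unweighted summed squared residual against
  the probe log(s); with centre and edge probes both given, residuals
  are summed. Noiseless self-generated curves are recovered exactly by
  construction; with 0.05 degC probe noise the estimate stays within
  one sweep step over a few-hour cooling horizon.

## Sensitivity analysis

`sensitivity_factor = |dT/T0| / |dp/p0|` (% per %) from one paired
simulation; probe-position rows use `%/mm` since a relative change of a
zero-based coordinate is meaningless. Uncertainty = sensitivity times
the parameter's measurement standard deviation, computed on the
*unrounded* sensitivity and displayed half-up at 2 decimals; group
totals combine *linearly* — the only rule consistent with both
published group totals (7.78% and 17.94%). `perturbation_study` drives
this from any deterministic evaluator, including the thermal solver;
dataclass scenarios are copied per perturbation, and perturbing
density, Cp or kappa holds kappa (the solver input) fixed while
re-deriving diffusivity.

Four published rows are not arithmetically consistent with their own
printed inputs (permittivity uncertainty, S11 sensitivity, the
heat-transfer-coefficient row, the alpha-coefficient row). These are
stored verbatim and flagged `consistency=False` rather than silently
recomputed; every self-consistent row is recomputed from first
principles at access time.

## Known limitations

- The Hann window is a resolution-reducing filter: a spatially varying
  temperature field is smoothed, so exact pointwise round-trip
  recovery holds without apodisation (or for spatially uniform
  changes, where the phase factors out of the convolution). This is a
  property of the method, not of the implementation.
- The explicit scheme's step count scales as `1/dx^2`; millimetre
  grids over the full phantom are possible but take minutes to hours.
- No covariance between perturbed parameters is modelled (independence
  is assumed, as in the published analysis), and no Monte-Carlo
  propagation is provided.
- The generator's hotspot and coil models are geometric stand-ins;
  agreement statistics on synthetic data do not certify agreement on
  any particular scanner.
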