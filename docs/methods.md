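# Methods

`ringfwi` reconstructs the three-dimensional sound-speed distribution of the
breast from single-frequency ultrasound transmission data acquired on a
multi-row ring array. This note records the model, the numerical choices,
and the limitations a user should know before trusting a reconstruction.

## Physical model

At angular frequency ω the complex pressure field u obeys the heterogeneous
Helmholtz equation

    (∇² + ω² s(x)²) u(x) = δ(x),

where s = 1/c is the acoustic slowness (s/m) and δ the source distribution.
Density is taken constant and attenuation is not modeled: the only unknown
is s on a Cartesian grid, which after discretization turns the equation into
a complex-symmetric sparse system A(ω, s) u = δ.

The array is a cylinder of point elements — `n_rows` rings of
`n_elements_per_row` elements with fixed row pitch (defaults: 0.11 m radius,
32 rows × 256 elements, 2.4 mm pitch). A *cylindrical-wave transmit* fires
the same circumferential element in every row simultaneously; the source
term is the sum of unit point sources at one azimuth across all rows. All
elements receive, so one transmit yields `n_rows × n_elements_per_row`
complex samples per frequency. A sampling operator K (multilinear
interpolation at the element coordinates; `nearest` available) extracts
p = K u; its exact sparse transpose injects receiver-domain residuals back
onto the grid, so the adjoint test ⟨Ku, r⟩ = ⟨u, Kᵀr⟩ holds to machine
precision by construction.

## Waveform inversion

Per frequency the misfit is E(ω, s) = ½ Σᵢ ‖pᵢ(ω, s) − p_obs,i(ω)‖² over
transmits i. Because the physical excitation's amplitude and phase are
unknown, each transmit carries a complex scale

    γᵢ = (pᵢᴴ p_obs,i) / (pᵢᴴ pᵢ),

the least-squares projection of the simulated trace onto the observed one,
re-estimated at every iteration; sources, fields and traces are rescaled by
γᵢ before the misfit and gradient are formed. The adjoint-state gradient is

    ∇ₛE = − Σᵢ Re{ (2ω² s ⊙ uᵢ)* ⊙ λᵢ },   λᵢ = A⁻ᴴ Kᵀ(pᵢ − p_obs,i),

i.e. one extra (adjoint) solve per transmit and iteration. The gradient is
zeroed outside a cylindrical support of the ring radius (and is never
defined in the absorbing pad): no data constrain the model there.

Minimization is Polak–Ribière+ nonlinear conjugate gradient with restarts
(steepest descent on the first iteration per frequency and whenever the
computed direction fails the descent test), and a backtracking Armijo line
search (c = 1e−4, shrink 0.5, ≤ 20 backtracks). The first trial step is
scaled so the largest single-update sound-speed change is about
`max_speed_change_per_step` (default 10 m/s) — a cheap trust-region-like
guard. Slowness is clipped to [1/1700, 1/1300] s/m after every accepted
step. Frequencies run low→high (default 200–800 kHz in 50 kHz steps, 5 NCG
iterations each, homogeneous 1500 m/s start), each warm-starting from the
previous frequency's model: the standard multiscale continuation that keeps
the inversion out of cycle-skipped local minima.

Two modes share this engine. *Volumetric 3D* inverts the full grid from all
receivers. *Slicewise 2D* treats each receiver row as sampling an
independent 2D slice (no elevational sound-speed variation assumed):
transmits become single in-plane point sources at the transmit azimuths,
each slice is inverted on the in-plane grid, and slices are stacked into a
volume by nearest-row assignment of the intermediate z layers. A slice
whose inversion fails is filled with the starting model and flagged.

## Helmholtz solvers

Both the forward and adjoint solves use the convergent Born series: with a
background k₀² and damping ε, write A = B + V, B = L + (k₀² + iε)I,
V = diag(k²) − (k₀² + iε)I, and iterate

    u ← u + (i/ε) V (G(δ − V u) − u),   G = B⁻¹ applied by FFT.

The defaults k₀² = midpoint of min/max Re(k²) and
ε = 1.02 · max|k² − k₀²| satisfy the contraction condition |V| ≤ ε, which
guarantees monotone convergence; the solver evaluates the *true* discrete
residual ‖Au − δ‖/‖δ‖ (default every 4 iterations) and stops at the
configured tolerance (default 1e−6, max 2000 iterations; failure raises
with the last residual attached).

Two implementation choices matter:

* **Discretization.** L is the second-order central-difference Laplacian
  with *periodic* boundary on the padded grid, so the FFT diagonalizes it
  exactly and the series solves the identical matrix the direct oracle
  (sparse LU, `MMD_AT_PLUS_A` ordering, ≤ 2e5 unknowns) factorizes — the
  two agree to ~1e−14, making the oracle test sharp rather than
  discretization-limited. Periodic wrap-around is physically suppressed by
  the absorbing pad.
* **Absorbing pad.** The interior grid is extended by `pad_width` voxels
  (default ~1.25 wavelengths); slowness is edge-replicated and k² acquires
  a positive imaginary part rising as a cosine-squared taper to
  `absorption_strength`·k² (default 1.0) at the boundary. Stronger
  absorption inflates ε (slower iterations) but kills reflections; the
  default keeps the homogeneous-medium point-source field within 5% of the
  free-space Green's function at 3–10 voxel radii.

The adjoint system is solved through complex symmetry (Aᵀ = A):
λ = conj(A⁻¹ conj(r)) — one code path, one testable identity.

Grid sampling below 6 points per minimum wavelength triggers a warning
(coarse studies legitimately run near 4); the solver never hard-errors on
sampling alone.

Two performance options, both leaving the solved system unchanged:
`dtype="complex64"` halves memory traffic for tolerance ≥ ~1e−5, and
`accelerator="gmres"` replaces the Richardson-type series iteration with
restarted GMRES on the same preconditioned operator (I + GV), verifying the
final iterate against the true discrete residual (one refinement retry,
then failure). FWI-scale runs use both; all oracle and identity tests run
the plain series in double precision. FWI objective and adjoint solves also
warm-start from the previous iterate's fields — the fixed-point map
contracts from any start, so only the iteration count changes.

## Synthetic phantoms and data

The phantom generator emulates the structure of numerical breast phantoms
used in simulation studies of ring-array tomography: an ellipsoidal breast
of subcutaneous fat (default 1440 m/s) in a water bath (1500 m/s),
ellipsoidal fibroglandular blobs (1560 m/s), spherical lesions (1580 m/s),
and an optional skin shell (1600 m/s); the piecewise-constant map is
smoothed by a Gaussian (default 3 mm) and converted to slowness. Tissue
speeds are stand-ins inside the 1400–1600 m/s display range typical of
breast tissue, not measurements. `PhantomSpec.random(seed)` draws blob and
lesion placements reproducibly.

Observed data are synthesized directly in the frequency domain — a
broadband pulse is *not* modeled, since the inversion works per frequency
and γᵢ absorbs any per-frequency source spectrum. Noise is circular complex
Gaussian, with per-entry power set `level_db` below the global mean
|signal|² across all entries and frequencies (−20 dB ⇒ noise-to-signal
power ratio 0.01), seed-reproducible. Simulating on the inversion grid
commits the "inverse crime"; `supersample=2` solves on a 2× finer grid with
the same element positions to gauge (log, not assert) that sensitivity.

What passing tests therefore show: the solver, adjoint, gradient and
optimizer are mutually consistent, and under matched forward models the 3D
acquisition genuinely beats the slicewise approximation. What they do not
show: robustness to real transducer directivity, calibration error,
attenuation, density contrast, or waveform model mismatch beyond grid
refinement.

## Desk-scale study conditions

Two end-to-end studies (`ringfwi.studies`) are sized for minutes on one CPU:

* `recovery_study`: 2D, 64² grid at 1.5 mm, single-row ring (radius 40 mm,
  32 elements), 8 transmits, +2% Gaussian inclusion, noiseless data,
  150/200/250 kHz × 5 NCG iterations. Multi-frequency FWI cuts the
  starting-model RMSE by well over half.
* `dimensionality_study`: 3D, 48³ grid at 2.5 mm (padded to 64³), ring
  radius 45 mm, 8 rows × 32 elements at 5 mm pitch, 16 cylindrical-wave
  transmits, −20 dB noise, phantom with a lesion centered 12 mm above the
  mid-plane, 100/140 kHz × 4 NCG iterations (a continuation length chosen
  for this problem scale), single-precision accelerated solves at 1e−4
  residual. Both volumetric 3D FWI and the slicewise baseline invert the
  same data; whole-volume RMSE and PCC are reported for both. The slicewise
  arm is structurally disadvantaged here — cylindrical transmits span the
  whole elevation and the lesion sits off-plane — which is exactly the
  regime the multi-row 3D acquisition is designed for; full-scale clinical
  slicewise imaging with elevation-focused arrays fares better than this
  baseline.

Metrics are RMSE in m/s and Pearson's correlation coefficient, by default
over the whole inversion volume (the absorbing pad is internal to the
solver and never part of the volume); an optional mask restricts them to a
region such as the breast. PCC is undefined (and raises) for a constant
volume over the mask.

## Known limitations

* No attenuation, density variation, elasticity, or time-domain modeling.
* Elements are ideal points — no directivity, aperture, or cross-talk.
* The 2nd-order stencil needs ≥ ~4 points per wavelength; push the schedule
  higher in frequency only with a finer grid.
* The slicewise baseline reconstructs only at row heights; inter-row voxels
  are nearest-row copies.
* Edge-replication of slowness into the pad means the gradient ignores the
  (masked-out) dependence of pad values on the outermost interior voxels.
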