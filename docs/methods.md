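# Methods

## Model and assumptions

Barbules and barbs are treated as slender rectangular keratin cantilevers.
Two idealisations are deliberately kept separate:

* **Vibration** uses a *uniform* Euler–Bernoulli cantilever: constant
  cross-section, no shear deformation or rotary inertia (no Timoshenko
  corrections), no damping, no aerodynamic drag, single-mode response. The
  eigenproblem is the classical clamped-free one: zero deflection and slope
  at the root, zero bending moment and shear at the free end, giving
  cos β = −sech β with β = k l. The response functions are first-mode only;
  the package refuses to build a response field from a higher mode rather
  than silently superpose.
* **Static deflection** uses a *linearly tapered* cantilever whose
  thickness closes to zero exactly at the tip (taper slope k = t/l) under a
  uniform pressure q = m g / A acting over the beam width (line load q·w).
  Because t − (t/l)x = (t/l)(l − x), the deflection integrand is constant
  and the deflection profile is exactly linear in x. Small-deflection
  theory throughout; no contact between neighbours, no hooklet mechanics.

Where a tapered barbule feeds the modal model (the synthetic pipeline), its
**root** dimensions define the uniform section (area w·t, inertia w·t³/12).
This is an assumption, not a derived rule: the vibration and statics models
are not reconciled for taper, and the summary tables flag nothing about it.
Frequencies of strongly tapered beams computed this way are systematically
approximate.

The released-tip-force excitation maps a static tip deflection
F l³/(3 E I_z) onto the first mode via the free-end shape value 2.000,
giving the modal amplitude C = F l³/(6 E I_z). The attached water drop used
to interpret the peak tip speed is massless — its inertia does not shift
the frequency. The angular velocity is the small-angle surrogate
ω(t) = v(l, t)/l with no arctangent correction. No default is shipped for
the tip force itself: how hard a preening stroke loads a barbule is not
modelled, so F is a required input where it matters.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| phase φ | π/2 | rad | release-from-rest: displacement at t = 0 equals the static shape, initial velocity zero |
| samples per period | 4096 | — | time-grid extrema converge from below; 4096 gives ~3e-8 relative shortfall on v_max |
| slenderness warning | δ_max/l > 0.1 | — | our own guard on linear theory, not a modelled bound |
| root-finder xtol | 1e-14 | — | roots are stable to 6 decimals from 1e-10 already; 1e-14 costs nothing |

Synthetic generator defaults (SI): barbule length 180–400 µm, barbule root
thickness 3–6 µm, barb length 15–30 mm, barb root thickness 150–300 µm,
width = 2 × thickness, E = 2.5 GPa, ρ = 1150 kg/m³, bird mass 0.35 kg,
wing+body area 0.06 m², g = 9.81 m/s². These are placeholder magnitudes
assembled from published feather-keratin and pigeon morphology values —
**not measurements**; no numeric micro-dimensions are available to this
package. Counts are drawn uniformly (inclusive), dimensions log-uniformly
(they are scale parameters). One material per feather. Every artifact
echoes its config and a SHA-256 config hash so a run is replayable.

## What the generator does and does not emulate

It reproduces the *hierarchy* (every barbule shorter than its parent barb,
enforced at config validation), plausible dimension magnitudes, and the
derived per-barbule beam sections the analyses need. It does not emulate
branching angles, hooklet/groove geometry, per-barbule material variation,
along-feather gradients, or any image-like output. A green pipeline test
therefore establishes that the mechanics runs correctly over realistic
magnitudes and is bit-reproducible — not that the geometry statistics match
any real feather.

## Numerical choices

* **Root finding.** Root j of cos β = −sech β is bracketed in
  [(2j−1)π/2 ± 0.5] (mode 1 in [1, 3]) and refined by Brent's method. The
  sech decay guarantees one root per bracket; brackets are validated and a
  failure raises with diagnostics rather than returning junk.
* **Overflow safety.** sech, σ and the mode shape are written with e^(−β)
  factors: σ = (1 − e^(−2β) − 2e^(−β) sin β)/(1 + e^(−2β) + 2e^(−β) cos β),
  and the shape uses (1−σ)e^z/2 + (1+σ)e^(−z)/2 − cos z + σ sin z with
  1−σ formed cancellation-free. Any mode count can be *solved*; shape
  evaluation is accurate while e^(βξ) is representable (modes into the
  hundreds), which covers every practical request.
* **Machine-precision limits, stated not hidden.** Two textbook identities
  are not representable in doubles at high modes: the determinant form
  |cos β cosh β + 1| is amplified by cosh β (≈1.6e7 at mode 6, so the best
  double leaves ~1.8e-8), and the asymptotic gap to (2n−1)π/2 sinks below
  the ulp of β past mode ~10. Tests assert the scaled determinant
  (<1e-12) everywhere, the raw form where representable, and the gap bound
  with an explicit few-ulp allowance.
* **Quadrature cross-checks.** The tapered-deflection and point-load
  closed forms each have a quadrature mode (adaptive `scipy.integrate.quad`
  of the uncancelled integrand) used as an independent oracle in tests
  (agreement 1e-8 / 1e-10 relative over random parameter decades).
* **Degenerate inputs.** Section inertia at the tapered tip is exactly
  zero: returned with a RuntimeWarning, not an error, because the
  deflection there is finite. Zero tip force gives identically zero
  response. Degenerate generator ranges (low = high) collapse to exact
  values, which the tests exploit.
* **Determinism.** No global RNG: one seeded `numpy` Generator per feather.
  Reports use pandas' shortest-repr float formatting and sorted-key JSON,
  so identical configs produce byte-identical files; logs carry no
  timestamps.

## Design choices where the model family is open

* σ is defined as (sinh−sin)/(cosh+cos) and *subtracted* in the shape —
  the sign convention that yields the positive printed coefficient 0.7341
  and free-end value +2.000.
* Modal excitability is not ranked: low modes dominate in practice, but no
  participation metric is computed; callers ask for the modes they want.
* The pipeline layer is a library (validated `RunConfig`, stage functions,
  report writers) plus narrative example scripts; there is no shell
  command. The functions are the interface.

## Known limitations

* First-mode-only response; no damping means predicted peak speeds are
  upper bounds.
* The uniform-section modal model applied to tapered barbules (root
  dimensions) overestimates stiffness toward the tip.
* The linear static model is trusted only while δ_max/l stays small; the
  0.1 warning threshold is a convention.
* Synthetic geometries are magnitude-realistic, not morphologically
  realistic.
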