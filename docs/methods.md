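# Methods

## The model

A gramicidin A channel is a head-to-head dimer of two β-helical monomers, one
per bilayer leaflet. Its dissociation is reduced here to one coordinate, the
axial centre-of-mass separation `r` of the two monomers, governed by two
competing terms:

```
V(r) = D_e * [(1 - exp(-β (r - r_e)))^2 - 1]  +  (H_B / 2) * (d - l(r))^2
```

* The **Morse bond** models the hydrogen-bonded subunit–subunit junction:
  depth `D_e` (the dissociation energy), equilibrium separation `r_e`,
  stiffness `β`. Near `r_e` it is harmonic with curvature `2 D_e β²`, so a
  Hookean junction constant `k` maps to `β = sqrt(k / (2 D_e))`.
* The **mismatch penalty** is the continuum elastic cost of the local bilayer
  deformation, collapsed into a single spring coefficient `H_B` acting on the
  hydrophobic mismatch `d - l(r)` between the bilayer hydrophobic thickness
  `d` and the dimer hydrophobic length `l`.

The geometry couples the two terms through `l(r) = l0 + s (r - r_e)` with
unit slope `s = 1` by default: as the monomers separate axially, the
hydrophobic length of the (still joined) dimer grows one nanometre per
nanometre of separation, relieving the mismatch. The slope is exposed
(`coupling_slope`) for sensitivity analyses but is not part of the standard
model. The penalty is an unrestricted harmonic: overshoot (`l > d`) is
penalized like undershoot.

With positive mismatch and sufficient bilayer stiffness the sum is a double
well: a *dimer well* near `r_e` where the bond has won, a *dissociated well*
near `r_e + (d - l0)` where the membrane has won and the mismatch is
relieved, and a transition state between them. The landscape regime is
classified explicitly (`double_well`, `single_well_dimer`,
`single_well_dissociated`, `barrierless`) because either well can disappear:
the dissociated well does not exist when `β (d - l0)` is small (the Morse
tail still dominates where the harmonic is stationary), and the dimer well
is destroyed when the membrane pull `H_B (d - l0)` exceeds the maximal bond
restoring force `D_e β / 2`.

## Kinetics

Transition-state theory gives the dissociation rate `k_diss = A
exp(-ΔV/kBT)` with `ΔV = V(r_ts) - V(r_dim)`, and the mean channel lifetime
`τ = 1/k_diss`. The pre-exponential factor `A` is not fixed by the model, so
lifetimes are reported as the dimensionless `ln(τ A) = ΔV / kBT`; every
trend with bilayer thickness or stiffness is independent of `A`. The
membrane *disjoining force* — the pull the deformed bilayer exerts on the
dimer at its well — is `F = H_B (d - l(r_dim))`, identical to minus the
derivative of the mismatch term at `r_dim`. In the `barrierless` regime no
Arrhenius barrier exists; the rate is reported as a lower bound (`rate ≥ A`)
rather than a fabricated number.

Since all reported quantities are energy differences, the Morse offset
convention (minimum at `-D_e`, plateau at 0) is documented and fixed, not
configurable.

## Parameters and the reference profile

All energies are held in thermal units (`kBT = 1`) and lengths in
nanometres by default; `UnitSystem` converts to/from other scales and the
round trip is exact to 1e-12. The shipped profile `paper2011` describes a
gramicidin A dimer in a solvent-free monoglyceride bilayer:

| symbol | value | unit | why |
| --- | --- | --- | --- |
| `D_e` | ln(100) ≈ 4.605 | kBT | dimer:monomer equilibrium ratio ≈ 1:100 |
| `r_e` | 1.3 | nm | centre-of-mass spacing of the two β6.3-helix monomers (~13 Å) |
| `k` | 920 | kBT/nm² | junction stiffness ≈ 3.8 N/m for the 4–6 hydrogen-bond interface, atomistic-profile order of magnitude; gives `β ≈ 9.99 nm⁻¹` |
| `l0` | 2.17 | nm | standard dimer hydrophobic length |
| `d` | 2.85 | nm | monoglyceride bilayer hydrophobic thickness |
| `H_B` | 12 | kBT/nm² | monoglyceride-range phenomenological spring coefficient |
| `A` | 1 | 1/time | reduced time unit (unassigned prefactor) |

These are representative literature-scale values assembled by this package,
chosen once to place the reference state in the double-well regime with
positive mismatch (`d - l0 = 0.68 nm`); they are a named config profile,
not constants in the model core, and any field can be overridden in TOML or
on the command line.

## Numerics

* **Stationary points.** The analytic gradient is evaluated on a 4001-point
  grid over `[max(ε, r_e - 5/β), r_e + max(d - l0, 0) + 5/β + 0.5 r_e]`
  (five Morse decay lengths of margin around both candidate wells); each
  sign change is refined with a bracket-preserving Brent iteration to
  machine precision (gradient residuals far below the 1e-10 reduced-unit
  tolerance). Roots closer than `1e-6 r_e` are merged; |curvature| below
  1e-8 (reduced) marks a degenerate point and flags the landscape
  `barrierless`, since at the well-merging bifurcation a minimum and the
  maximum coalesce. The minimum nearest `r_e` is the dimer well; the
  largest-`r` minimum is the dissociated well.
* **Oracle.** `oracle_grid_search` finds extrema purely from sampled
  potential values (no derivatives) and is used to cross-check the
  root-finder on randomized parameter sets (count, kind and location within
  one grid step, 100/100 seeded sets) — a deliberate dual route, never the
  production path.
* **Linear fits.** Ordinary least squares with an explicit convention for
  the degenerate constant-`y` case (`r² = 1`, flagged). Scan rows whose
  regime is not `double_well` are kept in the output table but excluded
  from fits, with the excluded count recorded in the scan metadata; the
  thresholds used to call a trend "approximately linear" (`r² ≥ 0.98` for
  lifetime trends, `≥ 0.99` for the force–mismatch line) are recorded there
  too.
* **Scan sizes.** Default sweeps are 9 points over ±0.4 nm in thickness and
  ±50% in stiffness around the profile values; the verification sweep uses
  100 random parameter sets against a grid-step-1e-4 (reduced) oracle.
  These sizes resolve the trends cleanly while keeping every analysis
  interactive (~1 s).

## What the random fixture generator emulates

`generate_fixture_parameters` samples bond depths of 2–30 kBT, Morse decay
lengths 1/β of (1/30–1/2) `r_e`, mismatches of −0.5 to +1.5 nm and bilayer
stiffnesses capped so the elastic energy at the dimer well never exceeds the
bond depth — i.e. the corner of parameter space where real
channel–bilayer systems live, including both single-well and double-well
landscapes. It emulates *parameter* diversity only: passing tests show the
numerics are correct across that space, not that the one-dimensional model
captures real membranes (no lateral monomer motion, no subunit
rotation/translation coupling, no intermediate hydrogen-bonded conducting
states, a single lumped elastic coefficient instead of compression and
bending moduli).

## Known limitations

* The model is a trend model: a two-body, one-dimensional reduction whose
  absolute barriers and lifetimes depend on the unassigned prefactor `A`
  and on the reconstructed parameter scale. Only the signs and approximate
  linearity of `ln(τ A)` versus thickness/stiffness, and the linear
  force–mismatch law, are meaningful outputs.
* Near the bifurcation where the dissociated well and the barrier are born,
  the transition-state *position* is the most sensitive observable: on
  parameter sets with shallow bonds (e.g. `D_e` of order 1 kBT) the relative
  change of the well-to-barrier distance across a thickness sweep can exceed
  the relative change of the barrier itself. The familiar "distance changes
  are small" behaviour holds on the reference profile (relative distance
  change 0.45 vs barrier change 0.55 across ±0.4 nm) but is not universal.
* The harmonic mismatch penalty is two-sided by construction; a rectified
  (compression-only) variant is out of scope, as are r-dependent `H_B` and
  any three-dimensional dissociation pathway.
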