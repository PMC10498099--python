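# ordose

A discrete-ordinates (Sn) linear Boltzmann transport dose engine for photon
and proton beams on Cartesian voxel phantoms, together with an analytic
proton depth-dose comparator.

The solver discretises direction space on a gantry/couch quadrature (a
standard 26-direction set and a fine 18 x 36 set), energy on multigroup
grids (14 photon groups to 10 MeV, 50 proton groups to 250 MeV), and space
on a voxel grid swept in upwind order with a hybrid diamond/step closure.

* **Photons**: a dual-source head model projects unscattered fluence along
  divergent rays (exponential attenuation over radiological depth); five
  source-iteration sweeps with empirically factored Compton tables produce
  the scattered field; Compton recoil electrons form a fixed source for an
  electron transport solve (Møller + Mott scattering), and dose is the
  stopping-power-weighted electron fluence.
* **Protons**: continuous slowing down (CSDA) with per-layer energy maps
  forms the fixed fluence for a spread-out Bragg peak (Bortfeld–Schlegel
  layer weights with the (d/R)^0.7 correction, linear nuclear loss λ,
  elastic loss τ·σ); elastic Mott scattering is solved by transport sweeps.
* **Comparator**: closed-form pristine Bragg curves (power-law range-energy
  relation, exact per-bin averages) with three-point range straggling
  (Δ = 1 mm) and layer superposition.
* Positional uncertainty enters through a 17³ → 64-point outer-product
  kernel applied to the unscattered fluence.
* Low-fluence 4×4×4 voxel clusters can be merged adaptively into 10 mm
  cells during sweeps.

## Command line

```bash
ordose quadrature-report                    # ordinate table (angles, weights)
ordose calc --particle proton --voxel 5 --out out/    # LBTE dose + curves
ordose analytic --out out/                  # analytic comparator curve
ordose compare --particle proton --out out/ # DO vs analytic, % local dose
ordose converge --particle proton --out out/  # per-iteration probe traces
```

Common flags: `--phantom {water,lung,bone}`, `--iterations` (default 5),
`--quadrature {standard,fine}`, `--adaptive/--no-adaptive`,
`--kernel <csv>`, `--ssd <mm>`. Outputs are MetaImage dose grids
(.mhd/.raw), CSV curves with the configuration echoed in the header, and a
JSON report; reruns with the same configuration are byte-identical.

## Package layout

| module | contents |
|---|---|
| `ordose.quadrature` | angular quadratures, energy grids, bilinear beam-to-ordinate assignment |
| `ordose.materials` | HU → tissue conversion, stopping powers, attenuation, range-energy relation |
| `ordose.xsections` | Compton (photon/electron), Møller and Mott tables on the quadrature |
| `ordose.sources` | head models, unscattered fluence, CSDA maps, SOBP weights, uncertainty kernel |
| `ordose.transport` | scatter sources, numba sweep kernels, photon/electron/proton solvers, adaptive mask |
| `ordose.dose` | fluence → dose, paired normalisation (3-D max = 100%), curve extraction |
| `ordose.analytic` | pristine Bragg closed form, straggling average, analytic SOBP |
| `ordose.phantoms` / `ordose.gridio` / `ordose.cli` | synthetic phantoms, MetaImage/CSV I/O, CLI |
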