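# esofield

Finite-element modelling of the electrical field produced in the wall of the
human esophagus by bipolar stimulation electrodes — ring electrodes mounted on
a catheter, or patch electrodes glued to an inflatable bag.  The package is
aimed at researchers who design esophageal stimulation catheters for visceral
pain studies and want to know, for a given electrode layout and injected
current, how much tissue of each wall layer is exposed to a nerve-activating
field, and what transmural impedance to expect.

## Model

The esophagus is a three-compartment volume conductor: a mucosal layer
(0.85 mm, σ = 0.05 S/m) and a muscle layer (2.72 mm, σ = 0.53 S/m) wrapped
around a non-conducting catheter/bag lumen, embedded in an effectively
infinite surrounding medium of serosa and lung (σ = 0.27 S/m).  Stimulation
pulses (1 ms at 200 Hz) are far below the dispersion range of these
conductivities, so each pulse obeys the quasistatic potential equation

    ∇·(σ∇V) = 0,        J = σE = −σ∇V,

with the injected current entering only through the electrode contacts.  Each
contact is an ideal-metal equipotential surface carrying a prescribed total
current ±I; the rest of the inner surface is insulated, and the truncated
far-field boundary is grounded.  First-order tetrahedral elements on a
structured, graded mesh (at least five element layers across every tissue
layer) are solved with a deterministic preconditioned conjugate-gradient
method to a relative tolerance of 1e-10.

From the nodal potentials the package derives:

* **transmural impedance** `Z = (V_source − V_sink)/I` in kΩ;
* **activation volumes**: the tissue volume per layer in which |E| exceeds
  the nerve-activation threshold (20 V/m by default, with 3 and 100 V/m as
  standard alternates), in mm³;
* exported VTU fields (V, |E|, per-threshold activation masks) for ParaView.

Six bundled scenarios pair the geometries used in practice — ring spacings of
2/10/20 mm and bag fillings of 2/4/5 mL — with the sensation-threshold (ST)
and pain-detection-threshold (PDT) currents measured in vivo for each
configuration.  The solver is linear in I, so one solve per scenario yields
the fields at both calibrated currents.

## Worked example

```
$ esofield run --scenario ring2 --threshold 3 --threshold 20 --threshold 100
mesh: 147000 nodes, 838656 tets (h = 0.17 mm)
solve: residual 9.80e-11, conservation error 5.84e-13
impedance_kohm  1.3487
threshold_Vpm   region    volume_mm3
3       mucosa  404.5
3       muscle  2494.9
3       surround        25013.0
20      mucosa  180.1
20      muscle  1103.6
20      surround        2371.7
100     mucosa  98.3
100     muscle  402.9
100     surround        87.8
```

This is the 2 mm ring pair (elliptical mucosal contact) driven at its PDT
current of 26 mA.  The transmural impedance is 1.35 kΩ.  At the default
20 V/m activation threshold, 180 mm³ of mucosa and 1104 mm³ of muscle see a
suprathreshold field — the muscle layer dominates the recruited volume, and
raising the threshold to 100 V/m sharply de-recruits it (403 mm³) while
lowering it to 3 V/m recruits most of the muscle in reach (2495 mm³).

`esofield table1 --out table1.tsv` runs all six scenarios and writes the
computed impedances and ST/PDT activation volumes side by side with the
published model values and their relative deviations.  Python users can reach
everything through `esofield.run_scenario`, `esofield.generate_mesh`,
`esofield.assemble_and_solve` and friends.

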