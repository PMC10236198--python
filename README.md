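# venoflow

Hemodynamic flow-complexity metrics for cerebral venous outflow models.

## The problem

In infants with high-flow arteriovenous shunts (vein of Galen malformations),
the paired venous outflow channels — transverse and sigmoid sinuses draining
through the jugular bulbs — can remodel asymmetrically: one jugular bulb may
progressively narrow (jugular bulb stenosis) while the other stays open.
First-order hemodynamic quantities such as the mean wall shear stress are
often *similar* between the two sides, so they cannot explain the asymmetric
fate.  Higher-order descriptors of disturbed flow can: the topology of the
wall-shear-stress vector field (its critical points) and the total length of
vortex core lines in the lumen differ several-fold between sides, and the
side with the greater mean critical-point count is the side that stenoses.

`venoflow` implements this analysis chain for synthetic, idealized venous
geometries, for researchers who want to study or extend these metrics without
patient imaging data: every input — geometry, boundary condition, flow field —
is generated by code with a known exact answer.

## The metrics

For a tangential WSS vector field **τ**(x, t) on the vessel wall over one
cardiac cycle T, evaluated on the jugular-bulb region of interest:

* **WSSmean** — spatial mean over the ROI of the time-averaged magnitude
  TAWSS(x) = (1/T) ∮ |**τ**| dt, in dyne/cm².
* **OSImean** — spatial mean of the oscillatory shear index
  OSI = ½ (1 − |∮ **τ** dt| / ∮ |**τ**| dt) ∈ [0, ½]: 0 for unidirectional
  shear, ½ for perfect reversal.
* **nCrPointsmean** — cycle-averaged count of critical points: zeros of **τ**
  located by linear interpolation within wall elements and classified from
  the eigenvalues of the local 2×2 Jacobian as source/sink nodes, source/sink
  foci or saddles (Poincaré index +1, except saddles −1).
* **corelen** — cycle-averaged total length of vortex core lines, extracted
  with the Sujudi–Haimes parallel-vectors method on linear tetrahedra: in
  each element whose velocity-gradient tensor has a complex eigenvalue pair,
  the locus where **u** is parallel to the real eigenvector.

Boundary conditions come from echocardiogram arithmetic (stroke volume
SV = EDV − ESV, cardiac output CO = HR × SV, and the excess over a
body-surface-area-referenced CO as the shunt flow) or from PC-MRI-style
flow-rate waveforms (site averaging, left/right split).  Flow fields come
from closed-form Poiseuille/Womersley/Lamb–Oseen samplers or from a minimal
2-D unsteady projection solver (prescribed inflow, zero-pressure outlet,
rigid no-slip walls, two cardiac cycles at dt = 0.01 s, second cycle
analysed).

## Worked example

```bash
python examples/bilateral_pipeline.py
```

```
--- symmetric null ---
  left : WSSmean  12.165 dyne/cm^2  OSImean  0.0000  corelen  0.00 cm  nCrPoints 0.00
  right: WSSmean  12.165 dyne/cm^2  OSImean  0.0000  corelen  0.00 cm  nCrPoints 0.00
  fold ratios : {'wss_mean': 1.0, 'osi_mean': 1.0, 'corelen': 1.0, 'n_cr_points_mean': 1.0}
  lateralization: none

--- left-sided planted vortex ---
  left : WSSmean  13.887 dyne/cm^2  OSImean  0.0009  corelen  3.00 cm  nCrPoints 1.00
  right: WSSmean  12.165 dyne/cm^2  OSImean  0.0000  corelen  0.00 cm  nCrPoints 0.00
  fold ratios : {'wss_mean': 1.1416..., 'osi_mean': None, 'corelen': None, 'n_cr_points_mean': None}
  lateralization: left
```

Two identical outflow branches carrying the same pulsatile Womersley flow are
perfectly symmetric: no side is called.  Planting a vortex (plus its
wall-footprint focus pattern) in the left branch leaves WSSmean within the
1.3-fold similarity band while corelen jumps from 0 to the branch length and
a critical point appears — so the left side is called.  Ratios against a zero
contralateral metric are reported as the raw pair with an "undefined" flag
rather than as infinity.

Other examples, one per capability: `echo_boundary_conditions.py`,
`waveform_averaging_and_split.py`, `wss_and_osi_on_tube.py`,
`planted_topology.py`, `vortex_core_lines.py`, `stenotic_channel.py`.

## Layout

```
src/venoflow/
  geometry.py   idealized tubes, bends, bifurcations, 2-D channels; ROIs,
                cross-sections (CGS units, swept-tet meshing)
  waveforms.py  echo arithmetic, waveform averaging/resampling/splitting,
                synthetic pulsatile waveforms
  analytic.py   Poiseuille/Womersley/Lamb-Oseen samplers, plantable WSS
                critical-point patterns (the test oracles)
  solver.py     2-D unsteady incompressible projection solver (MAC grid)
  wss.py        wall shear vectors, TAWSS, OSI, ROI spatial means
  topology.py   critical-point detection/classification, core-line extraction
  report.py     fold ratios, area changes, lateralization, pipeline
  vtkio.py      STL / legacy-VTK / waveform-CSV input and output
```
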