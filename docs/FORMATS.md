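# File formats

All files are plain text so runs diff cleanly.  Angles are degrees and image
numbers are 1-based in files; internally the package works in radians and
millimetres.

## Experiment JSON

One experiment per file:

```json
{
 "beam": {"direction": [0.0, 0.0, -1.0], "wavelength": 1.0},
 "goniometer": {"axis": [1.0, 0.0, 0.0]},
 "detector": [
  {"origin": [-211.8, -217.3, -250.0],
   "fast": [1.0, 0.0, 0.0],
   "slow": [0.0, 1.0, 0.0],
   "pixel_size": [0.172, 0.172],
   "image_size": [2463, 2527]}
 ],
 "crystal": {"U": [9 floats, row-major],
             "B": [9 floats, row-major],
             "crystal_system": "tetragonal"},
 "scan": {"image_range": [1, 300], "osc_start_deg": 0.0, "osc_width_deg": 0.1}
}
```

`direction` points from the source toward the sample; `wavelength` is in
angstroms.  `origin`, `fast` and `slow` are the laboratory-frame corner
position (mm) and in-plane unit vectors of each panel; `detector` is a list,
one entry per panel.  `B` holds the reciprocal-cell vectors (inverse
angstroms) as columns.  Files written by the package use sorted keys and are
byte-stable under a read/write round trip.

## Reflection table CSV

Fixed column order:

```
h,k,l,panel,entering,x_obs_mm,y_obs_mm,phi_obs_deg,var_x_mm2,var_y_mm2,
var_phi_deg2,x_calc_mm,y_calc_mm,phi_calc_deg,flags
```

`entering` is 1 when the reciprocal-lattice point crosses into the Ewald
sphere at the predicted angle, 0 when it exits.  Missing observations are
empty fields.  `flags` is a bitmask: 1 = used in refinement, 2 = outlier,
4 = near-axis.  Floats are written with `%.12g`, so write -> read -> write is
byte-identical.

## Run outputs

`refine` writes into its output directory: `refined_experiment.json` (one
per experiment), `refined_reflections.csv` (the working set with updated
calculated centroids and flags), `history.json` (per-iteration L, r.m.s.d.s
and parameter vector), `cell_esds.csv`, `correlation.csv` (labelled
correlation matrix of weighted Jacobian columns) and `run_config.json` (the
fully resolved options used, sufficient to re-run the command).
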