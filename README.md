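# nemorph

Morphometry of the reforming nuclear envelope (NE) from 3D electron
microscopy, for cell biologists quantifying mitotic NE reassembly:

- **vesicle sizing** — detect labelled vesicles in segmentation volumes
  by a sphericity criterion (similar x, y, z diameter) and measure
  their diameter distribution;
- **NE gaps and vicinity density** — find discontinuities of the
  reforming envelope, compute their vertical area (dx × dz), classify
  them into small/medium/large, and compare vesicle densities in 1 µm
  sampling fields (close ≤ 500 nm / far annulus) around gap endpoints
  vs random NE control points;
- **in situ rim curvature** — the quantity at the package's core. At a
  nuclear pore the inner and outer nuclear membranes join through the
  NE rim, the most highly curved region of the envelope. From a
  tomographic volume, each pore clip is rotated so the membranes run
  along x, rotated about x in 10° steps to the most circular (en-face)
  view, rotated back 90°, and the rim diameter RD — the distance
  between the dark membrane centre-lines where they just become
  parallel — is measured on both sides of the pore at its widest
  depth, along with the pore diameter. Curvature follows as

      κ = 2 / RD      [nm⁻¹]

  with Kruskal–Wallis + Dunn (or ANOVA + Tukey, after a Shapiro–Wilk
  normality gate) comparing conditions, and a Pearson check of angle
  dependence as QC against anisotropic section shrinkage.

No raw EM volumes ship with the package. Instead a first-class phantom
generator renders ground-truthed telophase scenes (NE sheet, gaps,
vesicle shells) and tomogram-like pore volumes (half-toroidal rim of
known RD at known tilt), so every stage is validated by parameter
recovery. See `docs/methods.md` for the model and numerical choices.

## Worked example

Measure a cohort of 6 synthetic pores with true RD 26 nm (κ = 0.0769):

```python
import numpy as np
from nemorph.pipelines import measure_pore_cohort, cohort_kappas

ms = measure_pore_cohort(6, rim_diameter=26.0, pore_diameter=80.0, seed=11)
for m in ms:
    print(f"pore {m.pore_id}: en-face {m.en_face_angle:.0f} deg, "
          f"RD {m.rim_diameter_i:.1f}/{m.rim_diameter_ii:.1f} nm, "
          f"pore {m.pore_diameter:.1f} nm")
print("median kappa:", round(float(np.median(cohort_kappas(ms))), 4), "/nm")
```

```
pore 0: en-face 170 deg, RD 26.0/26.0 nm, pore 82.1 nm
pore 1: en-face 0 deg, RD 26.2/26.1 nm, pore 84.2 nm
pore 2: en-face 30 deg, RD 26.3/26.1 nm, pore 83.1 nm
pore 3: en-face 140 deg, RD 25.6/25.8 nm, pore 82.3 nm
pore 4: en-face 160 deg, RD 26.1/25.9 nm, pore 82.2 nm
pore 5: en-face 10 deg, RD 25.9/25.9 nm, pore 84.0 nm
median kappa: 0.0768 /nm
```

Each pore was rendered at a random orientation (tilt ≤ 40°), measured
blind by the full clip → align → en-face → measure chain, and both rim
sides recover the true 26 nm within ~0.4 nm; the median curvature
0.0768 nm⁻¹ sits 0.2% from the ground truth 2/26.

The same stages are available from the shell:

```sh
nemorph simulate telophase --seed 4 --out scene/
nemorph vesicles --labels scene/labels.tif --voxel-size 4.5,4.5,4.5 --out vesicles.csv
nemorph gaps --labels scene/labels.tif --vesicles-csv vesicles.csv --out-dir results/
nemorph pores --volume tomo.mrc --centers centers.csv --out pores.csv
nemorph stats --measurements pores.csv --group-col condition --value-col kappa_i_invnm
```

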