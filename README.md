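# pollenholo

Lens-less digital in-line holographic microscopy (DIHM) analysis of
allergenic pollen: scalar-diffraction wave propagation, iterative
twin-image-suppressed reconstruction, automated refocusing, synthetic
hologram generation, and the agreement statistics of a two-expert,
two-modality visual classification study.

## The problem

In lens-less DIHM a sample sits a few millimetres above a bare image
sensor and is illuminated by a quasi-plane coherent wave (here: a 658 nm
laser diode, a 3840×2160 sensor with 2.0 μm pixels, object-to-sensor
distance h ≈ 2.5 mm).  The sensor records the in-line hologram
H(x, y) — the interference between the unscattered wave and the light
scattered by the object.  Backpropagating the field √H to the object
plane focuses the "real" image of the object's transmission function
T̃(x, y)·exp(i φ̃(x, y)), but superimposes the defocused conjugate
("twin") image, which degrades contrast.

The package implements the classical remedy, Gerchberg–Saxton (GS) phase
retrieval: starting from Ũ = √H at the sensor, the field is propagated
back and forth between the two planes with the angular spectrum method,
enforcing in the object plane that the object cannot amplify light
(|T̃| ≤ 1; offending pixels are clipped to 1 with their phase reset to 0)
and in the sensor plane that |Ũ| = √H.  After 200 iterations the
object-plane amplitude is a brightfield-like, twin-image-suppressed image
suitable for visual classification of pollen by species.

Around the reconstruction core the package provides:

* **`pollenholo.optics`** — exact (square-root kernel) angular-spectrum
  propagation with evanescent-wave cut-off and background-fill padding;
* **`pollenholo.reconstruction`** — normalisation, single
  backpropagation, the GS loop, Tamura-of-gradient autofocus, and a
  twin-suppression metric;
* **`pollenholo.synthetic`** — six-species stylised pollen phantoms
  (timothy grass, common ragweed, silver birch, common alder, olive,
  hazel), a forward hologram simulator with a shot/read-noise 12-bit
  sensor model, and synthetic two-evaluator reading-session records;
* **`pollenholo.stats`** — accuracy, confusion matrices, per-class F1 and
  Cohen's κ = (p_o − p_e)/(1 − p_e) for inter-observer and
  inter-modality agreement;
* a `pollenholo` CLI with `simulate`, `reconstruct`, `focus` and `stats`
  subcommands.

## Worked example

```python
import numpy as np
from pollenholo import (FieldGeometry, GSConfig, autofocus, gs_reconstruct,
                        normalize_hologram, render_phantom, simulate_hologram,
                        single_backpropagation, twin_suppression_ratio)

geom = FieldGeometry(n_x=512, n_y=512, pitch=2.0, wavelength=0.658)
scene = render_phantom(None, geom, n_grains=4, rng_seed=3)
holo = normalize_hologram(simulate_hologram(scene, h=2546.0))

scan = autofocus(holo, 2300.0, 2800.0, 10.0)
bp = single_backpropagation(holo, scan.best_h)
gs = gs_reconstruct(holo, scan.best_h, GSConfig(n_iterations=200))

truth = np.abs(scene.transmission.values)
print(f"recovered h   : {scan.best_h:.1f} um")
print(f"rmse backprop : {np.sqrt(np.mean((bp.amplitude - truth)**2)):.4f}")
print(f"rmse GS       : {np.sqrt(np.mean((gs.amplitude - truth)**2)):.4f}")
print(f"twin ratio    : {twin_suppression_ratio(bp, gs, scene.truth_mask):.2f}")
```

prints

```
recovered h   : 2551.8 um
rmse backprop : 0.0151
rmse GS       : 0.0021
twin ratio    : 27.58
```

the scene simulated at 2546 μm is refocused within one 10 μm grid step;
the 200-iteration GS reconstruction cuts the truth error of a single
backpropagation about sevenfold, and its background is far less noisy
(the twin ratio is the backpropagation-to-GS background
standard-deviation ratio; values above 1 mean the twin image was
suppressed).

On the statistics side, the built-in reference reading session (two
veterinary experts × two modalities × 48 test images, seven
misclassifications concentrated among the triangular/pentagonal taxa)
summarises as:

```python
from pollenholo import reference_study_records, summarize_study
print(summarize_study(reference_study_records()).to_string(index=False))
```

```
              metric     modality         evaluator  value
    accuracy_percent         DIHM          expert_1  97.90
    accuracy_percent         DIHM          expert_2  93.80
    accuracy_percent         DIHM            pooled  95.80
    accuracy_percent      optical          expert_1  95.80
    accuracy_percent      optical          expert_2  97.90
    accuracy_percent      optical            pooled  96.90
    accuracy_percent       pooled          expert_1  96.90
    accuracy_percent       pooled          expert_2  95.80
    accuracy_percent       pooled            pooled  96.40
kappa_inter_observer         DIHM expert_1|expert_2   0.90
kappa_inter_observer      optical expert_1|expert_2   0.93
kappa_inter_observer       pooled expert_1|expert_2   0.91
kappa_inter_modality DIHM|optical          expert_1   0.93
kappa_inter_modality DIHM|optical          expert_2   0.90
kappa_inter_modality DIHM|optical            pooled   0.91
```

i.e. pooled accuracies of 95.8% (DIHM) and 96.9% (optical microscopy)
with near-perfect chance-corrected agreement between the two readers.

## Command line

```bash
pollenholo simulate --seed 3 --n-grains 4 --size 512 --out run/sim
pollenholo reconstruct run/sim/hologram.tif --autofocus --out run/rec
pollenholo stats records.csv --out run/stats
```

Every run echoes its configuration to `config_echo.yaml`; identical
config + seed reproduces outputs byte for byte.

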