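# spectromesh

Geometric feature engineering for 1D biomedical sound classification:
a recording's spectrogram is treated as a **surface embedded in 3-space**,
triangulated, flattened injectively into the plane, and described by the
**geometric distortions** the flattening induces. The resulting 16-dimensional
shape signature feeds ordinary classifiers, alone or combined with a classical
MFCC baseline. Typical uses are lung-sound pathology classification and
speech accent detection — any setting where the time–frequency structure of a
signal carries class information in its *shape*.

## The method

1. **Surface.** For a signal $I$, the magnitude spectrogram defines the graph
   surface $S(I) = \{(x, y, z(x,y))\}$, with $x$ time, $y$ frequency and $z$
   the normalised log-magnitude, sampled on a uniform $N \times N$ grid.
2. **Mesh.** The grid is triangulated in the $(x,y)$ plane (Delaunay; grid
   ties broken deterministically) and lifted by the vertex heights, giving a
   disk-topology triangle mesh $(\mathcal{V}, \Im)$ with $N^2$ vertices and
   $2(N-1)^2$ triangles.
3. **Flattening.** A piecewise-affine map $f^\* = \arg\min_f E(f)$ subject to
   $\det df_t > 0$ for every triangle $t$ is computed: bijective Tutte
   (convex-combination) initialisation onto the unit disk, then projected-
   Newton descent of the symmetric Dirichlet energy with a line search capped
   strictly below the first triangle collapse, so no iterate ever inverts a
   triangle.
4. **Distortions.** On each triangle the Jacobian's signed singular values
   $\sigma_1 \ge |\sigma_2|$ evaluate eight closed-form energies — ARAP,
   symmetric Dirichlet, quasi-isometric and quasi-conformal dilatation, MIPS,
   unsigned area distortion, Dirichlet energy and conformal factor. The
   global distortion over a triangle subset $\Im_0$ is the area-weighted mean
   $D_{\Im_0}(f, E) = \sum_{t} E(\sigma_1, \sigma_2)\,\mathrm{area}(t) \big/
   \sum_{t} \mathrm{area}(t)$.
5. **Signature.** Triangles are split at the median centroid frequency into a
   low and a high band; 8 energies × 2 bands give the 16-feature signature
   $E_i(f) = D_{\Im_i}(f, E)$, $i = 1, 2$.
6. **Classification.** A 12-coefficient MFCC baseline (6 statistics each,
   72 features) can be joined with the signature (88 features) and reduced to
   the top 45 by random-forest importance ranked on the training portion.
   Evaluation uses an 80/20 split at the patient/speaker-group level,
   five-fold grouped cross-validation for hyper-parameters, class weights
   inverse to training frequencies, and reports accuracy, recall,
   Jaccard $= (TP+TN)/(2(P+N)-(TP+TN))$ and AUROC.

## Worked example

Distortion signatures separate a clean narrowband tone from a broadband,
amplitude-modulated recording, while a flat (constant-height) surface attains
the analytic minima exactly:

```python
from spectromesh import (generate_signals, signature_for_signal,
                         extract_signature, generate_height_field_mesh)
from spectromesh.synthetic import geometry_contrast_spec

spec = geometry_contrast_spec(n_per_class=1, groups_per_class=1, seed=0)
signals, labels, groups = generate_signals(spec)
for sig, label in zip(signals, labels):
    s = signature_for_signal(sig, kind="stft", grid_n=32)
    print(f"{label:10s} E_SD_1={s['E_SD_1']:.3f}  E_SD_2={s['E_SD_2']:.3f}  "
          f"E_QC_2={s['E_QC_2']:.3f}  E_AD_1={s['E_AD_1']:.3f}")

mesh = generate_height_field_mesh("flat", 32)
s = extract_signature(mesh)
print(f"{'flat mesh':10s} E_SD_1={s['E_SD_1']:.3f}  E_SD_2={s['E_SD_2']:.3f}  "
      f"E_QC_2={s['E_QC_2']:.3f}  E_AD_1={s['E_AD_1']:.3f}")
```

prints

```
tonal      E_SD_1=1.024  E_SD_2=1.021  E_QC_2=1.132  E_AD_1=1.025
broadband  E_SD_1=2.169  E_SD_2=2.169  E_QC_2=3.720  E_AD_1=1.336
flat mesh  E_SD_1=1.000  E_SD_2=1.000  E_QC_2=1.000  E_AD_1=1.000
```

The tonal surface is nearly developable — its flattening is almost isometric,
so every energy sits near its lower bound (symmetric Dirichlet 1, conformal
dilatation 1, area distortion 1). The broadband surface is rough: flattening
it stretches lengths (E_SD ≈ 2.2) and angles (E_QC ≈ 3.7) substantially,
and that gap is what the classifier uses.

A command-line interface mirrors the library:

```bash
spectromesh synth --spec spec.json --out data/        # synthetic WAVs + labels.csv
spectromesh surface data/tonal_000.wav --grid-n 64 --out surf   # surface + OFF mesh
spectromesh features data/ --labels data/labels.csv --out features.csv
spectromesh evaluate features.csv --model rf --seed 0
```

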