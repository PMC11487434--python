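# vertrot

Automated measurement of the **vertebral axial rotation angle** from 3D
vertebral point clouds.

Axial rotation of individual vertebrae is a key severity parameter in
idiopathic scoliosis. Measuring it on 2D radiographs or CT slices is
error-prone because projections hide the true transverse plane of a rotated
vertebra. `vertrot` implements a fully automated 3D pipeline for surgeons
and researchers working with reconstructed vertebral surface models:

1. **Sampling** — entropy-augmented farthest-point sampling downsamples a
   raw surface cloud to a fixed size (default 3072 points). The greedy
   max–min score of classic FPS is weighted by the Shannon entropy of each
   candidate's local distance distribution,
   `score(c) = d_min(c, S) · (1 + λ·Ĥ(c))`, which biases selection toward
   sparse or geometrically heterogeneous regions (vertebral point clouds
   are much denser on the arch than on the body).
2. **Segmentation** — a relation-attention transformer network predicts
   which points belong to the vertebral endplates and which to the
   pedicles. Its core block computes `F_SA = softmax(QKᵀ/d_a)·V` inside
   k-NN patches, takes the deviation `F_RA = F_in − F_SA`, and applies a
   residual Linear–BatchNorm–ReLU update `F_out = LBR(F_RA) + F_in`,
   embedded in a U-Net-style encoder–decoder (4 FPS downsampling stages
   with local max-pooling, 4 inverse-distance interpolation upsampling
   stages with skip connections). The network is pure NumPy with an
   in-package reverse-mode autodiff; training uses Adam (lr 0.003, decay
   0.5, batch 4) with the cross-entropy loss and mIoU
   `= (1/K)·Σₖ TPₖ/(TPₖ+FPₖ+FNₖ)·100%` for evaluation.
3. **Geometry** — k-means (k=2) splits the predicted endplate cloud into
   upper/lower caps and the pedicle cloud into left/right; the vertebral
   centroid is the midpoint of the endplate centers, the transverse plane's
   normal is the endplate axis, the local y-axis runs from the pedicle
   midpoint to the centroid, and the rotation angle is the angle between
   the projections of the local and global y-axes onto the transverse
   plane.
4. **Validation statistics** — Bland–Altman limits of agreement and the
   two-way absolute-agreement intraclass correlation coefficient
   (single-measures `ICC(A,1) = (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n)`),
   applied to subjects × raters measurement tables. A published
   10-vertebra benchmark table (three human observers plus the automated
   pipeline) ships with the package.

A synthetic **phantom** module generates labelled vertebra clouds — an
elliptical-cylinder body, two parallel endplate caps, two posterior pedicle
blobs, configurable density skew, noise, and a known applied axial rotation
— so the whole pipeline is testable end to end without patient data.

## Worked example

```python
from vertrot import (PhantomConfig, generate_vertebra, measure_vertebra,
                     load_reference_measurements)
from vertrot.agreement import agreement_report

# a noisy phantom with a known 12-degree axial rotation
ep, pd, truth = generate_vertebra(PhantomConfig(theta_deg=12.0, noise_sd=0.5, seed=42))
rec = measure_vertebra(ep.cloud, ep.labels, pd.labels, seed=0)
print(f"true axial rotation : {truth.theta_true:.3f} deg")
print(f"measured (unsigned) : {rec.angle_deg:.3f} deg")

# agreement between the automated pipeline and a human observer
table = load_reference_measurements()
rep = agreement_report(table.column("Automatic"), table.column("Observe1"))
print(f"ICC(A,1) Automatic vs Observe1 : {rep.icc_single:.3f}")
print(f"mean diff {rep.mean_diff:+.2f} deg, LoA [{rep.loa_low:.2f}, {rep.loa_high:.2f}]")
```

prints

```
true axial rotation : 12.000 deg
measured (unsigned) : 12.090 deg
ICC(A,1) Automatic vs Observe1 : 0.987
mean diff -0.47 deg, LoA [-1.58, 0.63]
```

The 0.09° error comes from the 0.5 mm surface noise; on a noiseless
phantom the measured angle equals the applied rotation to machine
precision. The ICC of 0.987 with a −0.47° mean difference says the
automated and manual measurements agree almost perfectly, with a small
systematic offset well inside the limits of agreement.

The same operations are available from the shell:

```sh
vertrot phantom --n 50 --theta-min 0 --theta-max 25 --noise 0.5 --seed 7 --out clouds/
vertrot measure --input clouds/phantom_0000.ply \
    --endplate-labels clouds/phantom_0000.endplate.labels \
    --pedicle-labels clouds/phantom_0000.pedicle.labels --json angle.json
vertrot train --task endplate --data clouds/ --points 512 --epochs 30 --out ep.ckpt.npz
vertrot segment --model ep.ckpt.npz --input clouds/phantom_0001.ply --out pred.labels
vertrot agree --form single --out agreement.json
```

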