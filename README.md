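# spinefs

Synthesis of sagittal T2-weighted **fat-saturated** (fs) spine MRI from
T1-weighted and non-fs T2-weighted inputs with a conditional GAN, plus the
statistics to ask whether the synthetic series actually helps a reader:
Cohen's kappa with confidence intervals, grading accuracy, Wilcoxon
signed-rank and McNemar tests over a six-pathology spine grading schema.

T2-w fs images make fluid conspicuous — bone-marrow edema, spondylodiscitis,
inflammatory (Modic type 1) endplate changes, acute fracture edema, cord
lesions, paravertebral collections — but are often missing from clinical
protocols. Because fat is bright on T1-w and non-fs T2-w yet suppressed on
T2-w fs, while fluid stays bright on both T2-w contrasts, the missing series
is largely a function of the two acquired ones. `spinefs` learns that
mapping slice-wise with a U-Net generator against a patch discriminator,
the generator optimizing the joint loss

```
L_G = (1 − SSIM(real, synthetic)) + λ · BCE(1, D(synthetic)),      λ = 50
L_D = BCE(1, D(real)) + BCE(0, D(synthetic))
```

trained in turns with Adam (lr 2·10⁻⁴) for 25 epochs on sagittal slices
normalized to [−1, 1]. A spine-phantom simulator (aligned multi-contrast
volumes over fat/water/fluid tissue compartments, with graded, ground-truth-
annotated lesions) makes every stage trainable and testable at desk scale
without patient data, and a simulated two-reader study feeds the agreement
statistics end to end. The networks and the differentiable SSIM loss run on
a small numpy autodiff engine included in the package, so the only heavy
dependencies are the scientific Python stack.

## Worked example

```python
import numpy as np
import spinefs as sf
from spinefs.config import PhantomConfig, make_phantom_dataset, build_training_dataset
from spinefs.gan_core import TrainConfig, train, make_generator_from_checkpoint
from spinefs.volume_synthesis import synthesize_volume

# 20 phantoms x 10 sagittal slices = 200 aligned (T1, T2) -> T2fs pairs
cfg = PhantomConfig()
train_sets = make_phantom_dataset(seed=7, cfg=cfg, n=20)
held_out = make_phantom_dataset(seed=7, cfg=cfg, n=3, first_id=20)

checkpoint, history = train(build_training_dataset(train_sets),
                            TrainConfig(epochs=25, seed=1))
print(f"epoch 1:  1-SSIM = {history[0]['g_ssim_term']:.3f}")
print(f"epoch 25: 1-SSIM = {history[-1]['g_ssim_term']:.3f}")

gen = make_generator_from_checkpoint(checkpoint)
d = held_out[0]
res = synthesize_volume(d["volumes"]["T1"], d["volumes"]["T2"], gen,
                        reference=d["volumes"]["T2FS"])
print(f"held-out volume-mean SSIM = {res.mean_ssim:.3f}")
```

Output from this exact run:

```
epoch 1:  1-SSIM = 0.946
epoch 25: 1-SSIM = 0.128
held-out volume-mean SSIM = 0.893
```

The reconstruction term falls by an order of magnitude over training, and
the synthetic T2-w fs volume matches the held-out ground truth at SSIM ≈ 0.9
— with fat-dominant voxels darker on the synthetic fs image than on the
input T2-w, i.e. the network learned fat suppression rather than copying
its input.

On the statistics side, feeding per-pathology kappa pairs for the two
reading protocols (with / without the synthetic series) into the aggregator:

```python
from spinefs.agreement_stats import aggregate_kappa_pairs
pairs = {"bone_marrow_abnormality": (0.73, 0.74),
         "spondylodiscitis_expansion": (0.35, 0.43),
         "modic_type1": (0.39, 0.68),
         "vertebral_fracture": (0.77, 0.77),
         "cord_lesion": (0.47, 0.52),
         "paravertebral_abnormality": (0.67, 0.73)}
agg = aggregate_kappa_pairs(pairs)
print(agg["mean_kappa"])     # {'two_sequence': 0.5633..., 'synthetic_protocol': 0.645}
print(round(agg["wilcoxon"].p, 3))   # 0.043
```

Mean kappa 0.56 vs 0.65 and a signed-rank p of 0.043: agreement with ground
truth is systematically higher when the fat-saturated series is on the
screen.

## Command line

```
spinefs simulate   --seed 1 --n-datasets 5 --out-dir phantoms/
spinefs preprocess --t1 t1.nii.gz --t2 t2.nii.gz --out-dir pre/
spinefs train      --data-dir phantoms/ --out gan.npz
spinefs synthesize --t1 pre/T1_preprocessed.nii.gz --t2 pre/T2_preprocessed.nii.gz \
                   --checkpoint gan.npz --out synthetic_t2fs.nii.gz
spinefs evaluate   --gradings gradings.csv --out report.json
spinefs run-all    --seed 1 --out-dir run/
```

`run-all` chains the whole pipeline (simulate → train → synthesize →
simulated reader study → agreement report) with cached, resumable stages;
rerunning with the same seed reproduces the report byte-identically.

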