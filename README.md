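# bronchoscore

Bronchiectasis detection and severity scoring on 2D axial lung CT slices.

Bronchiectasis — permanent dilation of the bronchi — is graded on CT by
comparing each dilated airway's lumen diameter d_lumen to the diameter
d_vessel of the adjacent pulmonary vessel: r = d_lumen/d_vessel in (1, 2]
is mild (grade 1), (2, 3] moderate (grade 2), and r > 3 severe (grade 3).
Radiologists summarize a slice with two composites over the per-lobe
grades g_l (each lobe scored by its most dilated finding):

* **modified Reiff** = Σ_l g_l over six regions (five lobes + lingula),
  maximum 18 (12 on the simplified four-lobe scheme);
* **BRICS** = max_l g_l + emphysema band (0–2), maximum 5.

`bronchoscore` implements the full slice-to-score chain, each stage usable
on its own:

| stage | module | method |
|---|---|---|
| contrast enhancement | `bronchoscore.enhance` | ACER: adaptive contrast enhancement (local-gain unsharp masking) composed with single-scale Retinex, r(x,y) = log(I+ε) − log(I∗G+ε) |
| lobe segmentation | `bronchoscore.lobeseg` | RDU-Net: residual, dilated U-Net (rate cycle 1-2-4-2-1, pooling replaced by strided convolution) |
| lesion detection | `bronchoscore.detect` | HDC Mask R-CNN: two-stage detector whose deepest backbone stage stacks dilated 3×3 convolutions on a hybrid schedule (1-2-5-2-1), plus an exact receptive-field oracle for the gridding effect |
| scoring | `bronchoscore.score` | ratio grading, modified Reiff, BRICS |
| evaluation | `bronchoscore.metrics` | box IOU, per-lobe confusion counts, sensitivity/specificity, class accuracy |
| synthetic data | `bronchoscore.phantom` | seeded lung phantoms with exact per-lesion diameter-ratio ground truth |

The neural models run on a small self-contained NumPy autodiff engine
(`bronchoscore.nn`) in float64 — deterministic, CPU-only, sized for
desk-scale experiments. Clinical-scale performance is out of scope; see
`docs/methods.md` for models, parameters, and limitations.

## Worked example

Generate a phantom with a single mild (r = 1.5) lesion in the left lower
lobe and run the full pipeline on it, using the generator's ground truth in
place of trained models (oracle mode):

```python
from bronchoscore.phantom import PhantomSpec, generate_phantom
from bronchoscore.pipeline import PipelineConfig, oracle_detections, run_pipeline

sample = generate_phantom(
    PhantomSpec(n_lesions=1, severity_ratios=[1.5], lesion_lobes=[2], seed=1)
)
config = PipelineConfig(
    oracle_lobe_mask=sample.lobe_mask,
    oracle_annotations=oracle_detections(sample.annotations),
)
score, report = run_pipeline(sample.image, config)
print(report["score"])
```

prints

```
{'per_lobe': {'left_upper': 0, 'left_lower': 1, 'right_upper': 0,
  'right_lower': 0}, 'reiff': 1, 'brics': 1, 'emphysema_band': 0,
 'scheme': 'lobes4'}
```

one grade-1 finding in the left lower lobe and none elsewhere, hence
Reiff = 0+1+0+0 = 1 and BRICS = max grade 1 + emphysema band 0 = 1.

To train the models instead of using oracle inputs:

```sh
bronchoscore phantom --n 20 --size 64 --lesions 0 --out ds_seg
bronchoscore lobeseg train --data ds_seg/manifest.json --out seg.npz --epochs 30
bronchoscore phantom --n 2 --size 96 --lesions 1 --out ds_det
bronchoscore detect train --data ds_det/manifest.json --out det.npz --steps 400
bronchoscore run ds_det/images/img_0000.png --lobeseg-model seg.npz \
    --detect-model det.npz --out case0/
```

Every subcommand (`phantom`, `enhance`, `lobeseg`, `detect`, `score`,
`run`, `run-batch`) is a thin wrapper over the library; `--help` lists the
options.

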