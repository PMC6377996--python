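# blurbench

A test bench for motion-blur orientation discrimination in early-vision
models. It measures how *linearly separable* horizontal vs vertical motion
blur is in two representations of natural-image windows:

* a **thalamic (LGN) representation** — 91 ON-centre and 91 OFF-centre
  difference-of-Gaussians units on a hexagonal mosaic, and
* a **cortical Layer-4 (L4) representation** — 182 recurrently coupled
  RBF-like units whose prototypes are adapted to natural input statistics.

The motivating application is a vision test for neurodegenerative disease:
at small blur extents, telling the motion axis apart is hard, and a model
of healthy cortex provides the reference performance curve that human
scores can later be compared against. The bench produces that curve
(classification accuracy vs blur size), a threshold report at a reference
blur size, and galleries of misclassified windows.

## The model

Each 25×25 window with intensities `PI ∈ [0,1]` is filtered by a
centre-surround profile

```
RF(D) = exp(-D²/2σ_c²)/(2πσ_c²) − exp(-D²/2σ_s²)/(2πσ_s²),
σ_c = 0.833 px,  σ_s = 3σ_c
```

at 91 hexagonally arranged centres; each centre emits the rectified pair
`ON = [0.1 + Σ RF·PI]₊`, `OFF = [0.1 − Σ RF·PI]₊`, giving a
182-dimensional thalamic vector `x`. The L4 units obey

```
τ dF_i/dt = −F_i + [ (w_i·x − θ‖x‖)/(1−θ) + λ Σ_{k≠i} u_ik F_k ]₊ ,  τ = 4 ms
```

where `w_i` are unit-norm prototype patterns adapted to a natural corpus by
competitive clustering, `u_ik` are output correlations, `θ` is the cosine
similarity threshold of the RBF units and `λ` scales lateral feedback. The
benchmark draws 4000 windows from five 500×335 isotropic 1/f surrogate
images, blurs disjoint halves with horizontal (label 0) or vertical
(label 1) box kernels, and scores a linear SVM over 10 stratified 50/50
holdout splits per blur size and representation.

Because the LGN code is (rectified-)linear and isotropic, the two blur
classes have identical feature means and the thalamic curve stays at
chance; the L4 stage turns class-specific correlation structure into mean
differences, which is exactly the "function linearization" the cortical
layer is hypothesised to perform.

## Worked example

```python
from blurbench import generate_surrogate_image, run_benchmark, threshold_report
from blurbench.evaluation import derive_seed

images = [generate_surrogate_image(500, 335, 1.0, seed=derive_seed(0, "image", i))
          for i in range(5)]
result = run_benchmark(images, n_windows=1000, blur_sizes=[1, 4, 8],
                       n_repetitions=5, master_seed=0)
print(result.summary().to_string(index=False))
```

prints

```
representation  blur_size  mean_accuracy  sd_accuracy  n_repetitions
            l4          1         0.5020     0.006000              5
            l4          4         0.5884     0.019463              5
            l4          8         0.6844     0.023126              5
      thalamic          1         0.5188     0.026405              5
      thalamic          4         0.5056     0.017228              5
      thalamic          8         0.5100     0.011832              5
```

Read: the thalamic representation is at chance (~0.50) at every blur size,
while the L4 representation becomes increasingly separable as the blur
grows (size 1 is the identity, so both sit at chance there). At the full
4000-window scale the L4 accuracy at blur size 8 reaches ≈ 0.75.
`threshold_report(result, reference_size=8, threshold=0.80)` adds the
pass/fail flag against the 80% reference threshold.

The same run is available from the shell:

```bash
blurbench --config config.yaml --out runs/demo run
```

which writes tidy and summary CSVs, the accuracy-vs-blur-size curve
(`curve.png`), a threshold report and misclassification galleries under
the run directory. See `blurbench --help` for the stage-by-stage
subcommands (`generate-images`, `build-dataset`, `train-l4`, `represent`,
`evaluate`, `curve`, `report`).

## Layout

```
src/blurbench/
  synthetic_images.py   1/f surrogate generator, PNG/PGM I/O, window sampling
  motion_blur.py        box-kernel motion blur, two-class dataset assembly
  lgn_model.py          DoG profile, hexagonal mosaic, ON/OFF responses
  l4_model.py           recurrent RBF units, training, steady states
  evaluation.py         SVM benchmark, threshold report, galleries
  cli.py                YAML-configured command-line pipeline
docs/methods.md         modelling assumptions, parameter choices, limitations
```
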