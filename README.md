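# eigenfluor

Spectral-PCA contrast enhancement for multichannel wide-field
fluorescence images of composite hard/soft tissue.

## The problem

Thick sections of mineralized composite tissue — a tooth root anchored in
alveolar bone by the periodontal ligament, wrapped in gingiva — cannot be
decalcified and thin-sectioned without destroying the structures a
histopathologist needs to see. Multi-dye wide-field fluorescence imaging
of non-decalcified 2-mm sections keeps the anatomy intact, but the raw
emission channels (blue, green, red, NIR) show weak inter-tissue
contrast: the dyes' emission spectra overlap (channel crosstalk), all
tissues share a low autofluorescence background, and illumination varies
across the field. `eigenfluor` implements the computational half of that
imaging workflow: it turns a stack of poorly contrasted emission channels
into false-color composites in which the tissue types separate cleanly.

It is a library plus a thin CLI, aimed at microscopists and image
analysts who have per-channel TIFF/PNG acquisitions and want
reproducible, parameter-traceable contrast enhancement.

## The method

Let the acquisition be *k* co-registered channels of *h × w* pixels
(canonically *k* = 4 at 1392 × 1040, so each flattened channel is a
vector in ℝ^1,447,680). Two preprocessing branches run independently,
each followed by a 4 × 4 median rank filter:

* **Std** — each image row is standardized across its x-axis:
  `x ↦ (x − μ_row) / σ_row` (population σ). This removes per-line
  illumination/exposure variation and emphasizes within-row tissue
  contrast.
* **CLAHE** — contrast-limited adaptive histogram equalization
  (OpenCV convention), clip limit 12.0, 10 × 10 tile grid, 256 bins,
  with bilinear interpolation of tile mappings.

Each branch then feeds a **channel-as-observation PCA**: the *k*
flattened channels are the observations, pixels are the features. The
centered *k × n* matrix `X` is decomposed exactly through its *k × k*
Gram matrix; the top three pixel-space axes `v_i = Xᵀu_i/√λ_i` reshape
back into three **eigen-images**. Min–max normalized onto [0, 255], PC1,
PC2 and PC3 become the red, green and blue planes of the false-color
composite. Because centering *k* = 4 observations leaves rank ≤ 3, the
three explained-variance ratios always sum to 1.

A synthetic **tissue phantom** generator (5 labeled regions, per-tissue
spectral signatures, row-stochastic crosstalk, autofluorescence,
illumination tilt, Poisson + Gaussian noise) and a **Fisher
separability** score trace(S_b)/trace(S_w) make the enhancement claim
testable without real data.

## Worked example

```sh
python examples/score_enhancement.py
```

```
sPCA composite (std branch): separability = 15.16
raw blue  channel:         separability = 10.54
raw green channel:         separability = 9.63
raw red   channel:         separability = 9.68
raw nir   channel:         separability = 10.18
```

The default phantom's composite separates the five tissue classes about
1.5× better (Fisher trace ratio 15.2 vs 10.5) than the best single raw
emission channel — the quantitative counterpart of "the merged
eigen-image composite shows tissue boundaries no single channel shows".
`examples/enhance_phantom.py` prints the per-branch explained-variance
ratios (e.g. Std branch: PC1 = 0.801, PC2 = 0.173, PC3 = 0.026, summing
to 1) and channel loadings, and writes both composites as PNG.

The same run from the shell:

```sh
eigenfluor phantom --height 256 --width 384 --seed 42 -o acq/
eigenfluor run acq/blue.tif acq/green.tif acq/red.tif acq/nir.tif -o out/
eigenfluor score out/std_composite.tif acq/labels.tif
```

`out/report.json` records parameters, input checksums, loadings and
explained-variance ratios for provenance.

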