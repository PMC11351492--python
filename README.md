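# fibermorph

Quantitative morphometry of collagen and elastic-fiber bundles in
stained skin histology sections — a "digital dermis" toolkit.

Photoaging and intrinsic skin aging change the dermal fiber network:
collagen bundles thin and fragment, and the distribution of bundle
cross-section areas shifts from a few very large bundles toward many
small ones. This package implements a complete pipeline for measuring
that shift on light-microscopy images of stained sections:

1. **Segmentation** — HSV color thresholding tuned per stain
   (hematoxylin–eosin, Mallory's trichrome, silver impregnation,
   Weigert's/orcein elastic stains) separates fiber bundles from
   nuclei, artifacts, and background.
2. **Morphometry** — fiber area fraction, per-bundle areas, and local
   bundle thickness by the inscribed-disk (Hildebrand–Rüegsegger)
   definition, with per-bundle maximum widths.
3. **Tail statistics** — the bundle-area distribution's upper tail is
   fit with a two-parameter generalized Pareto distribution (GPD) by
   maximum likelihood, with 95% observed-information confidence
   intervals. The fitted shape `k` acts as a regime discriminant:
   `k > 0.66` indicates a *large-bundle regime* (heavy tail, intact
   thick bundles), `k ≤ 0.66` a *small-bundle regime* (fragmented,
   lighter tail).
4. **Synthetic data** — a seeded micrograph generator renders bundle
   ribbons whose areas are exact GPD draws, with per-pixel ground
   truth, so every stage can be validated without proprietary imagery.

## Quick start

Fit a bundle-area tail and call the regime:

```python
import fibermorph as fm

x = fm.sample_gpd(0.7199, 2.4, 5000, seed=20)   # synthetic areas
f = fm.fit_gpd(x)
print(f.shape_k, f.k_ci95)
# 0.6955178062429285 (0.6478402662405365, 0.7431953462453205)
print(fm.classify_by_k(f).call)
# large_bundle_regime
```

Segment a micrograph and measure bundles:

```python
spec = fm.SyntheticSpec(shape_k=0.7, scale_sigma=50.0, n_bundles=50,
                        image_size=(512, 512), stain_type="mallory",
                        n_nuclei=30, noise_sd=0.0, seed=11)
img, truth = fm.render_micrograph(spec)

seg = fm.segment_stain(img)
print(fm.area_fraction(seg.fiber_mask))          # 3.94 (%)
ct = fm.label_components(seg.fiber_mask, min_area=10)
T = fm.local_thickness(seg.fiber_mask)
ct, markers = fm.max_bundle_width(T, ct)
print(ct.table.head(3))
#  component_id  area_px  centroid_row  centroid_col  max_thickness_px
#             1     4324    412.897317    219.654718         34.176015
#             2     1458    129.041152    184.463649         20.000000
#             3     1116    320.276882    146.992832         18.000000
```

sklearn-style estimators (`GeneralizedParetoMLE`, `StainSegmenter`)
back these functions and support `get_params`/`set_params` and fitted
trailing-underscore attributes.

## Command line

```bash
fibermorph synth spec.json out/          # render a synthetic micrograph + truth
fibermorph run manifest.csv --out run/   # batch pipeline over a study manifest
fibermorph fit areas.csv                 # GPD fit + regime call from a CSV of areas
```

The batch pipeline reads a manifest CSV (`path,stain,year,label[,sample_id]`),
segments each image, measures area fraction, bundle widths and area
histograms, fits the GPD tail per image, groups fits by year, and
reports the separating shape-threshold gap between groups. Outputs:
`report.json`, `area_fractions.csv`, `bundle_widths.csv`,
`gpd_fits.csv`, and diagnostic figures.

## Documentation

See `docs/methods.md` for the statistical model, the thickness-transform
convention, the synthetic generator's design and limits, and the
numerical choices in the MLE.
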