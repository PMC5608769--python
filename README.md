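# msilipid

A mass spectrometry imaging (MSI) lipidomics toolkit: from imzML per-pixel
spectra to deisotoped, accurate-mass-annotated, normalised feature images
with PCA and k-means segmentation of tissue regions — plus a synthetic
phantom generator with known ground truth so every pipeline stage is
testable without external data.

## Pipeline

1. **imzml_io** — read/write imzML 1.1.0 + ibd pairs (continuous and
   processed modes read; processed written, 64-bit m/z / 32-bit intensity).
2. **preprocess** — extract above-threshold ions, group them into a
   deterministic ppm-ladder of mass bins, define features by median m/z,
   filter by detection fraction, and build the features × pixels matrix.
3. **deisotope** — estimate carbon counts from m/z (0.055 C/Da), predict
   M+1/M+2 proportions (nC·0.0111, C(nC,2)·0.0111²) and remove isotope
   features whose mean-intensity ratio to the parent falls in the band.
4. **annotate** — generate a combinatorial lipid library (13 classes,
   configurable fatty-acid grid, electron-corrected adducts for each
   polarity), match features by signed ppm error, and search feature pairs
   for configured mass differences (oxidation, water loss, adduct
   spacings).
5. **normalise_scale** — median / TIC / standard-ion normalisation per
   pixel; centering + Pareto scaling per feature.
6. **multivariate** — SVD PCA with a fixed sign convention; seeded
   multi-restart Lloyd k-means; cluster-center spectra tables.
7. **imaging** — slice per-pixel values to 2-D maps (y down, x right, NaN
   background) and render PNGs, including 3-channel RGB ion overlays.
8. **phantom** — synthetic multi-region datasets with exact binomial
   isotope envelopes, lognormal noise, dropout, written as standard imzML.

## CLI

```sh
# make a synthetic dataset
msilipid phantom -o data/ --nx 50 --ny 50 --noise-cv 0.2 --seed 1

# full pipeline (every parameter also settable via --config pipeline.yaml)
msilipid process data/phantom.imzML -o results/ -k 3 --annotation-ppm 5

# per-stage subcommands operate on the CSV artifacts a full run writes
msilipid build-library --mode positive -o library.csv
msilipid deisotope results/feature_matrix.csv -o stage/
msilipid annotate results/deisotoped_matrix.csv -o ann.csv --mode positive
msilipid cluster results/deisotoped_matrix.csv -o stage/ -k 3
msilipid render results/normalised_matrix.csv --mz 760.585 -o ion.png
```

A full run writes: the feature/deisotoped/normalised matrices, isotope
report, lipid library, annotations, difference matches, PCA scores /
loadings / explained variance, cluster labels and center spectra (all
CSV), ion / score / cluster PNG images, a run log and the effective
configuration.

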