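# seedhsi

Single-seed viability assessment from hyperspectral imagery, plus
skeleton-based sprout (bud) length measurement.

The package implements the full desk-scale pipeline:

1. **Reflectance calibration** — `(raw − dark) / (white − dark)` against
   white-board and dark-current reference cubes.
2. **Seed masking** — single-band thresholding (Otsu by default) with
   small-component removal and consecutive instance labelling.
3. **Spectral preprocessing** — Savitzky–Golay smoothing and Standard
   Normal Variate on per-seed mean spectra; per-band z-scoring of block
   data with train-set statistics only.
4. **Key-wavelength selection** — successive projections algorithm (SPA)
   with an optional cross-validated subset-size search.
5. **Block classification** — each seed is tiled into non-overlapping
   5×5 full-foreground blocks; a multi-scale 3D CNN (parallel 3×3×3,
   3×3×5, 3×5×5 and 5×5×5 branches fused on the channel axis; 16/32/64
   filters per module) or a conventional single-kernel 3D CNN classifies
   blocks, and each seed receives the majority vote of its blocks
   (ties resolve to nonviable). The network (forward, backward, Adam) is
   implemented directly on NumPy, so training is deterministic under a
   fixed seed and needs no GPU.
6. **Bud length** — skeletonize a binary bud mask, prune side branches by
   taking the longest endpoint-to-endpoint geodesic, measure chamfer
   length (1 / √2 steps), and convert pixels to mm via a reference box.
7. **Evaluation metrics** — precision / recall / F1, all-points average
   precision, mAP, R² and RMSE.
8. **Synthetic data** — labelled hyperspectral seed scenes (with exact
   calibration round-trip) and bud masks of known centerline length, so
   every property above is testable without any external data.

## CLI

All stages are exposed through one `seedhsi` entry point:

```bash
seedhsi synth scene --spec scene.json --out-dir fixtures/   # synthetic scene
seedhsi calibrate --raw raw.npz --white white.npz --dark dark.npz --out cube.npz
seedhsi segment   --cube cube.npz --band-nm 801 --min-area 50 --out mask.png
seedhsi spectra   --cube cube.npz --mask mask.png --out spectra.csv
seedhsi preprocess --in spectra.csv --sg-window 11 --sg-order 2 --out prep.csv
seedhsi spa       --in prep.csv --k 18 --out bands.json
seedhsi blocks    --cube cube.npz --mask mask.png --bands bands.json --size 5 \
                  --labels labels.csv --out blocks.npz
seedhsi train     --blocks blocks.npz --arch multiscale --epochs 70 --seed 7 \
                  --out model.npz
seedhsi predict   --model model.npz --blocks test.npz --train-blocks blocks.npz \
                  --out predictions.csv
seedhsi metrics   --pred predictions.csv --truth labels.csv --out report.json
seedhsi synth bud --seed 1 --out bud.png --truth truth.json
seedhsi budlen    --mask bud.png --box-mm 250 --box-px 1164 --out lengths.csv
```

Cubes are read/written as ENVI (`.hdr` text header + `.dat`/`.raw` binary,
`bip`/`bil`/`bsq` interleave) or compressed `.npz`; masks as 16-bit
PNG/TIFF; spectra as CSV with a `seed_id,label,<λ…>` header.

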