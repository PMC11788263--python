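# ribsep

Bone suppression toolkit for pediatric chest radiographs. Decomposes a
radiograph `I` into a bone image `I_B` and a soft-tissue image `I_S` with
`I = I_B + I_S`, exactly.

The traditional (model-driven) pipeline:

1. **Edge handling** — binary bone-edge masks are encoded as
   distance-transform regression targets (`exp(-d/|sigma|)`, sigma = 5) for an
   edge-detection network, and decoded back (threshold 0.8 + skeletonization);
   skeletons are traced into ordered upper/lower edge polylines and paired
   per bone (`edge_targets`, `edge_lists`).
2. **Profile sampling** — each bone is straightened into a profile image by
   sampling along the local normal of the upper edge, from 10 samples outside
   the bone across 40 samples to the matched lower-edge point, with an
   invertible sampling map (`profile_geometry`).
3. **PCA blind source separation** — margin-anchored background filtering,
   2-means detection of corrupted profiles, rank-`r` PCA reconstruction at 95%
   cumulative variance, and along-bone smoothing (`pca_bss`).
4. **Reconstruction** — reverse sampling into image space, Poisson correction
   that pins every nonbone pixel to exactly zero, and a second PCA pass along
   the edges for residual edge signal (`reconstruction`).
5. **Networks** — desk-scale training scaffolding for the edge-regression
   network and the 4-channel (intensity, Sobel-x, Sobel-y, edge mask)
   bone-suppression network, with pretrain/fine-tune transfer, implemented in
   pure NumPy (`networks`).
6. **Metrics** — MBD, Weber contrast / RWC with automatic region derivation,
   RMAE-B, BSR, and masked PSNR/SSIM (`metrics`).
7. **Phantoms** — a synthetic scene generator with exact ground-truth
   decompositions (raised-cosine bones with known edges, smooth lung-field
   background, optional crossing corruptors and noise) so everything is
   testable without clinical data (`phantom`).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (metric identities,
oracle equivalences against brute-force references, conservation laws, the PCA
rank contract, phantom-recovery quality bars, and desk-scale learning checks).

## CLI

```bash
ribsep phantom --config cfg.yaml --seed 1 --out scene/       # synthetic scene
ribsep edges --mask anterior=a.png --mask posterior=p.png --out edges/
ribsep profiles --image scene/cxr.png --edges scene/edge_lists.json --out prof/
ribsep suppress --image scene/cxr.png --edges edges/edge_lists.json \
                --mode pca-m --out out/                      # traditional pipeline
ribsep train-edge --config cfg.yaml --out model/             # desk-scale training
ribsep train-suppressor --config cfg.yaml --pretrained model/model --out model2/
ribsep evaluate --truth scene/ --pred out/ --out report/
ribsep auto --image scene/cxr.png --model model/model --out out/  # fully automated
```

All tunables live in a YAML `RunConfig` (see `ribsep/config.py`); unknown keys
are rejected and every run emits a JSON provenance record (config hash, seed,
version). Images are exchanged as 16-bit PNG (8-bit for masks); edge lists as
JSON polylines. Clinical-scale defaults (512x512, guided-filter window 90,
opposite-point search radius 100, background smoothing 1000) are in the
config; `SuppressionConfig.for_phantom()` carries the rescaled values used for
the built-in 128-px phantoms.
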