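# polyprint

Minutia-by-minutia fingerprint matching with rotation/translation-invariant
polygon descriptors.

The pipeline has four stages:

1. **Preprocessing** (`polyprint.preprocessing`) — variance segmentation,
   mean/variance normalization, gradient-based ridge orientation, x-signature
   ridge frequency, oriented Gabor filtering and Zhang–Suen thinning of a gray
   fingerprint image into a unit-width ridge skeleton.
2. **Minutiae** (`polyprint.minutiae`) — Crossing-Numbers extraction of
   terminations/bifurcations from the skeleton, followed by three validation
   stages: a minimum same-type distance `delta`, a convex-hull region of
   interest eroded inward by `gamma` pixels, and replacement of tight minutiae
   clouds by their centroid.
3. **Polygon model** (`polyprint.polygon_model`) — each validated minutia is
   represented by all valid n-vertex polygons built from neighboring minutiae
   found by a growing radius search. A polygon is stored as a canonical vector
   of n edge lengths plus n central angles (largest edge first), which is
   invariant to rotation and translation of the whole print.
4. **Matching** (`polyprint.matching`) — two minutiae match when their closest
   descriptor pair (Euclidean distance) passes an element-wise relative-OR-
   absolute error test (`th_rel` %, `th_l` px for edges, `th_a` deg for
   angles); two fingerprints match when at least `tmc` minutiae pair up
   one-to-one.

`polyprint.evaluation` computes precision/recall/F1 and FMR/FNMR with an
equal-error-rate sweep over the `tmc` threshold, and `polyprint.synthetic`
generates seeded minutia point patterns, oriented ridge images and
genuine/impostor benchmarks so everything is testable without external
fingerprint databases.

## CLI

All stages are exposed as subcommands of a single `polyprint` executable
(exit codes: 0 match/success, 1 non-match, 2 usage error, 3 processing
error):

```sh
polyprint enhance print.png -o skeleton.png --block-size 16
polyprint extract skeleton.png -o template.txt --delta 10 --gamma 10
polyprint model template.txt -o model.json --n 5 --r-max 120
polyprint match modelA.json modelB.json --th-rel 11 --th-l 5 --th-a 10 --tmc 12
polyprint match --pairs pairs.tsv -o batch.json
polyprint evaluate --pairs results.tsv -o report.json --sweep
polyprint simulate --spec bench.yaml -o outdir/ --seed 1
polyprint pipeline print.png -o outdir/            # image -> model in one go
```

Shared parameters can be kept in a YAML config (`--config cfg.yaml`); the
defaults are the tuned configuration `n=5, th_rel=11, th_l=5, th_a=10,
tmc=12, delta=10, gamma=10`.

Templates are plain text (`x y type` per line with a `# width height`
header, type in {T, B, A}); models are JSON.

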