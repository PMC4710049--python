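# xyspot

Quantification and spatial statistics for **X/Y gametolog transcripts detected
in situ** by padlock probing and rolling-circle amplification (RCA).

Gametolog pairs such as *PCDH11X*/*PCDH11Y* and *NLGN4X*/*NLGN4Y* share 89–99%
sequence identity, so conventional hybridization cannot tell the X from the Y
transcript. Padlock probes ligated across a single discriminating nucleotide,
amplified by RCA, produce one bright sub-micrometer spot per detected
transcript molecule — and a quantification problem: which cell does each spot
belong to, do single cells express the X homolog, the Y homolog or both, and
are X- and Y-expressing cells spatially segregated across a tissue section
(e.g. the ventral vs dorsal spinal cord)? `xyspot` implements that analysis
as a tested, reusable pipeline for anyone working with dual-channel RCA spot
images or pre-called spot tables.

## What it computes

**Image quantification** (`xyspot.quant`) — nuclei segmented by global Otsu
thresholding; cell territories defined by a fixed Euclidean expansion of the
nucleus border (default 20 px); spots detected by white top-hat filtering plus
a manual per-channel threshold; each spot assigned to the cell whose territory
contains it.

**Per-cell classification** (`xyspot.profiles`) — with per-cell counts
\(x, y\) for the two homologs, cells fall into six mutually exclusive
categories:

| category | condition |
|---|---|
| no signal | x = 0, y = 0 |
| X = 1 | x = 1, y = 0 |
| Y = 1 | x = 0, y = 1 |
| mixed | x ≥ 1 and y ≥ 1 |
| X-specific | x ≥ 2, y = 0 |
| Y-specific | y ≥ 2, x = 0 |

plus the overlapping four-gene co-expression categories for simultaneous
PX/PY/NX/NY hybridizations, and counts normalized per 1000 cells.

**Spatial dimorphism** (`xyspot.spatial`) — per-gene kernel density maps
(each spot one pixel, convolved with a truncated 2-D Gaussian, window 150 px,
SD 25 px); the purity field p = Y/(X+Y); its histogram with 80%-purity
dominance cutoffs (X-dominant p ≤ 0.2, Y-dominant p ≥ 0.8); a
label-permutation null (100 randomizations of the X/Y labels over the fixed
spot positions) giving signed ±3 SD per-bin flags and percentile 95%
confidence intervals for the three dominance-category proportions; a
landmark-defined dorsal/ventral border with per-region X:Y count ratios and a
one-tailed Welch t-test.

**Probe targeting** (`xyspot.sites`) — enumeration of alignment columns where
all X isoforms differ from all Y isoforms by one unambiguous nucleotide, and
exon-level percent identity.

**Synthetic scenes** (`xyspot.synthetic`) — ground-truthed tissue sections
(nuclei, per-cell expression classes, spots, rendered TIFF channels) with a
tunable ventral enrichment of X-expressing cells, used throughout the test
suite and the acceptance script.

## Worked example

```python
from xyspot import (SceneConfig, generate_scene, permutation_null)

# a 512x512 section, ~1340 nuclei, X-expressing cells 3x enriched ventrally
cfg = SceneConfig(image_height=512, image_width=512, n_cells=1340,
                  min_nucleus_separation=8.0, nucleus_radius_mean=3.0,
                  ventral_x_enrichment=3.0, seed=40_000)
scene = generate_scene(cfg)
res = permutation_null(scene.true_spots, (512, 512), n_rand=100, seed=50_000)
print({k: round(v, 3) for k, v in res.observed_props.items()})
print({k: round(v, 3) for k, v in res.ci_high.items()})
print("y-dominant bins over-represented:",
      int((res.flags[res.bin_edges[:-1] >= res.cutoff] == 1).sum()))
```

prints

```
{'x_dominant': 0.231, 'mixed': 0.74, 'y_dominant': 0.029}
{'x_dominant': 0.086, 'mixed': 0.987, 'y_dominant': 0.02}
y-dominant bins over-represented: 9
```

Read: 23.1% of tissue pixels are X-dominant and 2.9% Y-dominant, against
null upper bounds of 8.6% and 2.0% — both dominance classes exceed what
random labeling of the same spot positions allows, and nine Y-side histogram
bins sit more than 3 SD above their randomized means. The ventrally
clustered X homolog segregates the section into an X-dominant ventral zone
and leaves the uniformly expressed Y homolog over-represented dorsally,
exactly the signature the permutation test is built to detect. (With
`ventral_x_enrichment=1` the labels are exchangeable and the test rejects at
its nominal ~5% rate.)

The same analysis runs from the shell on real data:

```sh
xyspot segment nuclei.tif --out nuclei_labels.tif
xyspot expand nuclei_labels.tif --distance 20 --out cell_labels.tif
xyspot detect chX.tif --gene X --threshold 120 --out spots_x.csv
xyspot permtest spots.csv --height 2048 --width 2048 --n-rand 100 --seed 1 --out perm.json
xyspot probesites pcdh11x.fasta pcdh11y.fasta --out sites.tsv
```

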