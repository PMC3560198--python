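# myofibre

Automated morphometry of transversally sectioned skeletal muscle.

Histological read-outs of dystrophic pathology — most prominently in the
*mdx* mouse model of Duchenne muscular dystrophy — are classically scored by
hand, which is slow and observer-dependent. `myofibre` automates the
standard per-section outcome measures from three registered images of one
muscle cross-section:

1. a **membrane stain** (e.g. fluorophore-conjugated wheat germ agglutinin)
   outlining every fibre,
2. a **nuclear stain** (e.g. Hoechst 33258),
3. a brightfield **myosin-heavy-chain double stain** (slow MHC in DAB brown,
   fast MHC in a blue-grey chromogen).

From these it segments every myofibre, measures its size, locates its nuclei
and calls its type, reporting per fibre and per section:

- **minimal Feret's diameter** — the minimum distance between two parallel
  tangents enclosing the cross-section, min<sub>θ</sub> w(θ). Computed by
  rotating calipers on the convex hull of the pixel-corner points, it is the
  fibre-size measure least biased by an oblique sectioning angle;
- **variance coefficient** of fibre size,
  VC = 1000 · SD(minimal Feret) / mean(minimal Feret), elevated in
  dystrophic muscle;
- **percentage of internally nucleated fibres** — a fibre counts as internal
  when at least one nucleus centroid lies deeper than a subsarcolemmal band
  (default 3 µm) from the fibre boundary; in rodents the marker of prior
  necrosis/regeneration;
- **fibre-size distribution** in 10-µm bins, as percentage of fibre count;
- **fibre type** (slow / fast / hybrid / unclassified) from colour
  deconvolution of the double stain in optical-density space.

Validation statistics used to compare automated against manual measurement
are included: Bland–Altman bias and 95 % limits of agreement, a Lilliefors
Kolmogorov–Smirnov normality screen, and the unpaired Student's t-test.

Because stained sections cannot be bundled with the code, the package ships
a synthetic-section generator (`myofibre.synthetic`): Lloyd-relaxed Voronoi
tessellations rendered into all three channels with exact ground truth, so
every stage of the pipeline is testable end to end.

## Worked example

Generate a 50-fibre synthetic section and analyse it:

```bash
myofibre simulate --seed 42 --out demo/sim
myofibre analyze --membrane demo/sim/membrane.png \
                 --nuclei demo/sim/nuclei.png \
                 --mhc demo/sim/mhc.png \
                 --out demo/out
```

The analysis log ends with

```
50 fibres | 30.0% internally nucleated | mean min Feret 29.56 um | VC 167.6
```

and `demo/out/` contains `fibres.csv` (one row per fibre), `summary.csv`,
`nuclei.csv`, an annotated `overlay.png` (peripheral-nucleated fibres
yellow, internally nucleated orange, nucleus centroids green/blue, fibre ids
at centroids) and `run_metadata.json` recording every parameter. The first
rows of `fibres.csv`:

```
fibre_id,area_um2,min_feret_um,max_feret_um,fibre_type,n_nuclei,n_internal_nuclei,nucleation_class,qc_pass
6,722.7500,28.9374,36.2802,fast,1,1,internal,True
7,947.2500,30.7859,45.1774,fast,1,1,internal,True
8,1194.2500,38.0499,44.5225,hybrid,1,0,peripheral,True
```

and `summary.csv` reports

```
n_fibres,pct_internally_nucleated,mean_min_feret_um,sd_min_feret_um,variance_coefficient
50,30.0000,29.5605,4.9549,167.6178
```

The section was planted with exactly 30 % internally nucleated fibres, so
the recovered 30.0 % and the ground-truth-matched sizes (truth mean
29.71 µm, VC 167.3) show the pipeline reading back what was drawn. For real
images, supply the spatial calibration and thresholds through a YAML config
(`--config`) or `--set` overrides, e.g.
`--set microns_per_pixel=0.323 --set nuclei.peripheral_band_um=2.5`.

Method comparison of two paired CSVs (columns `id` plus one column per
parameter):

```bash
myofibre compare --manual manual.csv --automated automated.csv --out cmp/
```

writes the per-parameter bias and limits of agreement with plot data.

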