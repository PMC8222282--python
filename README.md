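# mvtip

Quantitative analysis of membrane-protein exclusion from the tips of
T-cell microvilli in super-resolution images.

Lymphocyte microvilli (MV) are ~100 nm-wide actin protrusions that carry
the T cell receptor and act as antigen sensors. The bulky phosphatase CD45
is depleted from the MV tips even before any antigen contact, which leaves
tip-resident TCRs free to trigger. `mvtip` implements the image-analysis
chain used to establish and quantify this pre-exclusion:

* **MV-tip segmentation** — background masks (outside-cell, inside-cell
  lumen), the entire-cell analysis mask (SegBW), convex-hull tip detection,
  MV-length and tip-proximity filters (50 nm–1.5 µm, 50 nm merge), and
  MV-tip (<150 nm of a tip) / MV-column / cell-body zoning with 75 nm
  junction bands excluded.
* **Colocalization statistics** — the ratiometric intensity score
  `RIS = (X − Yₙ)/(X + Yₙ)` with Y mean-matched to X (+1 only X, −1 only Y,
  0 equal); Pearson R′ with the zero-variance convention R′ = 0; the
  segment-correlation coefficient

  `SR′ = Σ_seg (Xᵢ − X̄_cell)(Yᵢ − Ȳ_cell) / √(Σ_seg (Xᵢ − X̄_cell)² · Σ_seg (Yᵢ − Ȳ_cell)²)`

  which scores a constantly anticorrelated segment as −1 (ordinary Pearson
  is blind there) and equals R′ on the whole cell; Manders MOC/MCC₁/MCC₂;
  0–1 intensity normalization; distance profiles from the tips in 12.5 nm
  bins.
* **STORM pair correlation** — localization quality filters (precision
  0–14 nm, z ± 400 nm, photon/background/σ bounds), histogram-render
  cross-correlation channel registration with a 2D-Gaussian subpixel peak
  fit, 9 × 9-pixel (1.053 µm) tip windows, and the cross-channel 3D pair
  correlation g(r) in 10 nm shells.
* **MIL sequence metric** — the membrane integration limit: the longest
  run of non-charged residues (charged = K, R, E, D, H) overlapping an
  annotated TM helix; predicted helix length = 1.5 Å per residue. Human
  CD45 has MIL = 22 aa between K577 and K600 (~33 Å), versus a 27.4 aa
  mean (41.1 Å) for other lymphocyte membrane proteins.
* **Calcium traces** — per-frame Otsu/largest-component ROI extraction of
  Fluo-4 intensity and I − I(0) step traces.
* **Synthetic phantoms** — every stage is exercised on in-package
  generators (two-channel MV cells with exact ground-truth tips, STORM-like
  localization tables on the MV surface geometry, SR′ validation vectors,
  calcium step movies), so the full pipeline is testable with no external
  data.

## Worked example

```sh
mvtip run-demo --seed 1 --out demo/
```

generates a synthetic cell (20 MV on a 2 µm body; channel A tip-enriched,
channel B 90 % depleted within 150 nm of each tip), segments it, and
prints the per-zone statistics (X = the excluded channel B, Y = channel A):

```
 z_index zone  n_pixels  median_X  median_Y  median_RIS  mean_SRprime
       0  Tip      2397  0.000000       0.0   -0.936796   -0.366787
       0  Col      3484  0.060874       0.0    0.080371    0.792554
       0   CB      8605  0.178264       0.0    0.238569    0.460973
       0 Cell     15939  0.060874       0.0    0.123418    0.095769
g(r) peak at r_left = 160 nm
```

Reading the numbers: the median RIS in the MV-tip zone is strongly
negative (−0.94: the excluded channel is nearly absent where the tip
channel is bright) and rises through the column (0.08) to the cell body
(0.24), reproducing the characteristic Tip < Col < CB ordering; the mean
SR′ is negative only in the tip zone (anticorrelation of the two channels
there). The STORM g(r) between the tip channel and the excluded channel
peaks at the first shell beyond the generator's 150 nm exclusion zone.
The same library calls are available programmatically:

```python
from mvtip import SyntheticCellParams, generate_cell_image, segment_cell

image, truth = generate_cell_image(SyntheticCellParams(seed=1))
segmap = segment_cell(image)       # accepted tips, lengths, zone labels
```

CLI subcommands: `simulate`, `segment`, `stats`, `storm`, `mil`,
`calcium`, `run-demo`; all accept `--seed`, `--out`, and where relevant a
YAML `--config` (see `mvtip.config.RunConfig`).

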