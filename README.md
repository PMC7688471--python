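# spatmsi

Spatially aware analysis of drug distribution and tissue heterogeneity in
mass spectrometry imaging (MSI) data.

## The problem

Untargeted MALDI-MSI of a tumour section yields one mass spectrum per pixel:
hundreds of ion images acquired simultaneously, one of which is the drug
(e.g. paclitaxel in a xenograft model).  How evenly a drug penetrates a
tumour depends on the local tissue microenvironment, so the scientific
questions are spatial ones: which tissue subtypes does the section contain,
how spatially coherent is each subtype, where is the drug high or low, and
which ions mark the subtypes once the pervasive spatial autocorrelation of
ion images is taken into account?

`spatmsi` implements the full workflow for these questions:

1. **Pre-processing** (`spatmsi.preprocessing`) — maximum-intensity
   reference spectrum; wavelet peak picking (least-asymmetric Daubechies
   8-tap, hard shrinkage); adaptive m/z binning (peaks < 0.05 Da apart
   merged, gaps > 1 Da tiled with 0.5 Da bins); coverage and single-model
   filters; mask-aware 3×3 median filtering with tissue-edge correction;
   median normalisation; generalised-log transform
   g(x) = ln((x + √(x² + λ))/2); batch-effect removal; removal of features
   correlated (r > 0.9) with the drug ion.
2. **Segmentation** (`spatmsi.segmentation`) — bisecting k-means under
   correlation distance d(a,b) = 1 − r(a,b), splitting the largest cluster
   while it holds > 40 % of pixels, then while the Calinski–Harabasz index
   keeps improving.
3. **Homogeneity** (`spatmsi.homogeneity`) — size-zone homogeneity ratio:
   the fraction of tissue occupied by a cluster's connected components of
   at least *Nu* pixels (default 5, 8-connectivity).
4. **Drug distribution maps** (`spatmsi.spatial`) — distance-band spatial
   weights W, global Moran's I, spatial correlograms, and LISA maps
   classifying every pixel by the signs of its autoscaled drug intensity z
   and spatial lag Wz into HH / LL / HL / LH quadrants.
5. **Association** (`spatmsi.association`) — zone × cluster contingency
   tables and Cramér's V = √(χ² / (T·min(r−1, c−1))), by default on the
   spatially smooth HH/LL rows.
6. **Ion selection** (`spatmsi.regression`) — maximum-likelihood spatial
   lag (y = ρWy + Xβ + ε) and spatial error (u = λWu + ε) regression with
   exact eigenvalue log-determinants; per-section one-vs-rest cluster
   indicators, Benjamini–Hochberg correction across ions, and intersection
   of the significant sets over all sections.
7. **Synthetic benchmark** (`spatmsi.synthetic`) — SAR field generator
   y = (I − ρW)⁻¹ε and a planted-marker benchmark comparing OLS, SL and SE
   selection across analysis lag distances.

The clustering and regression cores are scikit-learn-style estimators
(`CorrelationKMeans`, `BisectingKMeans`, `SpatialLagModel`,
`SpatialErrorModel`) and compose with sklearn tooling; the module-level
functions are thin wrappers.

## Worked example

```python
import numpy as np
from spatmsi import build_weights, lisa_map, zone_cluster_table, cramers_v, \
    select_cluster_ions
from spatmsi.synthetic import generate_benchmark_dataset

# three sections of a 30x30 raster: 3 marker ions shifted by delta=1.5
# in tissue class 2, 12 spatially autocorrelated noise ions
ft, classes, truth = generate_benchmark_dataset(
    grid=(30, 30), p_informative=3, p_noise=12, delta=1.5,
    rho_gen=0.6, n_slices=3, seed=7,
)

# discrete drug-style map of the first marker ion on section s1
s1 = (ft.pixels["slice_id"] == "s1").to_numpy()
w = build_weights(ft.coords[s1], threshold=2, style="row_standardized")
zones = lisa_map(ft.matrix[s1, 0], w)
print("LISA zone counts:", zones.counts())

# association between the LISA map and the tissue classes
tab = zone_cluster_table(zones.zones, classes[s1])
print("Cramer V (HH/LL vs classes):", round(cramers_v(tab), 3))

# spatially aware marker selection: which ions separate class 2?
sel = select_cluster_ions(ft, classes, cluster=2, method="SL", lag_distance=2)
print("selected ions:", sel.final)
print("planted ions: ", truth.informative)
```

prints

```
LISA zone counts: {'HH': 303, 'LL': 319, 'HL': 142, 'LH': 136}
Cramer V (HH/LL vs classes): 0.672
selected ions: [200.0, 201.0, 202.0]
planted ions:  [200.0, 201.0, 202.0]
```

Most pixels fall in the spatially smooth HH/LL quadrants of the marker
ion's LISA map; those quadrants associate strongly with the two tissue
classes (V = 0.672); and the spatial lag model recovers exactly the three
planted marker ions, with no false positives among the twelve
autocorrelated noise ions.

A full pipeline run (`preprocess → segment → homogeneity → lisa →
associate → select`) is driven by a YAML config:

```sh
spatmsi run --config config.yaml --seed 1 --out results/
```

Subcommands `segment`, `lisa`, `simulate` and `benchmark` expose the
individual stages; every run writes a manifest with artifact hashes, so
identical configs and seeds reproduce byte-identical outputs.

## Documentation

See `docs/methods.md` for the statistical models, parameter defaults,
numerical choices, and the limitations of the synthetic benchmark.
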