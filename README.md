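# poleward

Analysis pipeline for pole-to-pole algal-microbiome transects: copy-number-aware
normalization of 16S/18S/Pfam abundance tables, diversity statistics, weighted
co-occurrence networks correlated with the environment, beta-diversity
**breakpoint** detection along the latitudinal temperature gradient, and
projection of breakpoint-defined temperature bands under ocean warming.

It is written for microbial ecologists and biological oceanographers who want
to ask: *where along a temperature gradient does a microbial community flip
from its cold regime to its warm regime, and where will that boundary sit in a
warmer ocean?* Every stage is exercisable end-to-end on synthetic transects
with planted ground truth, so the statistical machinery can be validated
without any sequencing data.

## The model at the core

**Breakpoint detection.** Community tables are reduced to presence–absence;
pairwise Sørensen dissimilarity β<sub>sor</sub>(i,j) = (b+c)/(2a+b+c) is
summarized to one beta-diversity value per station (mean dissimilarity to all
other stations); bivariate outliers are removed with a bagplot rule (Tukey
halfspace depth, 50% bag, fence = bag × 3); and a continuous broken-stick
regression

&nbsp;&nbsp;&nbsp;&nbsp;y = b₀ + b₁·x + b₂·max(0, x − ψ)

is fit at every candidate ψ (midpoints of consecutive sorted unique x), keeping
the ψ with the lowest mean squared error. Significance is an F-test against the
straight-line fit. The x axis is temperature (°C) or *altered latitude*
(North pole 0°, Equator 90°, South pole 180°).

**Co-occurrence networks.** Pearson correlations of log₁₀ feature profiles are
soft-thresholded to an adjacency a<sub>ij</sub> = |r|<sup>β</sup> (β = 11 for
combined 16S/18S taxa, 12 for Pfams; a signed variant ((1+r)/2)<sup>β</sup> is
available), converted to a topological overlap measure (TOM), clustered on
1 − TOM, and each module is summarized by its eigengene (first principal
component) whose correlation with temperature, nutrients, salinity and altered
latitude gives the module–trait map.

**Copy-number normalization.** 18S abundances are divided by copies predicted
from genome size through the log-log law fit on a reference table
(log₁₀ copies = slope·log₁₀ Mbp + intercept); 16S abundances by rrnDB-style
copy numbers averaged strain → species and propagated through the taxonomy,
with nearest-ancestor imputation for missing taxa. Rows are then rescaled to
hits per million.

**Warming projection.** Projected sea-surface temperatures are delta-bias
corrected (add the observed-minus-modelled historical difference per grid
cell) and classified into four bands bounded by the three breakpoint
temperatures 9.49 / 13.96 / 18.06 °C; sea-ice cells in the observed
climatology are excluded.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/05_breakpoint_analysis.py` prints:

```
planted threshold: 14.0 degC
recovered breakpoint psi = 14.41 degC (p = 9.01e-10, 0 outlier(s) removed)
broken stick: beta = 0.457 + -0.0090*T + 0.0295*max(0, T - psi)
scenario nearest_latitude: psi = 15.18 degC
scenario   donor_region_A: psi = 14.41 degC
scenario   donor_region_B: psi = 14.41 degC
scenario      both_donors: psi = 14.41 degC
```

The simulated transect planted a cold/warm regime switch at 14 °C; the
broken-stick search recovers it at 14.41 °C with a highly significant slope
change, and the four gap-fill scenarios (re-donating beta values into a masked
mid-latitude stretch from the nearest stations or from polar/subtropical donor
regions) show how strongly a sampling gap could move the estimate.

The full chain is also available as a CLI:

```bash
poleward all --outdir run1 --seed 1     # simulate -> normalize -> ... -> project
```

which writes every intermediate table plus JSON run reports (config hash,
seed, version) and ends with the recovered breakpoints, the module count and
the sign of each module's temperature correlation.

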