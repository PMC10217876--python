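# Methods

## Model and procedure

`sedrisk` assesses heavy-metal contamination of river bottom sediments from
a long-format panel of site × year × analyte concentrations (mg·kg⁻¹ dry
weight). The assessment compares each concentration to a *site-specific
geochemical background* rather than a single regional constant, because
background levels vary strongly along a river course.

**Geochemical background.** For each site, a corridor buffer is built by
dilating the first 2000 m of the upstream watercourse polyline by half the
buffer width (250 m) with flat end caps. A corridor (rather than a rectangle
oriented on the mean flow direction) is well defined for meandering reaches.
The background GB for element *i* is the area-weighted mean of the
background map's class values over that corridor, GB = Σ(GBCᵢ·Aᵢ)/ΣAᵢ. The
weighted mean is invariant under polygon subdivision and bounded by the
minimum and maximum contributing class values; both properties are tested.
Intersection areas are computed in the projected planar CRS with no geodesic
correction, and geographic (degree) coordinates are refused at read time
rather than silently reprojected.

**Indices.** Per sample: Igeo = log₂(C/1.5·GB); EF = (C/GB)/(C_Fe/GB_Fe)
with iron as the conservative reference element; SPI = C/GB; Er = Tr·SPI
with the Håkanson toxic-response coefficients (As 10, Cd 30, Co 5, Cr 2,
Cu 5, Hg 40, Mn 1, Ni 5, Pb 5, Zn 1); RI = ΣEr over the ten metals;
TRIᵢ = √(((C/TEL)² + (C/PEL)²)/2) for the seven metals with TEL/PEL
guidelines, and TRI = ΣTRIᵢ. The TRIᵢ form is the root mean square of the
two guideline ratios; it is 0 at C = 0, strictly increasing in C, and tends
to 1 as C approaches a common TEL = PEL limit. RI and TRI are computed on
whatever metals are present and carry a completeness flag instead of
refusing gappy panels, because real monitoring panels have gaps.

**Classification.** Igeo uses the Müller seven-grade convention: grade 0
for Igeo ≤ 0, then upper-inclusive unit bins up to grade 6 above 5. All
other schemes are lower-bound inclusive for every class above the lowest
(RI = 150 falls in the moderate class; Er = 40 in moderate; TRI = 5 in
low). Breakpoints: EF 2/5/20/40; Er 40/80/160/320; RI 150/300/600;
TRI 5/10/15/20. Every scheme is configurable through a JSON override, so a
strictly-greater reading of any boundary is available without code changes.
One documented edge follows from the conventions: a sample with every metal
exactly at background has Er(Hg) = 40·1 = 40, which lands one class above
the lowest for that single metal.

**Land use.** The same corridor intersected with a five-group Corine-style
land-cover mosaic gives areal shares summing to one. The site category is
the argmax over {anthropogenic, agricultural, forest}; wetland and water
contribute to shares but never win the category, and exact ties resolve in
the fixed order anthropogenic > agricultural > forest — arbitrary but
deterministic.

**Statistics.** Pooled per-analyte summaries use the sample standard
deviation (n−1), adjusted Fisher–Pearson skewness, excess kurtosis, and
type-7 (linear interpolation) quantiles for the IQR; the estimator
conventions behind published summary tables are rarely stated, so exact
reproduction of third-party skew/kurtosis cells is not claimed.
Mean-to-background ratios are rounded half-up to two decimals.
Correlations are Spearman rank with average ranks for ties, two-sided
p-values, and significance tiers at 10⁻⁴/10⁻³/10⁻²/0.05. Normality is
Shapiro–Wilk (3 ≤ n ≤ 5000). Land-use group differences use the two-sample
Mann–Whitney rank-sum test — groups of sites are independent, so the
two-sample form is the right reading of a generic "Wilcoxon test"; a
signed-rank variant is available by option. Raw p-values are reported by
default, with Holm adjustment behind a flag.

**Clustering.** For each year with at least three complete site profiles,
concentrations are log₁₀-transformed (marginals are right-skewed, roughly
log-normal) and z-scored per analyte — both steps configurable off — then
clustered with Ward linkage on Euclidean distance. The cluster count k
maximises the mean silhouette over 2…min(8, n−1); the elbow (largest second
difference of the within-cluster sum of squares) is reported alongside and
a disagreement is logged, with the silhouette winning. A silhouette below
0.3 sets a low-confidence flag. Years with fewer than three complete
profiles are skipped, mirroring campaigns where sparse years cannot be
clustered.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:

* **Marginals**: per-analyte log-normals with μ = ln(median) and σ solved
  in closed form from IQR/median = t − 1/t, t = exp(0.6745σ). Where a
  published IQR is non-positive (the As row prints 0, impossible for a
  continuous marginal), σ falls back to mean/median = exp(σ²/2). pH is
  normal (7.62 ± 0.42). Iron, absent from the published summary, uses a
  log-normal with median 8000 mg·kg⁻¹ and σ = 0.7 — a realistic lowland
  river sediment value.
* **Dependence**: a Gaussian copula with latent Pearson correlation
  r = 2·sin(π·ρ_s/6) targeting the published Spearman matrix
  (PSD-repaired by eigenvalue clipping when needed). Fe, not in the
  published matrix, gets a uniform 0.55 rank correlation to the metals and
  TOC and 0 to pH.
* **Point sources**: with probability 0.005 per metal cell, the value is
  multiplied by a log-uniform ×20–×200 factor — isolated maxima that
  inflate means but not medians.
* **Gaps**: whole site-years drop out independently with probability 0.45
  (inclusion 0.55), matching a campaign where roughly half the site-year
  grid is sampled.
* **Geometry**: a random-walk-bearing polyline with a bounded eastward
  drift; 35 sites at 2.5 km chainage spacing, so every upstream reach
  supports the 2 km buffer. The background map is a 500 m grid with
  truncated-normal (> 0) class values at the published means and
  between-class sd; the land-cover mosaic thresholds a smoothed Gaussian
  random field at the share quantiles (60.2 % agricultural, 32.5 % forest,
  5.6 % anthropogenic, 1.4 % water, 0.3 % wetland), which reproduces areal
  shares to grid resolution while giving buffers coherent dominant patches.

Not emulated: temporal autocorrelation within sites, land-use-dependent
concentration effects (the reference campaign found none significant),
hydrodynamic transport, and the spatial co-location of high concentrations
with particular reaches. Passing tests therefore demonstrate that the
pipeline computes its indices and statistics correctly under the assumed
marginal/dependence structure — not that it would reproduce any specific
real campaign's per-site results.

## Numerical choices

* No rounding inside computation; 12 significant digits at CSV write-out,
  which round-trips the numeric payload exactly in tests.
* Below-LOQ values "<x" are stored as x/2 with a `below_loq` flag — the
  conventional substitution, kept auditable via the flag.
* Missing (site, year) combinations are absent rows, never zeros.
* Degenerate inputs: constant summary series report skew/kurtosis 0 with a
  `degenerate` flag; all-identical cluster profiles yield a single flagged
  cluster; zero-variance analyte columns are dropped from the cluster
  matrix with a warning.
* Seeds: every generator takes an integer seed; sub-generators derive
  offsets (+1 river, +2 background map, +3 land cover) so the four inputs
  are independent but jointly reproducible.

## Problem sizes used in the checks

The test suite exercises the copula at n = 5000 joint draws (mean absolute
Spearman deviation < 0.05), the polygon overlay against a 10⁵-point Monte
Carlo oracle (1 % relative), classification against a brute-force lookup
table on 10⁴ values per index, index algebra on 10⁴ random samples,
planted two-cluster recovery across 20 seeds, and rank-sum null calibration
over 1000 replicates. The end-to-end pipeline test runs the full default
configuration (35 sites × 12 years).

## Known limitations

* The corridor buffer is centred on the river axis; offset-to-bank buffers
  are not modelled.
* EF requires an Fe background from the map; there is no default, since any
  constant would silently bias every EF value.
* The classification boundary conventions, while configurable, cannot make
  a single scheme simultaneously satisfy "low risk strictly below the first
  breakpoint" and "value exactly at the breakpoint stays lowest"; the
  lower-inclusive rule is applied uniformly and documented.
* Land-cover patch geometry is a grid mosaic, not vectorised landscape
  polygons; shares and dominant-category behaviour are faithful, parcel
  shapes are not.
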