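# Methods

`scanpower` measures, over an entire study region, how well a cluster
detection test (CDT) both *finds* and *locates* disease clusters. This note
records the models and procedures implemented, the defaults and why they
were chosen, and what the synthetic test conditions do and do not show.

## The simulation design

The study region is a set of *n* spatial units (SUs), each with a projected
planar centroid and an at-risk population (e.g. the mean annual number of
live births). To probe the CDT at every possible location with clusters of
a common class, the region is covered by an **exhaustive cluster
collection**: every SU is in turn the center of one simulated cluster made
of that SU and its *s* − 1 nearest neighbors by Euclidean centroid distance
(default *s* = 4, i.e. a center and its 3 nearest neighbors). Distance ties
are broken by ascending SU id, so the collection is deterministic.

Case counts are independent Poisson draws. With baseline incidence *I* and
per-SU expected counts ε*ᵢ* = *I* × population*ᵢ*,

- H₀ (homogeneous risk): *Nᵢ* ~ Pois(ε*ᵢ*),
- H₁ (one cluster, relative risk θ): *Nᵢ* ~ Pois(θ ε*ᵢ*) inside the
  cluster, Pois(ε*ᵢ*) outside.

Populations are annual means and incidences annual probabilities, so the
default dataset is one year of counts; a `years` multiplier on ε scales to
multi-year windows when the study design aggregates counts over a longer
registry period.

The four default risk scenarios cross two baseline incidences (0.48% and
2.26% of births — cardiovascular vs. all birth defects in the registry data
the design is modelled on) with relative risks 3 and 6.

## Kulldorff's Poisson spatial scan

Candidate zones are circles: each SU centroid is successively a center, and
growing the radius adds SUs in order of increasing centroid distance. The
zone sequence per center is truncated when the zone's population would
exceed a cap (default 50% of the regional population, the conventional scan
maximum; an optional SU-count cap is also available). For zone *z* with
*n_z* cases and population *N_z* (totals *n*, *N*) the statistic is, on the
log scale,

LLR(z) = *n_z* ln(*n_z*/λ*N_z*) + (*n* − *n_z*) ln((*n* − *n_z*)/λ(*N* − *N_z*))

when *n_z* > λ*N_z* and 0 otherwise (0 ln 0 ≡ 0). λ is the global
incidence; by default it is **estimated as n/N from each dataset**, which
makes the statistic coherent with the conditional Monte Carlo inference
below. A fixed-λ mode (the design incidence) is provided as a switch, since
either reading of "global incidence" is defensible. The zone with the
highest LLR is the most likely cluster (MLC); exact LLR ties go to the
smaller zone, then the lexicographically smaller center id.

Significance is by Monte Carlo: the observed maximum LLR is ranked among
the maxima of *R* null replicates, p = (1 + #{replicate max ≥ observed
max})/(R + 1). Null replicates redistribute the observed total
multinomially with cell probabilities ε*ᵢ*/Σε — the standard conditional
device for scan inference — with unconditional Poisson replicates available
as an option. Defaults: *R* = 999, α = 0.05.

The scan is exact, not approximate: a jit-compiled kernel evaluates every
zone of every replicate using cumulative counts along each center's
distance ordering and precomputed logarithm tables, and a pure-numpy path
computes the identical statistic (the two are cross-checked in the tests,
as is agreement with a brute-force zone enumeration on small random
regions).

## Extended power and AUC_EP

For a true cluster of size *s*, each dataset yields one of three outcomes:
H₀ not rejected; a significant detection of size *l* > *L* (discarded as
uninterpretably large — default *L* = 30 SUs); or an eligible detection
recorded as (*l*, *s**), with *s** the number of true-positive SUs. The
Takahashi–Tango weight

W(l, s*, q) = (s*/s) · max(0, 1 − q(l − s*)/s)

follows from penalties w⁻ = 1/s for false negatives and w⁺ = q/s for false
positives, with q = w⁺/w⁻ ∈ [0, 1] the stringency of the location
requirement (q = 0 ignores false positives; q = 1 weighs them like false
negatives). Extended power at q is Σ W·P(l, s*) over the tally, with
non-rejections and oversize detections in the denominator only. The
**AUC_EP** integrates EP(q) over [0, 1]; it is computed in closed form per
tally cell — with a = (l − s*)/s the cell integral is (s*/s)(1 − a/2) for
a ≤ 1 and (s*/s)/(2a) otherwise — and the numerical-quadrature route is
kept in the test suite as an independent oracle (the EP curve is piecewise
linear with kinks at q = s/(l − s*), so trapezoid integration on a grid
refined with the kink points is exact).

The EP(0) intercept equals Σ P(l, s*) · s*/s, i.e. detections are credited
by their true-positive fraction, not counted fully; a reading of the
intercept as "the rejection rate among eligible detections" is only exact
when every eligible detection contains all s true SUs.

Each cluster's AUC_EP is assigned to its central SU, giving one choropleth
map per scenario (assignment to the mean over member SUs is available
behind a flag). Rendering uses fixed class breaks — deciles of [0, 1] — so
maps from different scenarios are visually comparable.

## Synthetic regions

Test regions are rows × cols lattices of square SUs with three population
surfaces: uniform; a linear gradient across columns; and an "urban-rural"
surface, center · exp(−decay · distance-to-middle), mimicking a populous
urban core with sparse borderland. The default 15×15/200-per-SU grid (225
SUs, 45,000 annual births) matches the scale of a 221-SU administrative
region. The urban-rural surface used in the qualitative experiments (center
200, decay 0.35 on a 9×9 grid) yields 4-SU cluster populations from roughly
110 to 780 births — the range over which the scan's performance climbs from
near-inoperative to near-perfect, matching the population quartiles the
method is meant to resolve.

What the lattice does **not** emulate: irregular SU shapes and sizes,
spatially correlated population structure, edge effects of a real boundary
polygon, and multi-part geometries. Passing tests on these grids therefore
validate the statistical machinery and its qualitative behavior (risk and
population response, calibration), not any particular real-region map.

## Problem sizes and numerical choices

- Type-I calibration runs 1,000 null datasets on the 15×15 uniform grid
  with R = 199 and α = 0.05, and checks the rejection rate against the 99%
  binomial band [0.033, 0.069].
- The qualitative mapping experiments use the 9×9 urban-rural grid with
  100 datasets per cluster and R = 199 (60 and R = 99 in the faster test
  variant) — large enough that the scenario ordering and the population
  quartile trend are stable, small enough for a desk run.
- Mean AUC_EP is required to increase along both chains of the risk partial
  order (raising θ at fixed incidence; raising incidence at fixed θ). The
  two middle scenarios — low incidence/high RR vs. high incidence/low RR —
  are theoretically incomparable (they trade expected excess cases against
  background noise) and are not ordered against each other.
- Degenerate inputs: a region needs ≥ 2 SUs and positive total population;
  datasets with zero total cases return "no cluster" with p = 1; tallies
  must account for every dataset (counts + non-rejections + oversize).
- All randomness flows from one master seed through numpy `SeedSequence`
  spawn keys, one child seed per (cluster, scenario, replicate, purpose),
  so any single dataset or Monte Carlo stream is regenerable in isolation
  and checkpoint resumption cannot shift the stream.
- Population-quartile summaries break at the 25/50/75% quantiles of the
  cluster populations; with degenerate (equal) populations the classes
  collapse and a single class is reported.

## Limitations

- Circular zones and circular simulated clusters only; irregularly shaped
  true clusters would need a different cluster model and likely a
  non-circular scan.
- Single most-likely cluster per dataset; secondary clusters are ignored.
- Poisson counts without overdispersion or covariate adjustment.
- Geometry I/O is GeoJSON or centroid CSV in a projected CRS; coordinates
  that look geographic (lon/lat ranges) are rejected rather than
  reprojected, so reproject upstream.
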