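# Methods

## Geometric model

A cell resting on the wall of a spherical macropore of radius r
experiences principal curvature 1/r (Gaussian curvature 1/r²).  The
curvature "seen" by a whole cell is summarized by the solid angle
Ω = A / r² (steradians), where A is the cell surface area.  Ω is
dimensionless and invariant under uniform rescaling of all lengths, and
falls with the square of the pore radius — the 60–125 μm and 250–425 μm
pore classes differ by a factor of ≈13 at their midpoint radii.

The cell is modeled as a **prolate** spheroid: polar (symmetry) full
axis = the 20 μm cell width, equatorial full diameter = the 10 μm cell
height, giving the closed-form area

S = 2πa² (1 + c/(a·e) · asin e),  e = √(1 − a²/c²),  a = height/2, c = width/2,

≈ 537 μm² for 10 × 20 μm.  The oblate reading of "10 μm height, 20 μm
width" would give ≈ 867 μm²; the prolate reading is the one consistent
with the published cell-area value this package reproduces, and the
formula reduces to 4πR² when the axes are equal.  If callers swap the
axes the function swaps back with a warning rather than silently
producing an oblate area.

Pore radii come either from the midpoint of a nominal porogen sieve
range (the default: 168.75 μm and 46.25 μm for the large and small
classes) or from measured pore diameters.  Pore diameter is the longest
chord of an 8-connected mask component — the maximum pairwise distance
between pixel centers, computed exactly on the convex hull of the
component.  It is invariant to rotation within one pixel diagonal.

## Spatial point pattern analysis

Nuclei are reduced to centroids of 8-connected components and analyzed
as a point process inside an **observation window**: the binary mask of
pore space not occupied by polymer matrix.  Coordinates put pixel
centers at integer multiples of the pixel size (x = column, y = row);
the frame edge runs half a pixel beyond the outermost centers.
Distance to the window complement — used by all border corrections — is
the minimum of the distance to the nearest matrix-pixel center and to
the frame edge.

Estimators (statistic curves on an r-grid, default 128 equal steps from
0 to a quarter of the window's maximum extent, beyond which estimator
variance makes the curves uninformative):

- **Empty-space function F̂(r)**: reference locations are the true
  window pixel centers (optionally subsampled).  The default
  reduced-sample (border) estimator counts, among reference locations at
  least r from the complement, the fraction whose nearest event is
  within r.  This estimator is unbiased but not guaranteed monotone in
  r; the uncorrected variant ("none") is monotone but biased low near
  boundaries.  Under CSR, F(r) = 1 − e^(−λπr²).
- **Ripley's K̂(r)**: |W|/(n(n−1)) Σ_{i≠j} 1(d_ij ≤ r) without
  correction; the border correction keeps only events at least r from
  the complement as reference events and renormalizes (valid for
  arbitrary masks — pore space is not rectangular); the translation
  correction (e_ij = |W|/|W ∩ W_shift|) is offered for full-rectangle
  windows.  Under CSR, K(r) = πr².  Calibration: over 250 CSR
  simulations (n = 200, 128 μm square), the mean border-corrected K̂ is
  within 5% of πr² for r ≥ 1 μm (below one pixel the target πr²
  vanishes faster than Monte-Carlo error), and mean F̂ within 0.03 of
  theory — both asserted in the test suite.

**Envelopes.**  CSR is simulated conditional on the observed count
(binomial process: n i.i.d. uniform points on the window, by rejection
sampling), not with Poisson-random n.  The pointwise min/max of nsim
simulated curves is a rank-1 band with two-sided pointwise level
2/(nsim+1); nsim = 49 gives the conventional 96% envelope.  A fresh CSR
pattern exits the band at a fixed r with probability 2/50 = 4% (verified
by simulation in the suite).

**Departure summary.**  AUC = trapezoidal integral of
(empirical − theoretical) over the r-grid (grid points where the border
estimator is undefined are excluded; the integration range is reported).
Clustering pushes AUC_K positive and AUC_F negative.

**Clustered flag.**  Scanning a *pointwise* band across ~129 grid points
inflates the global false-positive rate well above the nominal 4%
(measured ≈ 12–20% under CSR).  The flag therefore requires both
(i) envelope exceedance in the clustering direction somewhere on the
grid, and (ii) a global one-sided Monte-Carlo rank test: the AUC
departure over the lower half of the r-range — where a cluster-scale
signal concentrates, and which avoids the variance-dominated tail —
must be in the clustering direction and rank in the top 2 of the
nsim + 1 exchangeable values (level 2/(nsim+1) = 4%, matching the
envelope).  On the default synthetic scenes this rule detects Thomas
clustering in ~100% of fields and flags CSR fields in ≤ 5%.

**Other statistics.**  Nearest-neighbor distances are exact (k-d tree).
Cell clusters are single-linkage components at a link distance
(d ≤ threshold, so chains at exactly the threshold connect); the
pipeline default is twice the median nucleus long axis when morphometry
is available, since "discrete cluster" has no canonical definition.

## Morphometry

All scores are area-based after thresholding (default Otsu; fixed
values accepted), so they are invariant to intensity rescaling above
threshold.  Nuclei are 8-connected components of the thresholded
nuclear (blue/DAPI) channel; components below a minimum area (pipeline
default 20 μm², below any real nucleus cross-section) are discarded,
and an option drops frame-truncated border nuclei, the standard
practice for shape measurements.  Axes are those of the
moment-equivalent ellipse (rotation-invariant; a bounding-box mode
exists for literal height-by-width replication).

- NAR = d_short/d_long ∈ (0, 1], 1 = round.  Because published prose
  sometimes calls elongated nuclei "higher aspect ratio", an
  `elongation=True` flag returns d_long/d_short instead; the default
  follows the printed formula and neither convention is asserted as
  canonical.
- Mean cross-sectional area = thresholded nuclear area / cell count.
- Colocalization ratio = marker⁺ area inside nuclei / total marker⁺
  area ∈ [0, 1]; NaN with a warning when no pixel passes the marker
  threshold.  The mask-based area ratio over segmented nuclei replaces
  manual freehand nucleus tracing — deterministic and testable;
  per-nucleus fractions are available as an optional output.
- Marker index = marker⁺ area / nuclei in field (μm² per nucleus).

## Expression

ΔΔCt: fold = 2^(−[(Ct_gene − Ct_ref)_sample − (Ct_gene − Ct_ref)_calibrator]),
with the calibrator ΔCt averaged over calibrator-condition samples.
Efficiency-corrected models are out of scope (only reference-gene
normalization is assumed).  Samples are clustered agglomeratively on
d = 1 − Pearson r (log2 fold by default; raw fold selectable — the
choice of clustered values is a documented switch), average linkage by
default, via scipy's deterministic implementation.  Pearson distance
makes the clustering invariant to per-sample affine transforms.
Zero-variance samples have undefined correlation and are rejected by
name.  Dendrograms export as Newick with height-difference branch
lengths.

## Synthetic data

Generators are pure functions of (parameters, seed) — identical calls
are bit-identical.  They emulate: circular pore cross-sections in a
solid matrix (single- and multi-pore windows, full rectangles); nuclei
placed by CSR (binomial) or by a Thomas cluster process (Poisson(κ|W|)
parents uniform on the window, Poisson(μ) offspring per parent with
isotropic Gaussian(σ) displacement, offspring off the window rejected);
nuclei rendered as constant-intensity ellipses at random orientation
with a controlled aspect ratio; and a marker channel whose positive
pixels are allocated between nuclear and cytosolic compartments at an
exact requested fraction and total area.

Default scenes fix the study conditions: *small-pore-like* = 92.5 μm
disc (midpoint of 60–125 μm) with Thomas clustering, κ|W| ≈ 6 parents,
μ = 6, σ = 6 μm — a few tight multicellular clumps, ≈ 35 nuclei per
pore section; *large-pore-like* = 337.5 μm disc (midpoint of
250–425 μm) with 120 CSR cells, a sparser areal density matching cells
lining a large pore.  Scene patterns are conditioned on at least 5
events (fields with fewer cells carry no spatial information and would
not be analyzed); nuclei default to a 12 μm long axis and NAR 0.7,
typical of MSC nuclei in sections.  The Ct generator produces two
opposite pore-condition archetypes over an osteogenic/
mechanotransduction panel plus a flat monolayer baseline that serves as
ΔΔCt calibrator, with 0.5-cycle Gaussian well noise (a realistic qPCR
replicate spread).  Fold changes are calibrated against the baseline
rather than either contrasted group — calibrating against a contrasted
group reduces that group's profiles to noise and destroys its
within-group correlation.

What the generators do **not** emulate: staining variability and
intensity gradients, out-of-focus light, touching-nucleus splitting
(clustered nuclei merge, as in real sections — segmentation counts are
therefore a lower bound in dense fields), 3-D structure, and chromatic
registration errors.  Passing recovery tests therefore demonstrates the
correctness of the estimators and formulas, not robustness to every
imaging artifact.

## Numerical choices and degenerate inputs

- Rendering jitters colliding nuclei with an escalating search radius
  and counts unresolvable overlaps rather than failing.
- F̂(0) is exactly 0 for generic (off-pixel-center) event positions; an
  event exactly on a reference pixel center contributes 1/N_ref.
- Border-corrected estimators return NaN where no reference
  event/location survives; AUCs and the flag exclude those grid points.
- Ties in agglomeration are resolved by scipy's deterministic ordering;
  input order is preserved in all outputs.
- Empty masks, blank channels and zero marker area warn and return
  empty/NaN results; geometry rejects non-positive lengths outright.

## Problem sizes

Test-suite simulations use windows of 100–300 px, patterns of tens to a
few hundred points, 49-simulation envelopes, and sweeps of 20–500
seeds — sizes at which the Monte-Carlo assertions above are stable from
run to run under their fixed seeds while the whole suite stays fast.

## Known limitations

- 2-D only: curvature is summarized from circular cross-sections and
  point statistics are planar; no 3-D stacks.
- Homogeneous-intensity F and K only; no inhomogeneous λ(x) variants,
  and envelopes are pointwise (the clustered flag adds a global rank
  test, but no simultaneous band is constructed).
- The F border estimator is reduced-sample, not the product-limit
  (Kaplan-Meier) estimator some ecosystems default to; on CSR data the
  two agree well within the calibration tolerances asserted here.
- Printed per-class curvature values measured from micrographs in the
  source literature depend on unreported measured radii and are not
  reproduction targets; midpoint radii are used instead and can be
  overridden with measured means.
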