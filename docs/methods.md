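# Methods

`macscore` quantifies calcified plaque burden in the three mesenteric
arteries — celiac (CA), superior mesenteric (SMA) and inferior
mesenteric (IMA) — on CT/CTA, and evaluates the resulting mesenteric
artery calcium score (MACS) as a screening test for chronic mesenteric
ischemia (CMI). This note records the model, the parameters that
matter, the numerical choices, and what the synthetic-data machinery
does and does not establish.

## The score

The score follows the Agatston construction. Inside an artery's
scoring territory, voxels at or above a threshold `T` (default 130 HU,
inclusive) are grouped per axial slice into 8-connected components.
A component of in-plane area `A` (mm²) whose peak attenuation falls in
130–199 / 200–299 / 300–399 / ≥400 HU receives weight `w` = 1 / 2 / 3 /
4 and contributes

    A · w · (t / 3 mm)

where `t` is the reconstructed slice thickness. The thickness factor
generalises the classic 3 mm protocol: at `t = 3` the score is exactly
the classic per-slice area × weight sum, and at other thicknesses it
stays proportional to lesion volume, which keeps thin-slice CTA scores
on a comparable scale. Components smaller than `min_area` (default
1 mm², the classic single-speckle filter) are discarded. The weight
uses the per-slice peak HU (the classic rule; a per-lesion 3D peak
would only differ for lesions spanning slices with different peaks).

Per-artery scores are summed into `CA+SMA` and
`total = CA + SMA + IMA`; both are plain sums with no reweighting.

Tunable parameters and defaults: threshold 130 HU (inclusive ≥),
min_area 1.0 mm², origin-region mode `ball`, all exposed in the API and
CLI. Every CLI report embeds the effective configuration and the
acquisition geometry, because the score is known to be sensitive to
both.

## Scoring territories

Mesenteric stenoses concentrate at the vessel origin, so the territory
is anatomically standardised:

* **Origin region** — all voxels whose centre lies within a distance of
  *one origin diameter* of the ostium centre. The schematic that
  motivates this is a 2D circle; because lesions at an ostium span
  slices, the default implementation is the 3D ball (the conservative
  volumetric reading), with a per-slice 2D disc mode available
  (`origin_mode="disc"`, applied on the slice containing the ostium).
* **Distal region** — operator-supplied per-slice polygons following
  the vessel to its anatomical end point (CA: bifurcation; SMA: first
  large jejunal branch; IMA: left colic artery). These are hand-drawn
  landmarks, not auto-detected: vessel segmentation is explicitly out
  of scope.

The scored territory is exactly the union of the two masks. Polygons
are rasterised by the pixel-centre-inside rule (even-odd; shapely does
the containment test, vertex orientation is irrelevant,
self-intersecting polygons are rejected). Annotations are stored in
world millimetres in a versioned JSON schema with a volume checksum, so
they survive resampling and detect being applied to the wrong
reconstruction.

## Contrast density and the adaptive threshold

Contrast-enhancement strength of a CTA is summarised as
`mean + 2·SD` of the HU values in a circular ROI at the centre of the
aortic lumen at the level of each artery origin, with the sample
(n−1) standard deviation (the ROI is a small hand-drawn sample, not a
population). On contrast-enhanced scans the hand-drawn territory is
normally responsible for excluding lumen; as an optional guard the
scoring threshold can be raised to `max(130, contrast density)`
(`--adaptive-threshold`, off by default, logged when it fires).

## Screening evaluation

* **ICC** — interobserver agreement uses the two-way random-effects,
  single-rater, absolute-agreement intraclass correlation (ICC(2,1)),
  the model in which raters are interchangeable and systematic rater
  offsets count as disagreement; ICC(3,1) is available. Confidence
  intervals use the standard F-distribution construction. Bands:
  <0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, ≥0.9 excellent.
  The implementation is the explicit ANOVA decomposition and is
  cross-checked in the test suite against pingouin.
* **ROC/AUC** — thresholds at the observed unique scores (positive iff
  score ≥ threshold), trapezoidal AUC (equal to the Mann–Whitney
  statistic with ties counted ½), DeLong 95% CI (midrank placements;
  cross-checked against R's pROC). Bands: 0.7–0.8 acceptable, 0.8–0.9
  excellent, ≥0.9 outstanding.
* **Cutoff selection** — Youden's J maximisation; ties broken toward
  higher sensitivity (screening favours not missing disease); the
  reported cutoff is the midpoint between the winning observed score
  and the next lower one, so perfectly separated data yield the gap
  midpoint. Degenerate all-equal scores return the minimum with a
  warning.
* **2×2 metrics** — sensitivity, specificity, PPV, NPV as percentages;
  unrounded values are retained and all internal comparisons use them;
  reports round to one decimal (cohort fractions to integer percent).
  PPV/NPV with an empty denominator are explicit nulls. The
  `negative_fraction_non_cmi` statistic — test-negative *and*
  disease-free as a share of the whole cohort — is the fraction of
  patients in whom further workup could have been avoided.
* **Group comparisons** — Wilcoxon rank-sum (exact for small tie-free
  samples, tie-corrected normal approximation otherwise) for continuous
  variables; chi-square for categorical, switching to Fisher's exact
  when any expected cell count is 5 or fewer (the conservative reading
  of the small-expected-count rule; the exact test is never invalid for
  a 2×2 table).
* **Sign test** — exact two-sided binomial on the sign of paired
  differences; zero differences are dropped and their count reported.
* **Summaries** — median (Q1–Q3) with linear-interpolation quartiles
  (numpy's default), stated here because quartile conventions differ.

## The phantom generator

Phantoms are small abdominal-style volumes: soft-tissue background
(−50 HU), an aortic cylinder, three branch tubes at the CA/SMA/IMA
ostium positions, and uniform-HU ball or box lesions, plus optional
Gaussian noise (seeded). Uniform lesions keep the ground truth
analytic: per slice the exact geometric cross-section area is a closed
form, so the analytic score is `Σ area(z_k) · w · t/3` over slice
centres, with the same `min_area` footprint filter the discrete scorer
applies. Overlapping lesions of different HU are rejected because
their truth would be ambiguous.

Two deliberate departures from realism:

* **Lumen enhancement is 100 HU by default**, below the 130 HU calcium
  floor. Real arterial-phase CTA lumen (several hundred HU) is scored
  as calcium by naive thresholding; human observers avoid this by
  drawing territories that exclude lumen, which an auto-generated
  annotation cannot do. Sub-threshold enhancement keeps the generated
  territories valid; high-contrast lumen remains configurable and is
  what the adaptive threshold is for.
* **No texture, blooming, beam hardening or reconstruction-kernel
  modelling.** Slab averaging (below) is the only acquisition physics.
  Tube voltage is metadata only.

Default phantom geometry places the three ostia 12 mm apart so that no
artery's origin ball (radius = origin diameter, at most 8 mm here)
reaches a neighbouring artery's lesion — otherwise per-artery
scored-vs-analytic comparisons are confounded by territory cross-talk.

**Acquisition simulation.** Thicker reconstructions are modelled by
slab averaging: groups of `round(t_new/t_native)` consecutive slices
are averaged (non-integer ratios fall back to the nearest integer slab,
logged; trailing slices are dropped). This is a first-order
partial-volume model. For lesions smaller than a slab it *raises* the
score on thick slices: dilution lowers the peak HU (smaller weight) but
spreads the above-threshold footprint over the projected lesion area,
and the `t/3` factor then multiplies that area by the full slab
thickness. The paired-protocol test exercises exactly this effect:
29 shared-anatomy pairs scored at 0.8 mm native and ~3 mm slab-averaged
reconstructions give a decisive sign test with the thick-slice score
higher in nearly all pairs — the direction reported for real paired
scans from referral centres (thin protocol) versus referring hospitals
(thick protocol).

**Score cohorts.** `make_cohort` draws per-artery scores from
zero-inflated log-normal distributions — calcium scores are
non-negative, zero in a large fraction of disease-free vessels, and
strongly right-skewed. Defaults (zero fraction, log-median, log-sd per
group and artery) were fitted by least squares to published group
median/IQR summaries; for the disease-free arteries, whose median is 0,
the zero fraction (0.55) and log-sd (1.5) were fixed a priori and only
the upper quartile informs the fit. Arteries are drawn independently —
real per-patient scores are correlated across arteries, so simulated
*combined*-score spreads are somewhat narrower than reality; tests
therefore only assert median containment within the published IQRs, not
distributional match.

## What passing tests do and do not show

The oracle-equivalence tests (flood-fill scorer, pairwise AUC,
exhaustive cutoff search, hand ANOVA) establish that the
implementation computes its definitions exactly. The phantom tests
establish rasterisation convergence (error at 0.25 mm pixels below the
1.0 mm error, within 10% at 0.5 mm) for uniform-HU lesions. None of
this validates the score on real patients: observer ROI placement,
contrast/calcium confusion at lesion borders, and scanner physics are
outside the phantom model. Clinical quantities that depend on the
original patient cohort (AUC ≈ 0.77, ICC ≈ 0.91) are not reproducible
from synthetic data and are not claimed; what is reproduced are the
screening percentages that follow deterministically from the published
group sizes and rates.

## Problem sizes

Default test and acceptance runs use 48×64×64–48×180×180 voxel
phantoms, 29 paired phantoms at 32×48×48, 50 random ≤32³ volumes for
oracle equivalence, and 500 patients per simulated cohort group —
sizes chosen to make every stage of the pipeline measurable in seconds
while keeping rasterisation error in the regime the convergence tests
probe.
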