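# Methods

`mugr` quantifies enteric ganglion density in longitudinal sections of
resected colon using circular muscle units as the spatial yardstick. This
note describes the model behind the synthetic data, the operational
definitions the scorer implements, the numerical choices made where the
protocol leaves them open, and the limits of what the synthetic validation
can show.

## The measurement

A longitudinal strip of colon shows the circular muscle as a band whose
outer edge (the side facing the myenteric plexus and longitudinal muscle)
carries periodic depressions. A **junction** is a valley of that edge at
least 30 µm deep; the tissue between consecutive junctions is one **muscle
unit** (mean width 249 ± 62 µm, measured along a line offset 50 µm inward
from the edge). A **ganglion** is a cluster of at least two HuC/D+ neurons;
an S100B+ structure wider than 40 µm containing no neurons is a
**hypertrophic nerve bundle**. The strip is partitioned into a normal zone
(oral to the first hypertrophic bundle), a transition zone (from that
bundle to the most distal ganglion) and an aganglionic zone.

The **muscle-unit-to-ganglion ratio (MGR)** of a zone is the mean, over
pairs of adjacent ganglia whose interval midpoint lies in the zone, of the
number of junctions strictly between the two ganglion centroids
(equivalently, the difference of their containing-unit indices). In
normally innervated colon nearly every unit holds a ganglion and the ratio
is ~1; in the hypoganglionated transition zone it rises. A secondary
definition — total units over total ganglia per zone — is reported
alongside, since the two coincide only in saturated tissue and the
literature does not fix the aggregation.

## Synthetic tissue model

No imaging data are publicly available for this protocol, so the package
generates ground-truthed sections and treats them as the test bed.

* **Geometry.** Unit widths are truncated normal (mean 249 µm, SD 62 µm,
  floor 80 µm). Junction depths are truncated normal (mean 42, SD 6, floor
  33 µm): every border is a true junction, and staying below 50 µm keeps
  the 50 µm-offset width measurement equal to the unit interval, matching
  how widths are read off in practice. Junctions are rendered as steep
  V-notches (4 µm of depth per µm of half-width); each unit also carries a
  shallow sub-threshold depression (depth uniform on 5–25 µm) with
  probability 0.3, so the 30 µm criterion is genuinely exercised.
* **Zones.** The layout assigns consecutive units to zones (default
  30 normal / 20 transition / 10 aganglionic units), so zone spans tile the
  strip exactly. The *realized* transition zone recorded in the truth is
  re-derived from the placed objects — first hypertrophic bundle to last
  ganglion — exactly as the scorer defines it.
* **Ganglia.** Each unit in a ganglionated zone receives at most one
  ganglion, independently with probability `p` (Bernoulli per unit). The
  gaps between occupied units are then geometric and the expected MGR is
  exactly `1/p`, which makes density recovery analytically checkable.
  Defaults: p = 0.78 in the normal zone and 0.52 in the transition zone
  (reciprocals of ratios ~1.29 and ~1.93); the cohort generator uses
  per-phenotype values (long: 0.74 / 0.485, short: 0.84 / 0.59).
* **Ganglion morphology.** Nuclei are 8 µm disks. Neurons form a chain of
  anchors spaced ≤ 20 µm apart; glia and unlabelled nuclei pack without
  overlap (≥ 8.8 µm centre separation) within 20 µm of a random anchor.
  This morphology is a modelling choice with two deliberate consequences:
  a 30 µm single-linkage cut always keeps one ganglion connected and never
  merges neighbours (nuclei keep an 18 µm margin to unit borders), and
  every member nucleus lies inside the neuron hull dilated by the link
  distance, so cluster membership is unambiguous.
* **Composition.** Nucleus classes are multinomial. The neuron share is
  0.30. The reported glia:neuron ratio of ~2.8 cannot coexist with a 30%
  neuron share and non-negative "other" nuclei (0.30 + 0.84 > 1), so the
  glia share is capped at 1 − 0.30 − 0.02 = 0.68, i.e. an effective ratio
  of ~2.27 with a 2% unlabelled remainder. Recovery tests compare against
  these effective generator values; the per-ganglion mean ratio the cohort
  reports lands near 2.6 (the per-ganglion ratio is upward-biased relative
  to the pooled ratio), inside the published spread.
* **Bundles and stray glia.** The transition span receives three S100B+
  bundles (width uniform on 45–80 µm, length 100 µm), the first placed as
  orally as the ganglion layout allows; bundles keep 34 µm of clearance
  from ganglion nuclei so their image components never fuse with ganglion
  neuropil. Isolated glia (0.15 per unit) are scattered through all zones,
  at least 45 µm from any ganglion so they never join a cluster.
* **Rendering.** Channels are DAPI (all nuclei), Hu (neuron nuclei) and
  S100B (glial nuclei, bundles, and ganglion neuropil drawn as 22 µm disks
  around each neuron anchor with non-glial nuclei left dark, as S100B is
  glial cytoplasm). Images are blurred (σ = 1 px) and carry additive
  Gaussian noise (SD 0.05 of the nuclear intensity) at 1 µm/px. Rendering
  refuses calibrations coarser than 10 µm/px, where a 30 µm valley would
  span fewer than three pixels.

## Segmentation

* **Nuclei**: threshold at 0.5, Laplacian-of-Gaussian blob centres
  (σ ≈ 2.8 µm) as watershed seeds on the thresholded mask, size gate
  15–250 µm². LoG seeding was chosen over distance-transform peaks because
  densely packed ganglion nuclei fuse into one mask component whose
  distance-transform maxima no longer correspond to nuclei.
* **Classification**: a nucleus is a neuron if its mean Hu intensity
  (2 µm disk at the centroid) exceeds `k × background` with k = 2 and
  background the channel median floored at 0.125; else glia by the same
  S100B test; else "other". A channel that is constant and non-zero is
  rejected as degenerate; an all-dark channel is valid (everything is
  simply negative).
* **Boundary profile**: per-column top edge of the muscle mask; the
  baseline envelope is a grey-scale morphological opening with a 400 µm
  window (wider than any junction), making valley depth behave like
  topographic prominence. The band must reach every column and form one
  axis-spanning component.
* **S100B components**: connected regions above intensity 0.25 and
  120 µm²; width is twice the maximum of the interior distance transform
  (maximal inscribed disk), robust for elongated bundles; neuron
  containment is evaluated on the hole-filled region because non-glial
  nuclei appear as dark holes inside real structures.

## Scoring conventions

* The junction criterion is inclusive (depth ≥ 30 µm counts); depth is
  scipy-style peak prominence, and detection is verified sample-exact
  against a brute-force shoulder-scan oracle.
* The >40 µm bundle criterion is strict by default; an inclusive mode
  exists because the source material is ambiguous on the boundary case,
  and the choice is surfaced rather than silently resolved.
* Interval zone assignment uses the interval midpoint; ganglion position
  is the mean neuron centroid.
* Sections are independent replicates; patient scores require ≥ 3 sections
  ("non-consecutive" is metadata, not computable from the images).
* Ties/degenerate cases: duplicate junction positions are rejected; units
  narrower than two profile samples are flagged and reported at interval
  length; zero-variance t-tests return t = 0, p = 1 when the mean
  difference is zero and are flagged degenerate.

## Statistics

Zone comparisons within patients use the classical paired t-test
(df = n − 1); group comparisons use the pooled-variance two-sample t-test
(Welch optional). p-values are two-sided and uncorrected; α = 0.05. The
enterocolitis composition comparison is computed both with patients and
with pooled ganglia as the unit of analysis, labelled accordingly, because
either convention is defensible and they answer different questions.

## Problem sizes used in validation

Width-distribution and density-recovery checks use strips of 2000–5000
units; oracle equivalence uses 500 random instances per operation; the
image path is validated on 20 noiseless and 20 noisy rendered sections of
24 units; statistical calibration uses 1000 synthetic null cohorts (two
groups of five patients, three 20-unit normal-zone sections each) and 100
eleven-patient cohorts for power. These sizes give Monte-Carlo error well
inside the tolerances tested while keeping the default suite to minutes.

## What passing tests do and do not show

The generator reproduces the *counting geometry* of the protocol — unit
widths, valley depths, per-unit ganglion occupancy, bundle widths, class
mixtures — with known truth, so the tests demonstrate that the scoring
definitions are implemented exactly and that the automated image path
recovers the truth under modest noise. Real immunofluorescence differs in
ways the generator does not attempt: tissue deformation and sectioning
artefacts, intensity inhomogeneity and bleed-through, partial ganglia at
the field edge, curved Swiss-roll geometry, and biological irregularity of
nucleus shape and packing. Results on synthetic sections therefore validate
the *method's implementation*, not its clinical performance.

## Known limitations

* One ganglion per unit at most; real transition zones can show clustered
  or partial-circumference ganglia ("leading edge" effects).
* The Bernoulli-per-unit placement is an assumption chosen for analytic
  tractability; the real spatial distribution of ganglia is unknown.
* Manual counting at the microscope has no intensity threshold; all
  positivity thresholds here are artifact decisions, exposed in
  configuration and echoed into run manifests.
* The submucosal plexus and transverse-section analyses are out of scope.
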