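# Methods

`projquant` quantifies the long-range axonal projections of single layer-2/3
pyramidal neurons of the mouse whisker primary somatosensory cortex (wS1,
"barrel cortex") from three-dimensional reconstructions, and estimates
projection-hotspot centres from bulk axon-density volumes. This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic-data pipeline does and does not establish.

## Coordinate conventions

All internal coordinates are millimetres in a bregma-referenced frame:

* `ml` — medio-lateral, midline 0, left hemisphere negative (the default
  model describes a left-hemisphere injection at ml −3.02);
* `ap` — antero-posterior, positive anterior to Bregma;
* `dv` — depth below the pial surface, increasing ventrally.

The injection-site-relative frame differs from the bregma frame by a pure
translation (the site's bregma coordinates); `injection_to_bregma` /
`bregma_to_injection` add/subtract the site and are exact inverses. SWC
files are read in micrometres by default (a `# UNITS mm` header or a flag
overrides this) and converted at parse time.

## Reconstructions and morphometrics

A reconstruction is a rooted tree of sample points with SWC compartment
codes. Invariants enforced on construction: unique ids, a single root,
parent-before-child ordering (which also proves acyclicity), and soma nodes
forming a connected subgraph containing the root. An edge belongs to the
compartment of its child node, so soma-internal cable is never counted and a
soma→neurite edge counts toward the neurite. Dendritic metrics pool basal
and apical compartments. A branch point is a node with ≥ 2 children of its
own compartment; a trifurcation counts once. Group statistics are means with
sample (n−1) SDs; SD is reported as NaN for single-member groups.

## Serial-section stitching

Tracing serial sections yields per-section forests with section-local depth.
Stitching places section *k* at a dv offset of *k* × thickness (0.080 mm for
single-cell material, 0.100 mm for viral material), applies the manifest's
rigid in-plane translation — translation only; no rotation or scaling, which
suffices for manifest-recorded offsets — and re-attaches every non-soma
fragment root to its nearest node in an adjacent section. Rules:

* merge tolerance 5 µm by default (configurable); an endpoint with no
  partner within tolerance aborts the stitch with a report of the unmerged
  endpoints rather than joining silently;
* among several candidates the nearest wins; exactly equidistant candidates
  are an error (no silent tie-break);
* partners closer than 1 nm are collapsed into one node instead of being
  joined by a zero-length edge;
* the merged graph must be a single rooted tree, else a structural error.

The inverse operation (`split_into_sections`) cuts edges analytically at the
section planes, so cutting conserves cable exactly; with the jitter recorded
in the manifest, a split/stitch round trip recovers cable length to floating
point and branch-point counts exactly. No tissue-shrinkage correction is
applied.

## Region model

Target regions are axis-aligned domains in the bregma frame: cortical
columns spanning dv 0–1.2 mm, and the dorsolateral striatum as a subcortical
box at dv 1.5–3.5 mm spanning roughly 0.3–1.7 mm posterior to Bregma. The
packaged default centres the columns on the across-animal hotspot-centre
table (wS1, wS2, wM1/2, PL1, PL2, AM, CM, PM, PP, TeA, striatum). Because
the source estimates are hotspot *centres*, all extents are model choices:
0.4 mm half-extents by default, wS1 sized to the barrel field (1.0 × 1.0
mm), wM1/2 elongated antero-posteriorly (half-extent 0.85 mm; the projection
runs from ~0.4 to ~2.0 mm anterior), TeA elongated antero-posteriorly
(half-extent 0.35 mm). Everything is overridable through a CSV config.

Overlaps are resolved by explicit priority (lower integer wins); wS1 has the
lowest cortical priority so the dysgranular subregions (AM/CM/PM) and wS2
win where they abut the barrel field — the dysgranular/wS1 boundary is
genuinely ambiguous in this system, and per-region lengths for PL/AM/CM/PM
should be read as rough estimates whose dominant uncertainty is the boundary
choice. With 0.4 mm half-extents some neighbouring boxes overlap each
other's centres (PL1/TeA sit 0.32 mm apart); priority makes the assignment
deterministic, and `effective_interior_box` exposes, per region, the largest
box that the priority rules assign entirely to that region. Points in no
region — including everything contralateral (ml > 0) — are `elsewhere`.

Point containment is boundary-inclusive. Cable assignment
(`clip_polyline_to_regions`) splits each segment analytically at region-face
crossings and assigns each piece by its midpoint, so the per-region lengths
sum to the exact segment length (the split parameters telescope).

## Branching vs passing axon

Target regions are distinguished from fibers of passage per connected
component of the region-restricted axonal cable: a component containing at
least one axonal branch point (an axon node with ≥ 2 axon children) located
inside the region is *branching* (target) axon; a component with no
intra-region branch point is *passing* cable. Both tallies are reported per
region, plus `elsewhere`, and always sum to the total axonal cable (checked
on construction at 1e-9 relative). The thresholded projection matrix uses
branching axon with strict thresholds: dark > 10 mm, light > 1 mm; boundary
values fall to the lower class, making the classes monotone in length.
Neurons are classified S2p or M1p by the larger of their wS2 vs wM1/2
branching cable — exact ties (including both zero) are `unclassified` — and
the core fraction is the branching cable in wS1+wS2+wM1/2 over all branching
cable.

## Density volumes and hotspot centres

`voxelize` distributes each axonal segment over an isotropic grid (default
0.04 mm voxels) by analytic clipping at voxel faces; mass is conserved to
floating point, and out-of-grid cable accumulates in a counter with a
warning. `find_hotspot_center` implements the basic centre estimator: the
depth-collapsed map is Gaussian-smoothed (default σ 0.1 mm) and the centre
is the density-weighted centroid of window pixels at or above 50% of the
window peak. Two comparable blobs inside one window therefore yield their
midpoint — by design; the window must separate them.

`aggregate_centers` estimates per-region centres per animal and aggregates
across animals. Design points:

* the depth collapse is restricted to each region's dv band, separating
  striatal from cortical signal the way coronal sections do;
* smoothing uses σ 0.05 mm here: neighbouring hotspot centres sit as close
  as ~0.32 mm (PL1/TeA), and with σ 0.1 their smoothed blobs merge into a
  single maximum;
* local maxima above 5% of the band maximum are candidate hotspots; regions
  are matched to candidates nearest-first (each used once, within 0.9 mm).
  Because injection-site placement translates the entire projection pattern
  coherently across animals, assignment runs twice: the median
  peak-minus-nominal shift from a first pass registers the animal, and the
  final assignment uses shift-corrected expected centres;
* each matched peak is refined with the 50%-of-peak centroid in a ±0.15 mm
  window around it (large enough to hold a blob's half-maximum support,
  small enough to exclude the nearest neighbouring centre);
* per-animal injection-relative coordinates subtract the animal's own
  estimated wS1 centre (unless sites are supplied), which is how the
  injection-relative frame is defined experimentally — the wS1 offset row is
  identically zero by construction;
* a region with signal in no animal is omitted with a warning.

On simulated 5-animal cohorts at the packaged table's printed SDs this chain
recovers every planted mean centre within ~0.01 mm (tolerance used in the
acceptance suite: 0.05 mm).

## Synthetic data: what it emulates

The generator plants every quantity the pipeline measures, exactly:

* soma 200–250 µm deep in the wS1 column; ~8 mm of dendrite on ~8 stems
  with ~64 branch nodes (stems, branch points and total length are realised
  exactly via per-stem caterpillar backbones with 0.02 mm twigs);
* dense local axon inside wS1 (branched serpentine arbor; the planted wS1
  length includes the descending trunk's intra-wS1 run);
* a trunk descending to a white-matter routing depth (0.15 mm below the
  cortical boxes, where no region exists), horizontal white-matter runs to
  below/above each target, and a riser entering the region 0.05 mm deep
  before the arbor — so each planted collateral length is realised exactly
  as intra-region branching cable, strictly interior to the region that the
  priority rules assign it to (`effective_interior_box`, 0.05 mm margin);
* fibers of passage as unbranched serpentines (planted as passing cable);
* cohorts: 6 S2p + 9 M1p by default, per-region lengths drawn from
  zero-inflated truncated normals with class parameters emulating the
  published group statistics (S2p wS1 41.7 ± 1.1 mm, wS2 12.2 ± 7.4 mm, no
  wM1/2 cable; M1p wM1/2 20.8 ± 11.7 mm, wS2 1.6 ± 2.7 mm mostly zero;
  occasional strong striatal/TeA targets). Since the classes are defined
  experimentally by retrograde labeling from the dominant target, M1p wS2
  draws are redrawn while they would exceed the wM1/2 draw, and minor-region
  draws are rescaled when needed so every neuron keeps > 78% of branching
  axon in wS1+wS2+wM1/2, matching the observed core-fraction property.
  Zero-inflation probabilities and the minor-region means/SDs are not
  published per region; they are fixed package choices informed by the
  published per-cell examples (e.g. 12.5 and 16.9 mm striatal arbors, a 7.7
  mm TeA arbor);
* bulk volumes: per animal, an injection site drawn around (−3.02, −1.65)
  with SD (0.06, 0.07) and one isotropic Gaussian blob per region (σ 0.05
  mm, 10 mm of cable) at site + N(offset mean, offset SD), at mid-depth of
  the region's dv band. Equal masses are a deliberately hard case for the
  assignment step (no region is distinguishable by brightness).

Every generator is deterministic given its seed (bit-identical output), and
generator ground truth is computed from the construction itself, never via
the quantification under test.

What synthetic data does *not* emulate: realistic arbor geometry
(tortuosity, taper, boutons), laminar structure of the local axon,
incomplete tracing and labeling, curved cortical surfaces, or contralateral
projections. Passing tests therefore establish the correctness of the
*quantification* (assignment, conservation, thresholds, classification,
stitching, centre estimation) under controlled geometry — not the biological
accuracy of any particular region-boundary choice on real tissue, where the
region-extent choice dominates per-region length uncertainty.

## Problem sizes and numerics

Default problem sizes: cohorts of 15 (study size) to 100 neurons (~500–1500
nodes each), density grids of 150 × 165 × 100 voxels at 0.04 mm, five
animals per bulk simulation. Tolerances: cable conservation 1e-9 relative
(analytic splitting), voxel-mass conservation 1e-6 relative, SWC round trip
1e-9 mm (coordinates are written at full double precision), planted-length
recovery 1e-6 mm, stitched-cable recovery 0.5% with exact branch counts,
hotspot-centre recovery 0.05 mm. Degenerate inputs are errors, not guesses:
zero-length chains, empty profile denominators (core fraction), equidistant
merge candidates, negative thresholds, and infeasible generator targets all
raise typed exceptions.

## Known limitations

* Region boundaries are boxes; no atlas registration or curved coordinates.
  Reproducing per-region cable on real reconstructions depends on the
  boundary choice, most strongly for the dysgranular zones.
* Neurolucida ASC/DAT import is out of scope; deposited data must be
  converted to SWC externally (one file per neuron).
* Stitching supports rigid in-plane translations only, supplied via the
  manifest; it does not estimate alignments from the data.
* The amygdala and other unmodelled structures fall under `elsewhere`
  unless the user adds a region definition.
* Laminar analyses of axon length and contralateral cable are deliberately
  not implemented.
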