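# Methods

## Pipeline model

The scoring system treats a whole-slide image as a raster in a single micron
coordinate frame (origin top-left, half-open pixel intervals, a pixel's
micron position is its top-left corner) and runs three inference stages at
fixed resolutions, each on 512 × 512 px tiles:

1. **Broad cancer segmentation** at 4 MPP (~2.5×): separates broadly
   cancerous tissue from normal tissue and background. Downstream analysis is
   restricted to this mask, so false tissue elsewhere on the slide cannot
   contaminate the score.
2. **Tumour/stroma/necrosis (TSN) segmentation** at 0.5 MPP (~20×), applied
   only within broadly cancerous tissue; pixels outside it are labelled
   `other` regardless of the model output.
3. **TIL detection** at 0.25 MPP (~40×) as heatmap regression: the model
   emits a per-pixel TIL likelihood, decoded to points by local-maximum blob
   detection with a confidence gate, then deduplicated across tile seams by
   point-based non-maximum suppression (NMS) in the micron frame.

Stages are pluggable backends behind a single `predict(tile) -> array`
contract. The shipped backends are deterministic pixel rules keyed to the
synthetic renderer's palette: nearest-palette-colour classifiers for the two
segmentation stages, and a disk-kernel matcher on the TIL-colour mask
(normalised so an isolated full disk peaks at exactly 1.0) for detection.
A normalised cross-correlation detector on raw intensity was considered and
rejected: NCC is contrast-invariant, so in flat-colour synthetic renderings
it produces spurious responses along compartment boundaries; matching on the
TIL-colour mask has zero response there by construction. Trained networks
drop in behind the same contract without touching any downstream code.

## Geometry and units

Tile plans cover the extent with stride `tile − overlap`; edge tiles are
clipped, never padded. Segmentation runs with overlap 0 (reconstruction is a
partition; seams resolved last-writer-wins in row-major order when an overlap
is configured). Detection runs with a 64 px overlap so a lymphocyte on a seam
is fully visible in at least one tile; NMS (radius 4 µm) removes the
duplicates. Class areas are `pixel count × (mpp/1000)²` mm². RGB is
downsampled by block averaging (area-weighted); label rasters resample
nearest-neighbour so class semantics are preserved.

## Stain normalisation

Macenko normalisation operates in optical density, `OD = −log10(I/255)`:
tissue pixels (all OD channels above β = 0.15) are projected onto the top-2
eigenplane of the OD covariance; the stain vectors are the 1st/99th angular
percentiles; per-pixel concentrations are solved by least squares, scaled so
their 99th percentile matches the reference maxima, and re-composited with a
fixed literature H&E reference basis. Fitting is per-tile. Background-only
or single-colour tiles raise a stain-estimation failure, which the pipeline
counts and surfaces as a slide flag. Normalising an image already expressed
in the reference stains changes it by at most 2 intensity levels per pixel
(verified in tests). Normalisation is off by default for the toy backends
(their palette is already canonical) and available via
`analyse_slide(..., normalize_stain=True)` for real scanner data.

## Point codec

Ground-truth heatmaps place an isotropic Gaussian (peak 1.0) at each
annotated point; overlaps combine by pixel-wise **maximum**, not sum, so a
peak value is always a calibrated confidence in [0, 1] — the decoding gate
(default 0.35) thresholds exactly that value. σ defaults to 2 µm (8 px at
0.25 MPP), matching a ~8 µm TIL nucleus. Decoding takes local maxima at or
above the gate, at least 4 µm apart (half the average TIL diameter); the
peak pixel centre is the reported position, with no sub-pixel refinement —
0.25 µm quantisation is negligible against the 4 µm evaluation radius. NMS
is greedy by descending confidence with deterministic tie-breaks (ties by
(y, x) order); a point within the radius (inclusive) of a kept point is
suppressed. The greedy pass is verified bit-exact against an independent
quadratic oracle.

## Field scoring

Detected points are assigned a compartment by nearest-pixel lookup in the
TSN mask; tumour-compartment points are the iTILs, necrosis and unassigned
points are recorded but never scored, stromal points are kept for future
stromal metrics. A non-overlapping grid of squares with the area of a
0.55 mm diameter HPF (side 1000·(d/2)·√π ≈ 487.43 µm, snapped to whole mask
pixels: 975 px at 0.5 MPP, area error < 0.2 %) is anchored at the tumour
bounding-box corner. Fields are half-open so no pixel or point is counted
twice (Σ L_i is conserved exactly). A field is eligible if tumour covers at
least 10 % of its full area — edge fields included, a documented choice where
the field extends past the mask. The patient score is the median of eligible
field densities pooled across all the patient's slides (even count: mean of
the two central order statistics); `score ≥ cutoff` (default 17/mm²) is
TIL-High. The boundary convention at exactly 17.0 is High, configurable.

Reliability flags (all thresholds configurable): tumour area < 1 mm²,
eligible fields < 5 (mirroring the five-field manual practice), cancer
fraction of detected tissue < 5 %, any stain-normalisation failure. Flagged
slides still receive scores; flags mark them for human review and cohort
summaries report the flag rate to one decimal.

## Survival layer

Follow-up is truncated at 1825 days (times beyond it are set to 1825 and
censored; exact 1825 is untouched; the operation is idempotent). Group
comparisons use Kaplan–Meier curves and two-sided log-rank tests; effects are
hazard ratios from Cox proportional-hazards models (lifelines, Efron ties),
univariate or with the full covariate roster. The cut-off search splits
patients into five equal groups (seeded, stratified by event status so each
repeat keeps a stable event count — the split is invariant to row order),
excludes one group per repeat, and scores every integer cut-off 1..100 by the
log-rank p of TIL-High vs TIL-Low; ties resolve by larger |log HR|, then
smaller cut-off, and cut-offs that empty a group are skipped for that repeat.
The consensus is the unanimous optimum when the repeats agree, otherwise the
modal optimum reported as non-unanimous. Stage II clinical high risk is any
of: T4, high grade, extramural venous invasion, lymphovascular invasion,
fewer than 12 nodes examined; all five must be recorded, otherwise the
patient is unclassified.

## Synthetic data: what it emulates and what it does not

The generators provide every input with known ground truth:

- **Layouts** — smooth Gaussian random fields thresholded at quantiles give
  cancer blobs (correlation length ~hundreds of µm) partitioned into
  tumour/stroma/necrosis with requested fractions (realised fractions track
  requests to pixel discretisation). Geometry is sampled on an 8 µm lattice
  and upsampled; tissue correlation lengths are far larger, so no structure
  is lost.
- **TILs** — homogeneous Poisson per compartment with a 6 µm hard-core
  minimum separation (a Matérn-II-style thinning keeps the codec's
  recovery assumptions valid by construction; expected loss < 1 % at the
  densities used). Every point lies strictly inside a pixel of its
  compartment.
- **Rendering** — flat palette colours with ± 3 seeded jitter; lymphocytes
  are 3 µm radius disks in compartment-specific colours, so a colour-rule
  TSN backend maps a lymphocyte pixel to its host compartment, as a trained
  model labels lymphocytes by their surrounding tissue.
- **Heatmaps** — planted Gaussians with peaks in [0.6, 1.0], optional decoy
  blobs with peaks in [0.05, 0.30] (below the 0.35 gate) and additive noise,
  emulating the faint spurious responses of a real detector.
- **Cohorts** — log-normal iTIL scores (median 17, σ_log 0.6); patients below
  the planted cut-off carry `HR×` the baseline exponential hazard
  (5 × 10⁻⁴/day ≈ 60 % events by five years); independent exponential
  censoring at 10⁻⁴/day. Covariates are drawn independently of outcome, so
  they double as negative controls in Cox fits.

None of this is photorealistic: there is no nuclear texture, no staining
gradient, no scanner noise, no mucin, and the toy backends are near-perfect
by construction. Passing tests therefore demonstrate that the *pipeline
machinery* — geometry, codec, restriction rules, scoring arithmetic,
statistics — is correct with controlled inputs; they say nothing about the
accuracy of any particular trained segmentation or detection model on real
tissue, which must be validated separately behind the backend contract.

## Study conditions for the recovery tests

End-to-end density recovery uses a tumour-dense, resection-like layout
(cancer fraction 0.95; TSN fractions 0.92/0.06/0.02; blob scale 1 mm; TSN
scale 0.6 mm), three 4.2 × 4.2 mm slides pooled per patient (~200 eligible
fields), planted densities λ ∈ {5, 17, 60}/mm², fixed seeds. Confluent
tumour sheets larger than one field are the regime the score is designed
for, and pooling across slides exercises the multi-WSI median. Survival
recovery uses 50 cohorts of n = 1000 (planted HR 2.0) for the Cox band and
20 cohorts of n = 400 for the cut-off search (planted cut-off 17, recovered
within ±2 in ≥ 90 % of runs).

## Known limitations

- **Score quantisation at low density.** Field counts are integers, so
  per-field densities move in steps of `1/T_i` — ≈ 4.21/mm² for a fully
  tumour-covered field. The median score inherits this lattice: at a true
  density of 5/mm² the nearest achievable median is 4.21 (−16 %), and with
  many partial-tumour fields the median collapses toward 0 because most
  fields contain no TIL at all. Recovery within 10 % is therefore
  structurally impossible below roughly 8–10 iTILs/mm², and the
  corresponding end-to-end assertion at λ = 5 fails for exactly this reason
  (the λ = 17 and λ = 60 recoveries pass). Near the clinically relevant
  cut-off the quantum is ~25 % of the score, which is why the binary call,
  not the raw score, is the clinical output.
- The 10 % field-eligibility test uses the full field area for edge fields;
  assessing it on the within-slide portion would admit slightly more edge
  fields.
- The toy TIL detector assumes the renderer's palette; it is a test
  instrument, not a lymphocyte detector for real H&E.
- No stromal-TIL or combined metric, no mucin class, and no time-varying or
  competing-risks survival models.
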