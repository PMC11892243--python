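# itilscore

Automated intraepithelial tumour-infiltrating-lymphocyte (iTIL) density
scoring for H&E-stained colorectal-cancer whole-slide images, with the
survival-analysis layer used to discover and validate a prognostic cut-off.

TILs on routine H&E slides are a well-established prognostic biomarker in
colorectal cancer: patients with dense lymphocyte infiltration of the tumour
epithelium relapse less and live longer. Manual scoring (counting TILs in
five high-power fields, HPFs) is slow and rater-dependent. This package
implements a fully automated, interpretable alternative for pathologists and
computational-pathology researchers: it localises cancerous tissue, separates
tumour / stroma / necrosis, detects individual TILs as points, and reduces
everything to one number per patient — the **AI iTIL score**

```
score = median_i ( L_i / T_i )        [iTILs per mm² tumour]
```

where the slide is covered by square fields with the same area as a 0.55 mm
diameter HPF (side ≈ 487.4 µm), `L_i` is the number of detected TILs whose
coordinate falls in tumour epithelium within field `i`, `T_i` is the tumour
area (mm²) in that field, and only fields with ≥ 10 % segmented tumour
contribute. Thresholding the score at **17 iTILs/mm² tumour** yields the
binary TIL-High (better prognosis) / TIL-Low call; 17/mm² is equivalent to
the manual criterion of 2 TILs/HPF when about half of an HPF is tumour.

## What is in the box

- `itilscore.geometry` — shared micron coordinate frame, tile planning,
  raster reconstruction, physical areas (`mm²`), resampling.
- `itilscore.stain` — Macenko stain normalisation (optical-density plane,
  angular percentiles, concentration rescaling to a reference basis).
- `itilscore.points` — the point-detection codec: Gaussian target heatmaps,
  blob decoding with a confidence gate (default 0.35), point-based
  non-maximum suppression across tile seams.
- `itilscore.backends` — contracts for the three model stages (broad cancer
  segmentation at 4 MPP, TSN at 0.5 MPP, TIL detection at 0.25 MPP) plus
  deterministic toy backends so the whole pipeline runs without trained
  networks; trained-model adapters plug in behind the same `predict` contract.
- `itilscore.scoring` — compartment assignment, HPF-equivalent field grid,
  per-field densities, median aggregation, classification, reliability flags,
  cohort summaries.
- `itilscore.evaluation` — distance-matched detection metrics (4 µm radius),
  average precision, confidence sweeps, segmentation Dice/F1.
- `itilscore.survival` — 5-year censoring, Kaplan–Meier + log-rank, Cox
  proportional hazards (lifelines), the five-group jackknife cut-off search,
  Stage II clinical-risk stratification.
- `itilscore.synthetic` — seeded generators for tissue layouts, planted TIL
  point processes, model-like heatmaps and survival cohorts with known ground
  truth; the test bed for everything above.

## Worked example

`examples/score_synthetic_slide.py` builds a 2 × 2 mm synthetic slide with a
planted iTIL density of 40/mm² tumour and runs the full pipeline:

```
planted iTILs: 75 over 2.06 mm^2 tumour (density 36.5/mm^2)
detected TILs within cancer: 81
eligible fields: 19 of 25
AI iTIL score (median of per-field L_i/T_i): 36.68 per mm^2
flagged: False
```

The detector recovers the planted TILs (plus the planted stromal TILs, which
are never scored), 19 of 25 grid fields contain enough tumour to be eligible,
and the median per-field density lands at 36.7/mm² against a realised planted
density of 36.5/mm² — a TIL-High call at the 17/mm² cut-off.

`examples/survival_cutoff_search.py` simulates a 400-patient cohort whose
risk truly changes at a score of 17 (hazard ratio 2 for TIL-Low) and
rediscovers the threshold from survival data alone:

```
consensus cut-off: 17 (unanimous across repeats: True)
univariate HR (TIL-Low vs TIL-High):   2.379  [1.844, 3.070]  p < 1e-10
log-rank p (TIL-High vs TIL-Low): 6.84e-12
```

The other examples cover detection evaluation (`detection_evaluation.py`)
and the manual-to-automated threshold conversion (`hpf_equivalence.py`).

A thin CLI mirrors the main workflows:

```bash
itilscore simulate --out sim/ --seed 3 --lambda-tumour 40
itilscore score --slide sim/slide_rgb.png --mpp 0.25 --out scored/
itilscore evaluate --pred scored/slide_detections.csv --gt sim/planted_points.csv
itilscore cutoff-search --cohort sim/cohort.csv --grid 1:100 --seed 7
```

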