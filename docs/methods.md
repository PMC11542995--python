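# Methods

## The biotic paleothermometer

The package estimates sea-surface temperature (SST) from presence/absence of
marine taxa whose habitat-temperature preferences are known or assessable.
Each taxon carries a thermal-tolerance interval [t_min, t_max] (°C); an
occurrence of that taxon in a collection is treated as evidence that local
SST lay inside the interval, summarized by the interval midpoint. The
approach leans on *taxonomic sufficiency*: genus- or family-level identity is
generally sufficient to capture community-scale ecological signal, so
occurrence compilations built from regional range charts are usable without
species-level revision. Estimates rely on presence of taxa only and are
therefore largely insensitive to sampling intensity, but they inherit every
bias of the tolerance assignments themselves.

Key assumptions:

- tolerance intervals are stationary over the interval analysed (defensible
  for the shelly benthos and nekton the method targets, not for groups with
  known niche drift);
- tolerance midpoints are a noisy but unbiased reading of local SST;
  narrower intervals are more informative, hence the width-based screening;
- paleolatitudes supplied with the records (from a plate-rotation model) are
  treated as exact inputs — no rotation is computed here;
- seasonality, currents, salinity anomalies and other local oceanographic
  effects are not modelled.

## Screening rules

`ScreeningConfig` defaults (all configurable):

| parameter | default | meaning |
|---|---|---|
| `max_tolerance_width` | 5.0 °C | widest interval still admissible |
| `narrow_cutoff` | 3.0 °C | narrow/moderate class boundary |
| `deep_cutoff_m` | 300 m | habitat depth separating shallow from deep |
| `exclude_deep` | true | drop deep-water records |
| `exclude_overlap` | true | drop grade-straddling (exotic) taxa |

Boundary semantics are inclusive upward: width exactly 3.0 °C is narrow,
exactly 5.0 °C is moderate (and admissible). The admissible set is closed at
5 °C because the two published class counts (narrow ≤3 °C plus moderate
3–5 °C) sum to the admitted total. Widths are compared after rounding at the
nano-degree so binary representation noise (12.3 − 7.3 exceeding 5 by one
ulp) cannot flip a boundary classification.

The deep-water cutoff is quoted in the literature as a 250–300 m band; the
default takes the permissive upper bound and exposes the value in config.
Records with unknown depth are retained (with a logged warning), because the
exclusion targets taxa *exclusively* found in deep water. Deep-water
exclusion is tallied three ways — records removed, taxa whose admissible
records are all deep, collections consisting only of deep records — since
published summaries quote such exclusions against different denominators.

The exotic/overlap rule uses two user-set temperature grades (warm "red",
cold "blue"). Membership can be judged by interval midpoint (default),
containment, or any-overlap; a taxon classified "both" under the chosen rule
has all of its records removed, mirroring the practice of provisionally
excluding rare migrants whose conflicting signal would otherwise need
case-by-case expert scrutiny. Exclusion is at taxon level because the rule
targets taxa, not individual occurrences.

## Estimator

`EstimatorConfig` defaults: `bin_width` 10°, `tukey_k` 1.5,
`quartile_method` `interp_orderstat`, `dedupe_mode` `unique`, `min_bin_n` 5.

- **Binning.** Labels are the nearest multiple of the bin width; bin *b*
  spans [b − w/2, b + w/2), boundary values going to the higher label. Sign
  is preserved, so hemispheres never merge (outside the equator-straddling
  bin 0). Center-labelled bins were chosen because published per-bin tables
  label bins 10, 20, 30, 40 for data spanning roughly 5–45°.
- **Deduplication.** Identical intervals (bounds equal after rounding to
  0.01 °C, absorbing text-parsing noise) collapse to one value. The robust
  statistics operate on the unique-interval midpoints by default: repeated
  records of one taxon are redundant evidence about one interval, not
  independent draws. `dedupe_mode="weighted"` (each interval counted with
  its multiplicity) is provided for calibration against datasets whose
  published statistics imply record-level weighting.
- **Quartiles.** Three conventions are selectable because published tables
  rarely state one: linear interpolation of order statistics at p·(m−1)
  (default, numpy's `linear`), Tukey hinges (`inclusive`), and p·(m+1)
  interpolation (`exclusive`). Q1/Q3/IQR are reported from the pre-Tukey
  deduplicated midpoints so the published IQR is the same one that defined
  the outlier fences; `quartiles_post_tukey=true` switches to post-filter
  quartiles.
- **Tukey filter.** One pass, inclusive fences [Q1 − k·IQR, Q3 + k·IQR],
  k = 1.5. With IQR = 0 (constant data) the fences degenerate to a point and
  equal values survive — the filter never empties a bin. The pass is not
  iterated: a second application can remove further points (fences shrink),
  and the procedure is defined as a single cleaning step.
- **Hodges–Lehmann.** The pseudo-median is the exact median of all
  m(m+1)/2 Walsh averages including self-pairs, computed by enumeration
  (bins hold at most a few hundred unique intervals, so the O(m²) cost is
  irrelevant). Even-length medians average the two central order statistics.
  No confidence interval is attached; a bootstrap would be a natural
  extension but is out of scope.

Bins with fewer than `min_bin_n` records are flagged `low_confidence` rather
than suppressed. Empty bins are simply absent. The per-stage trend is the
piecewise-linear interpolation through (bin, HLM) points — deliberately not
smoothed. Stage-level series report the unweighted mean of bin HLMs plus the
min/max of admitted midpoints, ordered by the bundled stage table.

The bundled stage table covers the Devonian–Triassic in 29 stage-level
slices (ICS ages). The full ICS list has 30; the Rhaetian is omitted as the
slice essentially unrepresented in the Siberian marine record the format
was designed around. Stage names match case-insensitively after trimming,
with an editable alias map for regional (Russian) stage synonyms.

## Climatic zones

Published shallow-water habitat ranges are encoded verbatim: tropical
20–35 °C, subtropical 18–25 °C, warm temperate 12–20 °C, cool temperate
4–10 °C, polar 0–4 °C; deep-water: tropical ≤ 12 °C (lower bound set
operationally to 5 °C), warm temperate 5–7 °C, cool temperate 1–4 °C. The
tropical/subtropical overlap (20–25 °C) and the 10–12 °C gap are preserved,
not repaired; `zones_for_temperature` may therefore return two zones or
none, and deterministic disambiguation lives solely in `nearest_zone`
(closest range, ties toward the warmer zone — every temperature in
[0, 35] °C is within 2 °C of some zone). All bounds are inclusive, matching
"from a to b" phrasing of the source ranges.

The nominal latitude bands (|lat| < 25° tropical, 25–35° subtropical,
35–50° warm temperate, 50–65° cool temperate, ≥ 65° polar) are a declared
convention — the published zonation is graphical only — used solely by the
plate-model consistency check and overridable through the zone-table CSV.
"Middle latitudes" (12–20 °C) are identified with the warm-temperate belt of
the five-zone list; the identification is implied but not stated in the
source material. A bin is "consistent" with a plate-model latitude when the
model's zone is among the zones matching the bin temperature, or, for
gap temperatures, equals the nearest zone.

## Synthetic data generator

`SyntheticSpec` defaults define the study conditions the tests measure
against: one stage, latitudes 5–75°, linear gradient T(l) = 25 − 0.25·l °C
(≈23.8 °C tropical to ≈6.3 °C near-polar — a plausible mid-Paleozoic
gradient), 200 taxa with tolerance widths uniform on 1–5 °C centred on the
taxon's local temperature plus N(0, 1 °C) noise, ~8 records per taxon
scattered within ±1° of its home latitude (so records greatly outnumber
unique intervals), 9% of taxa exclusively deep-water (cold 1–6 °C intervals)
and 3% exotic. Bounds are rounded to 0.1 °C as real tolerance tables are.
All randomness flows from a mandatory seed.

Exotic taxa model warm-water migrants at high latitude: they are planted in
the coldest quarter of the latitude range with intervals centred near local
temperature + `exotic_offset` (default +10 °C) and slid minimally so the
interval straddles the red/blue grade gap (13.5–16.5 °C by default); their
widths are drawn from [gap + 0.5, 5] °C so they stay admissible. Native
intervals that would straddle the gap by chance are nudged just off it.
This makes the planted exotics *identifiable by construction* — the overlap
rule recovers exactly the planted 3%, which is what the recovery tests
assert; the nudge displaces a small fraction of native midpoints near
15 °C by under half a degree, a bias absorbed by the ±1 °C recovery
tolerance. A pure offset without the slide cannot guarantee recovery, since
a ≤5 °C-wide interval shifted by +10 °C generally lands entirely inside the
warm grade.

What the generator deliberately does not emulate: taphonomic loss, uneven
sampling effort, stratigraphic miscorrelation, niche evolution, asymmetric
tolerance intervals, and spatially correlated noise. Passing recovery tests
therefore demonstrate that the pipeline's statistics are correct and
unbiased under the stated model — not that real tolerance compilations are
free of systematic error.

## Verification problem sizes

The test suite checks the pseudo-median against brute-force Walsh-average
enumeration exhaustively for all 1286 multisets of size ≤ 8 over a 5-value
grid plus 1000 random samples of size ≤ 40; Tukey conservation and
inside-fence identity over 1000 random samples each; and parameter recovery
on the default synthetic conditions (seed 42, ≥ 100 records per bin, every
bin within ±1 °C of truth, monotone trend, exact 9%/3% planted-exclusion
recovery). `scripts/acceptance.py` re-runs the recovery pipeline at a
user-supplied seed and writes the measured errors, slope and exclusion
percentages.

## Known limitations

- Tolerance assignments are inputs; the package cannot detect systematically
  mis-assessed taxa (only gross outliers and grade-straddlers).
- The latitude bands attached to climatic zones are conventions; consistency
  verdicts near band boundaries are correspondingly soft.
- The relational-deposit loader is configuration-driven (`JoinSpec`) because
  deposited table schemas vary; defaults follow the package's flat format
  and will usually need a column map for third-party deposits.
- Equator-straddling data mix hemispheres in bin 0; supply hemisphere-split
  inputs if that matters.
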