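# paleotherm

Sea-surface paleotemperature (SST) estimation from the taxonomic composition
of fossil assemblages.

Many marine invertebrate groups (corals, fusulinids, ammonoids, bivalves,
brachiopods, ostracods, conodonts…) have habitat temperature preferences that
are stable enough, at genus or family level, to serve as a biotic
paleothermometer: each taxon carries a thermal-tolerance interval
[t_min, t_max] in °C, and the mixture of taxa found together in a collection
constrains the water temperature at that place and time. `paleotherm` turns
occurrence tables built on this idea — one row per taxon occurrence with a
chronostratigraphic stage, a paleolatitude and a thermal-tolerance range —
into robust per-latitude temperature estimates, stage by stage. It is aimed
at paleontologists and paleoclimate/paleotectonic workers who have such
occurrence compilations (e.g. regional range-chart databases of the PaleoSib
kind) and want reproducible, scriptable temperature reconstructions rather
than hand-curated spreadsheets.

## Method

For each stage and each 10° paleolatitude bin:

1. **Screening.** Only taxa whose tolerance width w = t_max − t_min is at
   most 5 °C are informative (w ≤ 3 °C "narrow", 3 < w ≤ 5 °C "moderate").
   Records of exclusively deep-water taxa (habitat below ~250–300 m) are
   excluded: they track cold intermediate water, not the surface. Taxa whose
   tolerance straddles both a warm ("red") and a cold ("blue") temperature
   grade — rare out-of-zone migrants — are excluded at the taxon level.
2. **Reduction.** Each record contributes the midpoint (t_min + t_max)/2;
   identical intervals are collapsed, giving *n.int* unique intervals from
   *n* records.
3. **Outlier removal.** A single pass of Tukey's fences
   [Q1 − 1.5·IQR, Q3 + 1.5·IQR] on the unique-interval midpoints.
4. **Location.** The bin temperature is the Hodges–Lehmann pseudo-median —
   the median of all Walsh averages (xᵢ + xⱼ)/2 over pairs i ≤ j — which is
   robust to the distinctly non-normal distribution of tolerance midpoints.

Each bin reports n, n.int, HLM, Q1, Q3 and IQR. A climatic-zone table
(tropical 20–35 °C, subtropical 18–25 °C, warm temperate 12–20 °C, cool
temperate 4–10 °C, polar 0–4 °C shallow-water, with deep-water counterparts)
translates bin temperatures back into latitude belts, so estimates can be
checked for consistency against the paleolatitude a plate-tectonic model
assigns — disagreements flag either exotic faunas or questionable terrane
reconstructions. A seeded synthetic-data generator with a known latitudinal
gradient and planted deep-water/exotic contamination makes the whole pipeline
testable end to end without any external download.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```sh
paleotherm simulate --seed 42 --out occ.csv --truth truth.csv
printf 'screening:\n  red_range: [16.5, 45.0]\n  blue_range: [-5.0, 13.5]\n  membership_rule: overlap\n' > cfg.yaml
paleotherm run --config cfg.yaml --input occ.csv --outdir results
head -4 results/bins.csv
```

which prints

```
Stage,Paleolatitude,n,n_int,HLM,Q1,Q3,IQR
Pragian,10,218,29,22.4250,21.4500,23.2000,1.7500
Pragian,20,168,25,20.0000,19.1000,20.9500,1.8500
Pragian,30,131,21,17.6250,16.6500,18.6000,1.9500
```

The simulated world has true SST T(l) = 25 − 0.25·l, so bins 10/20/30 should
read 22.5/20.0/17.5 °C: 218 records at bin 10 collapse to 29 unique
intervals whose pseudo-median, 22.425 °C, recovers the truth to within
0.1 °C. The screening report (`results/report.json`) shows 1592 input
records, with 140 deep-water and 53 grade-straddling records removed —
tracing back to exactly the planted 9% and 3% of taxa — and `results/manifest.json`
records the exact configuration, input digests and per-stage counts needed to
reproduce the run bit-identically.

Every subcommand (`simulate`, `screen`, `estimate`, `trend`, `zones`, `run`)
is a thin wrapper over library functions in `paleotherm.*`; the same pipeline
is available programmatically via `read_occurrences` / `screen` /
`estimate_stage` / `check_consistency`.

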