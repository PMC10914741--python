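# Methods

## The parsing model

`gatherparse` treats an aggregated occurrence download as a mixture of
*gatherings* — unique collection events — each represented by one or more
digital duplicates. The workflow recovers the gathering structure from three
fields that duplicates share by construction (plant family, primary
collector's surname, collection number), then resolves the conflicts that
duplicates accumulate (identifications, coordinates, descriptive fields) by
scoring and merging rather than by discarding.

Key assumptions:

- **The event key is sufficient.** `FAMILY_SURNAME_COLLECTIONNUMBER`
  identifies a gathering as long as the collector's surname and number were
  transcribed consistently enough to normalize to the same form. Collection
  date would discriminate better but is too often absent to be usable; the
  family prefix guards against common surnames with low collection numbers
  colliding across families.
- **GBIF issue flags are a usable proxy for spatial quality.** No coordinate
  validation of our own is performed; records are ranked purely by the
  severity of the geospatial issues GBIF already attached (dedicated cleaning
  tools are the right place for active coordinate checks).
- **Duplicates vote on the taxon.** The accepted name most frequently applied
  at or below species rank across a gathering's duplicates is taken as the
  event's identity. Synonyms are resolved to accepted names *before* counting,
  so two synonymous determinations reinforce rather than split the vote.

## Scores and parameters

| Parameter | Default | Meaning |
|---|---|---|
| spatial score | 0 / −1 / −3 / −9 | impact class of the worst geospatial issue flag: none / low / medium / exclude |
| completeness score | 0–10 | number of populated key fields (ten unit flags; the country flag is the *absence* of GBIF's COUNTRY_INVALID issue) |
| field profiles | 54 (`standard`), 257 (`all`) columns | shipped as versioned text config (`src/gatherparse/data/*_profile.txt`) |
| issue table | 33 geospatial categories | shipped CSV config (`issue_scores.csv`), user-overridable |
| mergeable fields | habitat, fieldNotes, locality, municipality, stateProvince, countryCode, year, month, day, elevation, (lat, lon) | fields describing the gathering itself; identification history is never merged |

A record with unparseable or missing coordinates is forced to spatial score
−9 for the partition regardless of its issue flags: whatever its issues say,
it cannot support spatial analysis. COUNTRY_INVALID sits in the issue table
with impact *none* so it is tracked and counted, but it affects only the
completeness flag, not the spatial score.

Per-record aggregation over multiple issues uses the minimum (worst) score: a
record excluded for one reason stays excluded. Adding a flag can therefore
never improve a record's rank (tested as a property).

## Deterministic tie-breaks and degenerate inputs

- **Voucher selection**: highest total (spatial + completeness); ties broken
  by higher completeness, then lexicographically smallest record id. Output is
  therefore invariant under row permutation.
- **Consensus taxon**: plurality of accepted names at or below species rank;
  frequency ties resolve to the alphabetically first name; no species-level
  determination → `UNIDENTIFIED` (and the voucher is partitioned unusable).
- **Merging**: donors are scanned in descending total score (ties by record
  id); a non-empty voucher cell is never overwritten, so merging is a
  monotone fill and re-running the workflow on an already-parsed single-record
  dataset is a no-op. The coordinate pair moves atomically and is never taken
  from a donor whose own spatial score is −9 — a flagged-invalid coordinate
  must not leak into a voucher.
- **Incomplete keys**: records whose key lacks a surname (tagged
  `UNKNOWN-COLLECTOR`) or number receive their own record id as a singleton
  key; they are scored and partitioned like any event but have nothing to
  merge. The useable partition does not additionally require a complete key:
  an identified, spatially valid singleton is useable.
- **Name matching**: exact on the standardized string, ignoring authorship;
  among homonym rows a single Accepted row wins, several conflicting
  resolutions return `ambiguous` rather than a guess, and a synonym chaining
  to another synonym is reported `ambiguous`, not chased. An infraspecific
  string that misses falls back to its binomial, with the fallback recorded.
- **Hybrid notation**: `×` glued to an epithet always separates; a plain `x`
  separates only when followed by a consonant, so genuine x-initial epithets
  (*xanthocarpa*, *xerophila* — always x + vowel) survive intact. A glued
  hybrid epithet that itself starts with a vowel (`xalba`) is the one case
  this heuristic misses; it would need the `×` sign to be recognized.
- **Surname extraction**: first collector token (split on `;`, `|`, `&`,
  " and ", numbered lists), team suffixes ("et al.") stripped, then text
  before the first comma if present else the last word, folded to uppercase
  ASCII. Particles are kept only when they precede the comma ("de Melo, P." →
  `DE MELO`); "Initials Surname" strings keep only the final word, so an
  uncommaed multi-word surname loses its particle — a known limitation of the
  dialect heuristic, mitigated by the curated dictionary, whose exact-match
  lookup always overrides the heuristic.

## The synthetic-data generator

`gatherparse.synth` generates occurrence tables with known gathering
structure: each event carries one true taxon, collector and coordinate, and
each duplicate is rendered through realistic transcription dialects
(`"Gardner, G."`, `"G. Gardner"`, team strings, `"et al."`, diacritic-stripped
variants) and independently corrupted by the error modes aggregated data
exhibits — conflicting identifications, synonym substitution, lost collection
numbers or collectors, swapped or zeroed coordinates, centroid substitution
and dropped descriptive fields. Injected GBIF issue tokens stay consistent
with the injected coordinate errors (a zeroed coordinate carries
`ZERO_COORDINATE`, a swap carries `PRESUMED_SWAPPED_COORDINATE`, and so on).
All randomness flows through one seeded generator; a fixed scenario is
byte-reproducible.

Default study conditions: events sized by a Poisson with mean 1.4 records
(truncated at 1), matching the overall duplication level of a large aggregated
family download (~1.4 records per gathering); default per-duplicate error
rates (identification conflicts 10%, synonym substitution 15%, missing number
5%, missing collector 2%, coordinate swap 1%, zero coordinate 1%, centroid 2%,
per-field drop 15%) describe a plausibly messy download. The noiseless
recovery scenario (200 events × 3 duplicates, all rates 0) is the exactness
benchmark: the pipeline must return exactly 200 useable events, 400
duplicates, 0 unusable and 100% correct consensus taxa.

What the generator does **not** emulate: the spatial clustering, collector
network structure and institution-specific error correlations of real
aggregated data, cross-family misidentifications (all records carry one
family), and the long tail of free-text anomalies in real `recordedBy`
strings. Passing tests therefore demonstrate the correctness of the parsing
logic under controlled error modes, not the field-level recall of the
workflow on any particular real download.

## Numerical and I/O choices

- All occurrence I/O is the GBIF "simple download" dialect: tab-delimited
  UTF-8, header row, no quoting (a literal `"` is data); `NA`, `\N` and
  similar spellings canonicalize to the empty string on read.
- Richness grids index cells by `floor(coord / cell) * cell` on signed
  degrees — half-open cells with the west/south edge inclusive, unambiguous at
  negative coordinates. A taxon counts once per cell; the percent difference
  between two grids is `100 (a − b) / a` relative to the first (pre-parse)
  grid, with cells absent from one grid counted as 0 there and cells empty in
  the reference grid returning NaN.
- Problem sizes in the shipped tests and the acceptance script (hundreds of
  events, thousands of records) are chosen to exercise every code path and
  tie-break while keeping a full run in seconds; the workflow itself is
  O(records) with a per-group scan and handles full-family downloads
  streaming through pandas.

## Known limitations

- Duplicates of one gathering identified in *different families* produce
  different keys and cannot merge; the key design accepts this.
- The collector dictionary's standardized surname does not identify a unique
  person — it is a grouping key, not a person record.
- No fuzzy name matching: a misspelled determination is `unmatched` and the
  record can only contribute to an event's consensus if another duplicate
  carries a matchable name.
- Vouchers selected while lacking coordinates remain `unusable` even when a
  duplicate later donates coordinates during merging; the donated coordinates
  are exported for manual review rather than silently promoting the record.
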