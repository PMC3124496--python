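# Empirical fixture transcription checklist

The empirical analyses (31-taxon sphaerexochine character matrix, and the
geodispersal/vicariance area matrices) were published as supplementary
**DOC** tables plus a figure with per-taxon area codes. This package never
parses DOC files: the tables must be transcribed by hand into the four CSV
files below, placed in this directory. `sphaerexo.load_paper_fixtures()`
validates them on load, and the empirical acceptance tests
(`tests/test_acceptance.py`) run against them automatically once present.

No transcriptions ship with this repository because the source DOC payloads
were not available when it was built — only their captions. Until the files
exist, fixture-dependent tests fail with a pointer to this checklist, and
`sphaerexo reproduce` marks each empirical target as skipped with a reason.

## 1. `table_s1.csv` — character matrix (31 taxa × 39 characters)

CSV layout (see `sphaerexo.matrix_io`): header row `taxon,0,1,...,38`, one
row per taxon, single-digit states, `?` for missing, `0/1` for polymorphic
cells.

- [ ] 31 rows, 39 character columns (loader enforces this).
- [ ] Taxon names as in the taxa list, spaces replaced by underscores
      (e.g. `Forteyops_sexapugia`, `S_romingeri`).
- [ ] States transcribed column by column against the character list
      (all characters use states 0–2).
- [ ] `Forteyops_sexapugia` present — it is the outgroup for rooting.

## 2. `table_s2.csv` / `table_s3.csv` — geodispersal / vicariance matrices

CSV with the area name in the first column (`BiogeoMatrix.from_csv`):
rows = the 7 areas plus the all-zero `ANCESTOR` row; columns = one ordered
character per node/terminal of the area cladogram; states 0/1/2.

- [ ] Area row labels exactly: `Avalonia`, `Baltica`, `Bohemia`,
      `E_Laurentia`, `NW_Laurentia`, `Yangtze`, `Australia`.
- [ ] `ANCESTOR` row identically 0 (loader enforces this).
- [ ] Every cell in {0, 1, 2}.
- [ ] Note any extra/duplicated columns relative to the node+terminal count
      in `MANIFEST.md` (the coding-rule regeneration test compares
      column-for-column).

## 3. `fig5_areas.csv` — per-taxon area occurrences

Rows `taxon,area1;area2`, using either area names or the integer codes
1–7 (1 = Avalonia … 7 = Australia). These come from the bracketed codes
printed next to each terminal in the published consensus figure.

- [ ] One row per terminal taxon, every taxon assigned ≥ 1 area.
- [ ] `S_eurys` coded as `E_Laurentia` (Scotland treated as part of
      Eastern Laurentia in the source analysis).
- [ ] Taxa whose codes are illegible in the figure: leave the row out and
      record the omission in `MANIFEST.md` — the loader will reject the
      file until all consensus terminals are covered, making the gap
      explicit rather than silently invented.

## 4. `MANIFEST.md` — provenance notes

For each file record: source table/figure, date transcribed, transcriber,
and any judgment calls (illegible cells, naming normalizations).
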