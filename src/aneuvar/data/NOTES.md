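# Transcription notes for the bundled reference tables

These TSVs transcribe the published study tables of a ten-gene aneurysm-panel
screen of 155 abdominal aortic aneurysm (AAA) patients (99 familial, 56
sporadic), used here as golden fixtures.

* `table2_variants.tsv` — the 47 reported variants with their full evidence
  bundle and the published class as `gold_class` (P 2, LP 1, VUS 21, LB 23).
  The composite "MAF/MAC" cell is split into `maf_primary`/`mac_primary`;
  an em-dash (no frequency on record) is transcribed as empty = absent,
  never 0. Mixed segregation annotations ("-/nd", one family tested and
  non-segregating) are transcribed as `does_not_segregate`. The "gem"
  annotation (affected concordant twins carrying the variant) is transcribed
  as `segregation=twins`.
* `table4_patients.tsv` — the 13 published multi-variant patients (T4-*) plus
  the single-variant carrier records (F-*/S-*) reconstructed so that every
  per-variant familial/sporadic observation count in `table2_variants.tsv`
  is matched exactly. This reconstruction yields 31 familial and 11 sporadic
  carriers; the source text prints "12 sporadic" but no assignment of the 13
  sporadic observations to 12 patients is consistent with the other tables
  (2 multi-variant patients x 2 + 9 singletons = 11 carriers). Each
  concordant twin pair is one enrolled index record (`twin_pair_id` set);
  the co-twin exists only as the segregation annotation. The published
  row-13 labels swap the classes of MYLK c.3583A>G and c.5079G>A relative to
  the variant table; the variant table is authoritative for classes, the
  patient table only for grouping.
* `table3_genotypes.tsv` — MTHFR c.665C>T genotype counts per study/group
  with the printed MAF retained in `maf_printed` and the pooling arm in
  `pool_arm` (`subset` rows are sub-divisions of the current study and are
  excluded from pooling). One printed MAF (Strauss control, 0.231) does not
  recompute from its printed cells (32/150 = 0.213) and is flagged in
  `note`; the "<60 years" TT percentage prints 6 % where the cells give
  6.52 % -> 7 % under round-half-up. The accompanying source text prints
  "45 (38 %) heterozygous" where the table's 45/130 = 34.6 % -> 35 %; the
  table is authoritative.
* `table5_tested.tsv` — per-gene tested denominators (they vary by gene).
* `table5_burden_gold.tsv` — the published per-gene carrier cells and
  two-tailed exact-test p-values, kept for informational comparison: the
  printed familial cells are distinct-patient counts (EFEMP2 5, MYLK 12)
  while the printed EFEMP2 p-value (0.19) recomputes only from the 6
  familial variant observations; the printed COL3A1 p-value of 1 recomputes
  to 0.55 from its own cells.
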