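# aneuvar

Five-tier variant pathogenicity classification, gene-level case–control
burden and biallelic allele-frequency analysis for aneurysm gene-panel
screens.

## The problem

Panel sequencing of patients with abdominal aortic aneurysm (AAA) across the
thoracic-aneurysm genes (*ACTA2*, *COL3A1*, *EFEMP2*, *FBN1*, *MYH11*,
*MYLK*, *SMAD3*, *TGFB2*, *TGFBR1*, *TGFBR2*) yields dozens of rare variants
per cohort, almost all of ambiguous significance. Diagnostic practice sorts
them into five tiers — benign (B), likely benign (LB), unknown significance
(VUS), likely pathogenic (LP), pathogenic (P) — using population allele
frequency, splice predictions, in-silico protein predictions and curated
literature evidence. `aneuvar` implements that rule set as a deterministic,
auditable engine, together with the cohort-level analyses that go with it:
per-gene familial-vs-sporadic burden with an exact test, carrier and
complex-genotype tabulation, and minor-allele-frequency arithmetic with
multi-study pooling (the *MTHFR* c.665C>T analysis). A synthetic-cohort
generator makes every stage testable without any data download.

## The rules

A variant's evidence bundle is (MAF, splice verdict, damaging predictor count
`k` of panel size `m`, literature tier, truncation frame). Rules are tried in
fixed precedence; the first match assigns the tier and is recorded as
`rule_fired`:

1. MAF ≥ 0.01 in the selected population source → **B** (unconditional)
2. truncation with no possible in-frame protein (frameshift, nonsense,
   splice-destroying) → **P**
3. truncation creating a new in-frame protein → **LP**
4. prior disease report with reviewed supporting functional evidence → **LP**
5. predicted splice effect (non-truncating variant) → **VUS**
6. in-frame insertion/deletion → **VUS**
7. missense with k ≥ 2 damaging predictions → **VUS**
8. prior report without sufficient evidence (single unreplicated patient) →
   **VUS** floor
9. otherwise (silent/intronic without splice effect, missense with k ≤ 1) →
   **LB**

Segregation and conservation are carried as annotations but never change the
tier. Absent frequency is `None`, never 0, and can never satisfy rule 1.
Classifying under an alternate, population-specific frequency source
(`source="alt"`) and diffing against the primary source gives the
reclassification report.

The burden stage builds, per gene, the 2×2 table of familial/sporadic ×
carrier/non-carrier (either distinct patients or variant observations) against
per-gene tested denominators, and computes the two-tailed Fisher exact
p-value `p = Σ {P(X=x) : P(X=x) ≤ P(X=a)(1+1e-7)}` over the hypergeometric
support, in exact integer arithmetic. MAF from genotype counts is
`(n_CT + 2 n_TT) / 2n`, with round-half-up display rounding; pooling sums
genotype cells across studies.

## Worked example

```python
from aneuvar import classify_batch, reclassify_with_alt_frequency
from aneuvar.fixtures import load_bundle

bundle = load_bundle()   # bundled golden tables: 47 variants, 42 patients
results, counts = classify_batch(bundle.variants, threshold=0.01)
print({t.value: n for t, n in counts.items()})
changes = reclassify_with_alt_frequency(bundle.variants)
print([(c.variant_key, c.old_tier.value, c.new_tier.value) for c in changes])
```

prints

```
{'benign': 0, 'likely_benign': 23, 'vus': 21, 'likely_pathogenic': 1, 'pathogenic': 2}
[('MYLK:c.1327C>T', 'vus', 'benign')]
```

i.e. of the 47 bundled variants, 2 are pathogenic truncating variants, 1 is
a likely pathogenic missense with a functionally supported prior report, 21
are VUS and 23 likely benign; and exactly one VUS (MYLK p.Pro443Ser, Dutch
population MAF 0.014) becomes benign when the population-specific frequency
source replaces the reference databases. The scripts in `examples/` walk
through each capability (classification, burden, MTHFR frequencies,
simulation) and print the numbers they compute; `aneuvar --help` exposes the
same stages as a command-line pipeline (`classify`, `burden`, `genofreq`,
`simulate`, `fixtures`, `run`, `validate`).

## Layout

- `src/aneuvar/` — `model` (domain types, HGVS consequence inference),
  `classify` (rule engine), `burden` (exact test, burden tables, carrier
  summaries), `frequency` (MAF arithmetic and pooling), `simulate`
  (synthetic cohorts and genotypes), `io` (TSV schemas, VCF ingestion,
  validation), `fixtures` (bundled golden tables; see `data/NOTES.md`),
  `pipeline` and `cli`.
- `tests/` — unit, property and acceptance tests.
- `examples/` — narrative scripts, one per capability.
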