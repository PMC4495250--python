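# Methods

## Scope and data model

`aneuvar` operates downstream of variant calling and annotation. Its unit of
input is an *annotated variant*: gene, transcript, cDNA/protein HGVS, a
consequence class, a splice-prediction verdict reduced to effect/no-effect, a
damaging-call count `k` out of an in-silico predictor panel of size `m`, a
reference-population minor allele frequency (MAF) and count, an alternate
population-specific MAF, a curated literature tier, a truncation-frame flag
and (annotation-only) conservation and segregation. Running the upstream
predictors is out of scope: their verdicts are inputs. Absent evidence is
represented as absent (`None`/empty TSV cell), never as zero — a variant with
no frequency on record is unknown-frequency and can never satisfy a
frequency threshold. Records violating the domain invariants (e.g. a
missense variant with an empty predictor panel, `k > m`, a truncation flag
on a non-truncating consequence) are rejected with errors naming the field.

Consequence inference from HGVS text is a convenience for free-form input
and recognises only the notational signatures (``fs``, terminal
``X``/``*``/``Ter``, ``no-change``/``p.=``, intron-offset positions, del/dup/ins).
It refuses to guess when the text is ambiguous — an exonic substitution with
no protein-level description raises rather than defaulting to missense.
Curated records carry an explicit consequence that overrides inference, so
golden fixtures cannot be corrupted by parser edge cases.

## Classification rules

Classification is a total, deterministic function of the evidence bundle: a
fixed-precedence rule list is tried top to bottom and the first match wins
(see README for the list). Design decisions where the source material left
room:

* **Missense VUS boundary.** The tier definitions state the likely-benign
  side as "4/5 or 3/4 predictions neutral" and the VUS side as "more than 2
  damaging"; the curated table, however, classifies 2-of-4 and 2-of-5
  damaging missense variants as VUS. We take *k ≥ 2 damaging ⇒ VUS* (and
  generalise likely-benign to *k ≤ 1 on any panel size*), which reproduces
  every curated row and gives consistent behaviour on synthetic panels of
  arbitrary size.
* **Literature evidence is two-level.** A prior disease report whose
  supporting evidence survives review (functional studies, expression
  assays) promotes a non-truncating variant to likely pathogenic; a single
  unreplicated patient report only floors the tier at VUS. The tier is an
  input: no database is queried.
* **Frequency precedence is absolute.** MAF ≥ threshold (default 0.01)
  classifies benign regardless of other evidence. A common *truncating*
  variant is therefore benign; because that combination is biologically
  surprising the engine logs a warning when it happens. No such case occurs
  in the curated table, so this choice is not testable against it.
* **Annotations never reclassify.** Segregation (including the concordant
  twin flag) and conservation are carried through but have no rule: the
  curated table keeps segregating missense variants at VUS.

Reclassification runs the same engine twice (primary = reference-database
MAF; alt = population-specific MAF) and reports the tier diff. On the
bundled table exactly one variant changes (MYLK p.Pro443Ser, VUS → benign at
Dutch MAF 0.014 ≥ 0.01).

## Exact test

The two-tailed Fisher exact test is computed from first principles. For a
2×2 table with row totals `r1, r2` and carrier-column total `kc`, the number
of column assignments with `x` familial carriers is
`w(x) = C(r1, x) · C(r2, kc − x)`; weights are built by the exact integer
recurrence and the p-value is `Σ{w(x) : w(x) ≤ w(obs)·(1+1e-7)} / C(N, kc)`.
The relative tie tolerance `1 + 1e-7` matches the convention of standard
implementations. All arithmetic up to the final division is exact integer
work, so the test is exact for any cohort-scale counts (verified against
enumeration to 1e-12 relative on every table with N ≤ 30 and against an
independent implementation on random tables into the thousands). Degenerate
margins (no carriers anywhere, or an empty arm) carry no information and
return p = 1. p-values are reported at full precision, rounded only for
display, and are deliberately unadjusted for multiple testing (a log note
says so), matching how such panel screens are reported.

Burden tables support two counting modes because published per-gene cells
are ambiguous when one patient carries two variants in the same gene:
`patients` (default) counts distinct carrier patients, `observations` counts
variant entries. On the bundled cohort the published cells match `patients`
mode for every gene, while the published EFEMP2 p-value reproduces only from
`observations` counting — both readings are kept, and patient-mode cells can
never exceed observation-mode cells. Tested denominators are an explicit
per-gene input because panel coverage varies by gene; they are never derived
from the patient records. Benign variants are excluded from carrier and
burden counts (they are not reported variants).

## Allele frequencies

MAF from genotype counts is `(n_CT + 2·n_TT) / 2n`, computed on exact
rationals. Display rounding is round-half-up on the exact fraction (3 d.p.
for MAF, integer percents), the convention that reproduces the published
genotype tables (e.g. 69/260 → 0.265, 45/130 → 35 %). Pooling sums genotype
cells across studies before recomputing, so pooled counts are conserved and
the pooled MAF is the allele-weighted mean of member MAFs. The comparison
against a reference-population MAF is descriptive (a signed difference); no
hypothesis test is attached because none is appropriate without the
reference cohort's genotype counts. Hardy–Weinberg equilibrium is assumed
only by the synthetic generator and never tested on real tables.

## Bundled fixtures

The golden tables (47 variants with published tiers; 42 carrier patients; 16
genotype-count rows; per-gene tested denominators and published burden
cells) are transcribed in `src/aneuvar/data/`, with every transcription
decision and every internal inconsistency of the printed source documented
in `data/NOTES.md`. The notable ones: one genotype row's printed MAF (0.231)
does not recompute from its own printed cells (0.213); the printed sporadic
carrier total (12) is not constructible from the variant and patient tables
(11 is); each concordant twin pair is represented as one enrolled index
record, which is the only reading consistent with the published carrier and
per-gene counts. Tests assert recomputation wherever the source is
self-consistent and pin the documented exceptions.

## Synthetic data

`simulate_cohort` draws patient status (Bernoulli at the familial fraction),
per-gene/per-arm carrier events, and per-variant evidence bundles from an
evidence mixture; `simulate_genotypes` draws CC/CT/TT counts multinomially
under Hardy–Weinberg. Defaults are the study conditions: 155 patients,
familial fraction 99/155, per-gene carrier probabilities equal to the
published carrier rates, mixture weights equal to the golden-table
composition (2/47 out-of-frame truncating, 25/47 missense with the observed
damaging-count histogram, 13/47 synonymous, 7/47 intronic; literature tiers
41/5/1 of 47; MAF absent with probability 31/47, otherwise log-uniform on
[5·10⁻⁴, 8·10⁻³]), and `snp_maf` = 0.265. The alternate-frequency range
extends to 0.015 so that a small fraction of variants crosses the 0.01
threshold, emulating population-specific common polymorphisms. One integer
seed feeds `numpy` `SeedSequence` sub-streams (status, carriers, evidence),
so enlarging the cohort leaves earlier draws unchanged.

Deliberate simplifications: evidence is drawn independently of gene and of
carrier status; each carrier event creates a fresh variant (no recurrent
variants, no linkage, no pedigrees); HGVS strings are schematic but
parseable. Passing calibration tests therefore demonstrates correctness of
the rule engine, the exact test and the arithmetic under the stated
independence structure — not realism of any particular gene's mutation
spectrum. Because the mixture's independence is exactly the assumption of
`implied_tier_distribution`, the closed-form pushforward is an independent
oracle for the simulate-then-classify route.

## Numerical and testing choices

Tolerances: exact equality (integer counts, rationals) wherever arithmetic
is exact; 1e-12 relative for the exact-test oracle; 3 standard errors for
stochastic recovery checks (binomial for MAF recovery at n = 10,000,
multinomial for tier proportions at n = 50,000, binomial for the
2,000-replicate null-calibration bound 0.05 + 3·SE). Null calibration uses
study-sized cohorts (155 patients, carrier probability 0.10 in both arms)
with the realised arm sizes as denominators. Property tests run under a
derandomised hypothesis profile so the suite is reproducible. All problem
sizes were chosen as the smallest at which the statistical assertions have
comfortable power.

## Known limitations

No probabilistic/ACMG-2015 scoring, no odds ratios or regression modelling,
no multiple-testing correction, no HGVS grammar beyond the recognised
signatures, no genome coordinates or transcript models, and no VCF writing
(the VCF dialect is ingestion-only). The classification thresholds encode
one laboratory's diagnostic convention; they are parameters, not claims of
universality.
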