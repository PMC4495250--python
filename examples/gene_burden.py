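"""Per-gene familial-vs-sporadic burden on the bundled cohort.

Builds a 2x2 table (familial/sporadic x carrier/non-carrier) per gene from
the patient records and the per-gene tested denominators, and computes
two-tailed Fisher exact p-values from first principles.
"""

from aneuvar import classify_batch
from aneuvar.burden import carrier_summary, tabulate_gene_burden
from aneuvar.fixtures import load_bundle

bundle = load_bundle()
results, _ = classify_batch(bundle.variants)
classifications = {v.key: r.tier for v, r in zip(bundle.variants, results)}

rows = tabulate_gene_burden(
    bundle.patients, classifications, bundle.tested, mode="patients"
)
print(f"{'gene':8s} {'fam':>7s} {'spor':>7s} {'p_all':>6s} {'p_LP/P':>6s}")
for r in rows:
    print(
        f"{r.gene:8s} {r.carriers_familial:3d}/{r.n_familial:<3d} "
        f"{r.carriers_sporadic:3d}/{r.n_sporadic:<3d} "
        f"{r.p_all:6.2f} {r.p_lp_p:6.2f}"
    )
print("p-values are two-tailed exact tests, unadjusted for multiple testing;")
print("no gene shows a significant familial excess at these sample sizes.")

summary = carrier_summary(bundle.patients, classifications)
print(
    f"\nCarriers: {summary.familial_carriers} familial and "
    f"{summary.sporadic_carriers} sporadic patients carry >= 1 reported variant;"
)
print(
    f"{summary.multi_variant_total} patients carry two or more variants "
    f"({summary.multi_variant_familial} familial, "
    f"{summary.multi_variant_sporadic} sporadic)."
)
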