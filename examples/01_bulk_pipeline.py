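"""End-to-end SGS construction on a synthetic bulk cohort.

Simulates a 400-patient cohort in which one gene set's latent activity
raises the death hazard (true log-HR +0.7) and one lowers it (-0.7),
then runs the full pipeline: ssGSEA NES -> univariate Cox screen ->
signed SGS -> median split -> Kaplan-Meier / log-rank.
"""

from stemscore import (
    compute_sgs,
    generate_bulk,
    logrank_test,
    random_gene_sets,
    score_all,
    screen_gene_sets,
    stratify_median,
)

expr, surv, truth = generate_bulk(
    n_samples=400, seed=42, effects={"SET01": 0.7, "SET02": -0.7}
)
sets = random_gene_sets(expr.gene_ids, 36, 25, seed=42)
print(f"cohort: {expr.n_genes} genes x {expr.n_samples} samples, "
      f"{surv.n_events} deaths observed")

em = score_all(expr, sets, alpha=0.25, norm="global_range")
results = screen_gene_sets(em, surv, p_threshold=0.05)
risk = [r.set_name for r in results if r.direction == "risk"]
protective = [r.set_name for r in results if r.direction == "protective"]
print(f"screen retained {len(risk)} risk set(s) {risk} and "
      f"{len(protective)} protective set(s) {protective}")
print("  (the planted sets should appear here; any extras are the ~5% "
      "false positives a p<0.05 screen admits)")

sgs = compute_sgs(em, risk, protective)
table = stratify_median(sgs)
chi2, p = logrank_test(surv, table.group)
print(f"median SGS cutoff = {table.cutoff:.4f}; "
      f"{len(table.samples_in('high'))} high / {len(table.samples_in('low'))} low")
print(f"log-rank chi2 = {chi2:.2f}, p = {p:.2e}")
print("  a small p means the high-SGS half of the cohort dies measurably "
      "faster - the planted hazard signal was recovered end to end")
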