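# stemscore

Stemness-risk gene score (SGS) construction for transcriptomic cohorts,
at bulk and single-cell resolution.

Tumors with a stem-cell-like expression program tend to behave more
aggressively, and a patient's stemness burden can be summarized from a
panel of curated stemness gene sets.  `stemscore` implements the full
scoring pipeline for anyone who wants to build or validate such a
prognostic score on their own cohort:

1. **ssGSEA** — per-sample enrichment score for every gene set,
   rank-based with weight exponent α (default 0.25), normalized across
   the cohort by the global ES range to give NES;
2. **Cox screen** — univariate proportional-hazards regression of each
   set's NES on overall survival (Efron ties, Newton–Raphson); sets with
   Wald *p* < 0.05 are retained and labelled risk (HR > 1) or
   protective (HR < 1);
3. **SGS** — per sample, `SGS = Σᵢ NESᵢ − Σⱼ NESⱼ`, summing retained
   risk sets *i* and subtracting protective sets *j*;
4. **stratification** — high/low groups at the median SGS (a fixed
   cutoff can be frozen for validation cohorts);
5. **survival comparison** — Kaplan–Meier curves and the log-rank test
   between groups, plus Wilcoxon comparisons of any per-sample quantity
   (e.g. ssGSEA infiltration scores of stromal/immune signatures).

For single-cell matrices, the SGS is computed per cell with directions
transferred from a bulk screen, averaged per patient, and patients are
split at the median mean SGS.

Because survival-annotated expression cohorts are mostly
controlled-access, the package includes a synthetic generator
(`stemscore.synthetic`) that plants gene-set activities driving
proportional-hazards survival, so every stage can be exercised and
calibrated with known ground truth.  See `docs/methods.md` for the
model details and design choices.

## Worked example

```python
from stemscore import (generate_bulk, random_gene_sets, score_all,
                       screen_gene_sets, compute_sgs, stratify_median,
                       logrank_test)

expr, surv, truth = generate_bulk(n_samples=400, seed=42,
                                  effects={"SET01": 0.7, "SET02": -0.7})
sets = random_gene_sets(expr.gene_ids, 36, 25, seed=42)

em = score_all(expr, sets, alpha=0.25, norm="global_range")
results = screen_gene_sets(em, surv, p_threshold=0.05)
risk = [r.set_name for r in results if r.direction == "risk"]
protective = [r.set_name for r in results if r.direction == "protective"]

sgs = compute_sgs(em, risk, protective)
table = stratify_median(sgs)
chi2, p = logrank_test(surv, table.group)
print(risk, protective)
print(f"log-rank chi2 = {chi2:.2f}, p = {p:.2e}")
```

Output:

```
['SET01', 'SET32'] ['SET02']
log-rank chi2 = 93.32, p = 4.45e-22
```

The screen recovered the planted risk set (`SET01`, true log-HR +0.7)
and protective set (`SET02`, −0.7); `SET32` is the kind of false
positive a *p* < 0.05 screen admits at a ~5% rate.  The tiny log-rank
*p* says the high-SGS half of the cohort dies markedly faster — the
planted signal propagated through the whole pipeline.  The scripts in
`examples/` walk through this run, the single-cell path and the
infiltration-score comparison.

The same flow is available from the shell:

```bash
stemscore simulate --n-samples 400 --seed 42 --out sim/
stemscore enrich --expr sim/expr.tsv --gmt sim/sets.gmt --out nes.tsv
stemscore screen --nes nes.tsv --surv sim/surv.tsv --out screen.tsv
stemscore score --nes nes.tsv --screen screen.tsv --out scores.tsv
stemscore survdiff --surv sim/surv.tsv --groups scores.tsv --out km.tsv
```

or as one configured run (`stemscore run --config config.yaml`), which
writes `nes.tsv`, `screen.tsv`, `scores.tsv`, `km.tsv` and a
`manifest.json` with parameters, input checksums and retained sets.

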