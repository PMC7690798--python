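# crossdep

Bidirectional cross-association analysis between gene expression and
gene-level perturbation outcomes across a panel of samples. The package is
aimed at functional-genomics analysts who ask, per gene, two complementary
questions about an expression matrix paired with an RNAi/CRISPR efficacy
matrix (DepMap-style "gene effect" scores) over the same cancer cell lines:

* does the gene's mRNA level **predict** how strongly cells depend on it, and
* does the strength of dependence **describe** a difference in mRNA level?

The same machinery extends to patient cohorts, with relapse-free survival
(RFS) days taking the place of the efficacy score, complemented by
Kaplan–Meier curves and log-rank tests on the same expression groups.

## The scores

For one gene, samples are dichotomized at the median of one variable and the
other variable is contrasted between the groups (ties at the median go to the
low group):

```
predictivity  = avg(efficacy  | expression > median) − avg(efficacy  | expression ≤ median)
descriptivity = avg(expression | efficacy  > median) − avg(expression | efficacy  ≤ median)
```

All inputs are log2-scale, so each score is a log fold change between groups.
Significance comes from a two-sample Student t-test (pooled variance;
Welch's variant available) on the contrasted groups. A **hit** is a gene
significant on both axes (default p < 0.01 each) whose two scores share a
sign: *positive* hits (both > 0) are genes whose higher expression
accompanies numerically higher efficacy scores, *negative* hits the reverse.
In the survival variant, predictivity contrasts mean alive days between
high/low expression patients (threshold defaults p < 0.01 and p < 0.05).

Because a dependency score is more negative the stronger the knockdown or
knockout effect, a *negative* predictivity means high-expressing samples are
the more vulnerable ones.

## Worked example

```python
from crossdep import predictivity, descriptivity

expr = [1, 2, 3, 4, 5, 6]              # log2 expression over 6 cell lines
eff  = [-1, -1, -1, -3, -3, -3]        # gene-effect score, same cell lines

predictivity(expr, eff)
# PairScore(score=-2.0, p=0.0, n_high=3, n_low=3, status='ok')
descriptivity(expr, eff)
# PairScore(score=-3.0, p=0.0213..., n_high=3, n_low=3, status='ok')
```

The expression median is 3.5, so the three high-expression lines carry mean
efficacy −3 versus −1 in the low group: predictivity −2 (high expression,
stronger depletion). Splitting instead on the efficacy median (−2) contrasts
mean expression 2 vs 5: descriptivity −3. Both scores negative and
significant would make this a *negative* hit.

Genome-scale runs go through `simulate_paired_panel` /
`cross_association_scan` / `call_hits` (see `examples/cell_line_scan.py`,
which prints the planted-versus-recovered hit tally for a 2000-gene panel)
and, for cohorts, `simulate_survival_cohort` / `select_five_year_cohort` /
`survival_scan` (see `examples/survival_scan.py`). The same pipeline is
scriptable from a shell:

```bash
crossdep simulate --n-genes 1000 --n-samples 40 --seed 7 --cohort --out-dir sim/
crossdep scan --expression sim/expression.csv --efficacy sim/efficacy.csv --out-dir scan/
crossdep survival --expression sim/expression_cohort.tsv --clinical sim/clinical.tsv --out-dir surv/
crossdep report --scan scan/scan.tsv
```

Readers accept DepMap-dialect CSVs (samples × `"SYMBOL (ENTREZID)"` columns)
or their transpose, and GDC-style clinical TSVs (vital status, days to
death / last follow-up / new tumor event); every run writes TSV tables plus
a `provenance.json` with the configuration, its hash and all counts.

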