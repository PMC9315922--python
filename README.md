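# mutspec

Typing of IGHV somatic hypermutations and time-to-first-treatment (TTFT)
survival analysis for chronic lymphocytic leukemia (CLL) cohorts.

## The problem

CLL patients whose leukemic clone uses a somatically mutated IGHV gene
(M-CLL, ≥ 2% nucleotide difference from germline) fare better than those
with unmutated IGHV (U-CLL). One proposed mechanism is that replacement
mutations alter B-cell-receptor structure and abolish autoantigen-driven
signaling. `mutspec` implements the analysis needed to probe that
hypothesis on any cohort of rearranged IGHV-IGHD-IGHJ sequences with linked
clinical follow-up:

1. **Mutation calling** — align each rearrangement to its germline V gene
   (or accept IMGT/AIRR pre-aligned pairs) and enumerate nucleotide
   substitutions; percent difference from germline and the classical 2%
   U-CLL/M-CLL cutoff (boundary 2.0% is M-CLL).
2. **S/Rc/Rnc typing** — each substitution is silent (S), a conservative
   replacement (Rc), or a non-conservative replacement (Rnc), judged on the
   IMGT amino-acid physicochemical classes (hydropathy, volume, chemical
   characteristics). Default rule: conservative iff all three axes are
   conserved; a majority (≥ 2 of 3) rule is available.
3. **Ratio grouping** — the pseudocounted mutation-type ratio
   `(S + Rc + 0.05) / (Rnc + 0.05)`; sequences with ratio ≤ 1.0 form the
   Low Ratio Group (skewed toward structure-altering mutations), > 1.0 the
   High Ratio Group; zero-mutation sequences are undefined and excluded.
4. **Exact matching** — one-to-one random matching of High to Low Ratio
   patients on the identical total mutation count, removing group size and
   mutation burden as confounders.
5. **Survival analysis** — Kaplan-Meier TTFT curves and medians, pairwise
   log-rank (Mantel-Cox) tests with nominal p-values, and Cox
   proportional-hazards fits (Newton-Raphson on the partial likelihood,
   Efron ties), including the two-variable model with total mutation count
   and `ln((S + Rc + 0.5) / (Rnc + 0.5))` as additive covariates.
6. **Synthetic cohorts** — a generator that emits germline FASTA,
   pre-aligned AIRR rearrangement TSV and a clinical CSV with the marginal
   structure real CLL cohorts show (~35% zero-mutation clones, burdens
   1-36, hazard decreasing with burden, ~38% censoring), plus a per-patient
   truth table for exact end-to-end verification.

All survival machinery is implemented from first principles in
`mutspec.survival`; `lifelines` appears only in the test suite as an
independent cross-check.

## Worked example

```sh
python analysis/01_simulate_cohort.py      # 2,000 synthetic patients
python analysis/02_run_pipeline.py         # call + type + group
python analysis/03_match_groups.py         # exact burden matching
python analysis/04_survival_analysis.py    # KM / log-rank / Cox
```

Output of the last step (seed 1):

```
== TTFT by (S+Rc)/Rnc ratio group (all mutated patients) ==
  LOW: n=1235, treated=655, median TTFT = 4.29 years
  HIGH: n=68, treated=48, median TTFT = 3.62 years
  log-rank LOW vs HIGH: p = 0.0113

== TTFT by ratio group (matched for size and burden) ==
  LOW_matched: n=68, treated=43, median TTFT = 2.96 years
  HIGH_matched: n=68, treated=48, median TTFT = 3.62 years
  log-rank LOW_matched vs HIGH_matched: p = 0.9009

== Two-variable Cox ==
  HR per added mutation = 0.953 (95% CI 0.945-0.961), p = < 0.0001
  log-ratio coefficient = +0.014, p = 0.7820
```

Reading: before matching, the Low and High Ratio groups appear to differ
(p = 0.011) — but the groups differ grossly in mutation burden. After exact
matching on burden the difference disappears (p = 0.90), while each added
mutation still lowers the treatment hazard by ~5% (HR 0.953). In this
synthetic world the group effect is truly zero and the burden effect truly
exp(−0.05) ≈ 0.951 per mutation, so the pipeline recovers the generating
truth: mutation *quantity*, not type composition, drives TTFT here.

The same stages are available as a CLI (`mutspec run|simulate|match|survival`)
and as library functions.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole analysis from scratch on a freshly simulated
2,000-patient cohort: it verifies that pipeline-computed mutation counts,
S/Rc/Rnc counts and ratio groups equal the generator's truth table exactly,
runs the matched and unmatched survival comparisons and the two-variable
Cox fit, writes summary tables under `results/`, and writes the JSON object
to `--out`.
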