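# Methods

This note records the models, conventions and numerical choices behind
`mutspec`, and what the synthetic-data tests do and do not establish.

## Mutation calling

A patient rearrangement is compared to its germline V gene over an
equal-length gapped alignment. Pre-aligned pairs (IMGT-style gapped
strings, or AIRR `sequence_alignment`/`germline_alignment` columns) pass
through unchanged and are the recommended input; for raw sequences a global
pairwise alignment is computed (match +2, mismatch −1, gap open −6, gap
extend −1; the aligner's first reported alignment gives a deterministic
tie-break). These scores are internal defaults, not a claim about how any
reference tool aligns.

A mutation is a substitution at an aligned column where both characters are
unambiguous bases (A/C/G/T) and differ. Columns with a gap or N on either
strand contribute neither to the mutation count nor to the compared length;
indels are never counted as mutations. Percent difference is
`100 × substitutions / compared_length`, computed over the germline-encoded
V segment only (the CDR3/J region is not germline-encoded by the V
reference). Pairs with fewer than 60 compared positions are rejected as
insufficient overlap. The classical two-way status uses a 2.0% cutoff with
the boundary assigned to the mutated (≥ 2%) category.

## S / Rc / Rnc typing

Each substitution is translated in its germline codon context. If the
amino acid is unchanged the mutation is silent (S). Otherwise the
replacement is judged on three axes from the IMGT amino-acid
physicochemical classes (packaged in `mutspec/data/aa_classes.tsv`):

* hydropathy — hydrophobic / neutral / hydrophilic;
* volume — very small / small / medium / large / very large;
* chemical characteristics — aliphatic / aromatic / sulfur / hydroxyl /
  basic / acidic / amide.

Under the default **strict** rule a replacement is conservative (Rc) only
when all three axes are conserved; under the **majority** sensitivity
switch, when at least two are. The strict default reflects the conjunctive
reading of "charge, hydropathy, and size" as joint criteria; neither mode
is asserted to be the exact rule inside IMGT tooling, which is not
published — results that depend on the Rc/Rnc boundary should be run under
both modes.

Conventions for edge cases:

* **Several mutations in one codon** — each substitution is classified by
  its *isolated* effect on the germline codon (keeps per-nucleotide counts
  additive). The joint observed-codon comparison is available as a config
  flag.
* **Nonsense changes** — a substitution creating a stop codon is Rnc with
  `to_stop=True`; the sequence is kept (discarding would silently shrink
  cohorts).
* **Unclassifiable sites** (codon context missing, N or gap in the codon,
  or a stop germline codon) are excluded from S/Rc/Rnc counts but still
  count toward percent difference; both tallies are reported
  (`n_total` vs `n_unclassifiable`) so the discrepancy stays visible.

## Ratio, groups and bins

The mutation-type ratio is `(S + Rc + c) / (Rnc + c)` with pseudocount
c = 0.05, which keeps the ratio finite when a type is absent. Ratio ≤ 1.0
(boundary inclusive) defines the Low Ratio Group; > 1.0 the High Ratio
Group; zero-mutation sequences have no defined ratio and belong to neither
group. A `median` threshold mode recomputes the cutoff as the sample median
of ratios over mutated sequences instead of the fixed 1.0.

The Cox covariate uses its own pseudocount:
`log_ratio = ln((S + Rc + 0.5)/(Rnc + 0.5))`. The two pseudocounts (0.05
for grouping, 0.5 inside the log) are deliberately kept distinct and
independently configurable — both appear in the source analyses as printed
and cannot be reconciled from the available text.

Mutation-burden bins are {0}, 1–4, 5–6, 7–9, 10–12, 13–15, 16–18, 19–21,
> 21 (implemented as [22, ∞) on integer counts), with the zero bin kept for
comparison.

## Exact matching

Low Ratio patients are visited in a seeded random shuffle (avoiding
order-dependent exhaustion bias); for each, a High Ratio patient with the
*identical* total mutation count is drawn uniformly without replacement.
Low patients with no remaining candidate are dropped from the matched
analysis and counted in the report. On the matched subset the burden
multisets of the two groups are identical by construction — the invariant
the tests assert. The matching key is exactly `n_total`; no calipers.

## Survival analysis

* **Kaplan-Meier** — product-limit estimator; censored subjects leave the
  risk set without dropping the curve. Median = smallest time t with
  S(t) ≤ 0.5 (R convention), undefined when the curve plateaus above 0.5.
* **Log-rank (Mantel-Cox)** — observed-vs-expected events with the
  hypergeometric variance including the ties factor (N−d)/(N−1); p from
  χ²(1). The pairwise variant over k strata reports nominal p-values with
  no multiplicity adjustment, matching the reporting convention of the
  analyses this package reproduces; displayed p-values are floored at
  "< 0.0001" while raw values are retained in machine output.
* **Cox regression** — Newton-Raphson on the partial likelihood with
  Efron's approximation for tied event times (Breslow available; the two
  coincide without ties). Convergence when max |score| < 1e−9 or the
  relative log-likelihood change < 1e−10, at most 50 iterations, with
  step-halving; the linear predictor is centered before exponentiation to
  avoid overflow. Standard errors come from the inverse observed
  information; 95% CIs are exp(β ± 1.96·se).
* A subtlety worth recording: the textbook identity "two-sample log-rank =
  Cox score test for the group indicator" is exact only for untied event
  times; with ties the Mantel-Cox variance carries the (N−d)/(N−1) factor
  the Cox information at β = 0 lacks. The property test therefore uses
  continuous times.

## Synthetic cohorts: the stated world

`simulate_cohort` draws, per patient:

* zero-mutation indicator ~ Bernoulli(0.35);
* burden (if mutated) from a pmf over 1–36 shaped like the published
  mutation-number intervals (weights 389, 173, 232, 221, 257, 297, 240,
  539 for 1–4 … > 21), uniform within each interval — the within-interval
  uniformity is an invention, documented as such;
* substitutions at distinct positions, transitions weighted 2:1 over each
  transversion (transition probability 1/2); an optional WRC/GYW hotspot
  multiplier (default off) and an optional `scr_weight` that upweights
  silent/conservative alternatives when a study needs the High Ratio group
  well populated (default 1.0: composition is purely emergent from the
  genetic code plus the classifier — under the strict rule this skews
  cohorts toward the Low group, the opposite of real CLL cohorts, because
  random replacements are mostly non-conservative);
* TTFT from a Weibull proportional-hazards model,
  S(t|x) = exp(−(t/λ)^k · e^{βₘ·n + β_g·1[HIGH]}), defaults k = 1
  (exponential special case used in closed-form checks), λ = 3.2 y (baseline
  median ≈ 2.2 y, the order of real U-CLL medians), βₘ = −0.05 per mutation
  (≈ the hazard ratio 0.95/mutation scale reported for real cohorts),
  β_g = 0;
* independent exponential loss to follow-up (rate 0.12/y) truncated by an
  administrative cutoff at 25 y, giving ~35–40% censoring.

The generator emits the exact input formats of the pipeline plus a truth
table computed with the same classifier and class tables, so end-to-end
tests can demand *exact* equality of counts and groups. What a green test
establishes: the pipeline inverts the generator faithfully and the
statistical engines recover known parameters at nominal rates. What it does
not establish: realism of IGHV gene usage, clonal structure, indels,
sequencing error, per-patient (S, Rc, Rnc) joint distributions, or any
population value from real cohorts — real-data medians and hazard ratios
are not reproducible from synthetic data and are never asserted.

`fixture_small` is a deterministic 12-patient cohort covering every
accounting category (0 Mut, S only, R only, S+R), two sequences with ratio
exactly 1.0 (exercising the ≤ boundary), one nonsense mutation, and one Low
patient with no same-burden High partner (exercising the unmatched path).

## Other conventions

* Clinical dates (ISO 8601 only) convert to years by division by 365.25;
  untreated patients are censored at last follow-up.
* All randomness flows from a single seed; subordinate seeds are derived
  deterministically, so every run is exactly reproducible.
* Known limitations: no germline gene assignment (a `v_call` or pre-aligned
  pair is required), no IGK/IGL or CDR3 analysis, no time-varying
  covariates or proportionality diagnostics, no matching with replacement.
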