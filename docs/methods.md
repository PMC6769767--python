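# Methods

## Scope and assumptions

The package operates downstream of variant calling, clonal deconvolution
and evidence-base construction. It assumes:

- gene-level granularity: profiles, clones and evidence entries are sets of
  gene symbols; variant-level effects (specific alleles, hotspots) are not
  modelled beyond what the evidence base encodes;
- the evidence scores (GScore, DScore) are inputs whose provenance is
  trusted; the package never recomputes them;
- a clonal architecture is a *known* rooted tree with per-sample clone
  prevalence fractions — no deconvolution from raw VAFs is attempted, and
  VAF and cellular prevalence are deliberately kept as distinct notions (no
  ploidy/purity conversion);
- the bulk approximation equates single-sample sequencing with the most
  prevalent clone's mutation complement. This is a simplification: real
  bulk calling detects any variant above a VAF threshold, which can
  straddle clones. It is used here as a consistent, reproducible contrast
  for the ITH view.

## Prescription rules

Candidates are ranked by (DScore desc, GScore desc, drug name asc). No
combining formula of the two scores is assumed; the lexicographic order is
the least-assumptive reading of "higher suitability on stronger genes",
and the name tie-break makes rankings total and stable.

- `dscore_min = 0.7`, strict `>`: the suitability floor for a candidate.
- `gscore_min = 0.6`, strict `>`, applied at cohort level only
  (`RunConfig.thresholds(cohort_level=True)`); per-clone analyses use the
  DScore rule alone so that worked per-clone rankings are reproduced.
- Resistance veto: drug-level across the whole queried profile. One
  resistance association for a drug among the profile's genes excludes the
  drug regardless of co-occurring sensitivity entries. A consequence worth
  knowing: enlarging a profile (e.g. moving from bulk to ITH) can *remove*
  a drug from the ranking by revealing a resistance gene — gene-set
  inclusion between bulk and ITH is universal, drug-list inclusion is not.
- Association class (direct target / biomarker / pathway member) is
  annotation, not a ranking weight: no down-weighting of pathway members
  is applied because no principled weight is available at this layer.
- "Druggable gene" defaults to *has ≥ 1 evidence entry of any kind*; a
  strict mode (sensitivity entries above `dscore_min` only) is available
  where a conservative count is wanted.

## Genomic input filters

- VCF: only records whose FILTER is exactly `PASS` contribute genes
  (high-confidence somatic calls); multi-gene annotations split on commas.
  Coordinates are 1-based per VCF; downstream sets are coordinate-free.
- CNV: a gain counts only with over-expression (`z > 2`), a loss only with
  under-expression (`z < −2`), both strict. Sign concordance is the only
  biologically coherent reading of "supported by expression changes" and
  can be disabled (`require_concordance=False`) to fall back to a pure
  |z| filter. The z filter is applied to CNV support only, not to mutation
  genes.
- Drug names resolve through a user-supplied alias table,
  case-insensitively; unknown names pass through with a warning rather
  than failing a run.

## Temporal selection

Between timepoints t0 (diagnosis) and t1 (relapse), a gene is selected if
`vaf(t0) < low_vaf` and `vaf(t1) ≥ rise_min` (pre-existing, positively
selected) or if absent at t0 with `vaf(t1) ≥ rise_min` (relapse-specific).
Defaults `low_vaf = 0.01`, `rise_min = 0.10`: detection below 1% VAF is
what standard bulk callers miss, and 0.10 is a permissive expansion floor
(observed relapse VAFs in the motivating case sit at 0.30–0.40, so the
default is not the binding constraint there). The rule is applied per
gene profile, not per clone average.

## Regimen design

`trunk_plus_specific` (default) formalises the clinical reasoning "one
drug for the trunk, one per subclone": the top trunk candidate addresses
every clone; each clone's *private* alterations (complement minus trunk)
must additionally be matched by that clone's top-ranked candidate, else
the clone is reported **uncovered**. Coverage accounting in this strategy
is therefore clone-individual: a clone counts as covered when its private
alterations are matched (or it has none beyond the trunk), even though the
trunk drug pharmacologically reaches all clones — this is what makes
"uncovered" a useful flag for subclones that would escape individualised
targeting. A clone lacking a passing candidate is never assigned the best
sub-threshold drug.

`greedy_cover` maximises remaining prevalence-weighted clone mass per added
drug (ties: DScore desc, then name asc); `exact_cover` finds a
minimum-cardinality set covering every coverable clone by exhaustive
subset search and refuses pools above 20 candidate drugs (2^20 subsets is
the practical ceiling; use greedy beyond it). Both use plain
complement-membership coverage. Therapeutic coverage of a drug set in a
sample is the summed prevalence of clones covered by ≥ 1 drug — a
formalisation chosen here; drug interactions, dosing and scheduling are
out of model (a regimen is a set, not a schedule).

## Survival analysis

Kaplan–Meier and the two-group log-rank test are implemented directly
(product-limit recursion; hypergeometric mean/variance per distinct event
time, χ² with 1 df) so the stratification pipeline is testable end to end;
the test suite cross-checks both against lifelines on tied and censored
data and they agree to floating-point precision. Conventions: ties handled
by the standard formulation (d_i ≥ 1 allowed); subjects censored at an
event time count as at risk at that time; p-values are two-sided with no
multiplicity correction (the design has a single comparison). Monte-Carlo
calibration at n = 50 + 50 exponential null cohorts gives an empirical
type-I error of ≈ 0.054 at α = 0.05 — the familiar mild anticonservatism
of the χ² approximation at moderate sample sizes, inside the 0.035–0.065
band the acceptance suite asserts. Cox proportional-hazards modelling is
deliberately out of scope (no coefficients are consumed or produced
anywhere in the pipeline).

## Synthetic data

Generators are pure functions of a `SimulationConfig`; one RNG stream per
generator is spawned from the master seed (`SeedSequence(seed,
spawn_key)`), so consuming one generator never perturbs another.

- **Architectures**: uniform random parent choice yields unbalanced trees
  of the kind clonal deconvolution reports; novel gene sets are drawn
  without replacement from a shared universe (disjoint branches — real
  tumours can mutate a gene convergently, which this omits); per-sample
  prevalences are Dirichlet(α = 1.5) over a random clone subset
  (moderately concentrated mixtures).
- **Knowledge bases**: each gene is druggable with probability 0.3
  (defaults chosen to make random profiles partially, not fully,
  actionable), 1–3 entries per druggable gene to distinct drugs, GScore
  and DScore magnitude uniform on (0, 1), sensitivity with probability
  0.8, resistance entries carrying negative DScore.
- **Cohorts**: two arms of 150 patients by default, responder fraction
  0.5, exponential survival at baseline hazard 1/365 per day with hazard
  ratio 0.5 for responders (protection), censoring applied with
  probability 0.2 as an independent uniform draw on (0, T). Profiles are
  constructed so the a-priori classifier recovers the generating label
  exactly — this verifies the classification rule's self-consistency, not
  its clinical accuracy.

What passing tests on synthetic data do **not** show: performance on real
cohorts (evidence incompleteness, annotation noise, non-exponential
hazards, informative censoring) is outside what these generators emulate.

## Case-study fixtures

Three transcribed fixtures pin the worked examples: an AML
diagnosis/relapse pair (UPN933124: 330 shared / 5 primary-only / 78
relapse-only events; 18 low-VAF pre-existing plus 2 relapse-specific
selected genes, 10 of 20 druggable) and two multi-region NSCLC cases
(CRUK0056: 116-gene trunk, R2 = C3 12% + C4 88%, ITH 130 vs bulk 119
genes, 31 vs 25 druggable; CRUK0016: 507-gene trunk with dasatinib
0.64/0.95, paclitaxel 0.63/0.94, pemetrexed 0.79/0.84, subclone drugs
sorafenib/axitinib above 0.9, no passing candidate for C4). Gene names
beyond the printed handful (ERBB4, FLT4, ETV6, TMEM117, TP53, CAMK4,
DDR2) are synthetic placeholders, as are unprinted scores and the
CRUK0016 region prevalences; every test against these fixtures relies
only on cardinalities and printed values. The CRUK0056 tree
(C1 → {C3 → C2, C4}) is the unique small topology consistent with all
printed counts at once; CRUK0016 adds an ancestral root carrying the
trunk at zero sampled prevalence so trunk semantics hold with only three
sampled subclones.

## Numerical choices and degenerate inputs

- Prevalence sums must be within 1e−6 of 1; violating inputs are rejected,
  never renormalised (silent renormalisation hides upstream errors).
- Score thresholds are strict inequalities throughout.
- Exact prevalence ties for the predominant clone resolve to the
  lexicographically smallest clone id, with a warning.
- Druggability with an untargetable region returns 0 with a warning rather
  than dividing by zero.
- Empty rankings are a valid "no candidate" outcome, distinguished from
  errors.

## Problem sizes

The test suite and the acceptance script run fixture analyses (instant),
oracle comparisons on instances of ≤ 8 clones / ≤ 20 drugs (exhaustive
search stays trivial there), 2000 null and 500 alternative survival
replicates at 100–150 subjects each, and 200-patient synthetic cohorts —
sizes at which the Monte-Carlo standard error is small relative to the
asserted bands while the whole suite completes in seconds.

## Known limitations

Gene-level resolution (no allele specificity); no cancer-type filtering of
indications (annotation only); no acquired-resistance dynamics, synergy,
toxicity or scheduling; the bulk approximation is clone-based rather than
VAF-threshold-based; genome-build liftover is not performed (inputs must
share a build).
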