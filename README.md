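# clonotherapy

Intra-tumour-heterogeneity-aware in silico drug prescription: a tested
pipeline for ranking candidate anticancer drugs against a patient's altered
genes, comparing what bulk sequencing versus clone-resolved (ITH) analysis
makes therapeutically visible, designing combination regimens that cover a
tumour's clonal phylogeny, and stratifying patients a priori into
responders and non-responders with a survival comparison.

It is aimed at computational oncologists and bioinformaticians who have
(a) a gene–drug evidence knowledge base, (b) somatic variant calls and/or a
clonal architecture (phylogeny + per-region clone prevalences) for a
patient, and (c) optionally cohort survival data, and who want reproducible,
scriptable prescription analyses rather than a web service.

## The model

**Evidence scores.** Each gene–drug association carries a gene score
GScore ∈ [0, 1] (evidence for the gene's clinical/biological relevance in
cancer) and a drug score DScore ∈ [−1, 1] (suitability; positive =
sensitivity, negative = resistance), plus an association class (direct
target, biomarker, pathway member) and the drug's regulatory status.
Candidate drugs for a mutation profile are ranked by
(DScore desc, GScore desc, name asc) after two rules:

- *resistance veto* — a drug with any resistance association among the
  profile's genes is excluded outright;
- *score thresholds* — strict DScore > 0.7 for per-clone candidacy, with an
  additional GScore > 0.6 floor for cohort-level prescription.

**Clonal architecture.** A tumour is a rooted phylogeny of clones, each
carrying the genes newly mutated on its branch; a clone's full mutation
complement is the union of novel sets on its root path. Trunk (clonal)
mutations are those in every complement. A region's *bulk approximation*
is the complement of its most prevalent clone; the *ITH view* is the union
of complements of all clones present. Druggability of a clone in a region
is |targetable genes in the clone| / |targetable genes in the region|.

**Regimens.** The default strategy pairs the top trunk candidate (hitting
every tumour cell) with one clone-specific candidate per subclone's private
alterations; subclones with no candidate passing DScore > 0.7 are reported
uncovered. Greedy and exact prevalence-weighted set-cover strategies are
also available. Therapeutic coverage of a regimen in a region is the
prevalence mass of clones covered by ≥ 1 drug.

**Stratification.** For a drug class actually administered, a patient is
an a-priori *responder* iff their profile carries class sensitivity
evidence and no class resistance evidence; strata are compared by the
Kaplan–Meier estimator S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) and the two-group
log-rank test (χ², 1 df), both implemented from first principles.

## Worked example

Two transcribed case studies ship with the package (plus an AML temporal
case). `CRUK0016` is a two-region lung tumour with three subclones over a
507-gene trunk:

```python
>>> from clonotherapy import case_study_fixtures, trunk_genes, prescribe_profile, propose_regimen
>>> fx = case_study_fixtures()["CRUK0016"]
>>> [(r.drug, r.best_gscore, r.best_dscore)
...  for r in prescribe_profile(trunk_genes(fx.arch), fx.kb)]
[('dasatinib', 0.64, 0.95), ('paclitaxel', 0.63, 0.94), ('pemetrexed', 0.79, 0.84)]
>>> prop = propose_regimen(fx.arch, fx.kb)
>>> prop.drug_names, sorted(prop.uncovered_clones)
(('dasatinib', 'axitinib', 'sorafenib'), ['C4'])
```

Reading: dasatinib is the best trunk candidate (DScore 0.95 via its direct
target DDR2), so it addresses every clone; axitinib and sorafenib match
private alterations of subclones C12 and C8; no drug above the 0.7
suitability rule exists for C4's private alterations, so C4 is flagged
uncovered — a combination of the three drugs plus monitoring of C4 is the
actionable readout.

The same analyses are available from the shell:

```bash
clonotherapy fixtures --out fx/
clonotherapy regimen --arch fx/CRUK0016.arch.json --kb fx/CRUK0016.kb.tsv
clonotherapy ith-compare --arch fx/CRUK0056.arch.json --sample R2 --kb fx/CRUK0056.kb.tsv
clonotherapy simulate --seed 7 --out sim/   # synthetic arch/KB/cohort inputs
```

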