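"""Core prescription operators: per-profile and per-clone drug ranking,
druggability metrics, bulk-vs-ITH comparison, and a-priori responder
classification.

Given a set of altered genes, candidate drugs are ranked from the evidence
knowledge base (resistance veto, score thresholds, DScore/GScore ordering).
The ITH-aware operators compare what a single-sample bulk analysis would
see — assumed to be the most prevalent clone's mutations — against the
union of all clones present, and measure how much of a region's targetable
gene space each clone carries.  The responder classifier applies molecular
evidence for a fixed drug class: sensitivity with no resistance means
responder; resistance, or no evidence at all, means non-responder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .clonal_model import (
    ClonalArchitecture,
    full_complement,
    predominant_clone,
    region_union_genes,
)
from .evidence_kb import (
    EvidenceKB,
    RankedDrug,
    normalize_drug,
    normalize_gene,
    query_genes,
    rank_candidates,
)

__all__ = [
    "Thresholds",
    "PrescriptionRecord",
    "BulkIthComparison",
    "ResponderLabel",
    "prescribe_profile",
    "druggable_genes",
    "clone_druggability",
    "bulk_vs_ith",
    "classify_response",
    "alternative_therapies",
]


@dataclass(frozen=True)
class Thresholds:
    """Score cutoffs used across the prescription pipeline.

    ``dscore_min`` is the suitability floor for a candidate drug (strict
    ``>``); ``gscore_min`` the gene-evidence floor.  Cohort-level analyses
    use ``gscore_min = 0.6``; per-clone rankings default to 0.0 so that the
    DScore rule alone decides, as in the worked clonal examples.
    """

    dscore_min: float = 0.7
    gscore_min: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.dscore_min <= 1.0 or not 0.0 <= self.gscore_min <= 1.0:
            raise ValueError("thresholds outside legal score ranges")


@dataclass(frozen=True)
class PrescriptionRecord:
    """One candidate drug for a mutation profile.

    ``best_gscore``/``best_dscore`` are realized by at least one supporting
    entry; ``associations`` maps each supporting gene to its association
    classes (direct target, biomarker, pathway member).
    """

    drug: str
    supporting_genes: frozenset
    associations: Mapping[str, tuple]
    best_gscore: float
    best_dscore: float
    drug_status: str
    response: str = "sensitivity"

    def __post_init__(self) -> None:
        if not self.supporting_genes:
            raise ValueError(f"{self.drug}: supporting_genes must be non-empty")


@dataclass(frozen=True)
class BulkIthComparison:
    """Gene and drug yield of bulk vs ITH-aware analysis of one sample."""

    sample_id: str
    bulk_clone: str
    bulk_gene_count: int
    ith_gene_count: int
    bulk_druggable_genes: frozenset
    ith_druggable_genes: frozenset
    bulk_drugs: tuple
    ith_drugs: tuple

    def __post_init__(self) -> None:
        if self.bulk_gene_count > self.ith_gene_count:
            raise ValueError("bulk gene count cannot exceed ITH gene count")
        if not self.bulk_druggable_genes <= self.ith_druggable_genes:
            raise ValueError("bulk druggable genes must be a subset of ITH's")


@dataclass(frozen=True)
class ResponderLabel:
    """A-priori molecular-evidence response label for one patient."""

    patient_id: str
    label: str  # "responder" | "non_responder"
    reason: str  # "sensitivity_only" | "resistance_present" | "no_evidence"

    def __post_init__(self) -> None:
        if self.label not in {"responder", "non_responder"}:
            raise ValueError(f"bad label {self.label!r}")
        if self.reason not in {"sensitivity_only", "resistance_present", "no_evidence"}:
            raise ValueError(f"bad reason {self.reason!r}")
        if (self.label == "responder") != (self.reason == "sensitivity_only"):
            raise ValueError("label=responder iff reason=sensitivity_only")


def _record_from_ranked(r: RankedDrug) -> PrescriptionRecord:
    assoc: dict[str, set] = {}
    for e in r.entries:
        assoc.setdefault(e.gene, set()).add(e.association)
    return PrescriptionRecord(
        drug=r.drug,
        supporting_genes=r.supporting_genes,
        associations={g: tuple(sorted(a)) for g, a in sorted(assoc.items())},
        best_gscore=r.best_gscore,
        best_dscore=r.best_dscore,
        drug_status=r.drug_status,
    )


def prescribe_profile(
    genes: Iterable[str],
    kb: EvidenceKB,
    thresholds: Thresholds = Thresholds(),
) -> list[PrescriptionRecord]:
    """Ranked candidate drugs for a set of altered genes.

    Queries the KB for the profile's genes, applies the resistance veto and
    score thresholds, and returns one record per surviving drug in
    (DScore desc, GScore desc, name asc) order.  An empty ranking is a
    valid "no candidate" outcome.
    """
    genes = {normalize_gene(g) for g in genes if g and g.strip()}
    if not genes:
        return []
    entries = query_genes(kb, genes)
    ranked = rank_candidates(
        entries, dscore_min=thresholds.dscore_min, gscore_min=thresholds.gscore_min
    )
    return [_record_from_ranked(r) for r in ranked]


def druggable_genes(genes: Iterable[str], kb: EvidenceKB, strict: bool = False,
                    thresholds: Thresholds = Thresholds()) -> set[str]:
    """Genes of the input set with at least one KB entry.

    In ``strict`` mode only sensitivity entries above the DScore threshold
    count as evidence of druggability.
    """
    out = set()
    for g in genes:
        entries = kb.entries_for_gene(g)
        if strict:
            entries = [e for e in entries
                       if e.response == "sensitivity" and e.dscore > thresholds.dscore_min]
        if entries:
            out.add(normalize_gene(g))
    return out


def clone_druggability(
    arch: ClonalArchitecture,
    sample_id: str,
    clone_id: str,
    kb: EvidenceKB,
    strict: bool = False,
) -> float:
    """Fraction of a region's targetable genes carried by one clone.

    Defined as |druggable(clone complement)| / |druggable(region union)|.
    Returns 0 with a warning when the region has no targetable genes.
    """
    import warnings

    region = druggable_genes(region_union_genes(arch, sample_id), kb, strict=strict)
    if not region:
        warnings.warn(f"sample {sample_id!r}: no druggable genes in region", stacklevel=2)
        return 0.0
    clone = druggable_genes(full_complement(arch, clone_id), kb, strict=strict)
    return len(clone & region) / len(region)


def bulk_vs_ith(
    arch: ClonalArchitecture,
    sample_id: str,
    kb: EvidenceKB,
    thresholds: Thresholds = Thresholds(),
) -> BulkIthComparison:
    """Compare the gene/drug yield of bulk vs ITH-aware analysis of a sample.

    The bulk side assumes single-sample sequencing detects only the most
    prevalent clone's mutation complement; the ITH side uses the union over
    all clones present in the sample.
    """
    bulk_clone = predominant_clone(arch, sample_id)
    bulk_genes = full_complement(arch, bulk_clone)
    ith_genes = region_union_genes(arch, sample_id)
    return BulkIthComparison(
        sample_id=sample_id,
        bulk_clone=bulk_clone,
        bulk_gene_count=len(bulk_genes),
        ith_gene_count=len(ith_genes),
        bulk_druggable_genes=frozenset(druggable_genes(bulk_genes, kb)),
        ith_druggable_genes=frozenset(druggable_genes(ith_genes, kb)),
        bulk_drugs=tuple(prescribe_profile(bulk_genes, kb, thresholds)),
        ith_drugs=tuple(prescribe_profile(ith_genes, kb, thresholds)),
    )


def classify_response(
    patient_id: str,
    genes: Iterable[str],
    drug_class: Iterable[str],
    kb: EvidenceKB,
) -> ResponderLabel:
    """Label a patient responder/non-responder for a drug class a priori.

    Restricting the KB to (patient genes x class drugs): any resistance
    entry makes the patient a non-responder (resistance present); otherwise
    any sensitivity entry makes them a responder; with no entry at all the
    patient is a non-responder for lack of molecular evidence.
    """
    class_drugs = {normalize_drug(d) for d in drug_class if d and d.strip()}
    if not class_drugs:
        raise ValueError("drug_class must be non-empty")
    genes = {normalize_gene(g) for g in genes if g and g.strip()}
    relevant = [
        e for g in sorted(genes) for e in kb.entries_for_gene(g) if e.drug in class_drugs
    ]
    if any(e.response == "resistance" for e in relevant):
        return ResponderLabel(patient_id, "non_responder", "resistance_present")
    if any(e.response == "sensitivity" for e in relevant):
        return ResponderLabel(patient_id, "responder", "sensitivity_only")
    return ResponderLabel(patient_id, "non_responder", "no_evidence")


def alternative_therapies(
    genes: Iterable[str],
    excluded_class: Iterable[str],
    kb: EvidenceKB,
    thresholds: Thresholds = Thresholds(),
) -> list[PrescriptionRecord]:
    """Ranked candidates outside an excluded drug class.

    Used to propose tailored options for patients classified as
    non-responders to the class they actually received; records keep their
    ``drug_status`` so approved vs clinical-trial proportions can be
    summarized downstream.
    """
    excluded = {normalize_drug(d) for d in excluded_class}
    return [r for r in prescribe_profile(genes, kb, thresholds) if r.drug not in excluded]
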