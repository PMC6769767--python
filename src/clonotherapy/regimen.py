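"""Combination-regimen design over a clonal architecture.

The aim is a small set of drugs that together address every tumour cell
population: one drug matched to the trunk (clonal) alterations shared by
all clones, plus clone-specific drugs for the private alterations of each
subclone.  A drug "covers" a clone when at least one of its supporting
genes lies in the clone's mutation complement with passing sensitivity
evidence; therapeutic coverage of a sample is the prevalence mass of
covered clones.  Clones for which no candidate passes the suitability
threshold are reported uncovered rather than assigned a sub-threshold drug.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .clonal_model import ClonalArchitecture, full_complement, trunk_genes
from .evidence_kb import EvidenceKB
from .prescription import PrescriptionRecord, Thresholds, prescribe_profile

__all__ = [
    "RegimenProposal",
    "drug_covers_clone",
    "therapeutic_coverage",
    "propose_regimen",
    "EXACT_COVER_MAX_DRUGS",
]

EXACT_COVER_MAX_DRUGS = 20


@dataclass(frozen=True)
class RegimenProposal:
    """A proposed drug combination with its clone-coverage accounting.

    ``covered_clones`` maps each drug to the clone ids it targets;
    ``uncovered_clones`` lists clones no listed drug covers; per-sample
    coverage is the prevalence mass of clones covered by at least one drug.
    """

    strategy: str
    drugs: tuple  # ordered PrescriptionRecords
    covered_clones: Mapping[str, frozenset]
    uncovered_clones: frozenset
    coverage_by_sample: Mapping[str, float]

    def __post_init__(self) -> None:
        covered = set().union(*self.covered_clones.values()) if self.covered_clones else set()
        if covered & set(self.uncovered_clones):
            raise ValueError("a clone cannot be both covered and uncovered")
        for drug, clones in self.covered_clones.items():
            if clones and drug not in {r.drug for r in self.drugs}:
                raise ValueError(f"coverage listed for unlisted drug {drug!r}")

    @property
    def drug_names(self) -> tuple:
        return tuple(r.drug for r in self.drugs)


def drug_covers_clone(
    drug: PrescriptionRecord, arch: ClonalArchitecture, clone_id: str
) -> bool:
    """True iff one of the drug's supporting genes is mutated in the clone.

    Supporting genes of a :class:`PrescriptionRecord` already carry passing
    sensitivity evidence, so membership of any of them in the clone's full
    complement suffices.
    """
    return bool(drug.supporting_genes & full_complement(arch, clone_id))


def therapeutic_coverage(
    drugs: Iterable[PrescriptionRecord],
    arch: ClonalArchitecture,
    sample_id: str,
) -> float:
    """Prevalence mass of clones in a sample covered by >= 1 drug."""
    if sample_id not in arch.samples:
        raise KeyError(f"unknown sample {sample_id!r}")
    drugs = list(drugs)
    total = 0.0
    for cid, p in arch.samples[sample_id].prevalence.items():
        if p > 0 and any(drug_covers_clone(d, arch, cid) for d in drugs):
            total += p
    return min(total, 1.0)


def _coverage_map(
    drugs: Sequence[PrescriptionRecord], arch: ClonalArchitecture
) -> dict[str, frozenset]:
    return {
        d.drug: frozenset(c for c in arch.clones if drug_covers_clone(d, arch, c))
        for d in drugs
    }


def _finalize(
    strategy: str,
    chosen: Sequence[PrescriptionRecord],
    covered: Mapping[str, frozenset],
    uncovered: Iterable[str],
    arch: ClonalArchitecture,
) -> RegimenProposal:
    return RegimenProposal(
        strategy=strategy,
        drugs=tuple(chosen),
        covered_clones=dict(covered),
        uncovered_clones=frozenset(uncovered),
        coverage_by_sample={
            s: therapeutic_coverage(chosen, arch, s) for s in arch.sample_ids
        },
    )


def _trunk_plus_specific(
    arch: ClonalArchitecture, kb: EvidenceKB, thresholds: Thresholds
) -> RegimenProposal:
    chosen: list[PrescriptionRecord] = []
    covered: dict[str, frozenset] = {}
    uncovered: set[str] = set()
    trunk = trunk_genes(arch)
    trunk_ranked = prescribe_profile(trunk, kb, thresholds)
    trunk_drug = trunk_ranked[0] if trunk_ranked else None
    if trunk_drug is not None:
        chosen.append(trunk_drug)
    for cid in arch.clone_ids:
        private = full_complement(arch, cid) - trunk
        if not private:
            # nothing beyond the trunk: the trunk drug (if any) suffices
            if trunk_drug is not None:
                covered[trunk_drug.drug] = covered.get(trunk_drug.drug, frozenset()) | {cid}
            else:
                uncovered.add(cid)
            continue
        ranked = prescribe_profile(private, kb, thresholds)
        if ranked:
            top = ranked[0]
            if top.drug not in {r.drug for r in chosen}:
                chosen.append(top)
            covered[top.drug] = covered.get(top.drug, frozenset()) | {cid}
        else:
            uncovered.add(cid)
    return _finalize("trunk_plus_specific", chosen, covered, uncovered, arch)


def _candidate_pool(
    arch: ClonalArchitecture, kb: EvidenceKB, thresholds: Thresholds
) -> list[PrescriptionRecord]:
    pool: dict[str, PrescriptionRecord] = {}
    all_genes = set().union(*(full_complement(arch, c) for c in arch.clones))
    for rec in prescribe_profile(all_genes, kb, thresholds):
        pool[rec.drug] = rec
    return sorted(pool.values(), key=lambda r: (-r.best_dscore, r.drug))


def _clone_mass(arch: ClonalArchitecture) -> dict[str, float]:
    """Total prevalence mass of each clone across samples (for greedy ties)."""
    mass = {c: 0.0 for c in arch.clones}
    for s in arch.samples.values():
        for cid, p in s.prevalence.items():
            mass[cid] += p
    if not arch.samples:  # no sample info: weight clones equally
        mass = {c: 1.0 for c in arch.clones}
    return mass


def _greedy_cover(
    arch: ClonalArchitecture, kb: EvidenceKB, thresholds: Thresholds
) -> RegimenProposal:
    pool = _candidate_pool(arch, kb, thresholds)
    cover = _coverage_map(pool, arch)
    mass = _clone_mass(arch)
    coverable = set().union(*cover.values()) if cover else set()
    remaining = set(coverable)
    chosen: list[PrescriptionRecord] = []
    while remaining:
        best = min(
            pool,
            key=lambda r: (
                -sum(mass[c] for c in cover[r.drug] & remaining),
                -r.best_dscore,
                r.drug,  # name asc as final tie-break
            ),
        )
        gain = cover[best.drug] & remaining
        if not gain:
            break
        chosen.append(best)
        remaining -= gain
    covered = {r.drug: cover[r.drug] for r in chosen}
    uncovered = set(arch.clones) - (set().union(*covered.values()) if covered else set())
    return _finalize("greedy_cover", chosen, covered, uncovered, arch)


def _exact_cover(
    arch: ClonalArchitecture, kb: EvidenceKB, thresholds: Thresholds
) -> RegimenProposal:
    pool = _candidate_pool(arch, kb, thresholds)
    if len(pool) > EXACT_COVER_MAX_DRUGS:
        raise ValueError(
            f"exact_cover supports at most {EXACT_COVER_MAX_DRUGS} candidate drugs "
            f"(got {len(pool)}); use strategy='greedy_cover' instead"
        )
    cover = _coverage_map(pool, arch)
    coverable = set().union(*cover.values()) if cover else set()
    best_subset: tuple = ()
    for k in range(0, len(pool) + 1):
        found = None
        for combo in itertools.combinations(pool, k):
            hit = set().union(*(cover[r.drug] for r in combo)) if combo else set()
            if hit >= coverable:
                found = combo
                break  # combinations() is deterministic; first hit is the tie-break
        if found is not None:
            best_subset = found
            break
    chosen = list(best_subset)
    covered = {r.drug: cover[r.drug] for r in chosen}
    uncovered = set(arch.clones) - coverable
    return _finalize("exact_cover", chosen, covered, uncovered, arch)


def propose_regimen(
    arch: ClonalArchitecture,
    kb: EvidenceKB,
    thresholds: Thresholds = Thresholds(),
    strategy: str = "trunk_plus_specific",
) -> RegimenProposal:
    """Design a drug combination covering trunk and subclone populations.

    Strategies
    ----------
    ``trunk_plus_specific`` (default)
        The top-ranked candidate on the trunk genes (if any), then for each
        clone whose private alterations (complement minus trunk) are not yet
        addressed, its top-ranked clone-specific candidate.  Clones with
        private alterations but no passing candidate are reported uncovered.
    ``greedy_cover``
        Repeatedly add the drug covering the largest remaining
        prevalence-weighted clone mass; ties by (DScore desc, name asc).
    ``exact_cover``
        Minimum-cardinality drug set covering every coverable clone, by
        exhaustive search; refused above ``EXACT_COVER_MAX_DRUGS`` candidates.
    """
    if not arch.clones:
        raise ValueError("architecture has no clones")
    if strategy == "trunk_plus_specific":
        return _trunk_plus_specific(arch, kb, thresholds)
    if strategy == "greedy_cover":
        return _greedy_cover(arch, kb, thresholds)
    if strategy == "exact_cover":
        return _exact_cover(arch, kb, thresholds)
    raise ValueError(f"unknown strategy {strategy!r}")
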