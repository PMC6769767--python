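"""Gene–drug evidence knowledge base: data model, TSV reader, query and ranking.

The knowledge base holds curated gene–drug associations, each scored by a
gene-level evidence score (GScore, in [0, 1], how clinically/biologically
relevant the gene is in cancer) and a drug-level suitability score (DScore,
in [-1, 1]; positive values support sensitivity, negative ones resistance).
Associations are classed as direct target, biomarker, or pathway member, and
carry the drug's regulatory status.  Scores are inputs here: computing them
from primary evidence sources is upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "EvidenceEntry",
    "EvidenceKB",
    "KBValidationError",
    "RankedDrug",
    "load_kb",
    "query_genes",
    "rank_candidates",
    "normalize_gene",
    "normalize_drug",
]

RESPONSES = frozenset({"sensitivity", "resistance"})
ASSOCIATIONS = frozenset({"direct_target", "biomarker", "pathway_member"})
DRUG_STATUSES = frozenset({"approved", "clinical_trials", "experimental"})

KB_COLUMNS = (
    "gene",
    "drug",
    "gscore",
    "dscore",
    "response",
    "association",
    "drug_status",
    "indications",
)


class KBValidationError(ValueError):
    """Raised when a knowledge-base file or entry violates the schema."""


def normalize_gene(symbol: str) -> str:
    """Uppercase, whitespace-trimmed gene symbol."""
    return symbol.strip().upper()


def normalize_drug(name: str) -> str:
    """Lowercase, whitespace-trimmed drug name."""
    return name.strip().lower()


@dataclass(frozen=True)
class EvidenceEntry:
    """One gene–drug association with its evidence scores.

    Attributes
    ----------
    gene : str
        HGNC-style symbol, uppercase.
    drug : str
        Canonical drug name, lowercase.
    gscore : float
        Gene relevance score in [0, 1].
    dscore : float
        Drug suitability score in [-1, 1]; sign encodes response direction
        at the evidence level, while ``response`` is the curated call.
    response : str
        ``sensitivity`` or ``resistance``.
    association : str
        ``direct_target``, ``biomarker`` or ``pathway_member``.
    drug_status : str
        ``approved``, ``clinical_trials`` or ``experimental``.
    indications : frozenset[str]
        Cancer-type labels the drug is indicated for (may be empty).
    """

    gene: str
    drug: str
    gscore: float
    dscore: float
    response: str
    association: str
    drug_status: str
    indications: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        object.__setattr__(self, "drug", normalize_drug(self.drug))
        object.__setattr__(self, "indications", frozenset(self.indications))
        if not 0.0 <= self.gscore <= 1.0:
            raise KBValidationError(
                f"gscore {self.gscore!r} outside [0, 1] for {self.gene}/{self.drug}"
            )
        if not -1.0 <= self.dscore <= 1.0:
            raise KBValidationError(
                f"dscore {self.dscore!r} outside [-1, 1] for {self.gene}/{self.drug}"
            )
        if self.response not in RESPONSES:
            raise KBValidationError(f"unknown response token {self.response!r}")
        if self.association not in ASSOCIATIONS:
            raise KBValidationError(f"unknown association token {self.association!r}")
        if self.drug_status not in DRUG_STATUSES:
            raise KBValidationError(f"unknown drug_status token {self.drug_status!r}")


class EvidenceKB:
    """A collection of :class:`EvidenceEntry` with gene and drug indices.

    (gene, drug, association) triples are unique within a KB.
    """

    def __init__(self, entries: Iterable[EvidenceEntry]):
        self.entries: list[EvidenceEntry] = list(entries)
        seen: set[tuple[str, str, str]] = set()
        self._by_gene: dict[str, list[EvidenceEntry]] = {}
        self._by_drug: dict[str, list[EvidenceEntry]] = {}
        for e in self.entries:
            key = (e.gene, e.drug, e.association)
            if key in seen:
                raise KBValidationError(f"duplicate (gene, drug, association) triple {key}")
            seen.add(key)
            self._by_gene.setdefault(e.gene, []).append(e)
            self._by_drug.setdefault(e.drug, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def genes(self) -> set[str]:
        return set(self._by_gene)

    @property
    def drugs(self) -> set[str]:
        return set(self._by_drug)

    def entries_for_gene(self, gene: str) -> list[EvidenceEntry]:
        return list(self._by_gene.get(normalize_gene(gene), []))

    def entries_for_drug(self, drug: str) -> list[EvidenceEntry]:
        return list(self._by_drug.get(normalize_drug(drug), []))

    def to_tsv(self, path: str | Path) -> None:
        """Write the KB back out in the canonical eight-column TSV layout."""
        lines = ["\t".join(KB_COLUMNS)]
        for e in sorted(self.entries, key=lambda e: (e.gene, e.drug, e.association)):
            ind = ",".join(sorted(e.indications)) if e.indications else "."
            lines.append(
                f"{e.gene}\t{e.drug}\t{e.gscore:g}\t{e.dscore:g}\t"
                f"{e.response}\t{e.association}\t{e.drug_status}\t{ind}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def load_kb(path: str | Path) -> EvidenceKB:
    """Read a knowledge base from a tab-separated file.

    The file must carry a header naming the eight canonical columns
    (``gene drug gscore dscore response association drug_status indications``);
    indications are comma-joined tokens with ``.`` for empty.  Rows violating
    score ranges or enum vocabularies raise :class:`KBValidationError` naming
    the offending line.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise KBValidationError(f"{path}: empty KB file")
    header = [h.strip() for h in lines[0].split("\t")]
    if header != list(KB_COLUMNS):
        raise KBValidationError(
            f"{path}: bad header {header!r}; expected {list(KB_COLUMNS)!r}"
        )
    entries = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(KB_COLUMNS):
            raise KBValidationError(f"{path}:{lineno}: expected 8 fields, got {len(fields)}")
        gene, drug, gscore, dscore, response, association, status, ind = fields
        try:
            gs, ds = float(gscore), float(dscore)
        except ValueError as exc:
            raise KBValidationError(f"{path}:{lineno}: non-numeric score: {exc}") from None
        ind = ind.strip()
        indications = frozenset() if ind in {".", ""} else frozenset(
            t.strip() for t in ind.split(",") if t.strip()
        )
        try:
            entries.append(
                EvidenceEntry(gene, drug, gs, ds, response.strip(), association.strip(),
                              status.strip(), indications)
            )
        except KBValidationError as exc:
            raise KBValidationError(f"{path}:{lineno}: {exc}") from None
    try:
        return EvidenceKB(entries)
    except KBValidationError as exc:
        raise KBValidationError(f"{path}: {exc}") from None


def query_genes(kb: EvidenceKB, genes: Iterable[str]) -> list[EvidenceEntry]:
    """All KB entries whose gene is in ``genes``, in (gene, drug) order.

    Gene symbols are normalized before matching.  The query set must be
    non-empty after normalization; an empty *result* is allowed.
    """
    norm = {normalize_gene(g) for g in genes if g and g.strip()}
    if not norm:
        raise ValueError("query_genes requires a non-empty gene set")
    hits = [e for g in sorted(norm) for e in kb.entries_for_gene(g)]
    hits.sort(key=lambda e: (e.gene, e.drug, e.association))
    return hits


@dataclass(frozen=True)
class RankedDrug:
    """A candidate drug aggregated over its supporting evidence entries."""

    drug: str
    best_gscore: float
    best_dscore: float
    supporting_genes: frozenset
    drug_status: str
    entries: tuple = field(compare=False, default=())


def rank_candidates(
    entries: Sequence[EvidenceEntry],
    dscore_min: float = 0.7,
    gscore_min: float = 0.0,
    require_sensitivity: bool = True,
) -> list[RankedDrug]:
    """Group evidence entries by drug and rank surviving candidates.

    A drug is vetoed outright if *any* entry for it among the queried genes
    reports resistance — a profile carrying a resistance alteration for a
    drug disqualifies it regardless of co-occurring sensitivity evidence.
    Survivors are kept when their best supporting entry has
    ``dscore > dscore_min`` and ``gscore > gscore_min`` (strict), and sorted
    by (dscore desc, gscore desc, drug name asc) so higher-suitability drugs
    on stronger genes rank first.
    """
    if not -1.0 <= dscore_min <= 1.0 or not 0.0 <= gscore_min <= 1.0:
        raise ValueError("thresholds outside legal score ranges")
    by_drug: dict[str, list[EvidenceEntry]] = {}
    for e in entries:
        by_drug.setdefault(e.drug, []).append(e)
    ranked = []
    for drug, drug_entries in by_drug.items():
        if require_sensitivity and any(e.response == "resistance" for e in drug_entries):
            continue  # resistance veto
        support = [e for e in drug_entries if e.response == "sensitivity"] \
            if require_sensitivity else list(drug_entries)
        if not support:
            continue
        best_d = max(e.dscore for e in support)
        best_g = max(e.gscore for e in support)
        if not (best_d > dscore_min and best_g > gscore_min):
            continue
        # prefer the most advanced regulatory status among supporting entries
        status_order = {"approved": 0, "clinical_trials": 1, "experimental": 2}
        status = min((e.drug_status for e in support), key=status_order.__getitem__)
        ranked.append(
            RankedDrug(
                drug=drug,
                best_gscore=best_g,
                best_dscore=best_d,
                supporting_genes=frozenset(e.gene for e in support),
                drug_status=status,
                entries=tuple(support),
            )
        )
    ranked.sort(key=lambda r: (-r.best_dscore, -r.best_gscore, r.drug))
    return ranked
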