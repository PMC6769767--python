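"""Clonal architecture model and its set/graph computations.

A tumour's clonal architecture is a rooted phylogeny of clones, each clone
carrying the set of genes *newly* mutated on its branch; a clone's full
mutation complement is the union of novel sets along the root-to-clone
path.  Per-sample (region or timepoint) clone prevalences describe the
cellular composition of each sequenced sample.  From these the module
derives trunk (clonal) mutations, the genes an ITH-aware analysis reveals
in a region, the predominant clone a bulk analysis would see, and the
temporal selection of low-frequency variants that expand at relapse.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .evidence_kb import normalize_gene

__all__ = [
    "Clone",
    "SampleComposition",
    "ClonalArchitecture",
    "TemporalVafProfile",
    "TemporalSelection",
    "full_complement",
    "trunk_genes",
    "region_union_genes",
    "predominant_clone",
    "select_temporal_genes",
    "partition_events",
    "load_vaf_table",
]

PREVALENCE_TOL = 1e-6


@dataclass(frozen=True)
class Clone:
    """A tumour cell population: its parent in the phylogeny and the genes
    newly mutated on the branch leading to it."""

    id: str
    parent: str | None
    novel_genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "novel_genes", frozenset(normalize_gene(g) for g in self.novel_genes)
        )


@dataclass(frozen=True)
class SampleComposition:
    """Clone prevalence fractions in one sample (region or timepoint).

    Fractions of clones present must sum to 1 within ``PREVALENCE_TOL``;
    absent clones are implicitly at 0.
    """

    sample_id: str
    prevalence: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.prevalence.values())
        if abs(total - 1.0) > PREVALENCE_TOL:
            raise ValueError(
                f"sample {self.sample_id!r}: prevalences sum to {total}, not 1"
            )
        for cid, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sample {self.sample_id!r}: prevalence {p} for {cid}")


class ClonalArchitecture:
    """A clone phylogeny plus per-sample clone prevalences.

    Exactly one root (parent ``None``) is required and parent links must
    form a tree; every prevalence key must name a declared clone.
    """

    def __init__(self, clones: Sequence[Clone], samples: Sequence[SampleComposition]):
        self.clones = {c.id: c for c in clones}
        if len(self.clones) != len(clones):
            raise ValueError("duplicate clone ids")
        roots = [c.id for c in clones if c.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root clone, found {roots}")
        self.root = roots[0]
        for c in clones:
            if c.parent is not None and c.parent not in self.clones:
                raise ValueError(f"clone {c.id}: unknown parent {c.parent}")
        # cycle check via root-path walk; also caches complements
        self._complement: dict[str, frozenset] = {}
        for cid in self.clones:
            self._complement[cid] = self._walk_complement(cid)
        self.samples = {s.sample_id: s for s in samples}
        if len(self.samples) != len(samples):
            raise ValueError("duplicate sample ids")
        for s in samples:
            unknown = set(s.prevalence) - set(self.clones)
            if unknown:
                raise ValueError(f"sample {s.sample_id}: unknown clones {sorted(unknown)}")

    def _walk_complement(self, clone_id: str) -> frozenset:
        genes: set[str] = set()
        seen: set[str] = set()
        cur: str | None = clone_id
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle in phylogeny at clone {cur}")
            seen.add(cur)
            genes |= self.clones[cur].novel_genes
            cur = self.clones[cur].parent
        return frozenset(genes)

    @property
    def clone_ids(self) -> list[str]:
        return sorted(self.clones)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.samples)

    # ------------------------------------------------------------------ io
    @classmethod
    def from_dict(cls, d: Mapping, full_complements: bool = False) -> "ClonalArchitecture":
        clones = [
            Clone(c["id"], c.get("parent"), frozenset(c["novel_genes"]))
            for c in d["clones"]
        ]
        if full_complements:
            clones = _novelize(clones)
        samples = [
            SampleComposition(s["id"], dict(s["prevalence"])) for s in d.get("samples", [])
        ]
        return cls(clones, samples)

    @classmethod
    def from_json(cls, path: str | Path, full_complements: bool = False) -> "ClonalArchitecture":
        """Load from JSON.  With ``full_complements=True`` the per-clone gene
        lists are interpreted as full complements and converted to novel sets."""
        return cls.from_dict(json.loads(Path(path).read_text()), full_complements)

    def to_dict(self) -> dict:
        return {
            "clones": [
                {"id": c.id, "parent": c.parent, "novel_genes": sorted(c.novel_genes)}
                for c in sorted(self.clones.values(), key=lambda c: c.id)
            ],
            "samples": [
                {"id": s.sample_id,
                 "prevalence": {k: s.prevalence[k] for k in sorted(s.prevalence)}}
                for s in sorted(self.samples.values(), key=lambda s: s.sample_id)
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def _novelize(clones: Sequence[Clone]) -> list[Clone]:
    """Convert clones whose gene sets are full complements into novel sets."""
    by_id = {c.id: c for c in clones}
    out = []
    for c in clones:
        if c.parent is None:
            out.append(c)
        else:
            out.append(Clone(c.id, c.parent, c.novel_genes - by_id[c.parent].novel_genes))
    return out


# ----------------------------------------------------------------- queries

def full_complement(arch: ClonalArchitecture, clone_id: str) -> set[str]:
    """All genes mutated in a clone: the union of novel sets on its root path."""
    if clone_id not in arch.clones:
        raise KeyError(f"unknown clone {clone_id!r}")
    return set(arch._complement[clone_id])


def trunk_genes(arch: ClonalArchitecture) -> set[str]:
    """Clonal (trunk) mutations: genes present in every clone's complement."""
    ids = list(arch.clones)
    trunk = set(arch._complement[ids[0]])
    for cid in ids[1:]:
        trunk &= arch._complement[cid]
    return trunk


def region_union_genes(arch: ClonalArchitecture, sample_id: str) -> set[str]:
    """Genes an ITH-aware analysis reveals in a sample: the union of
    complements over clones present at prevalence > 0."""
    if sample_id not in arch.samples:
        raise KeyError(f"unknown sample {sample_id!r}")
    genes: set[str] = set()
    for cid, p in arch.samples[sample_id].prevalence.items():
        if p > 0:
            genes |= arch._complement[cid]
    return genes


def predominant_clone(arch: ClonalArchitecture, sample_id: str) -> str:
    """The most prevalent clone in a sample — what a single-sample bulk
    analysis is assumed to detect.  Exact ties resolve to the
    lexicographically smallest id, with a warning."""
    if sample_id not in arch.samples:
        raise KeyError(f"unknown sample {sample_id!r}")
    present = [(cid, p) for cid, p in arch.samples[sample_id].prevalence.items() if p > 0]
    if not present:
        raise ValueError(f"sample {sample_id!r} has no clone at prevalence > 0")
    best_p = max(p for _, p in present)
    winners = sorted(cid for cid, p in present if p == best_p)
    if len(winners) > 1:
        warnings.warn(
            f"sample {sample_id!r}: prevalence tie among {winners}; picking {winners[0]}",
            stacklevel=2,
        )
    return winners[0]


# ------------------------------------------------------ temporal selection

@dataclass(frozen=True)
class TemporalVafProfile:
    """Per-gene variant allele frequencies across timepoints.

    A missing timepoint means the variant was not detected there.
    """

    gene: str
    vaf_by_timepoint: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene(self.gene))
        for t, v in self.vaf_by_timepoint.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.gene}: VAF {v} at {t!r} outside [0, 1]")


class TemporalSelection(NamedTuple):
    """Genes positively selected between two timepoints, by origin."""

    pre_existing: set  # detected at t0 below low_vaf, expanded by t1
    relapse_specific: set  # absent at t0, present above rise_min at t1

    @property
    def genes(self) -> set:
        return self.pre_existing | self.relapse_specific


def select_temporal_genes(
    profiles: Iterable[TemporalVafProfile],
    t0: str,
    t1: str,
    low_vaf: float = 0.01,
    rise_min: float = 0.10,
) -> TemporalSelection:
    """Genes whose variants were rare or absent at ``t0`` but expanded by ``t1``.

    A gene is *pre-existing selected* when detected at ``t0`` with
    ``vaf(t0) < low_vaf`` and present at ``t1`` with ``vaf(t1) >= rise_min``;
    it is *relapse-specific* when absent at ``t0`` and ``vaf(t1) >= rise_min``.
    These are the variants a bulk caller at standard VAF cutoffs would have
    missed at diagnosis yet which drive the relapsed tumour.
    """
    if not (0.0 < low_vaf < 1.0 and 0.0 < rise_min < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    if low_vaf >= rise_min:
        raise ValueError("low_vaf must be smaller than rise_min")
    profiles = list(profiles)
    timepoints = {t for p in profiles for t in p.vaf_by_timepoint}
    for t in (t0, t1):
        if profiles and t not in timepoints:
            raise KeyError(f"timepoint {t!r} absent from all profiles")
    pre, rel = set(), set()
    for p in profiles:
        v1 = p.vaf_by_timepoint.get(t1)
        if v1 is None or v1 < rise_min:
            continue
        v0 = p.vaf_by_timepoint.get(t0)
        if v0 is None:
            rel.add(p.gene)
        elif v0 < low_vaf:
            pre.add(p.gene)
    return TemporalSelection(pre, rel)


def partition_events(primary: Iterable, relapse: Iterable) -> tuple[int, int, int]:
    """Partition event sets into (shared, primary-specific, relapse-specific)
    counts; the three counts sum to the union cardinality."""
    p, r = set(primary), set(relapse)
    return len(p & r), len(p - r), len(r - p)


def load_vaf_table(path: str | Path) -> list[TemporalVafProfile]:
    """Read temporal VAF profiles from a TSV with columns ``gene  timepoint  vaf``."""
    per_gene: dict[str, dict[str, float]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].strip().lower() == "gene":
            continue
        gene, t, vaf = normalize_gene(fields[0]), fields[1].strip(), float(fields[2])
        per_gene.setdefault(gene, {})[t] = vaf
    return [TemporalVafProfile(g, v) for g, v in sorted(per_gene.items())]
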