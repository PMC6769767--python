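"""Readers and filters turning raw genomic inputs into per-patient gene sets.

Somatic variants arrive as VCF; only records whose FILTER is exactly PASS
are trusted as somatic.  Copy-number calls are kept only when supported by a
concordant expression change (gain with over-expression, loss with
under-expression, |z| above threshold).  Drug names from clinical records
are standardised through an alias table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .evidence_kb import normalize_drug, normalize_gene

__all__ = [
    "VariantRecord",
    "CnvCall",
    "DrugAliasTable",
    "read_vcf_pass_genes",
    "cnv_expression_filter",
    "load_cnv_calls",
    "load_alias_table",
    "normalize_drug_names",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantRecord:
    """A somatic small variant with its gene annotation and filter status."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None
    filter_status: str
    vaf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")


@dataclass(frozen=True)
class CnvCall:
    """A per-gene copy-number call paired with the gene's expression z-score."""

    gene: str
    direction: str  # "gain" | "loss"
    expr_z: float

    def __post_init__(self) -> None:
        if self.direction not in {"gain", "loss"}:
            raise ValueError(f"direction must be 'gain' or 'loss', got {self.direction!r}")


def read_vcf_pass_genes(
    path: str | Path,
    gene_field: str = "GENE",
    gene_lookup: dict | None = None,
) -> set[str]:
    """Gene symbols of variants whose FILTER is exactly PASS.

    Gene annotations come from INFO[``gene_field``]; multi-gene annotations
    are split on commas and every symbol is emitted.  Alternatively a
    ``gene_lookup`` mapping ``(chrom, pos)`` to a symbol may be supplied for
    unannotated VCFs.  PASS records lacking any gene annotation are skipped
    with a warning; non-PASS records are dropped and counted.
    """
    path = Path(path)
    genes: set[str] = set()
    n_dropped = n_pass = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if list(rec.filter.keys()) != ["PASS"]:
                n_dropped += 1
                continue
            n_pass += 1
            raw = rec.info.get(gene_field) if gene_field in rec.info else None
            if raw is None and gene_lookup is not None:
                raw = gene_lookup.get((rec.chrom, rec.pos))
            if raw is None:
                warnings.warn(
                    f"PASS record {rec.chrom}:{rec.pos} has no gene annotation; skipped",
                    stacklevel=2,
                )
                continue
            if isinstance(raw, (tuple, list)):
                raw = ",".join(str(x) for x in raw)
            for sym in str(raw).split(","):
                if sym.strip():
                    genes.add(normalize_gene(sym))
    logger.info("%s: %d PASS records kept, %d non-PASS dropped", path.name, n_pass, n_dropped)
    return genes


def cnv_expression_filter(
    calls: Iterable[CnvCall],
    z_min: float = 2.0,
    require_concordance: bool = True,
) -> set[str]:
    """Genes whose copy-number change is supported by expression.

    A gain must show over-expression (``z > z_min``) and a loss
    under-expression (``z < -z_min``); both comparisons strict.  With
    ``require_concordance=False`` only the magnitude rule ``|z| > z_min``
    applies.
    """
    if z_min <= 0:
        raise ValueError("z_min must be positive")
    kept: set[str] = set()
    for c in calls:
        if require_concordance:
            ok = c.expr_z > z_min if c.direction == "gain" else c.expr_z < -z_min
        else:
            ok = abs(c.expr_z) > z_min
        if ok:
            kept.add(normalize_gene(c.gene))
    return kept


def load_cnv_calls(path: str | Path) -> list[CnvCall]:
    """Read CNV calls from a TSV with columns ``gene  direction  expr_z``."""
    calls = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].strip().lower() == "gene":
            continue
        gene, direction, z = fields[0], fields[1].strip().lower(), float(fields[2])
        calls.append(CnvCall(gene=gene, direction=direction, expr_z=z))
    return calls


class DrugAliasTable:
    """Mapping from drug-name aliases to canonical names (case-insensitive).

    Canonical names always map to themselves, so resolution is idempotent.
    """

    def __init__(self, aliases: dict):
        self._map: dict[str, str] = {}
        for alias, canonical in aliases.items():
            canon = normalize_drug(canonical)
            self._map[normalize_drug(alias)] = canon
            self._map.setdefault(canon, canon)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, name: str) -> bool:
        return normalize_drug(name) in self._map

    def resolve(self, name: str) -> str:
        key = normalize_drug(name)
        if key in self._map:
            return self._map[key]
        warnings.warn(f"drug name {name!r} not in alias table; passed through", stacklevel=2)
        return key


def load_alias_table(path: str | Path) -> DrugAliasTable:
    """Read a two-column TSV (``alias  canonical``) into a DrugAliasTable."""
    aliases = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        alias, canonical = line.split("\t")[:2]
        aliases[alias] = canonical
    return DrugAliasTable(aliases)


def normalize_drug_names(names: Sequence[str], aliases: DrugAliasTable) -> list[str]:
    """Resolve each name through the alias table, preserving order."""
    return [aliases.resolve(n) for n in names]
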