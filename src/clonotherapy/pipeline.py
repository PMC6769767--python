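"""Orchestration of the three analyses: responder stratification with
survival comparison, temporal-heterogeneity prescription, and spatial
(multi-region) prescription with regimen design.

Each runner is a pure function of its inputs and returns a JSON-serialisable
report; ``write_report`` persists the report together with a manifest
(config, input digests, package version) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import __version__
from .clonal_model import (
    ClonalArchitecture,
    TemporalVafProfile,
    select_temporal_genes,
)
from .evidence_kb import EvidenceKB
from .prescription import (
    PrescriptionRecord,
    Thresholds,
    alternative_therapies,
    bulk_vs_ith,
    classify_response,
    clone_druggability,
)
from .regimen import propose_regimen
from .survival import SurvivalRecord, stratified_os_analysis

__all__ = [
    "RunConfig",
    "run_stratification",
    "run_temporal",
    "run_spatial",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-level thresholds and bookkeeping.

    Defaults follow the evidence rules used throughout: candidate drugs need
    DScore > 0.7; cohort-level prescription additionally requires
    GScore > 0.6; temporal selection uses the <1% detection / 10% expansion
    VAF rule; CNV support needs |z| > 2.
    """

    dscore_min: float = 0.7
    gscore_min: float = 0.6
    low_vaf: float = 0.01
    rise_min: float = 0.10
    z_min: float = 2.0
    drug_classes: Mapping[str, tuple] = field(default_factory=dict)
    seed: int = 0

    def thresholds(self, cohort_level: bool = False) -> Thresholds:
        """Per-clone analyses rank on the DScore rule alone; cohort-level
        analyses add the GScore floor."""
        return Thresholds(
            dscore_min=self.dscore_min,
            gscore_min=self.gscore_min if cohort_level else 0.0,
        )


def _records_json(records: Iterable[PrescriptionRecord]) -> list[dict]:
    return [
        {
            "drug": r.drug,
            "status": r.drug_status,
            "response": r.response,
            "best_gscore": r.best_gscore,
            "best_dscore": r.best_dscore,
            "supporting_genes": sorted(r.supporting_genes),
            "associations": {g: list(a) for g, a in r.associations.items()},
        }
        for r in records
    ]


def run_stratification(
    cfg: RunConfig,
    profiles: Mapping[str, Iterable[str]],
    survival: Sequence[SurvivalRecord],
    kb: EvidenceKB,
    drug_class_name: str,
) -> dict:
    """A-priori responder stratification with overall-survival comparison.

    Classifies every patient against the named drug class, compares the two
    strata by Kaplan–Meier / log-rank, and proposes alternative (off-class)
    therapies for each non-responder.
    """
    if drug_class_name not in cfg.drug_classes:
        raise KeyError(f"drug class {drug_class_name!r} not configured")
    drug_class = cfg.drug_classes[drug_class_name]
    labels = [
        classify_response(pid, genes, drug_class, kb)
        for pid, genes in sorted(profiles.items())
    ]
    logger.info("stratification: %d patients classified", len(labels))
    os_report = stratified_os_analysis(labels, survival)
    os_report = {k: v for k, v in os_report.items() if k != "km"}
    alternatives = {}
    for lab in labels:
        if lab.label == "non_responder":
            alt = alternative_therapies(
                profiles[lab.patient_id], drug_class, kb, cfg.thresholds(cohort_level=True)
            )
            alternatives[lab.patient_id] = _records_json(alt)
    n_nonresp = sum(1 for lab in labels if lab.label == "non_responder")
    n_with_alt = sum(1 for v in alternatives.values() if v)
    return {
        "analysis": "stratification",
        "drug_class": {drug_class_name: sorted(drug_class)},
        "labels": [dataclasses.asdict(lab) for lab in labels],
        "label_counts": {
            reason: sum(1 for lab in labels if lab.reason == reason)
            for reason in ("sensitivity_only", "resistance_present", "no_evidence")
        },
        "survival": os_report,
        "alternative_therapies": alternatives,
        "alternative_therapy_rate": (n_with_alt / n_nonresp) if n_nonresp else None,
    }


def run_temporal(
    cfg: RunConfig,
    profiles: Sequence[TemporalVafProfile],
    kb: EvidenceKB,
    t0: str,
    t1: str,
) -> dict:
    """Temporal-heterogeneity prescription between two timepoints.

    Selects genes rare (<``low_vaf``) or absent at ``t0`` that expanded to at
    least ``rise_min`` VAF by ``t1``, then ranks candidate drugs for the
    selected genes, flagging each selected gene as pre-existing or
    relapse-specific.
    """
    timepoints = sorted({t for p in profiles for t in p.vaf_by_timepoint})
    if len(timepoints) < 2:
        raise ValueError(f"temporal analysis needs >= 2 timepoints, found {timepoints}")
    sel = select_temporal_genes(profiles, t0, t1, cfg.low_vaf, cfg.rise_min)
    from .prescription import druggable_genes, prescribe_profile

    ranked = prescribe_profile(sel.genes, kb, cfg.thresholds()) if sel.genes else []
    logger.info(
        "temporal: %d genes selected (%d pre-existing, %d relapse-specific)",
        len(sel.genes), len(sel.pre_existing), len(sel.relapse_specific),
    )
    return {
        "analysis": "temporal",
        "timepoints": {"t0": t0, "t1": t1},
        "selected_genes": sorted(sel.genes),
        "pre_existing": sorted(sel.pre_existing),
        "relapse_specific": sorted(sel.relapse_specific),
        "n_selected": len(sel.genes),
        "n_druggable": len(druggable_genes(sel.genes, kb)),
        "prescriptions": _records_json(ranked),
    }


def run_spatial(
    cfg: RunConfig,
    arch: ClonalArchitecture,
    kb: EvidenceKB,
    strategy: str = "trunk_plus_specific",
) -> dict:
    """Spatial-heterogeneity analysis of a multi-region architecture.

    Per region: bulk-vs-ITH comparison, per-clone druggability, and a
    combination-regimen proposal; a cross-region regimen is reported as the
    union of per-region drug sets.
    """
    if not arch.samples:
        raise ValueError("spatial analysis needs >= 1 sample")
    thresholds = cfg.thresholds()
    per_sample = {}
    regimen = propose_regimen(arch, kb, thresholds, strategy=strategy)
    for sid in arch.sample_ids:
        cmp = bulk_vs_ith(arch, sid, kb, thresholds)
        present = [c for c, p in arch.samples[sid].prevalence.items() if p > 0]
        per_sample[sid] = {
            "bulk_clone": cmp.bulk_clone,
            "bulk_gene_count": cmp.bulk_gene_count,
            "ith_gene_count": cmp.ith_gene_count,
            "bulk_druggable_count": len(cmp.bulk_druggable_genes),
            "ith_druggable_count": len(cmp.ith_druggable_genes),
            "bulk_drugs": _records_json(cmp.bulk_drugs),
            "ith_drugs": _records_json(cmp.ith_drugs),
            "clone_druggability": {
                c: clone_druggability(arch, sid, c, kb) for c in sorted(present)
            },
        }
    return {
        "analysis": "spatial",
        "samples": per_sample,
        "regimen": {
            "strategy": regimen.strategy,
            "drugs": _records_json(regimen.drugs),
            "covered_clones": {d: sorted(c) for d, c in regimen.covered_clones.items()},
            "uncovered_clones": sorted(regimen.uncovered_clones),
            "coverage_by_sample": dict(regimen.coverage_by_sample),
        },
    }


def _digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()[:16]


def write_report(
    report: Mapping,
    out_dir: str | Path,
    cfg: RunConfig,
    inputs: Mapping[str, Path] | None = None,
) -> Path:
    """Persist a report plus a reproducibility manifest.

    The manifest records the configuration, SHA-256 digests of every input
    file, and the package version — enough to re-run the analysis and obtain
    a byte-identical report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = report.get("analysis", "report")
    report_path = out_dir / f"{name}.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    manifest = {
        "config": dataclasses.asdict(cfg),
        "inputs": {
            k: _digest(Path(p).read_bytes()) for k, p in (inputs or {}).items()
        },
        "report_digest": _digest(report_path.read_bytes()),
        "version": __version__,
    }
    (out_dir / f"{name}.manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return report_path
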