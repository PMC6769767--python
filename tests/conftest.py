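"""Shared fixtures: small evidence bases, random architectures, and the
transcribed case-study bundle."""

from __future__ import annotations

import numpy as np
import pytest

from clonotherapy import (
    ClonalArchitecture,
    Clone,
    EvidenceEntry,
    EvidenceKB,
    SampleComposition,
    case_study_fixtures,
)


@pytest.fixture(scope="session")
def fixtures():
    return case_study_fixtures()


@pytest.fixture
def small_kb() -> EvidenceKB:
    e = EvidenceEntry
    return EvidenceKB([
        e("BRAF", "vemurafenib", 0.9, 0.95, "sensitivity", "direct_target", "approved"),
        e("BRAF", "dabrafenib", 0.9, 0.9, "sensitivity", "direct_target", "approved"),
        e("KRAS", "vemurafenib", 0.8, -0.8, "resistance", "biomarker", "approved"),
        e("TP53", "paclitaxel", 0.8, 0.86, "sensitivity", "biomarker", "approved"),
        e("EGFR", "erlotinib", 0.95, 0.92, "sensitivity", "direct_target", "approved"),
        e("EGFR", "gefitinib", 0.95, 0.65, "sensitivity", "direct_target", "approved"),
        e("MET", "crizotinib", 0.7, 0.75, "sensitivity", "direct_target", "clinical_trials"),
    ])


def random_kb(rng: np.random.Generator, n_genes: int = 20, n_entries: int = 30,
              sensitivity_prob: float = 0.8) -> EvidenceKB:
    """Small random KB for oracle comparisons (dedup on the unique triple)."""
    genes = [f"G{i}" for i in range(n_genes)]
    drugs = [f"d{i}" for i in range(max(5, n_genes // 2))]
    assoc = ["direct_target", "biomarker", "pathway_member"]
    status = ["approved", "clinical_trials", "experimental"]
    entries = {}
    for _ in range(n_entries):
        response = "sensitivity" if rng.random() < sensitivity_prob else "resistance"
        mag = float(rng.uniform(0, 1))
        e = EvidenceEntry(
            gene=str(rng.choice(genes)),
            drug=str(rng.choice(drugs)),
            gscore=float(rng.uniform(0, 1)),
            dscore=mag if response == "sensitivity" else -mag,
            response=response,
            association=str(rng.choice(assoc)),
            drug_status=str(rng.choice(status)),
        )
        entries[(e.gene, e.drug, e.association)] = e
    return EvidenceKB(entries.values())


def random_architecture(
    rng: np.random.Generator, n_clones: int = 5, n_samples: int = 2,
    gene_pool: int = 40,
) -> ClonalArchitecture:
    """Random clone tree with possibly overlapping novel sets and Dirichlet
    sample prevalences — independent of the package's own generator."""
    genes = [f"G{i}" for i in range(gene_pool)]
    ids = [f"C{i}" for i in range(1, n_clones + 1)]
    clones = [Clone(ids[0], None, frozenset(
        rng.choice(genes, size=rng.integers(1, 6), replace=False)))]
    for cid in ids[1:]:
        parent = ids[int(rng.integers(0, len(clones)))]
        novel = frozenset(rng.choice(genes, size=rng.integers(1, 6), replace=False))
        clones.append(Clone(cid, parent, novel))
    samples = []
    for s in range(n_samples):
        k = int(rng.integers(1, n_clones + 1))
        present = [str(c) for c in rng.choice(ids, size=k, replace=False)]
        prev = rng.dirichlet(np.ones(k))
        samples.append(SampleComposition(f"S{s}", dict(zip(present, prev.tolist()))))
    return ClonalArchitecture(clones, samples)
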