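"""Deterministic generators and transcribed case-study fixtures.

Everything the pipeline consumes can be produced here with no downloads:
random clonal architectures, gene–drug knowledge bases and two-arm survival
cohorts (all pure functions of a seed), plus three transcribed patient
fixtures — an AML relapse case (UPN933124) for temporal heterogeneity and
two multi-region NSCLC cases (CRUK0056, CRUK0016) for spatial
heterogeneity and regimen design.

Fixture gene names beyond the handful printed in the source figures
(ERBB4, FLT4, ETV6, TMEM117, TP53, CAMK4, DDR2) are synthetic
placeholders; analyses against these fixtures rely only on set
cardinalities and the printed score values, never on invented names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .clonal_model import Clone, ClonalArchitecture, SampleComposition, TemporalVafProfile
from .evidence_kb import EvidenceEntry, EvidenceKB
from .survival import SurvivalRecord

__all__ = [
    "SimulationConfig",
    "CohortConfig",
    "CohortBundle",
    "PatientFixture",
    "gen_architecture",
    "gen_kb",
    "gen_cohort",
    "case_study_fixtures",
]


@dataclass(frozen=True)
class CohortConfig:
    """Two-arm synthetic cohort design.

    Responders carry sensitivity evidence (and no resistance) for the drug
    class; their death hazard is ``baseline_hazard * hazard_ratio``
    (``hazard_ratio < 1`` means protection).  Non-responders carry either a
    resistance alteration or no evidence at all and die at the baseline
    hazard.  Censoring is independent and uniform over each subject's
    survival time, applied with probability ``censor_prob``.
    """

    n_patients: int = 150
    responder_fraction: float = 0.5
    hazard_ratio: float = 0.5
    baseline_hazard: float = 1.0 / 365.0  # per day
    censor_prob: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if not 0.0 <= self.censor_prob <= 1.0:
            raise ValueError("censor_prob must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Master configuration for all synthetic generators.

    One pseudo-random stream per generator is split from ``seed``, so adding
    or re-running one generator never perturbs the others.
    """

    seed: int = 0
    n_clones: int = 4
    n_trunk_genes: int = 30
    clone_gene_rate: float = 5.0  # mean novel genes per non-root clone
    n_samples: int = 2
    dirichlet_alpha: float = 1.5
    n_genes_kb: int = 200
    druggable_fraction: float = 0.3
    sensitivity_prob: float = 0.8
    gscore_bounds: tuple = (0.0, 1.0)
    dscore_bounds: tuple = (0.0, 1.0)  # magnitude; sign follows response
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if not 0.0 <= self.druggable_fraction <= 1.0:
            raise ValueError("druggable_fraction must be in [0, 1]")
        if not 0.0 <= self.sensitivity_prob <= 1.0:
            raise ValueError("sensitivity_prob must be in [0, 1]")


_STREAM = {"architecture": 0, "kb": 1, "cohort": 2}


def _rng(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(_STREAM[stream],))
    )


def _gene_universe(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


# ------------------------------------------------------------ architecture

def gen_architecture(cfg: SimulationConfig) -> ClonalArchitecture:
    """Random clonal architecture: a uniform random phylogeny over
    ``n_clones`` clones, disjoint novel gene sets drawn without replacement
    from the gene universe, and Dirichlet clone prevalences per sample over
    a random subset of clones."""
    rng = _rng(cfg, "architecture")
    universe = _gene_universe(cfg.n_genes_kb)
    rng.shuffle(universe)
    cursor = 0

    def draw(n: int) -> frozenset:
        nonlocal cursor
        if cursor + n > len(universe):
            raise ValueError(
                f"gene universe of {len(universe)} exhausted; lower n_trunk_genes "
                "or clone_gene_rate, or raise n_genes_kb"
            )
        out = frozenset(universe[cursor:cursor + n])
        cursor += n
        return out

    clone_ids = [f"C{i}" for i in range(1, cfg.n_clones + 1)]
    clones = [Clone(clone_ids[0], None, draw(cfg.n_trunk_genes))]
    for cid in clone_ids[1:]:
        parent = clone_ids[rng.integers(0, len(clones))]
        n_novel = max(1, int(rng.poisson(cfg.clone_gene_rate)))
        clones.append(Clone(cid, parent, draw(n_novel)))

    samples = []
    for s in range(1, cfg.n_samples + 1):
        k = int(rng.integers(1, cfg.n_clones + 1))
        present = sorted(rng.choice(clone_ids, size=k, replace=False))
        prev = rng.dirichlet(np.full(k, cfg.dirichlet_alpha))
        samples.append(SampleComposition(f"R{s}", dict(zip(present, prev.tolist()))))
    return ClonalArchitecture(clones, samples)


# --------------------------------------------------------------------- kb

_ASSOCIATIONS = ("direct_target", "biomarker", "pathway_member")
_STATUSES = ("approved", "clinical_trials", "experimental")


def gen_kb(cfg: SimulationConfig) -> EvidenceKB:
    """Random evidence knowledge base over the same gene universe the
    architecture generator uses.

    Each gene is druggable with probability ``druggable_fraction``; a
    druggable gene receives 1–3 entries to distinct drugs, with GScore and
    DScore magnitude uniform within the configured bounds, sensitivity
    response with probability ``sensitivity_prob`` (resistance entries get a
    negative DScore), and association/status uniform over their vocabularies.
    """
    rng = _rng(cfg, "kb")
    universe = _gene_universe(cfg.n_genes_kb)
    n_drugs = max(10, cfg.n_genes_kb // 2)
    drug_pool = [f"drug-{i:04d}" for i in range(1, n_drugs + 1)]
    glo, ghi = cfg.gscore_bounds
    dlo, dhi = cfg.dscore_bounds
    entries = []
    for gene in universe:
        if rng.random() >= cfg.druggable_fraction:
            continue
        for drug_idx in rng.choice(n_drugs, size=int(rng.integers(1, 4)), replace=False):
            response = "sensitivity" if rng.random() < cfg.sensitivity_prob else "resistance"
            dmag = float(rng.uniform(dlo, dhi))
            entries.append(
                EvidenceEntry(
                    gene=gene,
                    drug=drug_pool[int(drug_idx)],
                    gscore=float(rng.uniform(glo, ghi)),
                    dscore=dmag if response == "sensitivity" else -dmag,
                    response=response,
                    association=_ASSOCIATIONS[int(rng.integers(0, 3))],
                    drug_status=_STATUSES[int(rng.integers(0, 3))],
                )
            )
    return EvidenceKB(entries)


# ------------------------------------------------------------------ cohort

#: drug class used by the synthetic cohort (stands in for a targeted-therapy
#: class such as EGFR inhibitors)
COHORT_DRUG_CLASS = ("inhibitor-alpha", "inhibitor-beta")


@dataclass(frozen=True)
class CohortBundle:
    """Everything a stratification analysis needs, generated jointly."""

    labels: tuple  # intended ResponderLabel-compatible (patient_id, label, reason)
    survival: tuple  # SurvivalRecord per patient
    profiles: dict  # patient_id -> frozenset of altered genes
    kb: EvidenceKB
    drug_class: tuple = COHORT_DRUG_CLASS


def _cohort_kb() -> EvidenceKB:
    """Fixed evidence base for synthetic cohorts: class-drug sensitivity and
    resistance genes, plus off-class drugs enabling alternative therapies."""
    e = EvidenceEntry
    return EvidenceKB([
        e("SENSG1", "inhibitor-alpha", 0.8, 0.85, "sensitivity", "biomarker", "approved"),
        e("SENSG2", "inhibitor-beta", 0.7, 0.8, "sensitivity", "direct_target", "approved"),
        e("RESG1", "inhibitor-alpha", 0.8, -0.9, "resistance", "biomarker", "approved"),
        e("RESG2", "inhibitor-beta", 0.75, -0.8, "resistance", "biomarker", "approved"),
        # off-class options reachable for non-responders
        e("RESG1", "altdrug-a", 0.7, 0.8, "sensitivity", "direct_target", "approved"),
        e("BGDRUGGABLE", "altdrug-b", 0.65, 0.75, "sensitivity",
          "pathway_member", "clinical_trials"),
    ])


def gen_cohort(cfg: SimulationConfig) -> CohortBundle:
    """Synthetic two-arm cohort with survival tied to the responder label.

    Responder profiles carry a class-sensitivity gene and no class-resistance
    gene; non-responders alternate between a resistance-bearing profile and a
    no-evidence profile.  Applying the a-priori response classifier to the
    generated profiles recovers the generating label for every patient by
    construction.  Survival is exponential (responders at
    ``baseline_hazard * hazard_ratio``) with independent uniform censoring.
    """
    from .prescription import classify_response  # deferred: avoids import cycle

    rng = _rng(cfg, "cohort")
    cc = cfg.cohort
    kb = _cohort_kb()
    labels, records, profiles = [], [], {}
    n_resp = int(round(cc.n_patients * cc.responder_fraction))
    for i in range(cc.n_patients):
        pid = f"P{i + 1:04d}"
        is_responder = i < n_resp
        background = {f"BG{int(rng.integers(1, 50)):03d}"}
        if rng.random() < 0.3:
            background.add("BGDRUGGABLE")
        if is_responder:
            genes = {"SENSG1" if rng.random() < 0.5 else "SENSG2"} | background
            hazard = cc.baseline_hazard * cc.hazard_ratio
        else:
            if rng.random() < 0.5:
                genes = {"RESG1" if rng.random() < 0.5 else "RESG2"} | background
                # resistance may co-occur with sensitivity; label still non-responder
                if rng.random() < 0.3:
                    genes.add("SENSG1")
            else:
                genes = set(background)  # no molecular evidence
            hazard = cc.baseline_hazard
        t = float(rng.exponential(1.0 / hazard))
        if rng.random() < cc.censor_prob:
            records.append(SurvivalRecord(pid, float(rng.uniform(0.0, t)), 0))
        else:
            records.append(SurvivalRecord(pid, t, 1))
        profiles[pid] = frozenset(genes)
        labels.append(classify_response(pid, genes, COHORT_DRUG_CLASS, kb))
    return CohortBundle(tuple(labels), tuple(records), profiles, kb)


# ---------------------------------------------------------------- fixtures

@dataclass(frozen=True)
class PatientFixture:
    """One transcribed case study: evidence base plus whichever of clonal
    architecture, temporal VAF profiles and event sets apply."""

    name: str
    kb: EvidenceKB
    arch: ClonalArchitecture | None = None
    vaf_profiles: tuple = ()
    primary_events: frozenset = frozenset()
    relapse_events: frozenset = frozenset()


def _upn933124() -> PatientFixture:
    """AML relapse case: temporal heterogeneity between diagnosis and relapse.

    Bulk sequencing of primary and relapsed tumour validated 413 somatic
    events — 330 shared, 5 primary-specific, 78 relapse-specific.  Eighteen
    genes present at diagnosis below 1% VAF expanded to 30–40% VAF at
    relapse, and two more (ETV6, TMEM117) were relapse-specific; of these 20
    selected genes, 10 have evidence-base entries (druggable), and ERBB4,
    FLT4 and ETV6 match approved drugs above the 0.7 DScore rule.
    """
    shared = [f"UPNSH{i:03d}" for i in range(1, 331)]
    primary_only = [f"UPNPO{i:01d}" for i in range(1, 6)]
    relapse_only = [f"UPNRO{i:03d}" for i in range(1, 79)]
    primary_events = frozenset(shared + primary_only)
    relapse_events = frozenset(shared + relapse_only)

    pre_existing = ["ERBB4", "FLT4"] + [f"UPNPRE{i:02d}" for i in range(1, 17)]
    relapse_specific = ["ETV6", "TMEM117"]
    profiles = []
    for i, g in enumerate(pre_existing):
        profiles.append(TemporalVafProfile(
            g, {"diagnosis": 0.003 + 0.0003 * i, "relapse": 0.30 + 0.005 * i}))
    for i, g in enumerate(relapse_specific):
        profiles.append(TemporalVafProfile(g, {"relapse": 0.34 + 0.01 * i}))
    # background: founding-clone variants at high VAF at both timepoints
    for i in range(1, 6):
        profiles.append(TemporalVafProfile(
            f"UPNBG{i:02d}", {"diagnosis": 0.42, "relapse": 0.45}))

    e = EvidenceEntry
    entries = [
        # printed druggable genes with approved drugs above the 0.7 rule;
        # scores are documented placeholders (>0.7) — not printed in the source
        e("ERBB4", "vandetanib", 0.72, 0.85, "sensitivity", "direct_target", "approved"),
        e("FLT4", "vandetanib", 0.80, 0.83, "sensitivity", "direct_target", "approved"),
        e("ERBB4", "osimertinib", 0.72, 0.78, "sensitivity", "pathway_member", "approved"),
        e("ETV6", "idarubicin", 0.70, 0.88, "sensitivity", "biomarker", "approved",
          frozenset({"AML"})),
        e("ETV6", "imatinib", 0.70, 0.74, "sensitivity", "biomarker", "approved"),
        e("ERBB4", "acalabrutinib", 0.72, 0.75, "sensitivity", "pathway_member", "approved"),
    ]
    # seven further selected genes are druggable but below the 0.7 rule
    for i in range(1, 8):
        entries.append(e(f"UPNPRE{i:02d}", f"upn-lowdrug-{i}", 0.4, 0.5,
                         "sensitivity", "pathway_member", "experimental"))
    return PatientFixture(
        name="UPN933124",
        kb=EvidenceKB(entries),
        vaf_profiles=tuple(profiles),
        primary_events=primary_events,
        relapse_events=relapse_events,
    )


def _cruk0056() -> PatientFixture:
    """Multi-region NSCLC case with four clones over three regions.

    116 trunk alterations are shared by all clones; C2 and C3 share 11
    further genes including TP53; C4 carries 3 private non-druggable genes.
    Region R2 holds C3 (12%) and C4 (88%), so the ITH union there exposes
    130 genes (31 druggable) against 119 (25 druggable) for the
    predominant-clone bulk approximation; R1 and R3 are phylogenetically
    nested, so bulk equals ITH there.
    """
    trunk = [f"CK56T{i:03d}" for i in range(1, 117)]
    shared_c2c3 = ["TP53"] + [f"CK56S{i:02d}" for i in range(1, 11)]
    c4_private = [f"CK56P{i}" for i in range(1, 4)]  # non-druggable
    clones = [
        Clone("C1", None, frozenset(trunk)),
        Clone("C3", "C1", frozenset(shared_c2c3)),
        Clone("C2", "C3", frozenset({"CAMK4"})),
        Clone("C4", "C1", frozenset(c4_private)),
    ]
    samples = [
        SampleComposition("R1", {"C1": 0.06, "C4": 0.94}),
        SampleComposition("R2", {"C3": 0.12, "C4": 0.88}),
        SampleComposition("R3", {"C1": 0.02, "C2": 0.98}),
    ]
    e = EvidenceEntry
    entries = [
        # chemotherapies proposed on the clonal (trunk) profile; placeholder scores
        e(trunk[0], "paclitaxel", 0.63, 0.85, "sensitivity", "biomarker", "approved",
          frozenset({"NSCLC"})),
        e(trunk[1], "pemetrexed", 0.70, 0.82, "sensitivity", "biomarker", "approved",
          frozenset({"NSCLC"})),
        e(trunk[2], "alectinib", 0.65, 0.78, "sensitivity", "pathway_member", "approved",
          frozenset({"NSCLC"})),
        # TP53 (shared by C2/C3) also supports paclitaxel
        e("TP53", "paclitaxel", 0.80, 0.86, "sensitivity", "biomarker", "approved",
          frozenset({"NSCLC"})),
        # C2-specific sensitivity to gemcitabine via CAMK4
        e("CAMK4", "gemcitabine", 0.55, 0.76, "sensitivity", "biomarker", "approved"),
    ]
    # remaining druggable genes: 22 more trunk genes -> 25 trunk druggable;
    # 5 more C2/C3-shared genes -> 6 shared druggable -> 31 in the R2 union
    for i, g in enumerate(trunk[3:25]):
        entries.append(e(g, f"ck56-trunkdrug-{i + 1}", 0.5, 0.45,
                         "sensitivity", "pathway_member", "experimental"))
    for i, g in enumerate(shared_c2c3[1:6]):
        # the first shared gene's drug passes the 0.7 rule, so ITH analysis of
        # R2 widens the candidate list relative to the bulk approximation
        entries.append(e(g, f"ck56-shareddrug-{i + 1}", 0.5, 0.72 if i == 0 else 0.4,
                         "sensitivity", "pathway_member", "experimental"))
    return PatientFixture(
        name="CRUK0056",
        kb=EvidenceKB(entries),
        arch=ClonalArchitecture(clones, samples),
    )


def _cruk0016() -> PatientFixture:
    """Multi-region NSCLC case used for combination-regimen design.

    507 trunk mutations (including DDR2) are shared by all subclones; the
    trunk ranking yields dasatinib (GScore 0.64, DScore 0.95) ahead of
    paclitaxel (0.63, 0.94) and pemetrexed (0.79, 0.84).  Sorafenib and
    axitinib (DScore > 0.9) match genes private to C8 and C12 respectively,
    while no candidate above the 0.7 DScore rule exists for C4's private
    alterations.  The ancestral population carrying only the trunk is
    modelled as root clone C1 at zero prevalence in both regions; region
    prevalences are documented placeholders with C8 predominant in R1.
    """
    trunk = ["DDR2"] + [f"CK16T{i:03d}" for i in range(1, 507)]
    c4_private = [f"CK16C4P{i}" for i in range(1, 4)]
    c8_private = [f"CK16C8P{i}" for i in range(1, 4)]
    c12_private = [f"CK16C12P{i}" for i in range(1, 4)]
    clones = [
        Clone("C1", None, frozenset(trunk)),
        Clone("C4", "C1", frozenset(c4_private)),
        Clone("C8", "C1", frozenset(c8_private)),
        Clone("C12", "C1", frozenset(c12_private)),
    ]
    samples = [
        SampleComposition("R1", {"C8": 0.55, "C12": 0.45}),
        SampleComposition("R2", {"C4": 0.60, "C8": 0.40}),
    ]
    e = EvidenceEntry
    entries = [
        # trunk candidates with printed scores
        e("DDR2", "dasatinib", 0.64, 0.95, "sensitivity", "direct_target",
          "clinical_trials", frozenset({"NSCLC"})),
        e(trunk[1], "paclitaxel", 0.63, 0.94, "sensitivity", "biomarker", "approved",
          frozenset({"NSCLC"})),
        e(trunk[2], "pemetrexed", 0.79, 0.84, "sensitivity", "biomarker", "approved",
          frozenset({"NSCLC"})),
        # subclone-specific best-ranked drugs (DScore > 0.9)
        e(c8_private[0], "sorafenib", 0.65, 0.92, "sensitivity", "direct_target",
          "approved"),
        e(c12_private[0], "axitinib", 0.66, 0.91, "sensitivity", "direct_target",
          "approved"),
        # C4's only evidence sits below the 0.7 suitability rule
        e(c4_private[0], "ck16-weakdrug", 0.5, 0.5, "sensitivity", "pathway_member",
          "experimental"),
    ]
    return PatientFixture(
        name="CRUK0016",
        kb=EvidenceKB(entries),
        arch=ClonalArchitecture(clones, samples),
    )


def case_study_fixtures() -> dict[str, PatientFixture]:
    """The three transcribed case-study fixtures, keyed by patient id."""
    return {f.name: f for f in (_upn933124(), _cruk0056(), _cruk0016())}
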