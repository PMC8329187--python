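"""Synthetic two-arm, two-timepoint trial cohort with known ground truth.

Generates, fully in silico, everything the pipeline consumes: an MGS catalog
(gene membership, markers, genus labels), a gene->KO annotation map with
amino-acid synthesis/degradation module definitions, a genes x samples read
count matrix, per-subject clinical metadata and the ground truth behind all
of it, so every downstream stage has a recovery test.

The generative model mirrors the assumptions of the analysis stages:

* each subject draws a profile from one of ``n_enterotypes`` Dirichlet
  components whose concentration mass is shifted onto a single dominant genus
  (what DMM enterotyping assumes, and what makes dominant-genus labelling
  meaningful); the two timepoints are correlated Dirichlet jitter around that
  subject profile, mimicking the strong week-scale autocorrelation of gut
  communities;
* gene counts are multinomial at ``sequencing_depth`` with uniform weights
  across an MGS's member genes, so marker-gene means are unbiased estimators
  of MGS abundance;
* a designated producer pool of MGS carries complete amino-acid synthesis
  modules, and its abundance is multiplied by ``2**planted_aa_synthesis_log2fc``
  in the IP arm at T12 *before* renormalisation, so the planted signal must
  survive the entire gene -> KO -> module chain;
* per-subject species richness drifts by a random percentage
  (``richness_trajectory_sd``), and clinical changes are linear in the true
  richness change plus Gaussian noise (``richness_weightloss_slope`` kg per
  gained species), with baseline anthropometry drawn near typical values for
  an obese trial population (BMI ~32, visceral fat area ~200 cm^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import logging

import numpy as np
import pandas as pd

from .genes import GeneTable
from .mgs import MGSCatalog, MIN_GENES_PER_MGS
from .functional import ModuleDefinition, write_modules

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "GroundTruth", "CohortData",
           "generate_catalog", "generate_cohort", "write_cohort",
           "simulate_enterotype_counts"]

GENERA = ("Bacteroides", "Prevotella", "Ruminococcus", "Faecalibacterium",
          "Alistipes", "Roseburia", "Blautia", "Akkermansia")

SYNTHESIS_AAS = ("lysine", "histidine", "threonine", "leucine", "isoleucine",
                 "cysteine", "methionine", "proline", "ornithine", "tryptophan")
DEGRADATION_AAS = ("lysine", "histidine", "threonine", "leucine", "glutamine",
                   "tryptophan")

N_SYNTHESIS_STEPS = 4
N_DEGRADATION_STEPS = 3
N_ALTERNATIVES = 2

PRODUCER_FRACTION = 0.25
DEGRADER_FRACTION = 0.20
PARTIAL_SYNTHESIS_STEP_P = 0.05   # non-producers: per-step carriage probability
PARTIAL_DEGRADATION_STEP_P = 0.02  # sparser, as degradation annotation is in real repertoires
OCCUPANCY = 0.85                  # baseline per-MGS presence probability
WITHIN_SUBJECT_CONCENTRATION = 1000.0  # kappa: T0/T12 jitter around the subject profile


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic trial (defaults are the conditions
    every recovery test runs under; ``seed`` makes all outputs reproducible).
    """

    n_subjects: int = 25              # per arm
    n_mgs: int = 40
    genes_per_mgs: int = 520
    n_marker_genes: int = 30
    sequencing_depth: int = 100_000
    n_enterotypes: int = 2
    enterotype_separation: float = 5.0
    planted_aa_synthesis_log2fc: float = 1.0
    richness_trajectory_sd: float = 15.0     # percent of baseline richness
    richness_weightloss_slope: float = -0.2  # kg per gained species
    planted_vfa_arm_effect_cm2: float = 0.0  # extra IP-arm visceral-fat change
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_mgs", "genes_per_mgs", "n_marker_genes",
                     "sequencing_depth", "n_enterotypes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.genes_per_mgs <= MIN_GENES_PER_MGS:
            raise ValueError(
                f"genes_per_mgs={self.genes_per_mgs} violates the catalog rule: "
                f"an MGS must comprise more than {MIN_GENES_PER_MGS} genes"
            )
        if self.genes_per_mgs - self.n_marker_genes < 50:
            raise ValueError("need at least 50 non-marker genes per MGS for "
                             "functional annotation")
        if self.sequencing_depth < 10 * self.n_mgs:
            raise ValueError("sequencing_depth must be at least 10 x n_mgs")
        if self.n_enterotypes > len(GENERA):
            raise ValueError(f"at most {len(GENERA)} enterotypes supported")


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    enterotype: pd.Series                 # per sample
    abundances: pd.DataFrame              # MGS x sample, true relative abundances
    producers: dict[str, list[str]]       # amino acid -> producer MGS
    degraders: dict[str, list[str]]
    producer_pool: list[str]              # MGS receiving the planted shift
    subjects: pd.DataFrame                # per-subject truth (richness/clinical changes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "enterotype": self.enterotype.to_dict(),
            "abundances": {s: self.abundances[s].to_dict() for s in self.abundances},
            "producers": self.producers,
            "degraders": self.degraders,
            "producer_pool": self.producer_pool,
            "subjects": self.subjects.to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class CohortData:
    counts: GeneTable
    metadata: pd.DataFrame
    truth: GroundTruth


def _make_modules() -> list[ModuleDefinition]:
    modules = []
    ko = iter(range(1, 10_000))

    def steps(n):
        return tuple(
            frozenset(f"K{next(ko):05d}" for _ in range(N_ALTERNATIVES))
            for _ in range(n)
        )

    for aa in SYNTHESIS_AAS:
        modules.append(ModuleDefinition(
            f"MS_{aa.upper()[:3]}", f"{aa} biosynthesis", "aa_synthesis",
            steps(N_SYNTHESIS_STEPS), amino_acid=aa))
    for aa in DEGRADATION_AAS:
        modules.append(ModuleDefinition(
            f"MD_{aa.upper()[:3]}", f"{aa} degradation", "aa_degradation",
            steps(N_DEGRADATION_STEPS), amino_acid=aa, source="gmm"))
    modules.append(ModuleDefinition(
        "MO_RIB", "ribosome assembly", "other", steps(4)))
    modules.append(ModuleDefinition(
        "MO_GLY", "glycolysis", "other", steps(4)))
    return modules


def generate_catalog(config: SimulationConfig):
    """Build the MGS catalog, the gene->KO map and the module definitions.

    Returns ``(catalog, gene_to_ko, modules)``. Construction guarantees:
    producer MGS carry every step of their synthesis modules (completeness
    1.0); non-members carry strictly incomplete step subsets; degradation
    annotation is sparser than synthesis annotation overall.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    modules = _make_modules()

    mgs_ids = [f"MGS{i + 1:03d}" for i in range(config.n_mgs)]
    members = {m: [f"{m}_g{j + 1:04d}" for j in range(config.genes_per_mgs)]
               for m in mgs_ids}
    markers = {m: members[m][: config.n_marker_genes] for m in mgs_ids}
    genus = {m: GENERA[i % len(GENERA)] for i, m in enumerate(mgs_ids)}
    species = {m: f"{genus[m]} sp. {m}" for m in mgs_ids}

    n_prod = max(1, round(PRODUCER_FRACTION * config.n_mgs))
    n_degr = max(1, round(DEGRADER_FRACTION * config.n_mgs))
    pool = list(rng.choice(mgs_ids, size=n_prod, replace=False))
    degrader_pool = list(rng.choice(mgs_ids, size=n_degr, replace=False))

    producers: dict[str, list[str]] = {aa: [] for aa in SYNTHESIS_AAS}
    degraders: dict[str, list[str]] = {aa: [] for aa in DEGRADATION_AAS}
    # one amino acid per guild member: the cycle guarantees every amino acid
    # at least one producer/degrader while keeping module carriers disjoint
    # (so module-level dynamics are not artificially coupled)
    for i, m in enumerate(pool):
        producers[SYNTHESIS_AAS[i % len(SYNTHESIS_AAS)]].append(m)
    for i, m in enumerate(degrader_pool):
        degraders[DEGRADATION_AAS[i % len(DEGRADATION_AAS)]].append(m)

    rows: list[tuple[str, str]] = []
    for m in mgs_ids:
        # functional genes are drawn from the non-marker tail of the gene list
        free = iter(members[m][config.n_marker_genes:])

        def annotate(step_sets):
            for step in step_sets:
                ko = rng.choice(sorted(step))
                rows.append((next(free), ko))

        for module in modules:
            if module.category == "other":
                annotate(module.steps)  # housekeeping: complete everywhere
                continue
            if module.category == "aa_synthesis":
                complete = m in producers[module.amino_acid]
                p_step = PARTIAL_SYNTHESIS_STEP_P
            else:
                complete = m in degraders[module.amino_acid]
                p_step = PARTIAL_DEGRADATION_STEP_P
            if complete:
                annotate(module.steps)
            else:
                carried = [s for s in module.steps if rng.random() < p_step]
                if len(carried) == len(module.steps):  # keep strictly incomplete
                    carried = carried[:-1]
                annotate(carried)

    catalog = MGSCatalog(members=members, markers=markers, genus=genus, species=species)
    gene_to_ko = pd.DataFrame(rows, columns=["gene", "ko"])
    producers = {aa: sorted(v) for aa, v in producers.items()}
    degraders = {aa: sorted(v) for aa, v in degraders.items()}
    catalog.producers = producers      # ground-truth annotations carried along
    catalog.degraders = degraders
    catalog.producer_pool = sorted(pool)
    catalog.degrader_pool = sorted(degrader_pool)
    catalog.modules = modules
    return catalog, gene_to_ko, modules


def _component_alphas(config: SimulationConfig, catalog: MGSCatalog) -> np.ndarray:
    """Dirichlet concentration per enterotype: mass shifted to a dominant genus."""
    mgs_ids = catalog.mgs_ids
    alphas = np.ones((config.n_enterotypes, len(mgs_ids)))
    for k in range(config.n_enterotypes):
        dominant = GENERA[k]
        for j, m in enumerate(mgs_ids):
            if catalog.genus[m] == dominant:
                alphas[k, j] = config.enterotype_separation
    return alphas


def generate_cohort(config: SimulationConfig, catalog: MGSCatalog,
                    gene_to_ko: pd.DataFrame | None = None) -> CohortData:
    """Simulate the paired cohort: gene counts, metadata and ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    mgs_ids = catalog.mgs_ids
    n_mgs = len(mgs_ids)
    producer_pool = getattr(catalog, "producer_pool", [])
    pool_idx = np.array([mgs_ids.index(m) for m in producer_pool], dtype=int)
    alphas = _component_alphas(config, catalog)

    n_total_genes = sum(len(g) for g in catalog.members.values())
    if config.sequencing_depth < n_total_genes:
        logger.warning(
            "sequencing depth %d is below the catalog size %d; many genes "
            "will be undetectable", config.sequencing_depth, n_total_genes)

    subjects = [f"S{i + 1:03d}" for i in range(2 * config.n_subjects)]
    arm_assign = np.array(["IP"] * config.n_subjects + ["CP"] * config.n_subjects)
    rng.shuffle(arm_assign)

    gene_index = [g for m in mgs_ids for g in catalog.members[m]]
    mgs_of_gene = np.repeat(np.arange(n_mgs), [len(catalog.members[m]) for m in mgs_ids])
    genes_per = np.array([len(catalog.members[m]) for m in mgs_ids], dtype=float)

    counts = {}
    truth_abund = {}
    truth_et = {}
    meta_rows = []
    subj_rows = []

    for si, subj in enumerate(subjects):
        arm = arm_assign[si]
        et = int(rng.integers(config.n_enterotypes))
        alpha = alphas[et]

        # dominant-genus and guild MGS are core taxa: always present, so
        # richness churn happens on the accessory flora (amino-acid guilds
        # are built from prevalent commensals)
        guild = {mgs_ids.index(m) for m in
                 set(producer_pool) | set(getattr(catalog, "degrader_pool", []))}
        dominant = {j for j, m in enumerate(mgs_ids)
                    if catalog.genus[m] == GENERA[et]} | guild
        present0 = {j for j in range(n_mgs)
                    if j in dominant or rng.random() < OCCUPANCY}
        m0 = len(present0)
        delta = int(np.rint(rng.normal(0.0, config.richness_trajectory_sd / 100 * m0)))
        absent = [j for j in range(n_mgs) if j not in present0]
        removable = [j for j in sorted(present0) if j not in dominant]
        delta = max(-len(removable), min(delta, len(absent)))
        present12 = set(present0)
        if delta > 0:
            present12 |= set(rng.choice(absent, size=delta, replace=False))
        elif delta < 0:
            present12 -= set(rng.choice(removable, size=-delta, replace=False))

        # subject-level profile from the enterotype component; per-timepoint
        # compositions are correlated jitter around it (gut profiles are
        # strongly autocorrelated over weeks)
        theta = rng.dirichlet(alpha)
        comps = {}
        for tp, present in (("T0", present0), ("T12", present12)):
            idx = np.array(sorted(present))
            comp = np.zeros(n_mgs)
            kappa = WITHIN_SUBJECT_CONCENTRATION * theta[idx] / theta[idx].sum()
            comp[idx] = rng.dirichlet(np.maximum(kappa, 1e-3))
            if tp == "T12" and arm == "IP" and config.planted_aa_synthesis_log2fc != 0:
                comp[pool_idx] *= 2.0 ** config.planted_aa_synthesis_log2fc
                comp /= comp.sum()
            comps[tp] = comp
            sample = f"{subj}_{tp}"
            gene_p = comp[mgs_of_gene] / genes_per[mgs_of_gene]
            counts[sample] = rng.multinomial(config.sequencing_depth, gene_p)
            truth_abund[sample] = comp
            truth_et[sample] = et

        # clinical truth: linear in the true richness change
        true_delta_rich = len(present12) - len(present0)
        sex = "female" if rng.random() < 0.6 else "male"
        age = float(np.clip(rng.normal(48, 10), 25, 70))
        height = float(rng.normal(175, 7) if sex == "male" else rng.normal(162, 6))
        bmi = float(np.clip(rng.normal(32, 3.7), 27, 42))
        weight0 = bmi * (height / 100) ** 2
        vfa0 = float(np.clip(rng.normal(200, 70), 80, 420))
        fat0 = 0.35 * weight0 + rng.normal(0, 2)

        wchange = (-3.3 + config.richness_weightloss_slope * true_delta_rich
                   + rng.normal(0, 1.0))
        fchange = 0.7 * wchange + rng.normal(0, 0.8)
        vchange = 6.0 * wchange + rng.normal(0, 10.0)
        if arm == "IP":
            vchange += config.planted_vfa_arm_effect_cm2

        energy0 = float(max(rng.normal(2350, 600), 1200))
        energy12 = float(max(rng.normal(1780, 400), 900))
        prot0 = float(max(rng.normal(100, 40), 30))
        prot12 = float(max(rng.normal(134 if arm == "IP" else 88, 25), 30))

        for tp, t in (("T0", 0), ("T12", 1)):
            meta_rows.append({
                "sample": f"{subj}_{tp}", "subject": subj, "arm": arm,
                "timepoint": tp, "time": t,
                "age": age, "sex": sex, "bmi": bmi, "height_cm": height,
                "weight_kg": weight0 if t == 0 else weight0 + wchange,
                "fat_mass_kg": fat0 if t == 0 else fat0 + fchange,
                "visceral_fat_area_cm2": vfa0 if t == 0 else vfa0 + vchange,
                "energy_intake_kcal": energy0 if t == 0 else energy12,
                "protein_intake_g": prot0 if t == 0 else prot12,
            })
        subj_rows.append({
            "subject": subj, "arm": arm, "enterotype": et,
            "true_delta_richness": true_delta_rich,
            "weight_change_kg": wchange, "fat_mass_change_kg": fchange,
            "vfa_change_cm2": vchange,
        })

    count_df = pd.DataFrame(counts, index=pd.Index(gene_index, name="gene"))
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    truth = GroundTruth(
        enterotype=pd.Series(truth_et, name="enterotype"),
        abundances=pd.DataFrame(truth_abund, index=pd.Index(mgs_ids, name="mgs")),
        producers=getattr(catalog, "producers", {}),
        degraders=getattr(catalog, "degraders", {}),
        producer_pool=list(producer_pool),
        subjects=pd.DataFrame(subj_rows).set_index("subject"),
    )
    table = GeneTable(count_df, kind="raw", depth=config.sequencing_depth)
    return CohortData(counts=table, metadata=metadata, truth=truth)


def simulate_enterotype_counts(
    config: SimulationConfig,
    catalog: MGSCatalog,
    n_samples: int,
    depth: int = 10_000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genus-level counts drawn from the pure Dirichlet-multinomial mixture.

    Samples come straight from the enterotype components (no subject
    hierarchy, no planted effects): the exact generative model the DMM
    fitting stage assumes. Returns ``(genus x sample counts, true labels)``;
    used for component-recovery checks.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    alphas = _component_alphas(config, catalog)
    genus = pd.Series({m: catalog.genus[m] for m in catalog.mgs_ids})
    counts = {}
    labels = {}
    for i in range(n_samples):
        k = int(rng.integers(config.n_enterotypes))
        p = rng.dirichlet(alphas[k])
        mgs_counts = pd.Series(rng.multinomial(depth, p), index=catalog.mgs_ids)
        sample = f"sim{i + 1:03d}"
        counts[sample] = mgs_counts.groupby(genus).sum()
        labels[sample] = k
    return pd.DataFrame(counts), pd.Series(labels, name="enterotype")


def write_cohort(config: SimulationConfig, out_dir: str | Path) -> None:
    """Generate and write a full cohort to ``out_dir`` as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog, gene_to_ko, modules = generate_catalog(config)
    cohort = generate_cohort(config, catalog, gene_to_ko)
    cohort.counts.data.to_csv(out / "gene_counts.tsv", sep="\t")
    catalog.to_json(out / "catalog.json")
    gene_to_ko.to_csv(out / "gene_to_ko.tsv", sep="\t", index=False)
    write_modules(modules, out / "modules.txt")
    cohort.metadata.to_csv(out / "metadata.tsv", sep="\t")
    cohort.truth.to_json(out / "ground_truth.json")
    (out / "config.json").write_text(json.dumps(asdict(config)))
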