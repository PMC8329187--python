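"""Functional profiling: KO collapse, module scoring, guild construction.

Metabolic potential is summarised at three levels. Gene relative abundances
are first collapsed onto KEGG Orthology (KO) families. KOs are then scored
against *modules* — pathway units written as an ordered list of steps, each
step satisfiable by any of several alternative KOs — with the step-based rule
used by rule-based module quantifiers: a step's abundance is the sum of its
alternatives, a module is only called when enough steps are detected
(coverage cutoff), and its abundance is the median over all step abundances
(zeros included). Finally, projecting module step coverage onto each MGS's own
gene repertoire yields a completeness matrix from which producer (synthesis)
and degrader guilds per amino acid are constituted; guild abundance is the sum
of member MGS abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .community import log_fold_change
from .mgs import MGSAbundance, MGSCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleDefinition",
    "parse_modules",
    "write_modules",
    "ko_abundance",
    "module_abundance",
    "module_dynamics",
    "enrichment_proportion_test",
    "completeness",
    "functional_groups",
    "coverage_report",
]

CATEGORIES = ("aa_synthesis", "aa_degradation", "other")


@dataclass(frozen=True)
class ModuleDefinition:
    """A functional module: ordered steps, each a set of alternative KOs."""

    module_id: str
    name: str
    category: str
    steps: tuple[frozenset[str], ...]
    amino_acid: str | None = None
    source: str = "kegg"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if not self.steps or any(not s for s in self.steps):
            raise ValueError(f"module {self.module_id} must have >= 1 non-empty step")
        if self.category.startswith("aa_") and not self.amino_acid:
            raise ValueError(f"amino-acid module {self.module_id} needs an amino_acid")
        if self.category == "other" and self.amino_acid:
            raise ValueError(f"module {self.module_id}: amino_acid set on category 'other'")

    @property
    def kos(self) -> frozenset[str]:
        return frozenset().union(*self.steps)


def parse_modules(text: str) -> list[ModuleDefinition]:
    """Parse the module-definition text dialect.

    One module per block: a header line
    ``MODULE<tab>id<tab>name<tab>category[<tab>amino_acid[<tab>source]]``
    followed by one line per step listing its alternative KOs comma-separated.
    Blocks end at ``//``, a blank line or the next ``MODULE`` header.
    """
    modules: list[ModuleDefinition] = []
    header: list[str] | None = None
    steps: list[frozenset[str]] = []

    def flush() -> None:
        nonlocal header, steps
        if header is None:
            return
        _, mid, name, category, *rest = header
        aa = rest[0] if rest and rest[0] else None
        source = rest[1] if len(rest) > 1 else "kegg"
        modules.append(ModuleDefinition(mid, name, category, tuple(steps), aa, source))
        header, steps = None, []

    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.strip() == "//":
            flush()
            continue
        if line.startswith("MODULE\t"):
            flush()
            header = line.split("\t")
            if len(header) < 4:
                raise ValueError(f"malformed module header: {line!r}")
        else:
            if header is None:
                raise ValueError(f"step line outside a module block: {line!r}")
            kos = frozenset(k.strip() for k in line.split(",") if k.strip())
            steps.append(kos)
    flush()
    return modules


def write_modules(modules: list[ModuleDefinition], path: str | Path) -> None:
    lines = []
    for m in modules:
        lines.append("\t".join(["MODULE", m.module_id, m.name, m.category,
                                m.amino_acid or "", m.source]))
        for step in m.steps:
            lines.append(",".join(sorted(step)))
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def ko_abundance(genes, gene_to_ko: pd.DataFrame) -> pd.DataFrame:
    """Collapse gene relative abundances onto KOs (KO x sample).

    ``gene_to_ko`` has columns ``gene`` and ``ko``; genes without annotation
    are ignored and a gene annotated to several KOs contributes its full
    abundance to each (logged).
    """
    df = genes.data if hasattr(genes, "data") else genes
    ann = gene_to_ko[gene_to_ko["gene"].isin(df.index)]
    multi = ann["gene"].duplicated().sum()
    if multi:
        logger.info("%d multi-KO gene annotations: each KO receives the full gene abundance", multi)
    values = df.loc[ann["gene"]].to_numpy()
    out = pd.DataFrame(values, index=pd.Index(ann["ko"], name="ko"), columns=df.columns)
    return out.groupby(level=0).sum()


def _step_abundances(kos: pd.DataFrame, module: ModuleDefinition) -> np.ndarray:
    """steps x samples matrix of step abundances (sum of alternative KOs)."""
    rows = []
    for step in module.steps:
        present = [k for k in step if k in kos.index]
        rows.append(kos.loc[present].sum(axis=0).to_numpy() if present
                    else np.zeros(kos.shape[1]))
    return np.asarray(rows)


def module_abundance(
    kos: pd.DataFrame,
    modules: list[ModuleDefinition],
    coverage_cutoff: float = 0.66,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score modules per sample; returns (abundance, step coverage) tables.

    Coverage is the fraction of steps with nonzero abundance; the module
    abundance is the median over *all* step abundances (zeros included) when
    coverage >= cutoff, else 0.
    """
    if not 0 < coverage_cutoff <= 1:
        raise ValueError("coverage_cutoff must be in (0, 1]")
    ab, cov = {}, {}
    for m in modules:
        if not (m.kos & set(kos.index)):
            logger.warning("module %s references no known KO", m.module_id)
        steps = _step_abundances(kos, m)
        coverage = (steps > 0).mean(axis=0)
        med = np.median(steps, axis=0)
        ab[m.module_id] = np.where(coverage >= coverage_cutoff, med, 0.0)
        cov[m.module_id] = coverage
    abundance = pd.DataFrame(ab, index=kos.columns).T
    coverage = pd.DataFrame(cov, index=kos.columns).T
    return abundance, coverage


def module_dynamics(
    table: pd.DataFrame,
    pairs: pd.DataFrame,
    arms: pd.Series,
    pseudocount: float | None = None,
    log_base: float | None = None,
) -> pd.DataFrame:
    """Per-module, per-arm mean log fold change and its increase/decrease class.

    ``pairs`` has columns ``t0`` and ``t12`` (sample ids) indexed by subject;
    ``arms`` maps subject -> arm label. The class is ``increase`` for a mean
    fold change > 0, ``decrease`` for < 0 and ``unchanged`` at exactly 0
    (excluded from enrichment proportions).
    """
    records = []
    for arm in arms.unique():
        subj = arms.index[arms == arm]
        sub_pairs = pairs.loc[pairs.index.intersection(subj)]
        lfc = log_fold_change(table, sub_pairs, pseudocount=pseudocount, base=log_base)
        mean_lfc = lfc.mean(axis=1)
        cls = np.where(mean_lfc > 0, "increase", np.where(mean_lfc < 0, "decrease", "unchanged"))
        for module, m, c in zip(mean_lfc.index, mean_lfc, cls):
            records.append({"module": module, "arm": arm, "mean_lfc": m, "class": c})
    return pd.DataFrame(records)


def enrichment_proportion_test(
    dynamics: pd.DataFrame,
    modules: list[ModuleDefinition],
    category: str,
) -> pd.DataFrame:
    """Test whether the share of increased modules in a category departs from 1/2.

    Per arm: k increased of m classified (unchanged excluded), with a
    two-sided exact binomial test against 0.5. Between arms: chi-square on the
    2x2 increased/decreased x arm table without continuity correction.
    """
    ids = [m.module_id for m in modules if m.category == category]
    sub = dynamics[dynamics["module"].isin(ids) & (dynamics["class"] != "unchanged")]
    if sub.empty:
        raise ValueError(f"no classified module in category {category!r}")
    rows = []
    counts = {}
    for arm, grp in sub.groupby("arm"):
        k = int((grp["class"] == "increase").sum())
        m = len(grp)
        counts[arm] = (k, m - k)
        rows.append({
            "arm": arm, "category": category, "n_increased": k, "n_classified": m,
            "prop_increased": k / m,
            "binomial_p": stats.binomtest(k, m, 0.5).pvalue,
        })
    out = pd.DataFrame(rows)
    if len(counts) == 2:
        table = np.array(list(counts.values()))
        if table.sum(axis=0).min() == 0:  # degenerate margin: chi-square undefined
            chi_p = np.nan
        else:
            chi_p = stats.chi2_contingency(table, correction=False)[1]
        out["between_arm_chi2_p"] = chi_p
    return out


def completeness(
    catalog: MGSCatalog,
    gene_to_ko: pd.DataFrame,
    modules: list[ModuleDefinition],
) -> pd.DataFrame:
    """MGS x module matrix: fraction of steps the MGS's annotated genes cover."""
    ko_by_gene = gene_to_ko.groupby("gene")["ko"].apply(set)
    out = {}
    for mgs in catalog.mgs_ids:
        kos: set[str] = set()
        for g in catalog.members[mgs]:
            kos |= ko_by_gene.get(g, set())
        out[mgs] = {
            m.module_id: np.mean([bool(step & kos) for step in m.steps])
            for m in modules
        }
    return pd.DataFrame(out).T


def functional_groups(
    completeness_matrix: pd.DataFrame,
    mgs_table: MGSAbundance,
    modules: list[ModuleDefinition],
    threshold: float = 0.66,
) -> tuple[dict[tuple[str, str], list[str]], pd.DataFrame]:
    """Constitute producer/degrader guilds and their per-sample abundances.

    An MGS joins the producer group of amino acid X when its completeness of
    the X-synthesis module is >= threshold (degraders analogously). Returns
    ``(membership, group_table)`` where membership maps
    ``(amino_acid, role)`` -> member MGS list and the table holds the summed
    member abundances per sample (empty groups are absent from both).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    role_of = {"aa_synthesis": "producer", "aa_degradation": "degrader"}
    membership: dict[tuple[str, str], list[str]] = {}
    rows = {}
    for m in modules:
        role = role_of.get(m.category)
        if role is None:
            continue
        comp = completeness_matrix[m.module_id]
        members = sorted(comp.index[comp >= threshold])
        members = [x for x in members if x in mgs_table.abundance.index]
        if not members:
            logger.info("empty %s group for %s", role, m.amino_acid)
            continue
        membership[(m.amino_acid, role)] = members
        rows[f"{m.amino_acid}_{role}"] = mgs_table.abundance.loc[members].sum(axis=0)
    return membership, pd.DataFrame(rows).T


def coverage_report(
    completeness_matrix: pd.DataFrame,
    modules: list[ModuleDefinition],
    threshold: float = 0.66,
) -> pd.DataFrame:
    """Per-module completeness summary across MGS, with category averages.

    Flags degradation modules for which no MGS is fully complete — sparse
    degradation annotation is a known limitation of module repertoires and
    guild calls for those amino acids should be read cautiously.
    """
    rows = []
    for m in modules:
        comp = completeness_matrix[m.module_id]
        rows.append({
            "module": m.module_id, "category": m.category,
            "amino_acid": m.amino_acid,
            "mean_completeness": comp.mean(),
            "median_completeness": comp.median(),
            "frac_mgs_ge_threshold": (comp >= threshold).mean(),
            "no_complete_mgs": bool(m.category == "aa_degradation" and (comp < 1).all()),
        })
    return pd.DataFrame(rows).set_index("module")
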