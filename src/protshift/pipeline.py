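"""End-to-end convenience wrappers over the pipeline stages.

These functions chain the per-module operations in the order an analyst
would: counts -> normalise -> MGS/KO/module abundances -> per-arm dynamics ->
enrichment, and provide the planted-effect recovery estimator used to
validate the generator's amino-acid signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import community, functional, genes, mgs as mgs_mod
from .simulate import CohortData, SimulationConfig, generate_catalog, generate_cohort

__all__ = [
    "pairs_from_metadata",
    "simulate_and_profile",
    "planted_effect_estimate",
]


def pairs_from_metadata(metadata: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subject (t0, t12) sample-id pairs and arm labels from long metadata."""
    wide = metadata.reset_index().pivot(index="subject", columns="timepoint", values="sample")
    pairs = wide.rename(columns={"T0": "t0", "T12": "t12"})[["t0", "t12"]].dropna()
    arms = metadata.drop_duplicates("subject").set_index("subject")["arm"].loc[pairs.index]
    return pairs, arms


def simulate_and_profile(config: SimulationConfig, coverage_cutoff: float = 0.66) -> dict:
    """Generate a cohort and run the full profiling chain on it.

    Returns a dict with the cohort, catalog, normalised gene table, MGS and
    genus tables, KO and module abundances, per-arm module dynamics and the
    (t0, t12) pairing — the common substrate of the recovery analyses.
    """
    catalog, gene_to_ko, modules = generate_catalog(config)
    cohort = generate_cohort(config, catalog, gene_to_ko)
    norm = genes.normalise(cohort.counts)
    mgs_table = mgs_mod.mgs_abundance(norm, catalog)
    genus_table = mgs_mod.collapse_to_genus(mgs_table, catalog)
    kos = functional.ko_abundance(norm, gene_to_ko)
    module_table, coverage = functional.module_abundance(kos, modules, coverage_cutoff)
    pairs, arms = pairs_from_metadata(cohort.metadata)
    dynamics = functional.module_dynamics(module_table, pairs, arms)
    return {
        "config": config, "cohort": cohort, "catalog": catalog,
        "gene_to_ko": gene_to_ko, "modules": modules, "normalised": norm,
        "mgs": mgs_table, "genus": genus_table, "kos": kos,
        "module_abundance": module_table, "module_coverage": coverage,
        "dynamics": dynamics, "pairs": pairs, "arms": arms,
    }


def planted_effect_estimate(
    mgs_table: "mgs_mod.MGSAbundance",
    producer_pool: list[str],
    pairs: pd.DataFrame,
    arms: pd.Series,
) -> float:
    """Estimate the planted producer log2 fold change, free of closure bias.

    Because compositions are renormalised after the multiplicative boost, the
    raw producer-group fold change underestimates the planted effect. The
    log2 ratio of producer-pool to complement abundance is invariant to
    renormalisation, so its T12-T0 change, contrasted IP minus CP, estimates
    the planted log2FC without closure bias.
    """
    ab = mgs_table.abundance
    pool = [m for m in producer_pool if m in ab.index]
    grp = ab.loc[pool].sum(axis=0)
    rest = ab.drop(index=pool).sum(axis=0)
    logratio = np.log2(grp) - np.log2(rest)
    change = logratio[pairs["t12"]].to_numpy() - logratio[pairs["t0"]].to_numpy()
    change = pd.Series(change, index=pairs.index)
    return float(change[arms == "IP"].mean() - change[arms == "CP"].mean())
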