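"""Metagenomic-species (MGS) profiles and richness-response classification.

An MGS is a cluster of >500 co-abundant catalog genes treated as one organism.
Its relative abundance in a sample is estimated as the mean relative abundance
of a designated subset of marker genes, and it is called *present* when more
than a configurable fraction of those markers are detected. MGS richness (the
number of present species) is the species-level alpha diversity; subjects are
classified by the sign of its change over the intervention and that class is
related to relative clinical changes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MGSCatalog",
    "MGSAbundance",
    "mgs_abundance",
    "mgs_richness",
    "collapse_to_genus",
    "classify_richness_response",
    "stratify_lgc_hgc",
]

MIN_GENES_PER_MGS = 500


@dataclass
class MGSCatalog:
    """Gene membership, marker genes and taxonomy for each MGS.

    ``members`` maps MGS id -> list of gene ids (> 500, pairwise disjoint
    across MGS); ``markers`` maps MGS id -> marker gene subset; ``genus`` and
    ``species`` map MGS id -> taxon labels.
    """

    members: dict[str, list[str]]
    markers: dict[str, list[str]]
    genus: dict[str, str]
    species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mgs, genes in self.members.items():
            if len(genes) <= MIN_GENES_PER_MGS:
                raise ValueError(
                    f"MGS {mgs} has {len(genes)} genes; an MGS must comprise "
                    f"more than {MIN_GENES_PER_MGS} genes"
                )
            gene_set = set(genes)
            if gene_set & seen:
                raise ValueError(f"MGS {mgs} shares genes with another MGS")
            seen |= gene_set
            mk = self.markers.get(mgs, [])
            if not set(mk) <= gene_set:
                raise ValueError(f"markers of {mgs} are not a subset of its genes")

    @property
    def mgs_ids(self) -> list[str]:
        return list(self.members)

    def to_json(self, path: str | Path) -> None:
        payload = {
            mgs: {
                "genes": self.members[mgs],
                "markers": self.markers[mgs],
                "genus": self.genus.get(mgs, "unclassified"),
                "species": self.species.get(mgs, mgs),
            }
            for mgs in self.members
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MGSCatalog":
        payload = json.loads(Path(path).read_text())
        return cls(
            members={m: v["genes"] for m, v in payload.items()},
            markers={m: v["markers"] for m, v in payload.items()},
            genus={m: v.get("genus", "unclassified") for m, v in payload.items()},
            species={m: v.get("species", m) for m, v in payload.items()},
        )


@dataclass
class MGSAbundance:
    """MGS x sample relative abundances with a companion presence matrix."""

    abundance: pd.DataFrame
    presence: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.abundance.values < 0).any():
            raise ValueError("MGS abundances must be non-negative")
        if not self.abundance.index.equals(self.presence.index):
            raise ValueError("abundance and presence must share the same MGS index")


def mgs_abundance(
    genes,
    catalog: MGSCatalog,
    presence_min_marker_frac: float = 0.10,
    min_marker_coverage: float = 0.50,
) -> MGSAbundance:
    """Estimate MGS relative abundance as the mean of its marker-gene abundances.

    Parameters
    ----------
    genes :
        Normalised :class:`~protshift.genes.GeneTable` (or DataFrame of
        relative abundances, genes x samples).
    presence_min_marker_frac :
        An MGS is present in a sample when strictly more than this fraction
        of its markers have nonzero abundance (default 10%).
    min_marker_coverage :
        MGS whose marker genes are covered by the gene table at below this
        fraction are dropped with a warning (their mean would be biased).
    """
    df = genes.data if hasattr(genes, "data") else genes
    if hasattr(genes, "kind") and genes.kind != "normalised":
        raise ValueError("mgs_abundance expects a normalised gene table")
    abund = {}
    pres = {}
    for mgs in catalog.mgs_ids:
        markers = catalog.markers[mgs]
        if not markers:
            raise ValueError(f"MGS {mgs} has an empty marker set")
        found = [g for g in markers if g in df.index]
        if len(found) < min_marker_coverage * len(markers):
            logger.warning(
                "dropping %s: only %d/%d marker genes in table", mgs, len(found), len(markers)
            )
            continue
        sub = df.loc[found]
        abund[mgs] = sub.mean(axis=0)
        pres[mgs] = (sub > 0).mean(axis=0) > presence_min_marker_frac
    if not abund:
        raise ValueError("no MGS passed the marker-coverage requirement")
    return MGSAbundance(pd.DataFrame(abund).T, pd.DataFrame(pres).T)


def mgs_richness(table: MGSAbundance) -> pd.Series:
    """Number of present MGS per sample (column sums of the presence matrix)."""
    return table.presence.sum(axis=0).astype(int).rename("mgs_richness")


def collapse_to_genus(table: MGSAbundance, catalog: MGSCatalog) -> pd.DataFrame:
    """Sum MGS abundances within each genus; unlabelled MGS pool into 'unclassified'."""
    genus = pd.Series(
        {m: catalog.genus.get(m) or "unclassified" for m in table.abundance.index}
    )
    return table.abundance.groupby(genus).sum()


def relative_change(t0: pd.Series | float, t12: pd.Series | float):
    """Percent change from baseline, (T12 - T0) / T0 * 100."""
    return (t12 - t0) / t0 * 100.0


def classify_richness_response(
    richness_t0: pd.Series,
    richness_t12: pd.Series,
    clinical_t0: pd.DataFrame | None = None,
    clinical_t12: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify each subject as gained / lost / stable by the sign of its
    MGS-richness change, and attach relative clinical changes (percent).

    Subjects missing either timepoint are excluded (logged). ``stable``
    (no change) subjects carry a class of their own; gained-vs-lost
    contrasts should drop them.
    """
    common = richness_t0.index.intersection(richness_t12.index)
    missing = richness_t0.index.symmetric_difference(richness_t12.index)
    if len(missing):
        logger.warning("excluding %d subject(s) with a missing timepoint: %s",
                       len(missing), list(missing))
    delta = (richness_t12.loc[common] - richness_t0.loc[common]).astype(float)
    cls = pd.Series(np.where(delta > 0, "gained", np.where(delta < 0, "lost", "stable")),
                    index=common, name="response")
    out = pd.DataFrame({"delta_richness": delta, "response": cls})
    if clinical_t0 is not None and clinical_t12 is not None:
        rel = relative_change(clinical_t0.loc[common], clinical_t12.loc[common])
        rel.columns = [f"{c}_relchange_pct" for c in rel.columns]
        out = out.join(rel)
    return out


def stratify_lgc_hgc(
    baseline_richness: pd.Series,
    rule: str = "median",
    threshold: float | None = None,
) -> pd.Series:
    """Assign each subject a gene-count stratum: LGC (low) or HGC (high).

    ``rule="median"`` splits at the cohort median with the strict inequality
    ``richness < median`` defining LGC (ties go to HGC); ``rule="threshold"``
    uses a fixed external cut instead.
    """
    if rule == "median":
        cut = baseline_richness.median()
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule requires a threshold value")
        cut = threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return pd.Series(np.where(baseline_richness < cut, "LGC", "HGC"),
                     index=baseline_richness.index, name="gene_count_stratum")
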