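"""Gene-level profile operations: downsizing, normalisation, richness, prevalence.

The root measurement of shotgun quantitative metagenomics is a genes x samples
matrix of mapped-read counts. Because sequencing effort differs between
samples, count-based alpha diversity (gene richness) is only comparable after
rarefying every sample to a common depth; relative-abundance analyses instead
divide each sample by its total. Both operations live here, together with the
baseline prevalence filter used to restrict feature scans to commonly observed
genes or features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneTable",
    "downsize",
    "normalise",
    "gene_richness",
    "prevalence_filter",
]


@dataclass
class GeneTable:
    """A genes x samples abundance matrix with provenance flags.

    Parameters
    ----------
    data :
        DataFrame indexed by gene id with one column per sample. Raw tables
        hold read counts (non-negative); normalised tables hold relative
        abundances whose columns sum to 1.
    kind :
        ``"raw"`` or ``"normalised"``.
    depth :
        The common downsizing depth (reads) if the table was rarefied.
    n_draws :
        Number of rarefaction draws averaged; counts may be non-integer when
        ``n_draws > 1``.
    draw_richness :
        Per-sample gene richness averaged over the individual rarefaction
        draws (set by :func:`downsize` when ``n_draws > 1``).
    """

    data: pd.DataFrame
    kind: str = "raw"
    depth: int | None = None
    n_draws: int = field(default=1)
    draw_richness: pd.Series | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("raw", "normalised"):
            raise ValueError(f"kind must be 'raw' or 'normalised', got {self.kind!r}")
        if (self.data.values < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.kind == "normalised":
            totals = self.data.sum(axis=0)
            if not np.allclose(totals, 1.0, atol=1e-9):
                raise ValueError("normalised columns must sum to 1 +/- 1e-9")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def copy(self) -> "GeneTable":
        return replace(self, data=self.data.copy())


def _sample_seed(seed: int, sample: str) -> np.random.Generator:
    """Per-sample generator independent of sample order and gene order."""
    ss = np.random.SeedSequence([seed, *(ord(c) for c in str(sample))])
    return np.random.default_rng(ss)


def downsize(table: GeneTable, depth: int, seed: int, n_draws: int = 30) -> GeneTable:
    """Rarefy every sample to exactly ``depth`` reads without replacement.

    Each retained sample is a multivariate-hypergeometric subsample of its
    reads; samples whose total is below ``depth`` are dropped with a warning.
    With ``n_draws > 1`` the per-gene counts are averaged over independent
    draws (non-integer values, flagged via :attr:`GeneTable.n_draws`).

    Determinism: each sample uses its own seed stream derived from ``seed``
    and the sample id, and genes are processed in a canonical sorted order,
    so the result is invariant to row/column permutations of the input.
    """
    if table.kind != "raw":
        raise ValueError("downsize operates on raw counts")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    totals = table.data.sum(axis=0)
    keep = totals[totals >= depth].index
    dropped = [s for s in table.samples if s not in set(keep)]
    if dropped:
        logger.warning("dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    if len(keep) == 0:
        raise ValueError(f"all samples have fewer than {depth} reads")

    # canonical gene order makes the draw exchangeable w.r.t. input row order
    order = np.argsort(table.data.index.to_numpy().astype(str))
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))

    out = {}
    rich = {}
    for s in keep:
        counts = table.data[s].to_numpy()[order]
        rng = _sample_seed(seed, s)
        acc = np.zeros(len(counts), dtype=float)
        det = 0.0
        for _ in range(n_draws):
            draw = rng.multivariate_hypergeometric(counts.astype(np.int64), depth, method="marginals")
            acc += draw
            det += (draw > 0).sum()
        out[s] = (acc / n_draws)[inv]
        rich[s] = det / n_draws
    df = pd.DataFrame(out, index=table.data.index)
    if n_draws == 1:
        df = df.astype(np.int64)
    richness = pd.Series(rich, name="gene_richness") if n_draws > 1 else None
    return GeneTable(df, kind="raw", depth=depth, n_draws=n_draws, draw_richness=richness)


def normalise(table: GeneTable) -> GeneTable:
    """Divide each sample column by its total (relative abundances)."""
    totals = table.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return GeneTable(table.data / totals, kind="normalised",
                     depth=table.depth, n_draws=table.n_draws)


def gene_richness(table: GeneTable) -> pd.Series:
    """Number of genes with at least one mapped read, per sample.

    Richness is only comparable across samples at a common depth; a
    non-downsized input triggers a warning but is still scored. For tables
    rarefied with ``n_draws > 1`` the value is the per-draw richness averaged
    over draws (recorded by :func:`downsize`); otherwise it is the count of
    genes with a nonzero count.
    """
    if table.kind != "raw":
        raise ValueError("gene richness is defined on (downsized) raw counts")
    if table.depth is None:
        logger.warning("gene_richness on a non-downsized table: depths may not be comparable")
    if table.n_draws > 1 and table.draw_richness is not None:
        return table.draw_richness.reindex(table.samples)
    return (table.data > 0).sum(axis=0).rename("gene_richness")


def prevalence_filter(
    table: GeneTable | pd.DataFrame,
    threshold: float,
    baseline_samples: Sequence[str],
) -> pd.Index:
    """Feature ids whose nonzero prevalence among baseline samples is > threshold.

    The inequality is strict: a feature present in exactly
    ``threshold * n_baseline`` samples is excluded.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    df = table.data if isinstance(table, GeneTable) else table
    baseline = [s for s in baseline_samples if s in df.columns]
    if not baseline:
        raise ValueError("no baseline samples found in table")
    prev = (df[baseline] > 0).mean(axis=1)
    return df.index[prev > threshold]
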