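"""Dataset-level descriptive statistics for a poly-Q tract table.

Beyond the counts and moments, two screens are provided: a Welch t-test
comparing the protein lengths of tract-bearing genes against the
proteome background (poly-Q proteins are characteristically large,
multi-domain transcriptional regulators), and a chi-square test for
enrichment of tract positions in any one third of the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DatasetSummary", "summarize", "size_comparison", "tercile_enrichment"]


@dataclass(frozen=True)
class DatasetSummary:
    n_genes: int
    n_multi_tract: int
    #: genes with >=1 region whose purity is a single G-token of >= min_q
    n_pure_cag_genes_strict: int
    #: genes with >=1 region containing a pure CAG run of >= min_q
    n_pure_cag_genes_run: int
    mean_tract_q: float
    sd_tract_q: float
    mean_gene_max_q: float
    sd_gene_max_q: float
    max_tract_q: int
    max_tract_q_gene: str
    max_tract_count: int
    max_tract_count_gene: str

    def as_dict(self) -> dict:
        return asdict(self)


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def summarize(regions: pd.DataFrame, min_q: int = 5) -> DatasetSummary:
    """Descriptive statistics over a tract table (one row per region).

    Requires columns ``geneId, qCount, purity, longestPureCag``.  Tract
    means are per-region; gene-level means use each gene's longest tract.
    Standard deviations are sample (n-1) values.  Two pure-CAG gene
    counts are reported because "pure" admits two readings: the whole
    region is one uninterrupted CAG run (strict), or the region contains
    an uninterrupted run of >= ``min_q`` CAG (run).
    """
    if regions.empty:
        raise ValueError("empty tract table")
    per_gene = regions.groupby("geneId", sort=True)
    q = regions["qCount"].to_numpy()
    gene_max = per_gene["qCount"].max()
    tract_counts = per_gene.size()

    import re

    strict = regions["purity"].str.fullmatch(rf"G(\d+)") & (
        regions["longestPureCag"] >= min_q
    )
    strict_genes = regions.loc[strict, "geneId"].nunique()
    run_genes = regions.loc[regions["longestPureCag"] >= min_q, "geneId"].nunique()

    q_max = int(regions["qCount"].max())
    # ties broken lexicographically so the summary is order-invariant
    q_max_gene = regions.loc[regions["qCount"] == q_max, "geneId"].min()
    return DatasetSummary(
        n_genes=int(regions["geneId"].nunique()),
        n_multi_tract=int((tract_counts > 1).sum()),
        n_pure_cag_genes_strict=int(strict_genes),
        n_pure_cag_genes_run=int(run_genes),
        mean_tract_q=float(np.mean(q)),
        sd_tract_q=_sd(q),
        mean_gene_max_q=float(gene_max.mean()),
        sd_gene_max_q=_sd(gene_max.to_numpy()),
        max_tract_q=q_max,
        max_tract_q_gene=str(q_max_gene),
        max_tract_count=int(tract_counts.max()),
        max_tract_count_gene=str(tract_counts[tract_counts == tract_counts.max()].index.min()),
    )


def size_comparison(
    polyq_lengths: Sequence[float], background_lengths: Sequence[float]
) -> tuple[float, float, float, float, float]:
    """Welch two-sample t-test on protein lengths.

    Returns ``(mean_a, sd_a, mean_b, sd_b, p)`` where group a is the
    poly-Q set and b the background.
    """
    a = np.asarray(polyq_lengths, dtype=float)
    b = np.asarray(background_lengths, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero variance in both groups: test degenerate")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean()), _sd(a), float(b.mean()), _sd(b), float(res.pvalue)


def tercile_enrichment(
    position_fractions: Sequence[float],
) -> tuple[tuple[int, int, int], float, float]:
    """Chi-square test of tract positions against a uniform thirds split.

    Positions (region midpoint / protein length, in [0, 1]) are binned
    into [0, 1/3), [1/3, 2/3), [2/3, 1]; goodness of fit has 2 df.
    """
    fr = np.asarray(position_fractions, dtype=float)
    if len(fr) < 3:
        raise ValueError("need at least 3 positions")
    if ((fr < 0) | (fr > 1)).any():
        raise ValueError("position fractions must lie in [0, 1]")
    counts = np.histogram(fr, bins=[0.0, 1 / 3, 2 / 3, np.nextafter(1.0, 2.0)])[0]
    chi2, p = stats.chisquare(counts)
    return tuple(int(c) for c in counts), float(chi2), float(p)
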