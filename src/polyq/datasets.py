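"""Packaged reference datasets.

``load_polyq_panel`` returns the published genotyping survey of bovine
poly-Q repeat loci on a 185-animal cattle diversity panel: one row per
assayed repeat tract, with the tract's purity string, the number of
alleles observed, and the reported significance calls for the
subspecies (Bos taurus taurus vs Bos taurus indicus) and production-use
(beef vs dairy) comparisons.  The three genes assayed as negative
controls for the prioritization (AR, NFYA, ODAM) carry ``control == 1``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_polyq_panel", "panel_gene_summary"]


def load_polyq_panel() -> pd.DataFrame:
    """One row per assayed poly-Q tract (24 tracts across 22 genes)."""
    with resources.files("polyq.data").joinpath("bovine_polyq_panel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"control": int})


def panel_gene_summary(panel: pd.DataFrame | None = None) -> pd.DataFrame:
    """Collapse the tract-level panel table to one row per gene.

    ``alleles`` is the maximum allele count over a gene's assayed tracts;
    ``maxPureCag`` the longest uninterrupted CAG run over its purity
    strings (the ranking tie-break key).
    """
    from .repeat_annotation import longest_pure_cag

    if panel is None:
        panel = load_polyq_panel()
    rows = []
    for gene, grp in panel.groupby("gene", sort=True):
        rows.append(
            {
                "gene": gene,
                "alleles": int(grp["alleles"].max()),
                "maxPureCag": max(longest_pure_cag(p) for p in grp["purity"]),
                "control": int(grp["control"].max()),
            }
        )
    return pd.DataFrame(rows)
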