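"""Desk-scale census arithmetic over the curated-database summary table.

The built-in host-metadata table carries, per host genus, the yield of the
curation of the NCBI-derived lysin database (genomes retrieved, genes
detected by annotation, genes after curation, PF hits).  This module
recomputes its totals and the headline fractions of that census — e.g. the
share of proteins with a single significant PF hit and the per-Gram-group
signal-peptide fractions — from the underlying counts.
"""

from __future__ import annotations

import pandas as pd

from .io import HostTable, load_host_metadata

__all__ = ["REPORTED_COUNTS", "percent", "table_census", "census_summary"]

#: Headline per-protein counts of the curated database census that are not
#: per-genus rows of the metadata table: the number of proteins with exactly
#: one significant PF hit, and the per-Gram-group counts of predicted
#: N-terminal signal peptides (SAR-lysin candidates).
REPORTED_COUNTS: dict[str, int] = {
    "single_hit_proteins": 1512,
    "gneg_signal_peptides": 215,
    "gpos_signal_peptides": 106,
}


def percent(k: int | float, n: int | float, ndigits: int = 1) -> float:
    """Percentage k/n rounded to the printed precision (default 1 decimal)."""
    if n == 0:
        raise ValueError("zero denominator")
    return round(100.0 * k / n, ndigits)


def table_census(host_table: HostTable | None = None) -> dict[str, int]:
    """Column sums of the per-genus curation-yield table.

    ``genus_assigned`` excludes rows that are host *groups* rather than
    genera (the PRD1-like phages of several enterobacteria), so it counts
    proteins with a definite host genus.
    """
    table = host_table if host_table is not None else load_host_metadata()
    df = table.df
    is_genus = df["is_genus"].astype(bool)
    by_gram = df.groupby("gram")
    out = {
        "curated_total": int(df["genes_curated"].sum()),
        "genus_assigned_total": int(df.loc[is_genus, "genes_curated"].sum()),
        "pf_hits_total": int(df["pf_hits"].sum()),
        "n_genera": int(is_genus.sum()),
        "curated_gneg": int(by_gram["genes_curated"].sum().get("G-", 0)),
        "curated_gpos": int(by_gram["genes_curated"].sum().get("G+", 0)),
        "pf_hits_gneg": int(by_gram["pf_hits"].sum().get("G-", 0)),
        "pf_hits_gpos": int(by_gram["pf_hits"].sum().get("G+", 0)),
    }
    return out


def census_summary(host_table: HostTable | None = None) -> dict[str, float]:
    """Totals plus headline percentages, all recomputed from counts."""
    sums = table_census(host_table)
    return {
        **sums,
        "single_hit_fraction_pct": percent(
            REPORTED_COUNTS["single_hit_proteins"], sums["curated_total"]
        ),
        "gneg_signal_peptide_pct": percent(
            REPORTED_COUNTS["gneg_signal_peptides"], sums["curated_gneg"]
        ),
        "gpos_signal_peptide_pct": percent(
            REPORTED_COUNTS["gpos_signal_peptides"], sums["curated_gpos"]
        ),
    }
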