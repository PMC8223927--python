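"""Replication of the curated-database summary statistics from deposited data.

The curated lysin database (sequences, PF hits and signal-peptide calls) is
deposited externally and is not shipped with this package.  Given a local
copy, this module recomputes the headline statistics of that dataset:
per-Gram-group length medians, C-terminal EAD flank medians, the NCPR
effect size between Gram groups, and the hit count of the most abundant
domain family.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .architecture import flank_table
from .curation import assign_host
from .io import load_host_metadata, read_domain_hits, read_fasta
from .physchem import build_feature_table
from .robust import TestConfig, zeta_effect_size

__all__ = ["replicate_reference_database"]


def replicate_reference_database(directory: str | Path) -> dict[str, float]:
    """Recompute summary statistics from a local copy of the curated database.

    *directory* must contain ``lysins.fasta`` (headers
    ``id|annotation|phage_name|host_genus``) and ``hits.tsv`` (PfamScan-style
    or the package's simple dialect).  Raises FileNotFoundError with an
    explanatory message when the data are absent.
    """
    directory = Path(directory)
    fasta = directory / "lysins.fasta"
    hits_path = directory / "hits.tsv"
    if not fasta.exists() or not hits_path.exists():
        raise FileNotFoundError(
            f"curated-database files not found under {directory}; the deposited "
            "dataset must be downloaded separately (it is not shipped with the "
            "package) and unpacked as lysins.fasta + hits.tsv"
        )
    records = read_fasta(fasta)
    hits = read_domain_hits(hits_path)
    records, _ = assign_host(records, load_host_metadata())

    gneg = [r for r in records if r.gram and r.gram.value == "G-"]
    gpos = [r for r in records if r.gram and r.gram.value == "G+"]
    flanks = flank_table(records, hits)
    feats = build_feature_table(records, hits)
    x = feats.loc[feats["gram"] == "G-", "ncpr"].to_numpy()
    y = feats.loc[feats["gram"] == "G+", "ncpr"].to_numpy()
    return {
        "gneg_median_length": float(np.median([r.length for r in gneg])),
        "gpos_median_length": float(np.median([r.length for r in gpos])),
        "gneg_cterm_flank_median": float(
            flanks.loc[flanks["gram"] == "G-", "aa_after_last_ead"].median()
        ),
        "gpos_cterm_flank_median": float(
            flanks.loc[flanks["gram"] == "G+", "aa_after_last_ead"].median()
        ),
        "ncpr_zeta": zeta_effect_size(x, y, TestConfig()),
        "amidase_2_hits": float(sum(1 for h in hits if h.family == "Amidase_2")),
    }
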