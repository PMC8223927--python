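#!/usr/bin/env python
"""Domain-architecture census: hits per protein, EAD flanks, family shares.

Also recomputes the desk census of the real curated database from the
built-in per-genus yield table (totals and headline percentages).
"""

from pathlib import Path

import pandas as pd

from lysinscape import architecture, census
from lysinscape.curation import assign_host
from lysinscape.io import load_host_metadata, read_domain_hits, read_fasta

OUT = Path("results/analysis")


def main() -> None:
    records = read_fasta(OUT / "curated.fasta")
    records, _ = assign_host(records, load_host_metadata())
    kept = {r.id for r in records}
    hits = [h for h in read_domain_hits(OUT / "hits.tsv") if h.protein_id in kept]

    arch = architecture.summarize_all(records, hits)
    arch.to_csv(OUT / "architecture.tsv", sep="\t", index=False)
    dist, single = architecture.hits_per_protein_distribution(records, hits)
    dist.to_csv(OUT / "hits_per_protein.tsv", sep="\t")
    share = architecture.gram_share_per_family(hits, records)
    share.to_csv(OUT / "gram_share_per_family.tsv", sep="\t", index=False)
    ct = architecture.crosstab(hits, records, rows="genus", cols="family")
    ct.counts.to_csv(OUT / "crosstab_genus_family.tsv", sep="\t")

    print("single-hit fraction:", single.round(3).to_dict())
    flanks = architecture.flank_table(records, hits)
    print("C-terminal flank median:",
          flanks.groupby("gram")["aa_after_last_ead"].median().to_dict())
    print("top architectures:")
    print(arch["architecture"].value_counts().head(5).to_string())

    desk = census.census_summary()
    print("\nreal-database desk census:")
    for k in ("curated_total", "genus_assigned_total", "pf_hits_total",
              "single_hit_fraction_pct", "gneg_signal_peptide_pct",
              "gpos_signal_peptide_pct"):
        print(f"  {k} = {desk[k]}")


if __name__ == "__main__":
    main()
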