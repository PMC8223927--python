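#!/usr/bin/env python
"""Physicochemical profiling: per-protein descriptors, sequence-quartile net
charge, and binned average tendencies of local (11-aa window) net charge.

The written tendency table is the numeric counterpart of a local-property
plot: per-bin means of the windowed values along normalized position, per
Gram group.
"""

from pathlib import Path

import pandas as pd

from lysinscape import physchem
from lysinscape.curation import assign_host
from lysinscape.io import load_host_metadata, read_domain_hits, read_fasta

OUT = Path("results/analysis")


def main() -> None:
    records = read_fasta(OUT / "curated.fasta")
    records, _ = assign_host(records, load_host_metadata())
    hits = read_domain_hits(OUT / "hits.tsv")

    feats = physchem.build_feature_table(records, hits)
    feats.to_csv(OUT / "features.tsv", sep="\t", index=False)
    print(feats.groupby("gram")[
        ["ncpr", "gravy", "avg_hydrophobic_moment", "aliphatic_index"]
    ].median().round(3))

    rows = []
    for rec in records:
        if rec.gram is None:
            continue
        for q, v in enumerate(
            physchem.quartile_values(rec.sequence, "net_charge"), start=1
        ):
            rows.append({"protein_id": rec.id, "gram": rec.gram.value,
                         "quartile": f"Q{q}", "net_charge": v})
    pd.DataFrame(rows).to_csv(OUT / "quartile_net_charge.tsv", sep="\t", index=False)

    pairs = [
        (rec.gram.value, physchem.window_profile(rec.sequence, "net_charge",
                                                 protein_id=rec.id))
        for rec in records if rec.gram is not None
    ]
    tendency = physchem.average_tendency(pairs, n_bins=50)
    tendency.to_csv(OUT / "charge_tendency.tsv", sep="\t", index=False)
    tail = tendency[tendency["bin"] >= 45].groupby("label")["mean"].mean()
    print("\nmean local net charge over the last 10% of positions:")
    print(tail.round(3).to_string())


if __name__ == "__main__":
    main()
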