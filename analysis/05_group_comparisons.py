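#!/usr/bin/env python
"""Robust group comparisons: G- vs G+ net charge per sequence quartile
(Yuen-Welch on 20%-trimmed means, Bonferroni over the four quartiles, ζ
effect sizes), and per-EAD-family NCPR against the most abundant
near-neutral NAM-amidase family as reference.
"""

from pathlib import Path

import pandas as pd

from lysinscape import robust
from lysinscape.io import read_domain_hits

OUT = Path("results/analysis")


def main() -> None:
    quart = pd.read_csv(OUT / "quartile_net_charge.tsv", sep="\t")
    res = robust.compare_groups(quart, "net_charge", "gram", "quartile")
    res.to_csv(OUT / "quartile_tests.tsv", sep="\t", index=False)
    print("G- vs G+ net charge per quartile:")
    print(res[["label", "trimmed_mean_x", "trimmed_mean_y", "p_adjusted",
               "zeta", "effect", "stars"]].round(4).to_string(index=False))

    feats = pd.read_csv(OUT / "features.tsv", sep="\t")
    hits = read_domain_hits(OUT / "hits.tsv")
    ead_of = {}
    for h in hits:
        if h.func_class.value == "EAD":
            ead_of.setdefault(h.protein_id, h.family)
    feats["ead"] = feats["protein_id"].map(ead_of)
    sub = feats.dropna(subset=["ead"])
    counts = sub["ead"].value_counts()
    sub = sub[sub["ead"].isin(counts[counts >= 25].index)]
    if "Amidase_2" in set(sub["ead"]):
        per_ead = robust.compare_to_reference(sub, "ncpr", "ead", "Amidase_2")
        per_ead.to_csv(OUT / "per_ead_ncpr_tests.tsv", sep="\t", index=False)
        print("\nNCPR per EAD family vs Amidase_2 reference:")
        print(per_ead[["label", "trimmed_mean_x", "p_adjusted", "zeta", "stars"]]
              .round(4).to_string(index=False))


if __name__ == "__main__":
    main()
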