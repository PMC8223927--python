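#!/usr/bin/env python
"""Curate the simulated database: keyword screen, 50-550 aa length window,
98% identity de-duplication, domain-relevance filter, host assignment.

Reads the outputs of 01_simulate.py and writes the curated FASTA, the
per-stage report and the cluster map.  The telescoping stage counts printed
here mirror the per-genus yield bookkeeping of a real curation run.
"""

from pathlib import Path

import pandas as pd

from lysinscape.curation import run_curation
from lysinscape.io import load_host_metadata, read_domain_hits, read_fasta, write_fasta

OUT = Path("results/analysis")


def main() -> None:
    records = read_fasta(OUT / "lysins.fasta")
    hits = read_domain_hits(OUT / "hits.tsv")
    flags = pd.read_csv(OUT / "signal_flags.tsv", sep="\t")
    flagged = dict(zip(flags["protein_id"], flags["signal_peptide"]))
    records = [r.copy(signal_peptide=bool(flagged.get(r.id, False))) for r in records]

    curated, report = run_curation(records, hits, load_host_metadata())
    write_fasta(curated, OUT / "curated.fasta")
    pd.DataFrame(
        [{"stage": s.name, "n_in": s.n_in, "n_out": s.n_out,
          "n_removed": len(s.removed_ids)} for s in report.stages]
    ).to_csv(OUT / "curation_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"representative": rep, "member": m}
         for rep, members in report.cluster_map.items() for m in members]
    ).to_csv(OUT / "cluster_map.tsv", sep="\t", index=False)

    for s in report.stages:
        print(f"{s.name:20s} {s.n_in:4d} -> {s.n_out:4d}")
    n_multi = sum(1 for v in report.cluster_map.values() if len(v) > 1)
    print(f"clusters with removed redundancy: {n_multi}")


if __name__ == "__main__":
    main()
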