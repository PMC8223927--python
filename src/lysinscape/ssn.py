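"""Sequence similarity networks (SSNs) over lysin domain-family sequence sets.

Every pair of sequences is aligned locally (Smith–Waterman, BLOSUM62, gap
open 10 / extend 1); a pair is connected when its percent identity over the
aligned columns reaches the chosen threshold (≈40% for CHAP/LysM/SH3_5-like
sets, ≈30% for Amidase_2-like sets).  Because the optimal local alignment of
two unrelated proteins is often a short high-identity stretch, edges
additionally require a minimum number of aligned columns (default 50,
capped at the shorter sequence length), so spurious short matches never
connect unrelated sequences while identical short sequences still do.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import LysinRecord

__all__ = [
    "pairwise_similarity",
    "build_network",
    "component_labels",
    "export_graph",
    "DEFAULT_THRESHOLD",
    "AMIDASE2_THRESHOLD",
]

#: edge identity cutoff for most domain-family SSNs
DEFAULT_THRESHOLD = 0.40
#: looser cutoff used for the more diverse NAM-amidase (Amidase_2-like) sets
AMIDASE2_THRESHOLD = 0.30


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def _as_seq_map(sequences) -> dict[str, str]:
    if isinstance(sequences, Mapping):
        return dict(sequences)
    return {r.id: r.sequence for r in sequences}


def pairwise_similarity(sequences, denominator: str = "columns") -> pd.DataFrame:
    """All-vs-all local alignment table (one row per unordered pair).

    *sequences* is a mapping id -> sequence or a collection of records.
    Columns: ``id_a, id_b, score, identity, columns``.  ``identity`` is
    identical columns divided by aligned columns including gaps (set
    *denominator* to ``"shorter"`` for the shorter-sequence convention).
    The relation is symmetric; each pair is reported once.
    """
    seqs = _as_seq_map(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if denominator not in ("columns", "shorter"):
        raise ValueError("denominator must be 'columns' or 'shorter'")
    ids = list(seqs)
    aligner = _aligner()
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            aln = aligner.align(seqs[a], seqs[b])[0]
            c = aln.counts()
            ncol = c.identities + c.mismatches + c.gaps
            denom = ncol if denominator == "columns" else min(len(seqs[a]), len(seqs[b]))
            rows.append(
                {
                    "id_a": a,
                    "id_b": b,
                    "score": float(aln.score),
                    "identity": c.identities / denom if denom else 0.0,
                    "columns": int(ncol),
                }
            )
    return pd.DataFrame(rows, columns=["id_a", "id_b", "score", "identity", "columns"])


def build_network(
    similarities: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    sequences=None,
    min_columns: int = 50,
    node_metadata: Sequence[LysinRecord] | None = None,
) -> nx.Graph:
    """Threshold a similarity table into an undirected SSN.

    Nodes are all sequences (isolates included when *sequences* or
    *node_metadata* is given); an edge joins a pair with identity ≥
    *threshold* over at least ``min(min_columns, shorter length)`` aligned
    columns.  Node attributes (gram, genus, chemotype) are copied from
    *node_metadata* records when given.  Connected components are labeled in
    the ``component`` node attribute, largest first.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    graph = nx.Graph(threshold=threshold, min_columns=min_columns)
    lengths: dict[str, int] = {}
    if node_metadata is not None:
        for rec in node_metadata:
            graph.add_node(
                rec.id,
                gram=rec.gram.value if rec.gram else "",
                genus=rec.host_genus or "",
                chemotype=rec.chemotype or "",
            )
            lengths[rec.id] = rec.length
    elif sequences is not None:
        for sid, seq in _as_seq_map(sequences).items():
            graph.add_node(sid)
            lengths[sid] = len(seq)
    for row in similarities.itertuples():
        graph.add_nodes_from([row.id_a, row.id_b])
        if row.id_a == row.id_b:
            continue  # no self-edges
        floor = min_columns
        if row.id_a in lengths and row.id_b in lengths:
            floor = min(min_columns, lengths[row.id_a], lengths[row.id_b])
        if row.identity >= threshold and row.columns >= floor:
            graph.add_edge(
                row.id_a, row.id_b, score=float(row.score),
                identity=float(row.identity),
            )
    component_labels(graph)
    return graph


def component_labels(graph: nx.Graph) -> dict[str, int]:
    """Label connected components (0 = largest); stored as node attribute."""
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), sorted(c)))
    labels = {n: i for i, comp in enumerate(comps) for n in comp}
    nx.set_node_attributes(graph, labels, "component")
    return labels


def export_graph(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the SSN as GraphML or a plain TSV edge list."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, str(path))
    elif fmt == "tsv":
        rows = [
            {"id_a": a, "id_b": b, **{k: v for k, v in d.items()}}
            for a, b, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["id_a", "id_b", "score", "identity"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unsupported format: {fmt!r}")
    return path
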