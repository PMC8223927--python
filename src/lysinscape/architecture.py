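"""Domain-architecture census of lysins.

Counts are in units of PF hits (a repeat counts every time it matches, so a
streptococcal [EAD]5×[CW_binding_1] lysin contributes six hits), matching
the hit-level census of the curated database.  Architecture strings collapse
consecutive identical families to ``k×[family]`` and expand back losslessly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import DomainHit, FuncClass, Gram, LysinRecord

__all__ = [
    "ArchitectureRecord",
    "CrossTab",
    "resolve_overlaps",
    "architecture_string",
    "expand_architecture",
    "summarize_architecture",
    "summarize_all",
    "hits_per_protein_distribution",
    "flank_table",
    "crosstab",
    "gram_share_per_family",
]

logger = logging.getLogger(__name__)


@dataclass
class ArchitectureRecord:
    """Per-protein domain architecture summary."""

    protein_id: str
    n_hits: int
    families: list[tuple[str, int, int]]  # (family, start, end) sorted by start
    architecture: str
    n_eads: int
    n_cwbds: int
    aa_before_first_ead: int | None
    aa_after_last_ead: int | None


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Drop overlapping hits, keeping the lower E-value (tie: longer span)."""
    chosen: list[DomainHit] = []
    for h in sorted(hits, key=lambda h: (h.e_value, -h.span, h.start)):
        if all(h.end < c.start or h.start > c.end for c in chosen):
            chosen.append(h)
    return sorted(chosen, key=lambda h: h.start)


def architecture_string(families: Iterable[str]) -> str:
    """Collapse an ordered family list, e.g. [Amidase_2]5×[CW_binding_1]."""
    parts = []
    run: str | None = None
    count = 0
    for fam in list(families) + [None]:  # sentinel flushes the last run
        if fam == run:
            count += 1
            continue
        if run is not None:
            parts.append(f"[{run}]" if count == 1 else f"{count}×[{run}]")
        run, count = fam, 1
    return "".join(parts)


_ARCH_TOKEN = re.compile(r"(?:(\d+)×)?\[([^\]]+)\]")


def expand_architecture(architecture: str) -> list[str]:
    """Inverse of :func:`architecture_string`."""
    out: list[str] = []
    pos = 0
    for m in _ARCH_TOKEN.finditer(architecture):
        if m.start() != pos:
            raise ValueError(f"malformed architecture string: {architecture!r}")
        pos = m.end()
        out.extend([m.group(2)] * int(m.group(1) or 1))
    if pos != len(architecture):
        raise ValueError(f"malformed architecture string: {architecture!r}")
    return out


def summarize_architecture(
    record: LysinRecord, hits: Sequence[DomainHit]
) -> ArchitectureRecord:
    """Summarize one protein: ordered families, collapsed string, EAD flanks.

    Flanks: residues before the first EAD (by coordinate) and after the last
    EAD; CWBDs between EADs are ignored for flank purposes.  Both are missing
    when the protein has no EAD hit.
    """
    own = resolve_overlaps([h for h in hits if h.protein_id == record.id])
    fams = [(h.family, h.start, h.end) for h in own]
    eads = [h for h in own if h.func_class is FuncClass.EAD]
    n_cwbds = sum(1 for h in own if h.func_class is FuncClass.CWBD)
    before = after = None
    if eads:
        before = eads[0].start - 1
        after = record.length - eads[-1].end
    return ArchitectureRecord(
        protein_id=record.id,
        n_hits=len(own),
        families=fams,
        architecture=architecture_string([f for f, _, _ in fams]),
        n_eads=len(eads),
        n_cwbds=n_cwbds,
        aa_before_first_ead=before,
        aa_after_last_ead=after,
    )


def summarize_all(
    records: Sequence[LysinRecord], hits: Sequence[DomainHit]
) -> pd.DataFrame:
    """Architecture summary table, one row per protein."""
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    rows = []
    for rec in records:
        a = summarize_architecture(rec, by_protein.get(rec.id, []))
        rows.append(
            {
                "protein_id": a.protein_id,
                "length": rec.length,
                "gram": rec.gram.value if rec.gram else None,
                "n_hits": a.n_hits,
                "n_eads": a.n_eads,
                "n_cwbds": a.n_cwbds,
                "architecture": a.architecture,
                "aa_before_first_ead": a.aa_before_first_ead,
                "aa_after_last_ead": a.aa_after_last_ead,
            }
        )
    return pd.DataFrame(rows)


def hits_per_protein_distribution(
    records: Sequence[LysinRecord],
    hits: Sequence[DomainHit],
    group_by: str = "gram",
) -> tuple[pd.DataFrame, pd.Series]:
    """Distribution of PF hits per protein, stratified by a record attribute.

    Returns the ``n_hits × group`` protein-count table (zero rows kept for
    empty groups) and the per-group fraction of proteins with exactly one
    hit.
    """
    counts: dict[str, int] = {r.id: 0 for r in records}
    for h in hits:
        if h.protein_id in counts:
            counts[h.protein_id] += 1

    def group_of(rec: LysinRecord):
        v = getattr(rec, group_by)
        return v.value if isinstance(v, Gram) else v

    df = pd.DataFrame(
        {"group": [group_of(r) for r in records], "n_hits": [counts[r.id] for r in records]}
    )
    table = (
        df.pivot_table(index="n_hits", columns="group", aggfunc="size", fill_value=0)
        if not df.empty
        else pd.DataFrame()
    )
    grouped = df.groupby("group")["n_hits"]
    single = grouped.apply(lambda s: float((s == 1).mean()) if len(s) else np.nan)
    return table, single


def flank_table(
    records: Sequence[LysinRecord], hits: Sequence[DomainHit]
) -> pd.DataFrame:
    """Per-protein EAD flank lengths (one row per protein with ≥1 EAD)."""
    df = summarize_all(records, hits)
    return df.loc[df["n_eads"] > 0,
                  ["protein_id", "gram", "length", "aa_before_first_ead", "aa_after_last_ead"]]


@dataclass
class CrossTab:
    """Hit-count cross-tabulation with marginals."""

    counts: pd.DataFrame  # rows × cols count matrix
    row_totals: pd.Series
    col_totals: pd.Series

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


_ROW_ATTRS = {"genus": "host_genus", "host_genus": "host_genus",
              "gram": "gram", "chemotype": "chemotype"}


def crosstab(
    hits: Sequence[DomainHit],
    records: Sequence[LysinRecord],
    rows: str = "genus",
    cols: str = "family",
) -> CrossTab:
    """Cross-tabulate PF hit counts, e.g. genus × family or chemotype × activity.

    Row keys come from the record the hit belongs to (``genus``, ``gram`` or
    ``chemotype``); column keys from the hit (``family`` or ``activity``).
    Hits whose protein is not in the record collection are counted under an
    ``unassigned`` row and a warning is logged.
    """
    by_id = {r.id: r for r in records}
    row_rows, col_rows = [], []
    n_orphans = 0
    for h in hits:
        rec = by_id.get(h.protein_id)
        if rec is None:
            n_orphans += 1
            row_val = "unassigned"
        else:
            attr = _ROW_ATTRS.get(rows)
            if attr is None:
                raise ValueError(f"unsupported row key: {rows!r}")
            v = getattr(rec, attr)
            row_val = v.value if isinstance(v, Gram) else (v or "unassigned")
        if cols == "family":
            col_val = h.family
        elif cols == "activity":
            col_val = h.activity or "unknown"
        else:
            raise ValueError(f"unsupported column key: {cols!r}")
        row_rows.append(row_val)
        col_rows.append(col_val)
    if n_orphans:
        logger.warning("%d hits could not be joined to a record", n_orphans)
    counts = pd.crosstab(pd.Series(row_rows, name=rows), pd.Series(col_rows, name=cols))
    return CrossTab(
        counts=counts,
        row_totals=counts.sum(axis=1),
        col_totals=counts.sum(axis=0),
    )


def gram_share_per_family(
    hits: Sequence[DomainHit], records: Sequence[LysinRecord]
) -> pd.DataFrame:
    """Per-family total hit count and proportion of hits found in G+ hosts."""
    gram_of = {r.id: r.gram for r in records}
    rows: dict[str, list[int]] = {}
    for h in hits:
        g = gram_of.get(h.protein_id)
        if g is None:
            continue
        tot_pos = rows.setdefault(h.family, [0, 0])
        tot_pos[0] += 1
        if g is Gram.POS:
            tot_pos[1] += 1
    out = pd.DataFrame(
        [
            {"family": fam, "total_hits": tot, "gpos_share": pos / tot}
            for fam, (tot, pos) in sorted(rows.items())
        ]
    )
    return out
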