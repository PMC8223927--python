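"""Four-stage curation of annotated gene products into the analyzable lysin set.

Stage 0 screens free-text annotations with inclusion keywords (lysin,
lysozyme, murein, amidase, cell wall hydrolase, peptidase, peptidoglycan)
and overriding exclusion terms (structural, tail, holin, baseplate, virion
protein).  Curation proper then applies (i) a 50–550 aa length window,
(ii) redundancy removal by greedy identity clustering at 98%, (iii) removal
of sequences without a significant lysin-relevant domain hit (E ≤ 10,
EAD/CWBD families), and (iv) host-genus assignment from the metadata table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import DomainHit, FuncClass, HostTable, LysinRecord

__all__ = [
    "CurationConfig",
    "StageReport",
    "CurationReport",
    "pairwise_identity",
    "screen_annotations",
    "filter_length",
    "cluster_identity",
    "filter_domain_relevance",
    "assign_host",
    "run_curation",
]

DEFAULT_INCLUDE = (
    "lysin", "lysozyme", "murein", "amidase",
    "cell wall hydrolase", "peptidase", "peptidoglycan",
)
DEFAULT_EXCLUDE = ("structural", "tail", "holin", "baseplate", "virion protein")


@dataclass
class CurationConfig:
    include_terms: tuple[str, ...] = DEFAULT_INCLUDE
    exclude_terms: tuple[str, ...] = DEFAULT_EXCLUDE
    min_len: int = 50
    max_len: int = 550
    identity_threshold: float = 0.98
    evalue_cutoff: float = 10.0
    #: structural families that still count as lysin-relevant (virion-associated
    #: lysins); empty by default
    structural_exceptions: tuple[str, ...] = ()
    #: skip alignment for pairs sharing no exact 8-mer (sound at thresholds
    #: >= 0.9; see cluster_identity)
    kmer_prefilter: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity threshold must lie in (0, 1]")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not self.include_terms or not self.exclude_terms:
            raise ValueError("term lists must be non-empty")


@dataclass
class StageReport:
    name: str
    n_in: int
    n_out: int
    removed_ids: list[str]


@dataclass
class CurationReport:
    stages: list[StageReport] = field(default_factory=list)
    cluster_map: dict[str, list[str]] = field(default_factory=dict)
    flagged_unknown_host: list[str] = field(default_factory=list)

    def telescopes(self) -> bool:
        """Output count of each stage equals input count of the next."""
        return all(
            a.n_out == b.n_in for a, b in zip(self.stages, self.stages[1:])
        )


# ---------------------------------------------------------------------------
# identity


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: identical columns / shorter-sequence length.

    BLOSUM62 with gap open 10 / extend 1; the denominator follows the
    shorter-sequence convention of redundancy-removal clustering tools.
    """
    aln = _aligner().align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / min(len(seq_a), len(seq_b))


def _kmers(seq: str, k: int = 8) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def screen_annotations(
    records: Sequence[LysinRecord], config: CurationConfig | None = None
) -> list[LysinRecord]:
    """Keep records whose annotation matches an inclusion keyword and no
    exclusion term (case-insensitive substring; exclusion overrides)."""
    cfg = config or CurationConfig()
    kept = []
    for rec in records:
        text = (rec.annotation or "").lower()
        if any(t in text for t in cfg.exclude_terms):
            continue
        if any(t in text for t in cfg.include_terms):
            kept.append(rec)
    return kept


def filter_length(
    records: Sequence[LysinRecord], config: CurationConfig | None = None
) -> list[LysinRecord]:
    """Keep records with min_len <= length <= max_len (bounds inclusive)."""
    cfg = config or CurationConfig()
    return [r for r in records if cfg.min_len <= r.length <= cfg.max_len]


def cluster_identity(
    records: Sequence[LysinRecord], config: CurationConfig | None = None
) -> tuple[list[LysinRecord], dict[str, list[str]]]:
    """Greedy incremental redundancy clustering at the identity threshold.

    Records are processed longest-first (ties by id), so the outcome is
    independent of input order.  Each record joins the first already-founded
    cluster whose representative it matches at or above the threshold,
    otherwise it founds a new cluster.  Identity is
    :func:`pairwise_identity`.  An exact shared-8-mer prefilter skips
    hopeless alignments; at thresholds ≥ 0.9 and lengths ≥ 50 any pair at or
    above the threshold necessarily shares an 8-mer, so no merge is lost.
    """
    cfg = config or CurationConfig()
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    reps: list[LysinRecord] = []
    rep_kmers: list[set[str]] = []
    cluster_map: dict[str, list[str]] = {}
    use_prefilter = cfg.kmer_prefilter and cfg.identity_threshold >= 0.9
    for rec in ordered:
        kmers = _kmers(rec.sequence) if use_prefilter else None
        home = None
        for i, rep in enumerate(reps):
            if use_prefilter and not (kmers & rep_kmers[i]):
                continue
            if pairwise_identity(rec.sequence, rep.sequence) >= cfg.identity_threshold:
                home = rep
                break
        if home is None:
            reps.append(rec)
            rep_kmers.append(kmers if kmers is not None else set())
            cluster_map[rec.id] = [rec.id]
        else:
            cluster_map[home.id].append(rec.id)
    return reps, cluster_map


def filter_domain_relevance(
    records: Sequence[LysinRecord],
    hits: Sequence[DomainHit],
    config: CurationConfig | None = None,
) -> list[LysinRecord]:
    """Keep records with ≥1 significant lysin-relevant domain hit.

    Relevant means a family classed EAD or CWBD (plus configured structural
    exceptions) with E-value at or below the cutoff (cutoff inclusive).
    """
    cfg = config or CurationConfig()
    relevant: set[str] = set()
    for h in hits:
        if h.e_value > cfg.evalue_cutoff:
            continue
        if h.func_class in (FuncClass.EAD, FuncClass.CWBD) or (
            h.family in cfg.structural_exceptions
        ):
            relevant.add(h.protein_id)
    return [r for r in records if r.id in relevant]


def assign_host(
    records: Sequence[LysinRecord], metadata: HostTable
) -> tuple[list[LysinRecord], list[str]]:
    """Copy Gram group / envelope architecture / chemotype from the host table.

    Records whose genus is missing or unknown are flagged and retained (they
    are excluded from Gram-stratified analyses downstream), never dropped.
    Returns the updated records and the flagged ids.
    """
    out: list[LysinRecord] = []
    flagged: list[str] = []
    for rec in records:
        meta = metadata.lookup(rec.host_genus) if rec.host_genus else None
        if meta is None:
            out.append(rec.copy(host_unknown=True))
            flagged.append(rec.id)
        else:
            out.append(
                rec.copy(
                    gram=meta.gram,
                    chemotype=meta.chemotype,
                    outer_architecture=meta.outer_architecture,
                    host_unknown=False,
                )
            )
    return out, flagged


def run_curation(
    records: Sequence[LysinRecord],
    hits: Sequence[DomainHit],
    metadata: HostTable,
    config: CurationConfig | None = None,
) -> tuple[list[LysinRecord], CurationReport]:
    """Annotation screen, then length → identity → domain relevance → host.

    The report's stage counts telescope; every removed id appears in exactly
    one stage's removed list.  The procedure is idempotent: re-running it on
    its own output changes nothing.
    """
    cfg = config or CurationConfig()
    report = CurationReport()

    def log(name: str, before: Sequence[LysinRecord], after: Sequence[LysinRecord]):
        kept = {r.id for r in after}
        report.stages.append(
            StageReport(
                name=name,
                n_in=len(before),
                n_out=len(after),
                removed_ids=[r.id for r in before if r.id not in kept],
            )
        )

    current = list(records)
    stage = screen_annotations(current, cfg)
    log("annotation_screen", current, stage)
    current = stage

    stage = filter_length(current, cfg)
    log("length_filter", current, stage)
    current = stage

    if current:
        stage, cluster_map = cluster_identity(current, cfg)
        report.cluster_map = cluster_map
    else:
        stage, report.cluster_map = [], {}
    log("identity_clustering", current, stage)
    current = stage

    stage = filter_domain_relevance(current, hits, cfg)
    log("domain_relevance", current, stage)
    current = stage

    current, flagged = assign_host(current, metadata)
    report.flagged_unknown_host = flagged
    report.stages.append(
        StageReport(name="host_assignment", n_in=len(current), n_out=len(current),
                    removed_ids=[])
    )
    return current, report
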