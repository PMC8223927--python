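"""Data model and readers/writers for lysin sequences, domain hits and host metadata.

The on-disk formats are deliberately plain: FASTA for sequences (header
fields carry the accession, free-text annotation, phage name and host genus
in a configurable pipe-delimited dialect), PfamScan-style whitespace tables
or simple headered TSV for domain hits, and TSV for the host-genus metadata
(Gram group, cell-envelope architecture, peptidoglycan chemotype).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Gram",
    "FuncClass",
    "LysinRecord",
    "DomainHit",
    "HostMetadata",
    "HostTable",
    "FamilyClassMap",
    "read_fasta",
    "write_fasta",
    "read_domain_hits",
    "write_domain_hits",
    "load_family_classes",
    "load_host_metadata",
    "validate_hits",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in input sequences; X marks ambiguity and is inert in
#: every physicochemical computation.
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")

CHEMOTYPE_RE = re.compile(r"^A[0-9][α-ω]$")


class Gram(str, Enum):
    """Gram group of the bacterial host (mycolic-acid diderms count as G+)."""

    POS = "G+"
    NEG = "G-"

    @classmethod
    def parse(cls, text: str) -> "Gram":
        t = str(text).strip().replace("−", "-")  # unicode minus
        if t in ("G+", "+", "pos", "positive", "G_pos"):
            return cls.POS
        if t in ("G-", "-", "neg", "negative", "G_neg"):
            return cls.NEG
        raise ValueError(f"unrecognized Gram group: {text!r}")


class FuncClass(str, Enum):
    """Functional class of a Pfam domain family within a lysin."""

    EAD = "EAD"
    CWBD = "CWBD"
    STRUCTURAL = "STRUCTURAL"
    OTHER = "OTHER"


@dataclass
class LysinRecord:
    """One protein sequence with annotation, host assignment and curation state."""

    id: str
    sequence: str
    annotation: str = ""
    phage_name: str | None = None
    host_genus: str | None = None
    gram: Gram | None = None
    chemotype: str | None = None
    outer_architecture: str | None = None
    signal_peptide: bool | None = None
    host_unknown: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in ALLOWED_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {aa!r} at position {pos}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def copy(self, **changes) -> "LysinRecord":
        return replace(self, **changes)


@dataclass
class DomainHit:
    """One Pfam-family match on a protein, 1-based inclusive coordinates."""

    protein_id: str
    family: str
    accession: str
    start: int
    end: int
    e_value: float
    func_class: FuncClass = FuncClass.OTHER
    activity: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"hit {self.family} on {self.protein_id}: bad coordinates "
                f"{self.start}..{self.end}"
            )
        if self.e_value < 0:
            raise ValueError(f"hit {self.family} on {self.protein_id}: negative E-value")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HostMetadata:
    """Host-genus classifiers: Gram group, envelope architecture, chemotype."""

    genus: str
    gram: Gram
    outer_architecture: str
    chemotype: str


class HostTable:
    """Lookup table of host-genus metadata plus the per-genus curation census."""

    def __init__(self, df: pd.DataFrame):
        if df["genus"].duplicated().any():
            dups = df.loc[df["genus"].duplicated(), "genus"].tolist()
            raise ValueError(f"duplicate genus rows: {dups}")
        for chemo in df["chemotype"]:
            if not CHEMOTYPE_RE.match(str(chemo)):
                raise ValueError(f"chemotype {chemo!r} not in Schleifer-Kandler form")
        self.df = df.reset_index(drop=True)
        self._by_genus = {
            row.genus: HostMetadata(
                genus=row.genus,
                gram=Gram.parse(row.gram),
                outer_architecture=row.outer_architecture,
                chemotype=row.chemotype,
            )
            for row in df.itertuples()
        }

    def lookup(self, genus: str) -> HostMetadata | None:
        """Return metadata for *genus*, or None for genera not in the table."""
        return self._by_genus.get(genus)

    def genera(self) -> list[str]:
        return list(self._by_genus)

    def __len__(self) -> int:
        return len(self._by_genus)

    def __contains__(self, genus: str) -> bool:
        return genus in self._by_genus


class FamilyClassMap:
    """Editable family -> (accession, functional class, activity) lookup.

    Families absent from the map fall back to :class:`FuncClass` OTHER with
    unknown activity, mirroring how unclassified Pfam families are treated in
    the domain census.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df
        self._map = {
            row.family: (
                row.accession,
                FuncClass(row.func_class),
                (row.activity if isinstance(row.activity, str) and row.activity else None),
            )
            for row in df.itertuples()
        }

    def func_class(self, family: str) -> FuncClass:
        return self._map.get(family, ("", FuncClass.OTHER, None))[1]

    def activity(self, family: str) -> str | None:
        return self._map.get(family, ("", FuncClass.OTHER, None))[2]

    def accession(self, family: str) -> str | None:
        entry = self._map.get(family)
        return entry[0] if entry else None

    def families(self, func_class: FuncClass | None = None) -> list[str]:
        if func_class is None:
            return list(self._map)
        return [f for f, v in self._map.items() if v[1] is func_class]

    def __contains__(self, family: str) -> bool:
        return family in self._map


def _data_path(name: str) -> Path:
    return Path(str(resources.files("lysinscape").joinpath("data", name)))


def load_family_classes(path: str | Path | None = None) -> FamilyClassMap:
    """Load the family->class/activity map (built-in table by default)."""
    p = Path(path) if path is not None else _data_path("family_classes.tsv")
    df = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    return FamilyClassMap(df)


def load_host_metadata(path: str | Path | None = None) -> HostTable:
    """Load host-genus metadata; the built-in table ships with the package."""
    p = Path(path) if path is not None else _data_path("host_metadata.tsv")
    df = pd.read_csv(p, sep="\t")
    return HostTable(df)


# ---------------------------------------------------------------------------
# FASTA


def _parse_header(header: str, dialect: str) -> dict:
    """Split a FASTA header according to a pipe-delimited field dialect."""
    out: dict[str, str] = {}
    if "|" in header:
        for name, value in zip(dialect.split("|"), header.split("|")):
            value = value.strip()
            if value:
                out[name] = value
    if "id" not in out:
        # whitespace dialect fallback: first token is the id, rest annotation
        tokens = header.split(None, 1)
        out["id"] = tokens[0]
        if len(tokens) > 1:
            out.setdefault("annotation", tokens[1].strip())
    return out


def read_fasta(
    path: str | Path,
    dialect: str = "id|annotation|phage_name|host_genus",
) -> list[LysinRecord]:
    """Read a FASTA file into :class:`LysinRecord` objects.

    Headers are split on ``|`` per *dialect* (default
    ``id|annotation|phage_name|host_genus``); headers without pipes fall back
    to whitespace splitting (first token id, remainder annotation).
    Sequences are uppercased; residues outside the 20-letter alphabet plus X
    raise with the offending position; duplicate ids raise.
    """
    path = Path(path)
    records: list[LysinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        meta = _parse_header(entry.description, dialect)
        rec = LysinRecord(
            id=meta["id"],
            sequence=str(entry.seq),
            annotation=meta.get("annotation", ""),
            phage_name=meta.get("phage_name"),
            host_genus=meta.get("host_genus"),
        )
        if rec.id in seen:
            raise ValueError(f"duplicate record id in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Iterable[LysinRecord],
    path: str | Path,
    dialect: str = "id|annotation|phage_name|host_genus",
) -> None:
    """Write records as FASTA with headers in the given pipe dialect."""
    fields = dialect.split("|")
    out = []
    for rec in records:
        values = []
        for name in fields:
            v = getattr(rec, name, "") or ""
            values.append(str(v))
        # trim trailing empty fields so minimal records stay tidy
        while len(values) > 1 and values[-1] == "":
            values.pop()
        header = "|".join(values)
        out.append(SeqRecord(Seq(rec.sequence), id=header, description=""))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# Domain hits

#: column count of full PfamScan output rows
_PFAMSCAN_NCOL = 15
_SIMPLE_COLUMNS = ["protein_id", "start", "end", "accession", "family", "e_value"]


def read_domain_hits(
    path: str | Path,
    family_map: FamilyClassMap | None = None,
    dialect: str = "auto",
    coordinates: str = "envelope",
) -> list[DomainHit]:
    """Parse a PfamScan-style table of domain hits.

    Two dialects are accepted: ``simple`` — a headered TSV with columns
    ``protein_id  start  end  accession  family  e_value`` (the package's own
    writer format) — and ``pfamscan`` — the 15-column whitespace output of
    pfam_scan.pl, from which either envelope (default) or alignment
    coordinates are taken.  ``auto`` sniffs the dialect per file.  Lines
    beginning with ``#`` and blank lines are ignored.  Functional classes are
    assigned from *family_map* (built-in map by default).
    """
    path = Path(path)
    fmap = family_map if family_map is not None else load_family_classes()
    if coordinates not in ("envelope", "alignment"):
        raise ValueError("coordinates must be 'envelope' or 'alignment'")
    hits: list[DomainHit] = []
    with open(path) as fh:
        lines = fh.readlines()
    body = [
        (i + 1, ln.strip()) for i, ln in enumerate(lines)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not body:
        return hits
    mode = dialect
    if mode == "auto":
        first = body[0][1]
        if first.split("\t")[0] == "protein_id" or first.split()[0] == "protein_id":
            mode = "simple"
        elif len(first.split()) >= _PFAMSCAN_NCOL - 2:
            mode = "pfamscan"
        else:
            mode = "simple"
    for lineno, line in body:
        parts = line.split("\t") if "\t" in line else line.split()
        if mode == "simple" and parts[0] == "protein_id":
            continue  # header row
        try:
            if mode == "simple":
                if len(parts) < 6:
                    raise ValueError("expected 6 columns")
                pid, start, end, acc, fam, ev = parts[:6]
            else:
                if len(parts) < _PFAMSCAN_NCOL - 2:
                    raise ValueError("expected PfamScan row")
                pid = parts[0]
                if coordinates == "alignment":
                    start, end = parts[1], parts[2]
                else:
                    start, end = parts[3], parts[4]
                acc = parts[5].split(".")[0]
                fam = parts[6]
                ev = parts[12]
            hit = DomainHit(
                protein_id=pid,
                family=fam,
                accession=acc,
                start=int(start),
                end=int(end),
                e_value=float(ev),
                func_class=fmap.func_class(fam),
                activity=fmap.activity(fam),
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed domain-hit row: {exc}") from exc
        hits.append(hit)
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits as a headered TSV in the package's ``simple`` dialect."""
    df = hits_to_frame(hits)
    df[_SIMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def hits_to_frame(hits: Iterable[DomainHit]) -> pd.DataFrame:
    """Tabulate hits as a DataFrame (one row per PF hit)."""
    rows = [
        {
            "protein_id": h.protein_id,
            "start": h.start,
            "end": h.end,
            "accession": h.accession,
            "family": h.family,
            "e_value": h.e_value,
            "func_class": h.func_class.value,
            "activity": h.activity,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "start", "end", "accession", "family",
            "e_value", "func_class", "activity",
        ],
    )


def records_to_frame(records: Iterable[LysinRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "length": r.length,
            "annotation": r.annotation,
            "phage_name": r.phage_name,
            "host_genus": r.host_genus,
            "gram": r.gram.value if r.gram else None,
            "chemotype": r.chemotype,
            "outer_architecture": r.outer_architecture,
            "signal_peptide": r.signal_peptide,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def validate_hits(
    records: Sequence[LysinRecord], hits: Iterable[DomainHit]
) -> list[DomainHit]:
    """Check hits against a record collection; return orphan/overrun hits.

    A hit is flagged when its protein id is absent from the collection or its
    end coordinate exceeds the protein length.
    """
    lengths: Mapping[str, int] = {r.id: r.length for r in records}
    flagged = []
    for h in hits:
        L = lengths.get(h.protein_id)
        if L is None or h.end > L:
            flagged.append(h)
    return flagged
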