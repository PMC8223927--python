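"""Physicochemical descriptor engine for lysin sequences.

Computes, at whole-sequence, quartile and sliding-window resolution:

* net charge at a given pH by Henderson–Hasselbalch summation over the
  ionizable side chains (D, E, C, Y, H, K, R) and, optionally, the terminal
  amino and carboxyl groups, using a named pKa scale (default Dawson);
* NCPR, the net charge divided by the residue count;
* GRAVY, the grand average of Kyte–Doolittle hydropathy;
* the hydrophobic moment μH of an idealized helix at a configurable
  rotational angle (default 100°, the α-helical periodicity), normalized per
  residue, and its average over all 11-residue windows;
* the aliphatic index of Ikai (relative volume of A/V/I/L side chains).

X residues are treated as inert: zero hydropathy, non-ionizable, and
excluded from every mean/mole-percent denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DAWSON_PKA",
    "KYTE_DOOLITTLE",
    "PhyschemConfig",
    "PropertyProfile",
    "net_charge",
    "ncpr",
    "gravy",
    "hydrophobic_moment",
    "avg_hydrophobic_moment",
    "aliphatic_index",
    "quartile_split",
    "quartile_values",
    "window_profile",
    "average_tendency",
    "build_feature_table",
    "PROPERTY_FUNCS",
]

#: Dawson pKa values for the ionizable groups (side chains and termini),
#: as tabulated by the reference descriptor implementation; replaceable via
#: PhyschemConfig.pka_scale.
DAWSON_PKA: dict[str, float] = {
    "D": 3.9,
    "E": 4.0,
    "C": 8.3,
    "Y": 10.1,
    "H": 6.0,
    "K": 10.5,
    "R": 12.0,
    "nTer": 8.2,
    "cTer": 3.2,
}

#: residues whose side chains are positively charged when protonated
BASIC_RESIDUES = ("K", "R", "H")
#: residues whose side chains are negatively charged when deprotonated
ACIDIC_RESIDUES = ("D", "E", "C", "Y")

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass
class PhyschemConfig:
    """Tunables for the descriptor engine.

    pH 7.0, the Dawson pKa scale, the Kyte–Doolittle hydropathy scale, a
    100° helical rotation angle and 11-residue windows are the defaults used
    throughout the analysis.
    """

    ph: float = 7.0
    pka_scale: Mapping[str, float] = field(default_factory=lambda: dict(DAWSON_PKA))
    hydrophobicity_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE)
    )
    rotation_angle: float = 100.0  # degrees per residue
    window: int = 11
    #: whether quartile fragments keep ionizable terminal groups at the cut
    #: points (the real protein backbone is amide-bonded there, so default off)
    fragment_termini: bool = False
    #: remainder residues of the quartile split go to the last fragment
    remainder_to_last: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.ph < 14):
            raise ValueError("pH must lie in (0, 14)")
        if not (0 < self.rotation_angle <= 180):
            raise ValueError("rotation angle must lie in (0, 180] degrees")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.hydrophobicity_scale)
        if missing:
            raise ValueError(f"hydrophobicity scale missing residues: {sorted(missing)}")


_DEFAULT = PhyschemConfig()


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    return sequence.upper()


def net_charge(
    sequence: str,
    config: PhyschemConfig | None = None,
    include_nterm: bool = True,
    include_cterm: bool = True,
) -> float:
    """Net charge at ``config.ph`` by Henderson–Hasselbalch summation.

    Positive contributions: K, R, H side chains and (optionally) the
    N-terminal amine, each ``1/(1+10**(pH-pKa))``.  Negative contributions:
    D, E, C, Y side chains and (optionally) the C-terminal carboxyl, each
    ``1/(1+10**(pKa-pH))``.
    """
    cfg = config or _DEFAULT
    seq = _check_sequence(sequence)
    pka = cfg.pka_scale
    ph = cfg.ph
    unknown = set(seq) - set("ACDEFGHIKLMNPQRSTVWYX")
    if unknown:
        raise ValueError(f"residues not in charge model: {sorted(unknown)}")
    charge = 0.0
    if include_nterm:
        charge += 1.0 / (1.0 + 10 ** (ph - pka["nTer"]))
    if include_cterm:
        charge -= 1.0 / (1.0 + 10 ** (pka["cTer"] - ph))
    for aa in BASIC_RESIDUES:
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka[aa]))
    for aa in ACIDIC_RESIDUES:
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def ncpr(sequence: str, config: PhyschemConfig | None = None) -> float:
    """Net charge per residue: net charge divided by sequence length."""
    seq = _check_sequence(sequence)
    return net_charge(seq, config) / len(seq)


def gravy(sequence: str, config: PhyschemConfig | None = None) -> float:
    """Grand average of hydropathy; X excluded from the mean entirely."""
    cfg = config or _DEFAULT
    seq = _check_sequence(sequence)
    values = [cfg.hydrophobicity_scale[aa] for aa in seq if aa != "X"]
    if not values:
        raise ValueError("sequence contains no scorable residues (all X)")
    return float(np.mean(values))


def hydrophobic_moment(
    window_sequence: str, config: PhyschemConfig | None = None
) -> float:
    """Per-residue-normalized hydrophobic moment of one helical window.

    μH = sqrt((Σ h_n sin(δ n))² + (Σ h_n cos(δ n))²) / N with n = 0..N−1 and
    δ the rotation angle (converted to radians internally).  X residues carry
    zero hydropathy but still advance the helical phase and count in N.
    """
    cfg = config or _DEFAULT
    seq = _check_sequence(window_sequence)
    delta = math.radians(cfg.rotation_angle)
    scale = cfg.hydrophobicity_scale
    sin_sum = 0.0
    cos_sum = 0.0
    for n, aa in enumerate(seq):
        h = 0.0 if aa == "X" else scale[aa]
        sin_sum += h * math.sin(delta * n)
        cos_sum += h * math.cos(delta * n)
    return math.hypot(sin_sum, cos_sum) / len(seq)


def avg_hydrophobic_moment(
    sequence: str, config: PhyschemConfig | None = None
) -> float:
    """Mean μH over all windows; sequences shorter than the window are one window."""
    cfg = config or _DEFAULT
    seq = _check_sequence(sequence)
    w = cfg.window
    if len(seq) <= w:
        return hydrophobic_moment(seq, cfg)
    vals = [hydrophobic_moment(seq[i : i + w], cfg) for i in range(len(seq) - w + 1)]
    return float(np.mean(vals))


def aliphatic_index(sequence: str, config: PhyschemConfig | None = None) -> float:
    """Ikai's aliphatic index: X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu).

    Mole percentages are computed over non-X residues.
    """
    seq = _check_sequence(sequence)
    n = sum(1 for aa in seq if aa != "X")
    if n == 0:
        raise ValueError("sequence contains no scorable residues (all X)")
    x_ala = 100.0 * seq.count("A") / n
    x_val = 100.0 * seq.count("V") / n
    x_il = 100.0 * (seq.count("I") + seq.count("L")) / n
    return x_ala + 2.9 * x_val + 3.9 * x_il


def _property_on_fragment(
    prop: str,
    fragment: str,
    cfg: PhyschemConfig,
    include_nterm: bool,
    include_cterm: bool,
) -> float:
    if prop == "net_charge":
        return net_charge(fragment, cfg, include_nterm, include_cterm)
    if prop == "ncpr":
        return net_charge(fragment, cfg, include_nterm, include_cterm) / len(fragment)
    return PROPERTY_FUNCS[prop](fragment, cfg)


def quartile_split(sequence: str, config: PhyschemConfig | None = None) -> list[str]:
    """Split into 4 contiguous fragments of ⌊L/4⌋ residues, remainder to the last."""
    cfg = config or _DEFAULT
    seq = _check_sequence(sequence)
    L = len(seq)
    if L < 4:
        raise ValueError("quartile split needs length >= 4")
    q = L // 4
    if cfg.remainder_to_last:
        bounds = [0, q, 2 * q, 3 * q, L]
    else:  # remainder spread from the first fragment onward
        rem = L - 4 * q
        sizes = [q + (1 if i < rem else 0) for i in range(4)]
        bounds = [0]
        for s in sizes:
            bounds.append(bounds[-1] + s)
    return [seq[bounds[i] : bounds[i + 1]] for i in range(4)]


def quartile_values(
    sequence: str, prop: str, config: PhyschemConfig | None = None
) -> list[float]:
    """Property computed independently on each sequence quartile.

    For charge-type properties, terminal ionizable groups are dropped at the
    internal cut points (the backbone is amide-bonded there); the true N- and
    C-termini of the protein stay on the first and last fragments.  Setting
    ``config.fragment_termini`` treats every fragment as a free peptide.
    """
    cfg = config or _DEFAULT
    frags = quartile_split(sequence, cfg)
    out = []
    for i, frag in enumerate(frags):
        nt = cfg.fragment_termini or i == 0
        ct = cfg.fragment_termini or i == 3
        out.append(_property_on_fragment(prop, frag, cfg, nt, ct))
    return out


@dataclass
class PropertyProfile:
    """Windowed values of one property along one protein."""

    protein_id: str
    property: str
    values: np.ndarray  # one per window start
    centers: np.ndarray  # absolute 1-based window-center positions
    normalized_positions: np.ndarray  # centers / length, in (0, 1]
    length: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_id,
                "property": self.property,
                "value": self.values,
                "center": self.centers,
                "normalized_position": self.normalized_positions,
            }
        )


def window_profile(
    sequence: str,
    prop: str,
    config: PhyschemConfig | None = None,
    protein_id: str = "",
) -> PropertyProfile:
    """Sliding-window profile of a property (default 11-residue windows).

    Charge in a window is computed from side chains only (no terminal
    groups), since windows are internal peptide stretches.  Sequences shorter
    than the window yield a single whole-sequence window.
    """
    cfg = config or _DEFAULT
    seq = _check_sequence(sequence)
    w = min(cfg.window, len(seq))
    n_windows = len(seq) - w + 1
    values = np.empty(n_windows)
    centers = np.empty(n_windows)
    for i in range(n_windows):
        frag = seq[i : i + w]
        values[i] = _property_on_fragment(prop, frag, cfg, False, False)
        centers[i] = i + (w + 1) / 2.0  # 1-based center (half-integer for even w)
    return PropertyProfile(
        protein_id=protein_id,
        property=prop,
        values=values,
        centers=centers,
        normalized_positions=centers / len(seq),
        length=len(seq),
    )


def average_tendency(
    profiles: Mapping[str, Iterable[PropertyProfile]] | Iterable[tuple[str, PropertyProfile]],
    n_bins: int = 50,
) -> pd.DataFrame:
    """Per-label average tendency of windowed values along normalized position.

    Windows from all profiles of a label are pooled into ``n_bins``
    equal-width bins of normalized position over (0, 1]; the per-bin
    arithmetic mean is reported.  Bins with no windows are absent from the
    output (missing, not zero).
    """
    if isinstance(profiles, Mapping):
        items = [(label, p) for label, ps in profiles.items() for p in ps]
    else:
        items = list(profiles)
    rows = []
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    for label, profile in items:
        idx = np.clip(np.searchsorted(edges, profile.normalized_positions, side="left") - 1,
                      0, n_bins - 1)
        for b, v in zip(idx, profile.values):
            rows.append((label, b, v))
    df = pd.DataFrame(rows, columns=["label", "bin", "value"])
    if df.empty:
        return pd.DataFrame(columns=["label", "bin", "bin_center", "mean", "n"])
    agg = df.groupby(["label", "bin"])["value"].agg(["mean", "size"]).reset_index()
    agg = agg.rename(columns={"size": "n"})
    agg["bin_center"] = (edges[agg["bin"]] + edges[agg["bin"] + 1]) / 2.0
    return agg[["label", "bin", "bin_center", "mean", "n"]]


PROPERTY_FUNCS = {
    "net_charge": net_charge,
    "ncpr": ncpr,
    "gravy": gravy,
    "avg_hydrophobic_moment": avg_hydrophobic_moment,
    "aliphatic_index": aliphatic_index,
}


def build_feature_table(
    records,
    hits=None,
    config: PhyschemConfig | None = None,
    evalue_cutoff: float = 10.0,
) -> pd.DataFrame:
    """Per-protein descriptor table used for Gram-group classification.

    Columns: the four physicochemical descriptors (ncpr,
    avg_hydrophobic_moment, aliphatic_index, gravy) plus net_charge, length,
    n_pf_hits (significant hits only), signal_peptide and the gram label
    (NaN where the host is unassigned, so rows stay usable unsupervised).
    """
    cfg = config or _DEFAULT
    n_hits: dict[str, int] = {}
    if hits is not None:
        for h in hits:
            if h.e_value <= evalue_cutoff:
                n_hits[h.protein_id] = n_hits.get(h.protein_id, 0) + 1
    rows = []
    for rec in records:
        nc = net_charge(rec.sequence, cfg)
        rows.append(
            {
                "protein_id": rec.id,
                "net_charge": nc,
                "ncpr": nc / rec.length,
                "gravy": gravy(rec.sequence, cfg),
                "avg_hydrophobic_moment": avg_hydrophobic_moment(rec.sequence, cfg),
                "aliphatic_index": aliphatic_index(rec.sequence, cfg),
                "length": rec.length,
                "n_pf_hits": n_hits.get(rec.id, 0),
                "signal_peptide": bool(rec.signal_peptide)
                if rec.signal_peptide is not None
                else False,
                "gram": rec.gram.value if rec.gram else None,
            }
        )
    return pd.DataFrame(rows)
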