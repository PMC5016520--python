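"""CDR length distributions, IMGT position labels, and positional variability.

CDR positions follow the IMGT unique numbering for V domains.  CDR3
spans positions 105-117 (anchors C104 and W118/F118 excluded): for a
junction of L residues the first ceil(L/2) take positions 105 upward and
the last floor(L/2) take positions ending at 117; lengths above 13 place
insertion labels at the loop top (112.1 first, then 111.1, 112.2, 111.2,
...), lengths below 13 leave gaps there.  CDR1 (27-38) and CDR2 (56-65)
use the same symmetric rule on their own ranges.

Per-position residue (or residue-class) counts are summarised by three
variability indices:

* Shannon entropy  H = -sum p_i log2 p_i   (bits; 0 = monomorphic)
* Wu-Kabat         WK = k * N / n_max      (k classes, N total, n_max mode)
* Simpson          D = 1 - sum p_i^2       (in [0, 1])

Positions with H > 2 bits are conventionally called variable, H < 1
highly conserved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repertoire import Mode, RepertoireSet

__all__ = [
    "CLASS_SCHEMES",
    "load_class_schemes",
    "class_of",
    "LengthDistribution",
    "PositionProfile",
    "length_distribution",
    "list_cdr3_at_length",
    "imgt_cdr3_positions",
    "imgt_cdr_positions",
    "position_profile",
    "shannon_entropy",
    "wu_kabat",
    "simpson_index",
]

_CDR_RANGES = {1: (27, 38), 2: (56, 65), 3: (105, 117)}


def load_class_schemes() -> dict[str, dict[str, str]]:
    """Load residue-class memberships from the bundled (editable) data file."""
    with resources.files("clonostat.data").joinpath("imgt_aa_classes.json").open() as fh:
        raw = json.load(fh)
    schemes = {k: v for k, v in raw.items() if not k.startswith("_")}
    schemes["AA"] = {aa: aa for aa in "ACDEFGHIKLMNPQRSTVWY"}
    return schemes


CLASS_SCHEMES = load_class_schemes()

_LOOKUP: dict[str, dict[str, str]] = {
    scheme: {aa: cls for cls, members in classes.items() for aa in members}
    for scheme, classes in CLASS_SCHEMES.items()
}


def class_of(aa: str, scheme: str = "AA") -> str:
    """Map one residue to its class under the scheme."""
    try:
        return _LOOKUP[scheme][aa]
    except KeyError:
        if scheme not in _LOOKUP:
            raise ValueError(f"unknown class scheme {scheme!r}") from None
        raise KeyError(f"residue {aa!r} not covered by scheme {scheme!r}") from None


def _cdr_seq(rec, cdr_type: int) -> str:
    return {1: rec.cdr1_aa, 2: rec.cdr2_aa, 3: rec.cdr3_aa}[cdr_type]


@dataclass
class LengthDistribution:
    """Per-length counts for both sets, optionally per 10,000."""

    cdr_type: int
    mode: Mode
    counts1: dict[int, float]
    counts2: dict[int, float]
    normalized: bool
    labels: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(set(self.counts1) | set(self.counts2))
        return pd.DataFrame(
            {
                "length": lengths,
                self.labels[0]: [self.counts1.get(l, 0) for l in lengths],
                self.labels[1]: [self.counts2.get(l, 0) for l in lengths],
            }
        )


def length_distribution(
    set1: RepertoireSet,
    set2: RepertoireSet,
    cdr_type: int = 3,
    mode: Mode = "diversity",
    normalized: bool = False,
) -> LengthDistribution:
    """CDR length histogram for both sets.

    Diversity counts one per clonotype; expression weights by assigned
    sequences.  CDR3 uses the recorded junction length, CDR1/CDR2 the
    character length of their sequences (clonotypes without that CDR are
    omitted).  Normalisation rescales each set to a total of 10,000.
    """
    if cdr_type not in (1, 2, 3):
        raise ValueError("cdr_type must be 1, 2 or 3")

    def hist(rset: RepertoireSet) -> dict[int, float]:
        counts: dict[int, float] = {}
        for rec in rset.records:
            if cdr_type == 3:
                length = rec.cdr3_length
            else:
                seq = _cdr_seq(rec, cdr_type)
                if not seq:
                    continue
                length = len(seq)
            w = 1 if mode == "diversity" else rec.n_sequences
            counts[length] = counts.get(length, 0) + w
        if normalized:
            total = sum(counts.values())
            if total > 0:
                counts = {l: c / total * 10_000 for l, c in counts.items()}
        return counts

    return LengthDistribution(
        cdr_type, mode, hist(set1), hist(set2), normalized, (set1.label, set2.label)
    )


def list_cdr3_at_length(rset: RepertoireSet, length: int) -> pd.DataFrame:
    """All kept clonotypes with the given CDR3 length, one row each."""
    rows = [
        {
            "cdr3_aa": r.cdr3_aa,
            "v_call": r.v_call.canonical(),
            "j_call": r.j_call.canonical(),
            "n_sequences": r.n_sequences,
        }
        for r in rset.records
        if r.cdr3_length == length
    ]
    return pd.DataFrame(rows, columns=["cdr3_aa", "v_call", "j_call", "n_sequences"])


def _symmetric_positions(first: int, last: int, length: int) -> list[str]:
    """Position labels for a loop of ``length`` residues over [first, last].

    The first ceil(L/2) residues take positions from ``first`` upward,
    the last floor(L/2) positions ending at ``last``.  Shorter loops gap
    at the top (between the blocks); longer loops insert decimal labels
    at the top, alternating right (``left_top+1 . k``) then left
    (``left_top . k``).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    n_base = last - first + 1
    n_left_base = math.ceil(n_base / 2)
    n_right_base = n_base - n_left_base
    left_top = first + n_left_base - 1  # e.g. 111 for CDR3
    right_top = left_top + 1            # e.g. 112

    n_left = math.ceil(length / 2)
    n_right = length - n_left

    left = [str(first + i) for i in range(min(n_left, n_left_base))]
    left += [f"{left_top}.{i}" for i in range(1, n_left - n_left_base + 1)]
    right_base = [str(right_top + i) for i in range(n_right_base)]
    right = right_base[n_right_base - min(n_right, n_right_base):]
    right = [f"{right_top}.{i}" for i in range(n_right - n_right_base, 0, -1)] + right
    return left + right


def imgt_cdr3_positions(length: int) -> list[str]:
    """IMGT position labels for a CDR3 of ``length`` residues (max 45)."""
    if not 1 <= length <= 45:
        raise ValueError("CDR3 length must be in 1..45")
    return _symmetric_positions(*_CDR_RANGES[3], length)


def imgt_cdr_positions(cdr_type: int, length: int) -> list[str]:
    """IMGT position labels for CDR1, CDR2 or CDR3 of the given length."""
    if cdr_type not in _CDR_RANGES:
        raise ValueError("cdr_type must be 1, 2 or 3")
    if cdr_type == 3:
        return imgt_cdr3_positions(length)
    return _symmetric_positions(*_CDR_RANGES[cdr_type], length)


def shannon_entropy(counts: Sequence[float] | Mapping[str, float]) -> float:
    """Shannon entropy in bits of a count vector."""
    c = np.asarray(list(counts.values()) if isinstance(counts, Mapping) else counts, float)
    c = c[c > 0]
    total = c.sum()
    if total <= 0:
        raise ValueError("entropy undefined for all-zero counts")
    p = c / total
    return float(-(p * np.log2(p)).sum())


def wu_kabat(counts: Sequence[float] | Mapping[str, float]) -> float:
    """Wu-Kabat variability: (number of classes) * N / (count of the mode)."""
    c = np.asarray(list(counts.values()) if isinstance(counts, Mapping) else counts, float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("Wu-Kabat undefined for all-zero counts")
    return float(c.size * c.sum() / c.max())


def simpson_index(counts: Sequence[float] | Mapping[str, float]) -> float:
    """Simpson diversity 1 - sum p_i^2 (probability two draws differ)."""
    c = np.asarray(list(counts.values()) if isinstance(counts, Mapping) else counts, float)
    c = c[c > 0]
    total = c.sum()
    if total <= 0:
        raise ValueError("Simpson index undefined for all-zero counts")
    p = c / total
    return float(1.0 - (p**2).sum())


@dataclass
class PositionProfile:
    """Residue/class counts and variability indices per IMGT position."""

    cdr_type: int
    length: int
    class_scheme: str
    positions: list[str]
    counts: pd.DataFrame     # classes x positions
    indices: pd.DataFrame    # rows shannon/wu_kabat/simpson x positions
    n_profiled: int
    n_skipped: int


def position_profile(
    rset: RepertoireSet,
    cdr_type: int,
    length: int,
    class_scheme: str = "AA",
    mode: Mode = "diversity",
) -> PositionProfile:
    """Tabulate residue classes at every IMGT position of one CDR length.

    Each clonotype whose CDR of ``cdr_type`` has exactly ``length``
    residues contributes its residue (mapped through the class scheme)
    at every position, weighted 1 (diversity) or by its assigned
    sequences (expression).  Sequences containing residues outside the
    scheme are skipped and counted in ``n_skipped``.
    """
    positions = imgt_cdr_positions(cdr_type, length)
    lookup = _LOOKUP.get(class_scheme)
    if lookup is None:
        raise ValueError(f"unknown class scheme {class_scheme!r}")
    classes = sorted(CLASS_SCHEMES[class_scheme])
    counts = pd.DataFrame(0, index=classes, columns=positions, dtype=int)
    n_profiled = n_skipped = 0
    for rec in rset.records:
        seq = _cdr_seq(rec, cdr_type) if cdr_type != 3 else rec.cdr3_aa
        if len(seq) != length:
            continue
        try:
            mapped = [lookup[aa] for aa in seq]
        except KeyError:
            n_skipped += 1
            continue
        w = 1 if mode == "diversity" else rec.n_sequences
        for pos, cls in zip(positions, mapped):
            counts.loc[cls, pos] += w
        n_profiled += w

    idx = pd.DataFrame(index=["shannon", "wu_kabat", "simpson"], columns=positions, dtype=float)
    for pos in positions:
        col = counts[pos]
        if col.sum() > 0:
            idx.loc["shannon", pos] = shannon_entropy(col.to_numpy())
            idx.loc["wu_kabat", pos] = wu_kabat(col.to_numpy())
            idx.loc["simpson", pos] = simpson_index(col.to_numpy())
    return PositionProfile(
        cdr_type=cdr_type,
        length=length,
        class_scheme=class_scheme,
        positions=positions,
        counts=counts,
        indices=idx,
        n_profiled=n_profiled,
        n_skipped=n_skipped,
    )
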