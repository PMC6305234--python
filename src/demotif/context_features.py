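"""Physicochemical context of DE motifs: flanking hydrophobicity (H),
flanking charge (C) and structural order class (O/D/B).

H sums Kyte-Doolittle hydropathy over up to ``half_width`` residues on
each side of the motif; C sums unit formal charges over the same window.
The D and E of the motif itself are excluded by default. Windows truncate
at the termini and the number of residues actually used is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core_model import Dataset

logger = logging.getLogger(__name__)

#: Kyte & Doolittle (1982) hydropathy scale; X imputed neutral (0.0)
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

#: default per-side flanking window in residues
DEFAULT_HALF_WIDTH = 3

ORDERED_STATES = frozenset("HE")


def residue_charge(residue: str, histidine_charge: float = 0.0) -> float:
    """Formal charge: D/E -> -1, K/R -> +1, H configurable (default 0)."""
    if residue in "DE":
        return -1.0
    if residue in "KR":
        return +1.0
    if residue == "H":
        return histidine_charge
    return 0.0


@dataclass
class DEMotifContext:
    """One DE occurrence with its local physical descriptors."""

    protein_id: str
    start: int  # 0-based position of the D
    H: float
    C: float
    order_class: str | None  # 'O', 'D', 'B', or None when no structure
    n_flank_left: int
    n_flank_right: int


def _check_de(sequence: str, start: int) -> None:
    if not (0 <= start <= len(sequence) - 2
            and sequence[start:start + 2] == "DE"):
        raise ValueError(f"position {start} is not a DE motif")


def _windows(sequence: str, start: int, half_width: int,
             include_motif: bool) -> tuple[str, str]:
    left = sequence[max(0, start - half_width):start]
    right = sequence[start + 2:start + 2 + half_width]
    if include_motif:
        left = left + sequence[start]
        right = sequence[start + 1] + right
    return left, right


def window_hydrophobicity(sequence: str, start: int,
                          half_width: int = DEFAULT_HALF_WIDTH,
                          include_motif: bool = False) -> float:
    """Summed Kyte-Doolittle hydropathy of the DE flanking window."""
    _check_de(sequence, start)
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    left, right = _windows(sequence, start, half_width, include_motif)
    return sum(KYTE_DOOLITTLE[r] for r in left + right)


def window_charge(sequence: str, start: int,
                  half_width: int = DEFAULT_HALF_WIDTH,
                  histidine_charge: float = 0.0,
                  include_motif: bool = False) -> float:
    """Summed formal charge of the DE flanking window."""
    _check_de(sequence, start)
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    left, right = _windows(sequence, start, half_width, include_motif)
    return sum(residue_charge(r, histidine_charge) for r in left + right)


def order_class(ss_string: str, start: int) -> str:
    """O if both motif residues are helix/sheet, D if both are coil,
    B (border) otherwise."""
    if ss_string is None:
        raise ValueError("order class undefined: no secondary structure")
    if not (0 <= start <= len(ss_string) - 2):
        raise ValueError(f"position {start} out of range")
    s1, s2 = ss_string[start], ss_string[start + 1]
    for s in (s1, s2):
        if s not in "HEC":
            raise ValueError(f"invalid structure state {s!r}")
    in1, in2 = s1 in ORDERED_STATES, s2 in ORDERED_STATES
    if in1 and in2:
        return "O"
    if not in1 and not in2:
        return "D"
    return "B"


def motif_context(record, start: int, half_width: int = DEFAULT_HALF_WIDTH,
                  histidine_charge: float = 0.0,
                  include_motif: bool = False) -> DEMotifContext:
    """Context record for the DE starting at ``start`` in one protein."""
    seq = record.sequence
    _check_de(seq, start)
    left, right = _windows(seq, start, half_width, include_motif=False)
    oc = order_class(record.ss_string, start) if record.ss_string else None
    return DEMotifContext(
        protein_id=record.id,
        start=start,
        H=window_hydrophobicity(seq, start, half_width, include_motif),
        C=window_charge(seq, start, half_width, histidine_charge,
                        include_motif),
        order_class=oc,
        n_flank_left=len(left),
        n_flank_right=len(right),
    )


def annotate_dataset(dataset: Dataset, half_width: int = DEFAULT_HALF_WIDTH,
                     histidine_charge: float = 0.0,
                     include_motif: bool = False) -> list[DEMotifContext]:
    """One context record per DE occurrence per protein, in dataset order
    then ascending position. Per-record failures are logged, not fatal."""
    from .motif_scan import find_de_motifs

    contexts: list[DEMotifContext] = []
    for rec in dataset:
        try:
            for hit in find_de_motifs(rec.sequence, rec.id):
                contexts.append(motif_context(
                    rec, hit.start, half_width, histidine_charge,
                    include_motif))
        except ValueError as exc:  # pragma: no cover - defensive
            logger.warning("skipping %s: %s", rec.id, exc)
    return contexts


def contexts_by_protein(contexts: list[DEMotifContext]
                        ) -> dict[str, list[DEMotifContext]]:
    grouped: dict[str, list[DEMotifContext]] = {}
    for ctx in contexts:
        grouped.setdefault(ctx.protein_id, []).append(ctx)
    return grouped
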