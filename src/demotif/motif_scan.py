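"""Scanners for DE, phosphorylatable-X diacidic variants and LIR motifs.

All scanners return every match (overlaps allowed) in ascending start
order. Positions are 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

#: residues with phosphorylation propensity: O-phospho S/T/Y, N-phospho H/R/K
PHOSPHO_X = "STYHRK"

#: phospho-context kinds -> 3-residue template; 'X' marks the variable slot
PHOSPHO_KINDS = {
    "XDE": "XDE",
    "DXE": "DXE",
    "DEX": "DEX",
    "XED": "XED",
    "EXD": "EXD",
    "EDX": "EDX",
}

#: aromatic-x-x-aliphatic LIR core
LIR_CORE_REGEX = re.compile(r"(?=([WFY]..[LIV]))")
#: extended 6-residue LIR consensus
LIR_XLIR_REGEX = re.compile(
    r"(?=([ADEFGLPRSK][DEGMSTV][WEFY][DEILQTV][ADEFHIKLMPSTV][ILV]))"
)

MOTIF_KINDS = ("DE", *PHOSPHO_KINDS, "LIR_core", "LIR_xlir")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on one protein."""

    protein_id: str
    start: int
    length: int
    kind: str
    x_residue: str = ""

    @property
    def end(self) -> int:
        """Exclusive end index."""
        return self.start + self.length


def find_de_motifs(sequence: str, protein_id: str = "") -> list[MotifHit]:
    """Every position where 'D' is immediately followed by 'E'."""
    hits = []
    pos = sequence.find("DE")
    while pos != -1:
        hits.append(MotifHit(protein_id, pos, 2, "DE"))
        pos = sequence.find("DE", pos + 1)
    return hits


def find_phospho_context_motifs(sequence: str, protein_id: str = "",
                                kinds: Iterable[str] | None = None
                                ) -> list[MotifHit]:
    """Matches of the six 3-residue diacidic patterns with a
    phosphorylatable insertion X in {S,T,Y,H,R,K}.

    A position may yield several kinds; hits are sorted by (start, kind).
    """
    wanted = PHOSPHO_KINDS if kinds is None else {
        k: PHOSPHO_KINDS[k] for k in kinds}
    hits = []
    for i in range(len(sequence) - 2):
        window = sequence[i:i + 3]
        for kind, template in wanted.items():
            x = ""
            ok = True
            for w, t in zip(window, template):
                if t == "X":
                    if w not in PHOSPHO_X:
                        ok = False
                        break
                    x = w
                elif w != t:
                    ok = False
                    break
            if ok:
                hits.append(MotifHit(protein_id, i, 3, kind, x))
    hits.sort(key=lambda h: (h.start, h.kind))
    return hits


def find_lir_motifs(sequence: str, mode: str = "core",
                    protein_id: str = "") -> list[MotifHit]:
    """LIR motif matches: ``core`` = [WFY]..[LIV] tetrapeptide,
    ``xlir`` = the extended 6-residue consensus."""
    if mode == "core":
        regex, length, kind = LIR_CORE_REGEX, 4, "LIR_core"
    elif mode == "xlir":
        regex, length, kind = LIR_XLIR_REGEX, 6, "LIR_xlir"
    else:
        raise ValueError(f"unknown LIR mode {mode!r}")
    return [MotifHit(protein_id, m.start(), length, kind)
            for m in regex.finditer(sequence)]


def de_lir_contiguous(de_hit: MotifHit, lir_hit: MotifHit,
                      max_gap: int = 0) -> bool:
    """True iff the DE interval overlaps or abuts the LIR interval.

    ``max_gap`` widens adjacency: 0 (default) means the intervals must
    touch or overlap.
    """
    if de_hit.protein_id != lir_hit.protein_id:
        raise ValueError(
            f"hits from different proteins: {de_hit.protein_id!r} vs "
            f"{lir_hit.protein_id!r}")
    gap = max(lir_hit.start - de_hit.end, de_hit.start - lir_hit.end)
    return gap <= max_gap


def lir_contiguity_summary(dataset, mode: str = "core",
                           max_gap: int = 0) -> dict:
    """Per (group, label) counts of proteins with at least one contiguous
    DE-LIR pair, none, or no LIR motif at all."""
    summary: dict[tuple[str, str], dict[str, int]] = {}
    for rec in dataset:
        de_hits = find_de_motifs(rec.sequence, rec.id)
        lir_hits = find_lir_motifs(rec.sequence, mode, rec.id)
        key = (rec.group, rec.label)
        bins = summary.setdefault(
            key, {"contiguous": 0, "discontiguous": 0, "no_lir": 0})
        if not lir_hits:
            bins["no_lir"] += 1
        elif any(de_lir_contiguous(d, l, max_gap)
                 for d in de_hits for l in lir_hits):
            bins["contiguous"] += 1
        else:
            bins["discontiguous"] += 1
    return summary
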