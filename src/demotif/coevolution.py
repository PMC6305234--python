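"""Simplified statistical-coupling pipeline over consensus-binarized MSAs.

Sequences above a gap-fraction threshold are dropped, a per-column
consensus is built, the alignment is binarized (1 = matches consensus),
and pairwise couplings are the absolute co-occurrence deviations
|f_ij - f_i f_j|, optionally weighted by the classic SCA frequency
factor.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .core_model import MSA

DEFAULT_MAX_GAP = 0.2


@dataclass
class BinarizedMSA:
    matrix: np.ndarray          # n_seq x n_col, uint8 in {0, 1}
    consensus: str
    column_freq: np.ndarray     # fraction of 1s per column
    kept_ids: list[str]


@dataclass
class CouplingMatrix:
    C: np.ndarray               # n_col x n_col, symmetric, zero diagonal
    mode: str                   # 'plain' or 'sca_weighted'
    qbar: float = 0.05
    column_freq: np.ndarray | None = None


def filter_by_gap(msa: MSA, max_gap: float = DEFAULT_MAX_GAP) -> MSA:
    """Keep sequences whose gap fraction is <= ``max_gap`` (inclusive)."""
    if not msa.rows:
        raise ValueError("empty MSA")
    width = msa.ncols
    ids, rows = [], []
    for sid, row in zip(msa.ids, msa.rows):
        if row.count("-") / width <= max_gap + 1e-12:
            ids.append(sid)
            rows.append(row)
    if not rows:
        raise ValueError(
            f"no sequence passes gap threshold {max_gap}; raise max_gap")
    return MSA(ids=ids, rows=rows)


def build_consensus(msa: MSA) -> str:
    """Most frequent non-gap residue per column; ties broken
    alphabetically; all-gap columns yield 'X'."""
    if not msa.rows:
        raise ValueError("empty MSA")
    consensus = []
    for j in range(msa.ncols):
        counts = Counter(row[j] for row in msa.rows if row[j] != "-")
        if not counts:
            consensus.append("X")
            continue
        best = min(counts, key=lambda r: (-counts[r], r))
        consensus.append(best)
    return "".join(consensus)


def binarize(msa: MSA, consensus: str | None = None) -> BinarizedMSA:
    """1 where the residue equals the consensus, 0 otherwise (gaps 0)."""
    if consensus is None:
        consensus = build_consensus(msa)
    if len(consensus) != msa.ncols:
        raise ValueError(
            f"consensus length {len(consensus)} != ncols {msa.ncols}")
    cons = np.frombuffer(consensus.encode(), dtype="S1")
    data = np.frombuffer("".join(msa.rows).encode(), dtype="S1")
    data = data.reshape(msa.nseq, msa.ncols)
    matrix = (data == cons[None, :]).astype(np.uint8)
    return BinarizedMSA(
        matrix=matrix,
        consensus=consensus,
        column_freq=matrix.mean(axis=0),
        kept_ids=list(msa.ids),
    )


def coupling_matrix(bmsa: BinarizedMSA, mode: str = "plain",
                    qbar: float = 0.05) -> CouplingMatrix:
    """Pairwise couplings C[i,j] = |f_ij - f_i f_j|.

    ``sca_weighted`` multiplies by phi_i phi_j with
    phi_i = |ln(f_i (1-qbar) / (qbar (1-f_i)))|; phi is 0 for constant
    columns, so their couplings vanish in both modes.
    """
    if mode not in ("plain", "sca_weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    M = bmsa.matrix.astype(float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("at least 2 sequences required")
    f = bmsa.column_freq.astype(float)
    fij = (M.T @ M) / n
    C = np.abs(fij - np.outer(f, f))
    if mode == "sca_weighted":
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.abs(np.log(f * (1 - qbar) / (qbar * (1 - f))))
        phi[~np.isfinite(phi)] = 0.0
        C = C * np.outer(phi, phi)
    np.fill_diagonal(C, 0.0)
    return CouplingMatrix(C=C, mode=mode, qbar=qbar, column_freq=f)


def top_partners(cm: CouplingMatrix, position: int, k: int = 5,
                 z_threshold: float = 2.0) -> list[tuple[int, float, float, bool]]:
    """Top-k coupling partners of one column.

    Returns ``(partner, score, z, flagged)`` tuples sorted by descending
    score; z is computed against the mean/SD of that column's off-
    diagonal scores and ``flagged`` marks z >= ``z_threshold``.
    """
    C = cm.C
    ncol = C.shape[0]
    if not (0 <= position < ncol):
        raise IndexError(f"position {position} out of range 0..{ncol - 1}")
    scores = np.delete(C[position], position)
    partners = np.delete(np.arange(ncol), position)
    mean = float(scores.mean())
    sd = float(scores.std(ddof=0))
    order = np.lexsort((partners, -scores))
    out = []
    for idx in order[:min(k, len(partners))]:
        score = float(scores[idx])
        z = (score - mean) / sd if sd > 0 else 0.0
        out.append((int(partners[idx]), score, float(z),
                    bool(z >= z_threshold)))
    return out


def map_de_to_columns(msa: MSA, sequence_id: str,
                      de_positions: list[int]) -> list[tuple[int, int]]:
    """Map residue indices (0-based, gap-free) of D in DE motifs of one
    aligned sequence to the (D, E) alignment columns."""
    try:
        row = msa.rows[msa.ids.index(sequence_id)]
    except ValueError:
        raise KeyError(f"sequence {sequence_id!r} not in MSA") from None
    residue_to_col = [j for j, ch in enumerate(row) if ch != "-"]
    out = []
    for pos in de_positions:
        if pos + 1 >= len(residue_to_col):
            raise IndexError(
                f"residue position {pos} beyond sequence length "
                f"{len(residue_to_col)}")
        cd, ce = residue_to_col[pos], residue_to_col[pos + 1]
        if row[cd] != "D" or row[ce] != "E":
            raise ValueError(
                f"residues at positions {pos},{pos + 1} are "
                f"{row[cd]}{row[ce]}, expected DE")
        out.append((cd, ce))
    return out
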