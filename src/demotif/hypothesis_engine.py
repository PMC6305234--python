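"""The 16 "most relevant DE" selection hypotheses.

Each case is one cell of the Cartesian product

    {order preference O, D} x {border regrouped to O, D}
        x {charge extreme min, max} x {hydrophobicity extreme min, max}

and selects, per protein, a single representative DE motif whose (H, C,
order) features feed one logistic-regression design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .context_features import DEMotifContext

__all__ = [
    "HypothesisCase", "DesignRow", "ExtremeFeatures", "enumerate_cases",
    "effective_order", "select_representative_de", "build_design_matrix",
    "extreme_features",
]


@dataclass(frozen=True)
class HypothesisCase:
    """One DE-selection rule."""

    case_id: int
    order_pref: str       # 'O' or 'D': which order class hosts the signal
    charge_extreme: str   # 'min' or 'max'
    hydro_extreme: str    # 'min' or 'max'
    border_regroup: str   # 'O' or 'D': what class B collapses into


@dataclass
class DesignRow:
    """One protein's features under one hypothesis case."""

    protein_id: str
    label: int            # secretory = 1
    H: float
    C: float
    order_indicator: int  # 1 iff the selected DE is O after regrouping
    selected_start: int
    fallback: bool = False


@dataclass
class ExtremeFeatures:
    """Per-protein extrema of C and H over all its DE motifs."""

    protein_id: str
    min_charge: float
    max_charge: float
    min_hydro: float
    max_hydro: float


def enumerate_cases() -> list[HypothesisCase]:
    """The 16 cases in canonical order: order preference outermost, then
    border regrouping, then charge extreme, then hydrophobicity extreme."""
    cases = []
    case_id = 1
    for order_pref in ("O", "D"):
        for border_regroup in ("O", "D"):
            for charge_extreme in ("min", "max"):
                for hydro_extreme in ("min", "max"):
                    cases.append(HypothesisCase(
                        case_id, order_pref, charge_extreme,
                        hydro_extreme, border_regroup))
                    case_id += 1
    return cases


def effective_order(ctx: DEMotifContext, case: HypothesisCase) -> str:
    """Order class after collapsing B per the case's regrouping."""
    if ctx.order_class is None:
        raise ValueError(
            f"{ctx.protein_id}: order class undefined (no structure)")
    return case.border_regroup if ctx.order_class == "B" else ctx.order_class


def select_representative_de(contexts: Sequence[DEMotifContext],
                             case: HypothesisCase,
                             fallback_to_all: bool = True
                             ) -> tuple[DEMotifContext, bool]:
    """Pick one DE per the case rule.

    Candidates are the motifs whose regrouped order class equals the
    case's preference; when none exist, selection falls back to all
    motifs (flagged) unless ``fallback_to_all`` is False, in which case
    a ``LookupError`` is raised.

    Selection is lexicographic: charge extreme first, hydrophobicity
    extreme on ties, smallest start on remaining ties.
    Returns ``(selected_context, used_fallback)``.
    """
    if not contexts:
        raise ValueError("empty context list")
    preferred = [c for c in contexts
                 if effective_order(c, case) == case.order_pref]
    fallback = not preferred
    if fallback:
        if not fallback_to_all:
            raise LookupError(
                f"no motif of class {case.order_pref} for "
                f"{contexts[0].protein_id}")
        preferred = list(contexts)

    c_sign = 1.0 if case.charge_extreme == "min" else -1.0
    h_sign = 1.0 if case.hydro_extreme == "min" else -1.0
    best = min(preferred, key=lambda c: (c_sign * c.C, h_sign * c.H, c.start))
    return best, fallback


_LABEL_CODE = {"secretory": 1, "non_secretory": 0}


def build_design_matrix(dataset, contexts: Sequence[DEMotifContext],
                        case: HypothesisCase,
                        fallback_to_all: bool = True) -> list[DesignRow]:
    """One DesignRow per labelled protein under one case.

    Proteins with an ``unknown`` label are skipped (they cannot enter a
    binary regression); proteins without DE contexts cannot appear here
    because they are excluded at dataset load.
    """
    from .context_features import contexts_by_protein

    grouped = contexts_by_protein(list(contexts))
    rows: list[DesignRow] = []
    for rec in dataset:
        if rec.label not in _LABEL_CODE:
            continue
        ctxs = grouped.get(rec.id)
        if not ctxs:
            raise ValueError(f"protein {rec.id} has no DE contexts")
        sel, fb = select_representative_de(ctxs, case, fallback_to_all)
        rows.append(DesignRow(
            protein_id=rec.id,
            label=_LABEL_CODE[rec.label],
            H=sel.H,
            C=sel.C,
            order_indicator=int(effective_order(sel, case) == "O"),
            selected_start=sel.start,
            fallback=fb,
        ))
    return rows


def extreme_features(contexts: Sequence[DEMotifContext]) -> ExtremeFeatures:
    """Min/max charge and hydrophobicity over one protein's DE motifs."""
    if not contexts:
        raise ValueError("empty context list")
    pid = contexts[0].protein_id
    if any(c.protein_id != pid for c in contexts):
        raise ValueError("contexts from multiple proteins")
    charges = [c.C for c in contexts]
    hydros = [c.H for c in contexts]
    return ExtremeFeatures(
        protein_id=pid,
        min_charge=min(charges),
        max_charge=max(charges),
        min_hydro=min(hydros),
        max_hydro=max(hydros),
    )
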