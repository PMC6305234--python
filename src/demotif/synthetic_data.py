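"""Synthetic labelled protein datasets and MSAs with planted ground truth.

Proteins get random sequences with a controlled number of planted DE
dipeptides inside a run-structured secondary-structure string; the
secretion label is drawn from a logistic model on the (H, C, order)
features of the one "signal" DE selected by a hypothesis case. MSAs get
a random consensus, per-column consensus-match probabilities, planted
covarying column pairs and i.i.d. gap noise.

All randomness flows through one ``numpy`` generator per call; the seed
fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context_features import DEFAULT_HALF_WIDTH, annotate_dataset
from .core_model import AMINO_ACIDS, MSA, Dataset, ProteinRecord
from .hypothesis_engine import (HypothesisCase, effective_order,
                                enumerate_cases, select_representative_de)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ProteinGenConfig:
    n_proteins: int = 100
    length_range: tuple[int, int] = (40, 80)
    de_count_range: tuple[int, int] = (1, 4)
    beta0: float = 0.0
    beta_H: float = 0.0
    beta_C: float = 0.0
    beta_order: float = 0.0
    #: the hypothesis case whose selection rule designates the signal DE
    signal_case: HypothesisCase = field(
        default_factory=lambda: enumerate_cases()[0])
    background_freqs: dict[str, float] | None = None
    #: mean geometric run length per secondary-structure state
    ss_run_means: dict[str, float] = field(
        default_factory=lambda: {"H": 6.0, "E": 4.0, "C": 5.0})
    half_width: int = DEFAULT_HALF_WIDTH
    group: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.length_range
        kmax = self.de_count_range[1]
        if self.de_count_range[0] < 1:
            raise ValueError("each protein needs at least one DE")
        # planted motifs need non-overlapping starts two residues apart
        if lo < 2 * kmax + 2:
            raise ValueError(
                f"length_range min {lo} too short for up to {kmax} DE motifs")
        if any(m <= 0 for m in self.ss_run_means.values()):
            raise ValueError("ss run means must be positive")


def _gen_ss(rng: np.random.Generator, length: int,
            run_means: dict[str, float]) -> str:
    states = list(run_means)
    parts: list[str] = []
    total = 0
    prev = None
    while total < length:
        choices = [s for s in states if s != prev] if len(states) > 1 else states
        state = choices[rng.integers(len(choices))]
        run = 1 + rng.geometric(1.0 / run_means[state])
        parts.append(state * run)
        total += run
        prev = state
    return "".join(parts)[:length]


def gen_protein_dataset(config: ProteinGenConfig) -> Dataset:
    """Generate a labelled dataset; the planted truth (betas and the
    per-protein signal DE) is stored on ``dataset.truth``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    if config.background_freqs is None:
        probs = np.full(len(alphabet), 1.0 / len(alphabet))
    else:
        probs = np.array([config.background_freqs.get(a, 0.0)
                          for a in AMINO_ACIDS])
        probs = probs / probs.sum()

    records: list[ProteinRecord] = []
    signal_table: list[dict] = []
    case = config.signal_case
    lo, hi = config.length_range
    klo, khi = config.de_count_range
    for idx in range(config.n_proteins):
        pid = f"sim{idx:05d}"
        length = int(rng.integers(lo, hi + 1))
        k = int(rng.integers(klo, khi + 1))
        seq = rng.choice(alphabet, size=length, p=probs)
        # non-overlapping DE starts: draw from a thinned grid then jitter
        starts = rng.choice(length // 2, size=k, replace=False) * 2
        starts = np.minimum(starts, length - 2)
        for s in np.sort(starts):
            seq[s] = b"D"
            seq[s + 1] = b"E"
        sequence = seq.tobytes().decode()
        ss = _gen_ss(rng, length, config.ss_run_means)
        rec = ProteinRecord(id=pid, sequence=sequence, ss_string=ss,
                            group=config.group)
        tmp = Dataset(records=[rec])
        contexts = annotate_dataset(tmp, half_width=config.half_width)
        signal, fallback = select_representative_de(contexts, case)
        o_ind = int(effective_order(signal, case) == "O")
        eta = (config.beta0 + config.beta_H * signal.H
               + config.beta_C * signal.C + config.beta_order * o_ind)
        secretory = bool(rng.random() < _sigmoid(eta))
        rec.label = "secretory" if secretory else "non_secretory"
        records.append(rec)
        signal_table.append({
            "protein_id": pid, "signal_start": signal.start,
            "signal_H": signal.H, "signal_C": signal.C,
            "signal_order": o_ind, "fallback": fallback,
        })

    truth = {
        "kind": "protein_dataset",
        "beta0": config.beta0, "beta_H": config.beta_H,
        "beta_C": config.beta_C, "beta_order": config.beta_order,
        "signal_case_id": case.case_id,
        "seed": config.seed,
        "signals": signal_table,
    }
    return Dataset(records=records, provenance=f"synthetic seed={config.seed}",
                   truth=truth)


@dataclass
class MSAGenConfig:
    n_seq: int = 200
    n_col: int = 50
    match_prob: float = 0.5
    #: planted covarying pairs as (col_i, col_j, rho) with disjoint columns
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    gap_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.match_prob < 1.0:
            raise ValueError("match_prob must be in (0, 1)")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")
        used: set[int] = set()
        for i, j, rho in self.planted_pairs:
            if i == j or not (0 <= i < self.n_col and 0 <= j < self.n_col):
                raise ValueError(f"invalid planted pair ({i}, {j})")
            if {i, j} & used:
                raise ValueError("planted pairs must be disjoint")
            used |= {i, j}
            if not 0.0 <= rho <= 1.0:
                raise ValueError(
                    f"correlation {rho} outside attainable range [0, 1] "
                    "for equal-marginal columns")


def gen_msa(config: MSAGenConfig) -> MSA:
    """Generate an MSA with planted covarying column pairs.

    Each column matches a random consensus residue with ``match_prob``;
    a planted pair (i, j, rho) copies column i's match indicator to
    column j with probability rho (independent redraw otherwise), giving
    match-indicator correlation rho. Gaps are injected i.i.d. afterwards.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m, p = config.n_seq, config.n_col, config.match_prob
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    cons_idx = rng.integers(len(alphabet), size=m)

    match = rng.random((n, m)) < p
    for i, j, rho in config.planted_pairs:
        copy = rng.random(n) < rho
        match[:, j] = np.where(copy, match[:, i], rng.random(n) < p)

    # non-consensus residues drawn uniformly from the other 19
    alt = rng.integers(len(alphabet) - 1, size=(n, m))
    alt = alt + (alt >= cons_idx[None, :])
    res_idx = np.where(match, cons_idx[None, :], alt)
    chars = alphabet[res_idx]
    if config.gap_rate > 0:
        chars = np.where(rng.random((n, m)) < config.gap_rate, b"-", chars)

    rows = [chars[i].tobytes().decode() for i in range(n)]
    ids = [f"seq{i:05d}" for i in range(n)]
    truth = {
        "kind": "msa",
        "consensus": alphabet[cons_idx].tobytes().decode(),
        "planted_pairs": [tuple(pair) for pair in config.planted_pairs],
        "match_prob": p,
        "gap_rate": config.gap_rate,
        "seed": config.seed,
    }
    return MSA(ids=ids, rows=rows, truth=truth)


def truth_report(obj, path=None) -> pd.DataFrame:
    """Tabulate the planted ground truth of a generated dataset or MSA."""
    truth = getattr(obj, "truth", None)
    if truth is None:
        raise ValueError("object has no planted truth record")
    if truth["kind"] == "protein_dataset":
        frame = pd.DataFrame(truth["signals"])
        for key in ("beta0", "beta_H", "beta_C", "beta_order",
                    "signal_case_id", "seed"):
            frame[key] = truth[key]
    else:
        frame = pd.DataFrame(
            [{"col_i": i, "col_j": j, "rho": r}
             for i, j, r in truth["planted_pairs"]])
        frame["match_prob"] = truth["match_prob"]
        frame["gap_rate"] = truth["gap_rate"]
        frame["seed"] = truth["seed"]
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
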