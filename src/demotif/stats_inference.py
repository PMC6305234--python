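"""Binary logistic regression (IRLS, implemented here), Wald and
likelihood-ratio inference, and 2x2 contingency analysis with odds
ratios and Fisher's exact test.

The regression is unpenalized maximum likelihood by default so that the
reported p-values are the textbook ones; a small ridge penalty can be
switched on to rescue separated fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

MAX_ITER = 100
TOL = 1e-8


@dataclass
class RegressionResult:
    """Fit summary of one binary logistic regression."""

    case_id: int | None
    n: int
    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    odds_ratios: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    loglik: float
    loglik_null: float
    lrt_p: float
    converged: bool
    separation_detected: bool
    n_iter: int = 0

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def ci(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return (float(np.log(self.or_ci_low[i])),
                float(np.log(self.or_ci_high[i])))


@dataclass
class ContingencyResult:
    """2x2 table analysis: rows motif present/absent, cols secretory/non."""

    table: tuple[int, int, int, int]  # (a, b, c, d)
    odds_ratio: float
    or_ci_95: tuple[float, float]
    fisher_p_two_sided: float
    correction_applied: bool = False


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log-sigmoid written stably: -log(1 + exp(-eta)) etc.
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_xy(X: np.ndarray, y: np.ndarray,
                    names: Sequence[str] | None = None,
                    case_id: int | None = None,
                    ridge: float = 0.0,
                    max_iter: int = MAX_ITER,
                    tol: float = TOL) -> RegressionResult:
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares. ``X`` must include the intercept column.

    Convergence: max |delta coef| < ``tol`` (default 1e-8) or ``max_iter``
    iterations. Complete/quasi-separation is flagged, not silently
    diverged on.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("labels must be 0/1")
    if uniq.size < 2:
        raise ValueError("both label classes required for a fit")
    if n <= k:
        raise ValueError(f"n={n} must exceed number of parameters k={k}")
    if names is None:
        names = [f"x{i}" for i in range(k)]

    beta = np.zeros(k)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu)
        # guard against singular weights while leaving the MLE unchanged
        info = X.T @ (X * np.maximum(w, 1e-12)[:, None])
        if ridge > 0:
            info = info + ridge * np.eye(k)
        score = X.T @ (y - mu)
        if ridge > 0:
            score = score - ridge * beta
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    # separation heuristics: fitted probs pinned to the labels, or the
    # optimizer still marching outward with huge coefficients
    pinned = bool(np.all(np.abs(y - mu) < 1e-4))
    diverging = (not converged) and bool(np.max(np.abs(beta)) > 20)
    separation = (ridge == 0.0) and (pinned or diverging)
    if separation:
        warnings.warn("possible complete/quasi-separation detected",
                      RuntimeWarning, stacklevel=2)

    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = X.T @ (X * w[:, None])
    if ridge > 0:
        info = info + ridge * np.eye(k)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    wald_p = 2.0 * stats.norm.sf(np.abs(z))

    ll = _loglik(y, eta)
    pbar = float(np.mean(y))
    ll0 = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    df = k - 1
    lrt = lrt_pvalue(ll, ll0, df) if df >= 1 else 1.0

    half = 1.959963984540054 * se
    return RegressionResult(
        case_id=case_id, n=n, names=list(names),
        coefficients=beta, standard_errors=se, wald_z=z, wald_p=wald_p,
        odds_ratios=np.exp(beta),
        or_ci_low=np.exp(beta - half), or_ci_high=np.exp(beta + half),
        loglik=ll, loglik_null=ll0, lrt_p=lrt,
        converged=converged, separation_detected=separation,
        n_iter=n_iter)


DESIGN_NAMES = ["intercept", "H", "C", "order"]


def fit_logistic(design_rows: Sequence, case_id: int | None = None,
                 ridge: float = 0.0) -> RegressionResult:
    """Fit label ~ intercept + H + C + order_indicator on DesignRows."""
    if not design_rows:
        raise ValueError("no design rows")
    X = np.array([[1.0, r.H, r.C, float(r.order_indicator)]
                  for r in design_rows])
    y = np.array([r.label for r in design_rows], dtype=float)
    return fit_logistic_xy(X, y, names=DESIGN_NAMES, case_id=case_id,
                           ridge=ridge)


def lrt_pvalue(loglik: float, loglik_null: float, df: int) -> float:
    """Likelihood-ratio p-value: chi-square survival at the deviance."""
    if df < 1:
        raise ValueError("df must be >= 1")
    dev = 2.0 * (loglik - loglik_null)
    if dev < -1e-8:
        raise ValueError(f"negative deviance {dev}")
    return float(stats.chi2.sf(max(dev, 0.0), df))


def _checked_table(table: Sequence[int]) -> tuple[int, int, int, int]:
    a, b, c, d = (int(v) for v in table)
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return a, b, c, d


def odds_ratio(table: Sequence[int]) -> ContingencyResult:
    """OR = ad/bc with Haldane-Anscombe +0.5 correction on zero cells;
    95% CI from the log-OR normal approximation. The Fisher p is filled
    in as well so the result is complete."""
    a, b, c, d = _checked_table(table)
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = ((v + 0.5 for v in (a, b, c, d)) if corrected
                      else (a, b, c, d))
    orr = (aa * dd) / (bb * cc)
    se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
    log_or = float(np.log(orr))
    ci = (float(np.exp(log_or - 1.96 * se)),
          float(np.exp(log_or + 1.96 * se)))
    return ContingencyResult(
        table=(a, b, c, d), odds_ratio=float(orr), or_ci_95=ci,
        fisher_p_two_sided=fisher_exact_two_sided(table),
        correction_applied=corrected)


def fisher_exact_two_sided(table: Sequence[int],
                           rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher's exact p: sum of hypergeometric probabilities of
    all same-margin tables no more probable than the observed one."""
    a, b, c, d = _checked_table(table)
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = float(np.sum(pmf[pmf <= p_obs * (1.0 + rel_tol)]))
    return min(p, 1.0)


def phospho_contingency(dataset, kinds: Sequence[str] | None = None
                        ) -> ContingencyResult:
    """2x2 table (has >=1 phospho-context motif) x (secretory), with OR
    and Fisher p. Presence is the protein-level OR over all hits."""
    from .motif_scan import find_phospho_context_motifs

    a = b = c = d = 0
    for rec in dataset:
        if rec.label not in ("secretory", "non_secretory"):
            continue
        present = bool(find_phospho_context_motifs(rec.sequence, rec.id,
                                                   kinds))
        secretory = rec.label == "secretory"
        if present and secretory:
            a += 1
        elif present:
            b += 1
        elif secretory:
            c += 1
        else:
            d += 1
    if a + b + c + d == 0:
        raise ValueError("empty dataset")
    return odds_ratio((a, b, c, d))


def phospho_contingency_by_group(dataset,
                                 kinds: Sequence[str] | None = None
                                 ) -> dict[str, ContingencyResult]:
    """Per-group phospho contingency tables (plus overall under 'all')."""
    out = {"all": phospho_contingency(dataset, kinds)}
    for group in dataset.groups():
        sub = dataset.subset(group=group)
        try:
            out[group] = phospho_contingency(sub, kinds)
        except ValueError:
            continue
    return out
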