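"""Conditional logistic regression for 1:m matched sets.

With exactly one case per set the exact conditional likelihood reduces to a
per-set softmax:

    l(beta) = sum_s [ x_case(s) . beta  -  log sum_{j in s} exp(x_j . beta) ]

which is maximised by Newton-Raphson with step-halving, starting from
beta = 0.  Standard errors come from the inverse observed information;
exp(beta -/+ 1.96 se) gives the 95% Wald interval for the incidence rate
ratio.  Under incidence-density sampling the conditional odds ratio
estimates the rate ratio of the underlying proportional-hazards model, so
exp(beta) is reported as an IRR throughout.

Sets whose rows all carry identical covariates contribute a constant and
are dropped as non-informative; matching factors are conditioned out and
must never be entered as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class EstimationError(RuntimeError):
    """The conditional likelihood cannot be maximised (no informative sets)."""


@dataclass
class MatchedDesign:
    """Row-per-participant design: one case and >=1 controls per set."""

    X: np.ndarray  # (n_rows, n_cov)
    y: np.ndarray  # 1 for the case row
    set_ids: np.ndarray
    names: list[str]
    n_dropped_constant: int = 0

    def __post_init__(self) -> None:
        order = np.argsort(self.set_ids, kind="stable")
        self.X = np.asarray(self.X, dtype=float)[order]
        self.y = np.asarray(self.y, dtype=int)[order]
        self.set_ids = np.asarray(self.set_ids)[order]
        uniq, starts, counts = np.unique(
            self.set_ids, return_index=True, return_counts=True
        )
        self.starts = starts
        self.counts = counts
        cases_per_set = np.add.reduceat(self.y, starts)
        if not np.all(cases_per_set == 1):
            raise ValueError("every matched set must contain exactly one case")
        # informative sets: some covariate varies within the set
        informative = np.zeros(len(uniq), dtype=bool)
        for k, (s, c) in enumerate(zip(starts, counts)):
            informative[k] = bool(np.any(self.X[s : s + c] != self.X[s]))
        keep_rows = np.repeat(informative, counts)
        self.n_sets = len(uniq)
        self.n_informative = int(informative.sum())
        self._Xi = self.X[keep_rows]
        self._yi = self.y[keep_rows]
        ci = counts[informative]
        self._starts_i = np.concatenate(([0], np.cumsum(ci)[:-1]))
        self._counts_i = ci

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


def design_from_long(
    df: pd.DataFrame,
    covariates: list[str],
    set_col: str = "set_id",
    role_col: str = "role",
) -> MatchedDesign:
    """Build a design from a long-form table, dropping all-constant columns.

    Columns constant across every row carry no information in a conditional
    likelihood (and make the information singular), so they are removed and
    counted in ``n_dropped_constant``.
    """
    X = df[covariates].to_numpy(dtype=float)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = X.shape[1] - len(keep)
    return MatchedDesign(
        X=X[:, keep],
        y=(df[role_col] == "case").astype(int).to_numpy(),
        set_ids=df[set_col].to_numpy(),
        names=[covariates[j] for j in keep],
        n_dropped_constant=dropped,
    )


def _loglik_score_info(beta, X, y, starts, counts):
    eta = X @ beta
    seg = np.repeat(np.arange(len(starts)), counts)
    m = np.maximum.reduceat(eta, starts)
    ex = np.exp(eta - m[seg])
    denom = np.add.reduceat(ex, starts)
    loglik = float(eta[y == 1].sum() - (np.log(denom) + m).sum())
    p = ex / denom[seg]
    xbar = np.zeros((len(starts), X.shape[1]))
    np.add.at(xbar, seg, p[:, None] * X)
    score = X[y == 1].sum(axis=0) - xbar.sum(axis=0)
    info = (X.T * p) @ X - xbar.T @ xbar
    return loglik, score, info


def conditional_loglik(beta, design: MatchedDesign) -> float:
    """Exact conditional log-likelihood over all sets (log-sum-exp stabilised)."""
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    ll, _, _ = _loglik_score_info(beta, design.X, design.y, design.starts, design.counts)
    return ll


@dataclass
class FitResult:
    beta: np.ndarray
    se: np.ndarray
    irr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    n_sets: int
    n_informative_sets: int
    converged: bool
    n_iter: int
    names: list[str] = field(default_factory=list)
    status: str = "ok"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "beta": self.beta,
                "se": self.se,
                "irr": self.irr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


Z_95 = 1.96  # normal-theory Wald multiplier for 95% intervals


def fit(
    design: MatchedDesign,
    tol: float = 1e-8,
    max_iter: int = 50,
    separation_threshold: float = 15.0,
) -> FitResult:
    """Maximise the conditional likelihood by Newton-Raphson with step-halving.

    Convergence is declared when the score sup-norm falls below ``tol``.
    Monotone likelihoods (separation) are detected when any coefficient
    exceeds ``separation_threshold`` in absolute value; the result is then
    flagged not-converged with status ``"separation"``.
    """
    if design.n_informative == 0:
        raise EstimationError("no informative matched sets: likelihood is flat")
    X, y = design._Xi, design._yi
    starts, counts = design._starts_i, design._counts_i
    p = design.n_covariates
    beta = np.zeros(p)
    ll, score, info = _loglik_score_info(beta, X, y, starts, counts)
    converged = False
    status = "ok"
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving on non-increase of the likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, score_new, info_new = _loglik_score_info(cand, X, y, starts, counts)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.max(np.abs(beta)) > separation_threshold:
            status = "separation"
            break
    else:
        status = "max_iter"
    if status == "ok" and not converged and np.max(np.abs(score)) < tol:
        converged = True

    with np.errstate(over="ignore"):
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
        irr = np.exp(beta)
        ci_low = np.exp(beta - Z_95 * se)
        ci_high = np.exp(beta + Z_95 * se)
    return FitResult(
        beta=beta,
        se=se,
        irr=irr,
        ci_low=ci_low,
        ci_high=ci_high,
        loglik=ll,
        n_sets=design.n_sets,
        n_informative_sets=design.n_informative,
        converged=converged and status == "ok",
        n_iter=it,
        names=list(design.names),
        status=status,
    )


def format_irr(irr: float, lo: float, hi: float) -> str:
    """Render ``"2.77 (2.48–3.10)"`` with two decimal places."""
    return f"{irr:.2f} ({lo:.2f}–{hi:.2f})"


def irr_table(
    fits: list[tuple[FitResult | None, FitResult | None]],
    labels: list[str],
) -> pd.DataFrame:
    """Tabulate (univariable, multivariable) fit pairs, one row per contrast term.

    Each entry of ``fits`` pairs the univariable and adjusted fit for one
    exposure contrast; ``labels`` names the contrasts.  Exposure terms are
    those whose names start with the contrast label.
    """
    if len(fits) != len(labels):
        raise ValueError(
            f"{len(fits)} fit pairs but {len(labels)} labels"
        )
    rows = []
    for (uni, multi), label in zip(fits, labels):
        terms = [t for t in (multi or uni).names if t.startswith(label)] or [label]
        for term in terms:
            row = {"contrast": label, "term": term}
            for which, res in (("univariable", uni), ("multivariable", multi)):
                if res is None or term not in res.names:
                    row[which] = ""
                else:
                    j = res.names.index(term)
                    row[which] = format_irr(res.irr[j], res.ci_low[j], res.ci_high[j])
            row["n_sets"] = (multi or uni).n_sets if (multi or uni) else 0
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["contrast", "term", "univariable", "multivariable", "n_sets"]
    )


def render_irr_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of :func:`irr_table` output."""
    if not len(table):
        return "contrast  term  univariable  multivariable  n_sets\n"
    widths = {
        col: max(len(col), int(table[col].astype(str).str.len().max()))
        for col in table.columns
    }
    lines = ["  ".join(col.ljust(widths[col]) for col in table.columns)]
    for _, row in table.iterrows():
        lines.append("  ".join(str(row[col]).ljust(widths[col]) for col in table.columns))
    return "\n".join(lines) + "\n"
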