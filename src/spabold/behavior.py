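"""Behavioral analyses: accuracy modeling, signal detection, span scoring.

The accuracy model is a mixed-effects logistic regression on trialwise
correctness with fixed effects for hearing acuity (PTA), age, working
memory, syntactic complexity, adjectival phrase position, and the
PTA x syntax interaction, plus a random per-subject intercept.  The gender
judgment is a two-alternative forced choice, so sensitivity and bias are
computed with signal detection theory treating "male" as the signal class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, ndtri
from numpy.polynomial.hermite_e import hermegauss

from .errors import InputError

FIXED_EFFECTS = ("intercept", "pta", "age", "wm", "syntax_or",
                 "position_early", "pta_x_syntax")


@dataclass
class AccuracyModelResult:
    """Fixed-effect table plus the random-intercept scale of the fitted model."""

    coefficients: pd.DataFrame      # index: FIXED_EFFECTS; estimate/se/z/p
    random_intercept_sd: float
    converged: bool
    n_subjects: int
    n_trials: int
    method: str

    def __getitem__(self, term: str) -> pd.Series:
        return self.coefficients.loc[term]

    def ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        row = self.coefficients.loc[term]
        half = float(ndtri(0.5 + level / 2.0)) * row["se"]
        return float(row["estimate"] - half), float(row["estimate"] + half)


class _AgqLogistic:
    """Random-intercept logistic likelihood via adaptive Gauss-Hermite quadrature.

    For each subject the marginal likelihood integrates the Bernoulli
    likelihood over the Gaussian random intercept.  The integral is
    re-centered at the per-subject posterior mode (found by a damped Newton
    iteration, warm-started across objective evaluations) and scaled by the
    posterior curvature before applying a fixed-order Hermite rule, the
    standard adaptive scheme that stays accurate even when a subject's mode
    sits far from zero.  Parameters are (beta, log tau).
    """

    def __init__(self, y, X, codes, n_sub, n_nodes: int = 15):
        order = np.argsort(codes, kind="stable")
        self.y = np.asarray(y, float)[order]
        self.X = np.asarray(X, float)[order]
        codes = np.asarray(codes)[order]
        self.n_sub = n_sub
        self.codes = codes
        counts = np.bincount(codes, minlength=n_sub)
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        # probabilists' Hermite rule: integrates f(x) exp(-x^2/2)
        x, w = hermegauss(n_nodes)
        self.nodes = x
        self.logw = np.log(w)
        self.uhat = np.zeros(n_sub)

    def _group_sum(self, rows):
        return np.add.reduceat(rows, self.starts, axis=-1)

    def _mode(self, eta0, tau2):
        u = self.uhat
        for _ in range(50):
            p = expit(eta0 + u[self.codes])
            g = self._group_sum(self.y - p) - u / tau2
            h = self._group_sum(p * (1.0 - p)) + 1.0 / tau2
            step = g / h
            step = np.clip(step, -4.0, 4.0)
            u = u + step
            if np.max(np.abs(step)) < 1e-9:
                break
        self.uhat = u
        return u, 1.0 / np.sqrt(h)

    def negloglik(self, theta):
        beta, log_tau = theta[:-1], theta[-1]
        tau = np.exp(log_tau)
        eta0 = self.X @ beta
        uhat, sig = self._mode(eta0, tau * tau)
        # adaptive nodes u_k = uhat + sig * x_k per subject
        U = uhat[None, :] + sig[None, :] * self.nodes[:, None]
        ETA = eta0[None, :] + U[:, self.codes]
        row_ll = self.y[None, :] * ETA - np.logaddexp(0.0, ETA)
        S = self._group_sum(row_ll)                       # (K, n_sub)
        log_prior = -0.5 * (U / tau) ** 2 - np.log(tau) - 0.5 * np.log(2.0 * np.pi)
        # importance-corrected Hermite weights for the adaptive shift
        log_terms = (self.logw[:, None] + 0.5 * self.nodes[:, None] ** 2
                     + np.log(sig[None, :]) + S + log_prior)
        m = log_terms.max(axis=0)
        ll = float(np.sum(m + np.log(np.sum(np.exp(log_terms - m), axis=0))))
        return -ll

    def fit(self, beta0, log_tau0):
        theta0 = np.concatenate([beta0, [log_tau0]])
        res = optimize.minimize(self.negloglik, theta0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7})
        hess = _numerical_hessian(self.negloglik, res.x)
        cov = np.linalg.pinv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return res, se


def _numerical_hessian(fun, x0, rel_step: float = 1e-4):
    p = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    H = np.empty((p, p))
    f0 = fun(x0)
    for i in range(p):
        for j in range(i, p):
            if i == j:
                xp, xm = x0.copy(), x0.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (fun(xp) - 2.0 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]; xpm[j] -= h[j]
                xmp[i] -= h[i]; xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4.0 * h[i] * h[j])
    return H


def fit_accuracy_model(records: pd.DataFrame, cohort: pd.DataFrame,
                       n_quadrature: int = 9) -> AccuracyModelResult:
    """Fit the mixed-effects logistic accuracy model on sentence trials.

    Maximum likelihood with the random subject intercept integrated out by
    adaptive Gauss-Hermite quadrature (``n_quadrature`` nodes); Wald Z and
    two-sided normal p-values come from the inverse observed information.
    PTA, age, and working memory are centered at their cohort means.
    Non-convergence of the optimizer is flagged via ``converged`` rather
    than raising, so callers can inspect the diagnostics.
    """
    sent = records[records["stimulus_class"] == "sentence"]
    if sent.empty:
        raise InputError("no sentence trials in the records")
    df = sent.merge(cohort[["subject_id", "pta_db_hl", "age_years", "wm_span"]],
                    on="subject_id", validate="many_to_one")
    if df["subject_id"].nunique() < 2:
        raise InputError("the random subject intercept needs at least 2 subjects")
    if df["is_correct"].isna().any():
        raise InputError("sentence trials with missing correctness")

    pta_c = (df["pta_db_hl"] - df["pta_db_hl"].mean()).to_numpy()
    age_c = (df["age_years"] - df["age_years"].mean()).to_numpy()
    wm_c = (df["wm_span"] - df["wm_span"].mean()).to_numpy()
    is_or = (df["syntax"] == "object_relative").to_numpy(float)
    is_early = (df["phrase_position"] == "early").to_numpy(float)
    X = np.column_stack([np.ones(len(df)), pta_c, age_c, wm_c, is_or,
                         is_early, pta_c * is_or])
    y = df["is_correct"].to_numpy(bool).astype(float)

    subjects = pd.Categorical(df["subject_id"])
    model = _AgqLogistic(y, X, subjects.codes, len(subjects.categories),
                         n_nodes=n_quadrature)
    # moment-style starting values: pooled logit intercept, zero slopes
    p_bar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    beta0 = np.zeros(X.shape[1])
    beta0[0] = np.log(p_bar / (1.0 - p_bar))
    res, se = model.fit(beta0, log_tau0=np.log(0.3))

    est = res.x[:-1]
    se_fe = se[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se_fe
    p = 2.0 * stats.norm.sf(np.abs(z))
    coefs = pd.DataFrame({"estimate": est, "se": se_fe, "z": z, "p": p},
                         index=list(FIXED_EFFECTS))
    return AccuracyModelResult(
        coefficients=coefs,
        random_intercept_sd=float(np.exp(res.x[-1])),
        converged=bool(res.success),
        n_subjects=len(subjects.categories),
        n_trials=len(df),
        method=f"ml-agq{n_quadrature}",
    )


# ---------------------------------------------------------------------------
# signal detection
# ---------------------------------------------------------------------------

@dataclass
class SdtResult:
    hit_rate: float
    false_alarm_rate: float
    d_prime: float
    criterion: float
    correction: str
    n_signal: int
    n_noise: int


def sdt_2afc(records: pd.DataFrame, signal: str = "male",
             forced_choice_scaling: bool = False) -> SdtResult:
    """Sensitivity and bias of the gender judgment, signal class ``signal``.

    Hits are ``signal`` responses on trials whose correct answer is
    ``signal``; false alarms are ``signal`` responses on the other trials.
    Rates of exactly 0 or 1 are corrected by the 1/(2N) rule before the
    inverse-normal transform.  ``d' = z(H) - z(FA)`` and
    ``c = -(z(H) + z(FA)) / 2``; with ``forced_choice_scaling`` d' is
    divided by sqrt(2) (the 2AFC convention; the default treats the task as
    a classification, matching the analysis this package mirrors).
    """
    other = "female" if signal == "male" else "male"
    sent = records[(records["stimulus_class"] == "sentence")
                   & records["response"].isin([signal, other])]
    sig = sent[sent["correct_answer"] == signal]
    noi = sent[sent["correct_answer"] == other]
    if sig.empty or noi.empty:
        raise InputError("need trials of both stimulus classes to compute d'")

    def rate(frame):
        n = len(frame)
        r = float((frame["response"] == signal).mean())
        corrected = False
        if r == 0.0:
            r, corrected = 1.0 / (2 * n), True
        elif r == 1.0:
            r, corrected = 1.0 - 1.0 / (2 * n), True
        return r, corrected

    h, ch = rate(sig)
    fa, cf = rate(noi)
    zh, zfa = float(ndtri(h)), float(ndtri(fa))
    d = zh - zfa
    if forced_choice_scaling:
        d /= np.sqrt(2.0)
    return SdtResult(
        hit_rate=h, false_alarm_rate=fa, d_prime=float(d),
        criterion=float(-(zh + zfa) / 2.0),
        correction="1/(2N)" if (ch or cf) else "none",
        n_signal=len(sig), n_noise=len(noi),
    )


def sdt_by_subject(records: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-subject d' and criterion, one row per subject."""
    rows = []
    for sid, grp in records.groupby("subject_id", sort=True):
        res = sdt_2afc(grp, **kwargs)
        rows.append({"subject_id": sid, "d_prime": res.d_prime,
                     "criterion": res.criterion,
                     "hit_rate": res.hit_rate, "false_alarm_rate": res.false_alarm_rate})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# working-memory span scoring
# ---------------------------------------------------------------------------

@dataclass
class SpanScore:
    per_set: dict[int, float]
    score: float
    rule: str


def weighted_span_score(per_set_results) -> SpanScore:
    """Weighted span score from per-set-size proportions correct.

    Each set size s = 1..5 contributes its proportion correct weighted by
    s (harder sets weigh more); the default rule divides the weighted sum
    by the number of set sizes, giving a score in [0, 3].  The rule
    identifier is stored so alternative weightings can be swapped without
    invalidating stored scores.
    """
    if not isinstance(per_set_results, dict):
        per_set_results = {s + 1: v for s, v in enumerate(per_set_results)}
    expected = set(range(1, 6))
    missing = sorted(expected - set(per_set_results))
    if missing:
        raise InputError(f"missing set sizes: {missing}")
    for s, pc in per_set_results.items():
        if not 0.0 <= pc <= 1.0:
            raise InputError(f"proportion correct for set size {s} outside [0, 1]: {pc}")
    score = sum(s * per_set_results[s] for s in expected) / len(expected)
    return SpanScore(per_set={s: float(per_set_results[s]) for s in sorted(expected)},
                     score=float(score), rule="weighted-mean-over-5-sets")


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("correlate needs two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("constant input has no defined correlation")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))
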