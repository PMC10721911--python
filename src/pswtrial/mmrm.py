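"""Weighted mixed model for repeated measures (MMRM) on change from baseline.

The model is the marginal multivariate-normal longitudinal model standard for
depression-trial primary analyses: for subject *i* with observed post-baseline
visit set :math:`V_i`,

.. math::  y_i \\sim N(X_i \\beta, \\ \\Sigma_{V_i} / w_i)

with fixed effects for visit (categorical), baseline total score,
baseline-by-visit and treatment-by-visit interactions, an unstructured
:math:`T \\times T` within-subject covariance :math:`\\Sigma`, and a
per-subject precision weight :math:`w_i` (the SAS ``WEIGHT`` convention:
covariance divided by the weight).  Estimation is REML on the log-Cholesky
parameterization of :math:`\\Sigma`; missing visits contribute nothing
(direct-likelihood MAR handling).  Unit weights reproduce the conventional
unweighted analysis exactly.

Outputs are the Table-style summaries of an antidepressant trial: LS means
(arm means at the overall mean baseline), the treatment effect TE (placebo
minus active LS-mean difference at end of study, positive when active improves
more), its standard error with Satterthwaite degrees of freedom, Tukey
(studentized-range, all-pairwise family) adjusted p-values, the model pooled
SD at EOS, and the between-group effect size ``|TE| / pooled_SD``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .propensity import PropensityScores
from .simulate import SubjectTrajectory

__all__ = [
    "LongFormatDataset",
    "MmrmError",
    "MmrmFit",
    "TreatmentComparison",
    "prepare_long_dataset",
    "fit_mmrm",
    "ls_means",
    "treatment_effects",
    "tukey_adjust",
    "tukey_adjusted_p",
    "effect_size",
]

REML_REL_TOL = 1e-12  # relative change of the -2 REML objective
_PENALTY = 1e12  # objective value returned for infeasible covariance parameters


class MmrmError(RuntimeError):
    """Model could not be fit (non-convergence or invalid covariance)."""


@dataclass(frozen=True)
class LongFormatDataset:
    """Post-baseline response rows plus the dropped-subject tally."""

    data: pd.DataFrame  # subject_id, arm, visit_week, change_from_baseline,
    #                     baseline_total, weight
    n_dropped_no_post_baseline: int


def prepare_long_dataset(
    trajectories: Sequence[SubjectTrajectory],
    scores: PropensityScores | None,
    eos_week: float,
) -> LongFormatDataset:
    """Build the MMRM response table from trajectories.

    ``change_from_baseline`` is the post-baseline total minus the week-0
    total.  Weights are 1 for the reference (unweighted) analysis or the
    propensity weights when scores are supplied; a retained subject without a
    score is an error (the weighted analysis must cover the full ITT set).
    Subjects with no post-baseline observation are dropped and counted.
    """
    weight_of: dict[str, float] | None = None
    if scores is not None:
        weight_of = dict(
            zip(scores.table["subject_id"], scores.table["w"].astype(float))
        )

    rows = []
    n_dropped = 0
    seen_eos = False
    for s in trajectories:
        if 0.0 not in s.item_scores:
            raise MmrmError(f"subject {s.subject_id} has no baseline visit")
        base = float(s.total(0.0))
        post = [w for w in s.observed_weeks if w > 0]
        if not post:
            n_dropped += 1
            continue
        if weight_of is not None and s.subject_id not in weight_of:
            raise MmrmError(
                f"propensity score missing for retained subject {s.subject_id}"
            )
        w = 1.0 if weight_of is None else weight_of[s.subject_id]
        for week in post:
            seen_eos = seen_eos or week == eos_week
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "arm": s.arm,
                    "visit_week": week,
                    "change_from_baseline": float(s.total(week)) - base,
                    "baseline_total": base,
                    "weight": w,
                }
            )
    if not rows:
        raise MmrmError("no post-baseline data to analyze")
    if not seen_eos:
        raise MmrmError(f"no subject observed at the EOS week {eos_week}")
    return LongFormatDataset(pd.DataFrame(rows), n_dropped)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


def _design_row(
    visit_idx: int, arm: str, base_centered: float, visits: list[float], arms: list[str]
) -> np.ndarray:
    """One fixed-effect row: per-visit intercept, per-visit (centered) baseline
    slope, and per-visit non-reference arm effects."""
    T = len(visits)
    A = len(arms)
    row = np.zeros(T * (A + 1))
    row[visit_idx] = 1.0
    row[T + visit_idx] = base_centered
    a = arms.index(arm)
    if a > 0:  # arms[0] is the reference level
        row[2 * T + (a - 1) * T + visit_idx] = 1.0
    return row


def _coef_names(visits: list[float], arms: list[str]) -> list[str]:
    names = [f"visit[{v:g}]" for v in visits]
    names += [f"baseline:visit[{v:g}]" for v in visits]
    for a in arms[1:]:
        names += [f"arm[{a}]:visit[{v:g}]" for v in visits]
    return names


@dataclass
class _Pattern:
    X: np.ndarray  # (m, t, p)
    y: np.ndarray  # (m, t)
    w: np.ndarray  # (m,)
    vis_idx: np.ndarray  # observed visit indices into the full schedule


def _theta_to_chol(theta: np.ndarray, T: int) -> np.ndarray:
    L = np.zeros((T, T))
    rows, cols = np.tril_indices(T)
    L[rows, cols] = theta
    L[np.diag_indices(T)] = np.exp(np.diag(L))
    return L


def _chol_to_theta(L: np.ndarray) -> np.ndarray:
    M = L.copy()
    M[np.diag_indices(len(L))] = np.log(np.diag(L))
    rows, cols = np.tril_indices(len(L))
    return M[rows, cols]


def _neg2_reml(
    theta: np.ndarray, patterns: list[_Pattern], T: int, p: int, want_fit: bool = False
):
    """-2 restricted log-likelihood (additive constant dropped)."""
    L = _theta_to_chol(theta, T)
    Sigma = L @ L.T
    XtX = np.zeros((p, p))
    Xty = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    try:
        for pat in patterns:
            S = Sigma[np.ix_(pat.vis_idx, pat.vis_idx)]
            t = len(pat.vis_idx)
            m = len(pat.w)
            cS = np.linalg.cholesky(S)
            logdet += m * 2.0 * np.sum(np.log(np.diag(cS)))
            logdet -= t * np.sum(np.log(pat.w))
            sw = np.sqrt(pat.w)
            # whiten each subject's t-block: L_S^{-1} X_i, scaled by sqrt(w_i)
            Xw = solve_triangular(
                cS, pat.X.transpose(1, 0, 2).reshape(t, m * p), lower=True
            ).reshape(t, m, p) * sw[None, :, None]
            yw = solve_triangular(cS, pat.y.T, lower=True) * sw[None, :]
            XtX += np.einsum("tmp,tmq->pq", Xw, Xw)
            Xty += np.einsum("tmp,tm->p", Xw, yw)
            yty += float(np.sum(yw * yw))
        cX = cho_factor(XtX)
    except np.linalg.LinAlgError:
        # large finite penalty keeps finite-difference gradients well defined
        return (_PENALTY, None) if want_fit else _PENALTY
    beta = cho_solve(cX, Xty)
    rss = yty - 2.0 * beta @ Xty + beta @ (XtX @ beta)
    rss = max(rss, 1e-12)
    logdet_XtX = 2.0 * np.sum(np.log(np.diag(cX[0])))
    f = logdet + logdet_XtX + rss
    if not np.isfinite(f):
        return (_PENALTY, None) if want_fit else _PENALTY
    if want_fit:
        return f, (beta, XtX, Sigma)
    return f


def _num_gradient(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.zeros(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _num_hessian(f, x: np.ndarray, h: float = 1e-4, f0: float | None = None) -> np.ndarray:
    q = len(x)
    H = np.zeros((q, q))
    if f0 is None:
        f0 = f(x)
    for i in range(q):
        ei = np.zeros(q)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, q):
            ej = np.zeros(q)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return H


def _polish_newton(f, theta: np.ndarray, f_val: float, iters: int = 2):
    """Sharpen the optimizer solution with damped Newton steps; the
    finite-difference gradient noise of the quasi-Newton stage limits the
    parameter accuracy otherwise."""
    for _ in range(iters):
        g = _num_gradient(f, theta)
        H = _num_hessian(f, theta, f0=f_val)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        # near the optimum the true improvement can fall below float
        # resolution of f; accept small steps that do not measurably worsen it
        slack = 1e-10 * max(1.0, abs(f_val))
        improved = False
        for damp in (1.0, 0.5, 0.25):
            cand = theta - damp * step
            fc = f(cand)
            if fc < f_val or (fc <= f_val + slack and np.linalg.norm(damp * step) < 0.05):
                theta, f_val = cand, min(fc, f_val)
                improved = True
                break
        if not improved:
            break
        if np.linalg.norm(step) < 1e-9:
            break
    return theta, f_val


@dataclass
class MmrmFit:
    beta: pd.Series
    beta_cov: np.ndarray
    Sigma: pd.DataFrame  # unstructured within-subject covariance, visits x visits
    visit_weeks: list[float]
    arms: list[str]
    baseline_mean: float
    n_subjects: int
    neg2_reml: float
    converged: bool
    df_method: str
    theta: np.ndarray = field(repr=False)
    _patterns: list[_Pattern] = field(repr=False, default_factory=list)
    _hess_inv2: np.ndarray | None = field(repr=False, default=None)

    # -- Satterthwaite machinery -------------------------------------------
    def _beta_cov_at(self, theta: np.ndarray) -> np.ndarray:
        _, aux = _neg2_reml(
            theta, self._patterns, len(self.visit_weeks), len(self.beta), want_fit=True
        )
        if aux is None:
            raise MmrmError("covariance evaluation failed off the optimum")
        return np.linalg.inv(aux[1])

    def _theta_cov(self) -> np.ndarray:
        """Asymptotic covariance of theta: 2 * inverse Hessian of -2 REML."""
        if self._hess_inv2 is None:
            T, p = len(self.visit_weeks), len(self.beta)
            H = _num_hessian(
                lambda th: _neg2_reml(th, self._patterns, T, p),
                self.theta,
                f0=self.neg2_reml,
            )
            self._hess_inv2 = 2.0 * np.linalg.pinv(H)
        return self._hess_inv2

    def contrast(self, c: np.ndarray) -> tuple[float, float, float]:
        """Estimate, SE and degrees of freedom for a fixed-effect contrast."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta.to_numpy())
        var = float(c @ self.beta_cov @ c)
        se = float(np.sqrt(var))
        df_resid = max(self.n_subjects - len(self.arms), 1)
        if self.df_method == "between_within":
            return est, se, float(df_resid)
        # Satterthwaite: df = 2 var^2 / Var(var), Var(var) by delta method
        try:
            q = len(self.theta)
            h = 1e-4
            g = np.zeros(q)
            for i in range(q):
                e = np.zeros(q)
                e[i] = h
                v_plus = float(c @ self._beta_cov_at(self.theta + e) @ c)
                v_minus = float(c @ self._beta_cov_at(self.theta - e) @ c)
                g[i] = (v_plus - v_minus) / (2 * h)
            denom = float(g @ self._theta_cov() @ g)
            df = 2.0 * var**2 / denom if denom > 0 else df_resid
            if not np.isfinite(df) or df <= 0:
                df = df_resid
        except (MmrmError, np.linalg.LinAlgError):
            df = float(df_resid)
        return est, se, float(min(df, 1e6))

    def ls_mean_row(self, arm: str, visit_week: float) -> np.ndarray:
        """Contrast vector for an arm's adjusted mean at the mean baseline."""
        return _design_row(
            self.visit_weeks.index(visit_week), arm, 0.0, self.visit_weeks, self.arms
        )


def fit_mmrm(
    data: LongFormatDataset | pd.DataFrame,
    normalize_weights: bool = True,
    df_method: str = "satterthwaite",
    maxiter: int = 500,
) -> MmrmFit:
    """REML fit of the weighted unstructured-covariance MMRM.

    With ``normalize_weights`` (default) the subject weights are rescaled to
    mean one before fitting, so every reported quantity — including the
    estimated covariance and hence the pooled SD and effect size — is
    invariant to multiplying all weights by a positive constant.  With raw
    weights the fixed effects, their SEs and p-values remain invariant but
    the fitted covariance scales with the weights.
    """
    frame = data.data if isinstance(data, LongFormatDataset) else data
    required = {"subject_id", "arm", "visit_week", "change_from_baseline",
                "baseline_total", "weight"}
    missing = required - set(frame.columns)
    if missing:
        raise MmrmError(f"long dataset missing columns {sorted(missing)}")
    if (frame["weight"] <= 0).any():
        raise MmrmError("weights must be positive")
    wspan = frame.groupby("subject_id")["weight"].nunique()
    if (wspan > 1).any():
        raise MmrmError("weights must be constant within subject")

    visits = sorted(frame["visit_week"].unique())
    arms = sorted(frame["arm"].unique())
    if len(arms) < 2:
        raise MmrmError("need at least two arms")
    arm_sizes = frame.groupby("arm")["subject_id"].nunique()
    if (arm_sizes < 2).any():
        raise MmrmError("need at least two subjects per arm")

    T, A = len(visits), len(arms)
    p = T * (A + 1)
    vindex = {v: i for i, v in enumerate(visits)}
    base_mean = float(frame.groupby("subject_id")["baseline_total"].first().mean())

    subj_weight = frame.groupby("subject_id")["weight"].first()
    wvals = subj_weight.to_numpy(dtype=float)
    wnorm = wvals / wvals.mean() if normalize_weights else wvals
    weight_of = dict(zip(subj_weight.index, wnorm))

    # group subjects by missing pattern for vectorized likelihood evaluation
    groups: dict[tuple[int, ...], list[tuple[np.ndarray, np.ndarray, float]]] = {}
    resid_wide = np.full((frame["subject_id"].nunique(), T), np.nan)
    for si, (sid, g) in enumerate(frame.groupby("subject_id", sort=True)):
        g = g.sort_values("visit_week")
        vis = tuple(vindex[v] for v in g["visit_week"])
        bc = float(g["baseline_total"].iloc[0]) - base_mean
        X = np.stack(
            [_design_row(vi, g["arm"].iloc[0], bc, visits, arms) for vi in vis]
        )
        y = g["change_from_baseline"].to_numpy(dtype=float)
        groups.setdefault(vis, []).append((X, y, weight_of[sid]))
        resid_wide[si, list(vis)] = y

    patterns = [
        _Pattern(
            X=np.stack([x for x, _, _ in items]),
            y=np.stack([y for _, y, _ in items]),
            w=np.array([w for _, _, w in items]),
            vis_idx=np.array(vis),
        )
        for vis, items in groups.items()
    ]
    n_subjects = int(frame["subject_id"].nunique())

    # start: pairwise-complete covariance of raw responses, ridged to PD
    S0 = pd.DataFrame(resid_wide).cov(min_periods=1).to_numpy()
    S0 = np.where(np.isfinite(S0), S0, 0.0)
    scale = max(np.nanvar(frame["change_from_baseline"].to_numpy()), 1e-3)
    evals = np.linalg.eigvalsh((S0 + S0.T) / 2)
    if evals.min() < 1e-6 * scale:
        S0 = (S0 + S0.T) / 2 + (1e-3 * scale - min(evals.min(), 0)) * np.eye(T)
    theta0 = _chol_to_theta(np.linalg.cholesky(S0))

    res = optimize.minimize(
        _neg2_reml,
        theta0,
        args=(patterns, T, p),
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": REML_REL_TOL, "gtol": 1e-6},
    )
    if not np.isfinite(res.fun) or res.fun >= _PENALTY:
        raise MmrmError(f"REML optimization failed: {res.message}")
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise MmrmError(f"REML optimizer aborted: {res.message}")

    theta_hat, _ = _polish_newton(
        lambda th: _neg2_reml(th, patterns, T, p), res.x, float(res.fun)
    )
    f, aux = _neg2_reml(theta_hat, patterns, T, p, want_fit=True)
    if aux is None:
        raise MmrmError("covariance not positive definite at the optimum")
    beta, XtX, Sigma = aux
    evals = np.linalg.eigvalsh(Sigma)
    if evals.min() <= 0:
        raise MmrmError(
            "estimated covariance is not positive definite; consider a "
            "structured-covariance fallback"
        )

    return MmrmFit(
        beta=pd.Series(beta, index=_coef_names(visits, arms)),
        beta_cov=np.linalg.inv(XtX),
        Sigma=pd.DataFrame(Sigma, index=visits, columns=visits),
        visit_weeks=visits,
        arms=arms,
        baseline_mean=base_mean,
        n_subjects=n_subjects,
        neg2_reml=float(f),
        converged=bool(res.success),
        df_method=df_method,
        theta=theta_hat,
        _patterns=patterns,
    )


def ls_means(fit: MmrmFit, visit_week: float | None = None) -> pd.DataFrame:
    """Adjusted arm means (at the overall mean baseline) with delta-method SEs.

    One row per arm x visit (or the single requested visit)."""
    visits = fit.visit_weeks if visit_week is None else [visit_week]
    rows = []
    for v in visits:
        if v not in fit.visit_weeks:
            raise MmrmError(f"visit {v} not in the fitted schedule")
        for arm in fit.arms:
            c = fit.ls_mean_row(arm, v)
            est = float(c @ fit.beta.to_numpy())
            se = float(np.sqrt(c @ fit.beta_cov @ c))
            rows.append({"arm": arm, "visit_week": v, "lsmean": est, "se": se})
    return pd.DataFrame(rows)


def tukey_adjusted_p(t_abs: float, n_arms: int, df: float) -> float:
    """Two-sided p-value adjusted for the all-pairwise Tukey family.

    Uses the studentized-range distribution with ``n_arms`` groups; with two
    arms the studentized range reduces exactly to the two-sided t-test, which
    is used directly.
    """
    if n_arms < 2:
        raise ValueError("Tukey adjustment needs at least two arms")
    if n_arms == 2:
        return float(min(2.0 * stats.t.sf(t_abs, df), 1.0))
    p = float(stats.studentized_range.sf(np.sqrt(2.0) * t_abs, n_arms, df))
    return float(min(max(p, 0.0), 1.0))


def effect_size(te: float, pooled_sd: float) -> float:
    """Between-group effect size: |LS-mean difference| / pooled SD."""
    if pooled_sd <= 0:
        raise ValueError("pooled SD must be positive")
    return abs(te) / pooled_sd


@dataclass(frozen=True)
class TreatmentComparison:
    comparison: str
    te: float
    std_err: float
    df: float
    p_unadjusted: float
    p_adjusted: float
    pooled_sd: float
    effect_size: float

    def __post_init__(self) -> None:
        if self.p_adjusted + 1e-12 < self.p_unadjusted:
            raise ValueError("adjusted p cannot fall below the unadjusted p")


def tukey_adjust(
    comparisons: Sequence[TreatmentComparison], n_arms: int
) -> list[TreatmentComparison]:
    """Re-adjust a set of comparisons for a different family size."""
    out = []
    for c in comparisons:
        t_abs = abs(c.te) / c.std_err if c.std_err > 0 else np.inf
        p_adj = tukey_adjusted_p(t_abs, n_arms, c.df)
        out.append(
            TreatmentComparison(
                comparison=c.comparison,
                te=c.te,
                std_err=c.std_err,
                df=c.df,
                p_unadjusted=c.p_unadjusted,
                p_adjusted=max(p_adj, c.p_unadjusted),
                pooled_sd=c.pooled_sd,
                effect_size=c.effect_size,
            )
        )
    return out


def treatment_effects(
    fit: MmrmFit,
    eos_week: float,
    placebo_arm: str,
    pooled_sd_method: str = "eos_diagonal",
) -> list[TreatmentComparison]:
    """Placebo-vs-active comparisons at end of study.

    TE = placebo LS mean minus active LS mean (changes are negative for
    improvement, so TE > 0 means the active arm improved more).  p-values are
    from t statistics with the fit's degrees-of-freedom method and adjusted
    with the all-pairwise Tukey family over ``len(fit.arms)`` arms; the pooled
    SD defaults to the square root of the EOS diagonal of the estimated
    covariance, with the across-visit average variance available as an
    alternative.
    """
    if eos_week not in fit.visit_weeks:
        raise MmrmError(f"EOS week {eos_week} absent from the fitted schedule")
    if placebo_arm not in fit.arms:
        raise MmrmError(f"placebo arm {placebo_arm!r} not in the fit")
    if pooled_sd_method == "eos_diagonal":
        pooled_sd = float(np.sqrt(fit.Sigma.loc[eos_week, eos_week]))
    elif pooled_sd_method == "average_variance":
        pooled_sd = float(np.sqrt(np.mean(np.diag(fit.Sigma.to_numpy()))))
    else:
        raise ValueError(f"unknown pooled SD method {pooled_sd_method!r}")

    comparisons = []
    for arm in fit.arms:
        if arm == placebo_arm:
            continue
        c = fit.ls_mean_row(placebo_arm, eos_week) - fit.ls_mean_row(arm, eos_week)
        te, se, df = fit.contrast(c)
        t_abs = abs(te) / se if se > 0 else np.inf
        p_raw = float(min(2.0 * stats.t.sf(t_abs, df), 1.0))
        p_adj = max(tukey_adjusted_p(t_abs, len(fit.arms), df), p_raw)
        comparisons.append(
            TreatmentComparison(
                comparison=f"Pbo vs. {arm}",
                te=te,
                std_err=se,
                df=df,
                p_unadjusted=p_raw,
                p_adjusted=p_adj,
                pooled_sd=pooled_sd,
                effect_size=effect_size(te, pooled_sd),
            )
        )
    return comparisons


def comparisons_to_frame(comparisons: Sequence[TreatmentComparison]) -> pd.DataFrame:
    """Table-shaped output: Comparison, TE, StdErr, P, SD, Effect_size."""
    return pd.DataFrame(
        {
            "Comparison": [c.comparison for c in comparisons],
            "TE": [c.te for c in comparisons],
            "StdErr": [c.std_err for c in comparisons],
            "P": [c.p_adjusted for c in comparisons],
            "SD": [c.pooled_sd for c in comparisons],
            "Effect_size": [c.effect_size for c in comparisons],
        }
    )
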