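"""Random-intercept logistic analysis of four-alternative forced choices.

Each trial shows four abstract images; the participant picks the most
positive (or safest) and the most negative (or most threatening) one.  The
picked-high image becomes a binary observation with outcome 1, the
picked-low image one with outcome 0, and the two neutral images are
discarded.  Outcomes are modelled as

    logit P(outcome = 1) = x' beta + b_participant,   b ~ N(0, sd^2)

with a full Length x Angularity x Orientation factorial (sum-to-zero coded
factors) as fixed effects and a Gaussian random intercept per participant
(optionally an additional intercept per trial within participant).  The
marginal likelihood is handled by the Laplace approximation; each effect is
tested by a likelihood-ratio test against the model with that effect's
columns removed (all other terms retained, so the tests are Type-III-style
under the sum-to-zero coding).

Numerically, the random intercepts *and* the fixed effects are profiled
out at the joint penalized mode (Newton iterations with Schur elimination
of the per-group blocks), leaving a one-dimensional (or, with trial
intercepts, two-dimensional) search over the log random-effect scale(s).
Observations sharing a participant and design cell are aggregated to
binomial counts first, which makes each fit essentially independent of the
number of trials.  Log-likelihoods use the Bernoulli (sum over raw
observations) convention, so they are directly comparable with an ordinary
logistic regression on the disaggregated rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .stimuli import ANGULARITY_CLASSES, LENGTH_CLASSES, ORIENTATION_CLASSES

__all__ = [
    "FACTOR_LEVELS",
    "EFFECTS",
    "GlmmFit",
    "LrtResult",
    "ConvergenceError",
    "MalformedTrialError",
    "RandomInterceptLogit",
    "design_matrix",
    "build_choice_observations",
    "fit_logistic_glmm",
    "likelihood_ratio_tests",
    "condition_summaries",
]

FACTOR_COLUMNS = ("length_class", "angularity_class", "orientation_class")

#: Factor levels in the (alphabetical) order that fixes the sum-to-zero coding.
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "Length": tuple(sorted(LENGTH_CLASSES)),
    "Angularity": tuple(sorted(ANGULARITY_CLASSES)),
    "Orientation": tuple(sorted(ORIENTATION_CLASSES)),
}

#: The seven testable effects of the full factorial, with their df.
EFFECTS: tuple[str, ...] = (
    "Orientation",
    "Angularity",
    "Length",
    "Orientation:Angularity",
    "Orientation:Length",
    "Angularity:Length",
    "Orientation:Angularity:Length",
)

_FACTOR_TO_COLUMN = {
    "Length": "length_class",
    "Angularity": "angularity_class",
    "Orientation": "orientation_class",
}


class ConvergenceError(RuntimeError):
    """Raised when the penalized Newton iterations fail to converge."""

    def __init__(self, message: str, trace: list[float] | None = None) -> None:
        super().__init__(message)
        self.trace = trace or []


class MalformedTrialError(ValueError):
    """Raised for trials whose choices violate the 4AFC invariants."""


def _sum_code(values: pd.Series, levels: Sequence[str], name: str) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero contrast columns for one factor (k levels -> k-1 columns)."""
    unknown = set(values.unique()) - set(levels)
    if unknown:
        raise ValueError(f"unknown {name} levels: {sorted(unknown)}")
    cols = np.zeros((len(values), len(levels) - 1))
    arr = values.to_numpy()
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = np.where(arr == lev, 1.0, np.where(arr == levels[-1], -1.0, 0.0))
    names = [f"{name}[{lev}]" for lev in levels[:-1]]
    return cols, names


def design_matrix(
    data: pd.DataFrame, drop_effects: Sequence[str] = ()
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Full-factorial sum-coded design matrix with intercept.

    Returns the matrix, the column names, and a mapping from effect name to
    the indices of its columns.  ``drop_effects`` removes whole effects
    (used by the likelihood-ratio tests).
    """
    unknown = set(drop_effects) - set(EFFECTS)
    if unknown:
        raise ValueError(f"unknown effects: {sorted(unknown)}")
    missing = [c for c in FACTOR_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"observations are missing factor columns: {missing}")

    main: dict[str, tuple[np.ndarray, list[str]]] = {}
    for fname, col in _FACTOR_TO_COLUMN.items():
        main[fname] = _sum_code(data[col], FACTOR_LEVELS[fname], fname)

    blocks: list[np.ndarray] = [np.ones((len(data), 1))]
    names: list[str] = ["(Intercept)"]
    effect_cols: dict[str, list[int]] = {}
    for effect in EFFECTS:
        if effect in drop_effects:
            continue
        parts = effect.split(":")
        cols, cnames = main[parts[0]]
        for part in parts[1:]:
            pc, pn = main[part]
            cols = np.einsum("ni,nj->nij", cols, pc).reshape(len(data), -1)
            cnames = [f"{a}:{b}" for a in cnames for b in pn]
        start = sum(b.shape[1] for b in blocks)
        effect_cols[effect] = list(range(start, start + cols.shape[1]))
        blocks.append(cols)
        names.extend(cnames)
    return np.hstack(blocks), names, effect_cols


# ---------------------------------------------------------------------------
# likelihood machinery


def _bernoulli_ll(eta: np.ndarray, succ: np.ndarray, tot: np.ndarray) -> float:
    return float(np.sum(succ * eta - tot * np.logaddexp(0.0, eta)))


def _glm_newton(
    X: np.ndarray,
    succ: np.ndarray,
    tot: np.ndarray,
    offset: np.ndarray | float = 0.0,
    ridge: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, bool]:
    """Plain logistic Newton fit on (possibly aggregated) binomial rows."""
    p = X.shape[1]
    beta = np.zeros(p)
    ll = -np.inf
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = special.expit(eta)
        new_ll = _bernoulli_ll(eta, succ, tot) - 0.5 * ridge * beta @ beta
        grad = X.T @ (succ - tot * mu) - ridge * beta
        w = tot * mu * (1.0 - mu)
        H = X.T @ (X * w[:, None]) + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # backtracking to guarantee ascent
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            eta_c = X @ cand + offset
            cand_ll = _bernoulli_ll(eta_c, succ, tot) - 0.5 * ridge * cand @ cand
            if cand_ll >= new_ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if abs(cand_ll - ll) < tol * (1.0 + abs(cand_ll)):
            return beta, cand_ll, True
        ll = cand_ll
    return beta, ll, False


def _joint_mode_participant(
    X: np.ndarray,
    succ: np.ndarray,
    tot: np.ndarray,
    g: np.ndarray,
    n_groups: int,
    s2: float,
    beta0: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-11,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool]:
    """Newton ascent of the penalized log-likelihood over (beta, b)."""
    p = X.shape[1]
    beta = beta0.copy()
    b = np.zeros(n_groups)

    def pen_ll(beta: np.ndarray, b: np.ndarray) -> float:
        eta = X @ beta + b[g]
        return _bernoulli_ll(eta, succ, tot) - 0.5 * float(b @ b) / s2

    ll = pen_ll(beta, b)
    for _ in range(max_iter):
        eta = X @ beta + b[g]
        mu = special.expit(eta)
        resid = succ - tot * mu
        w = tot * mu * (1.0 - mu)
        grad_beta = X.T @ resid
        grad_b = np.bincount(g, resid, minlength=n_groups) - b / s2
        A = X.T @ (X * w[:, None])
        B = np.vstack(
            [np.bincount(g, X[:, j] * w, minlength=n_groups) for j in range(p)]
        )
        D = np.bincount(g, w, minlength=n_groups) + 1.0 / s2
        S = A - (B / D) @ B.T
        rhs = grad_beta - B @ (grad_b / D)
        try:
            dbeta = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError:
            dbeta = np.linalg.lstsq(S, rhs, rcond=None)[0]
        db = (grad_b - B.T @ dbeta) / D
        t = 1.0
        for _ in range(40):
            cand_ll = pen_ll(beta + t * dbeta, b + t * db)
            if cand_ll >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * dbeta
        b = b + t * db
        if abs(cand_ll - ll) < tol * (1.0 + abs(cand_ll)):
            w_hat = tot * special.expit(X @ beta + b[g]) * (
                1.0 - special.expit(X @ beta + b[g])
            )
            return beta, b, cand_ll, np.bincount(g, w_hat, minlength=n_groups), True
        ll = cand_ll
    raise ConvergenceError(
        f"penalized Newton did not converge in {max_iter} iterations", trace=[ll]
    )


def _laplace_ll_participant(
    log_sd: float,
    X: np.ndarray,
    succ: np.ndarray,
    tot: np.ndarray,
    g: np.ndarray,
    n_groups: int,
    beta0: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    s2 = float(np.exp(2.0 * log_sd))
    beta, b, pen, wsum, _ = _joint_mode_participant(X, succ, tot, g, n_groups, s2, beta0)
    ll = pen - 0.5 * float(np.sum(np.log1p(s2 * wsum)))
    return ll, beta, b


def _joint_mode_nested(
    X: np.ndarray,
    succ: np.ndarray,
    tot: np.ndarray,
    g: np.ndarray,
    t_idx: np.ndarray,
    trial_group: np.ndarray,
    n_groups: int,
    n_trials: int,
    s2_b: float,
    s2_c: float,
    beta0: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-11,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Penalized mode over (beta, b, c) with trial intercepts nested in
    participants; returns the mode and the Laplace log-determinant term."""
    p = X.shape[1]
    beta = beta0.copy()
    b = np.zeros(n_groups)
    c = np.zeros(n_trials)

    def pen_ll(beta, b, c):
        eta = X @ beta + b[g] + c[t_idx]
        return (
            _bernoulli_ll(eta, succ, tot)
            - 0.5 * float(b @ b) / s2_b
            - 0.5 * float(c @ c) / s2_c
        )

    ll = pen_ll(beta, b, c)
    for _ in range(max_iter):
        eta = X @ beta + b[g] + c[t_idx]
        mu = special.expit(eta)
        resid = succ - tot * mu
        w = tot * mu * (1.0 - mu)
        grad_beta = X.T @ resid
        grad_b = np.bincount(g, resid, minlength=n_groups) - b / s2_b
        grad_c = np.bincount(t_idx, resid, minlength=n_trials) - c / s2_c
        A = X.T @ (X * w[:, None])
        Bb = np.vstack([np.bincount(g, X[:, j] * w, minlength=n_groups) for j in range(p)])
        Bc = np.vstack([np.bincount(t_idx, X[:, j] * w, minlength=n_trials) for j in range(p)])
        Db = np.bincount(g, w, minlength=n_groups) + 1.0 / s2_b
        Dc = np.bincount(t_idx, w, minlength=n_trials) + 1.0 / s2_c
        # cross term between b and c: one participant per trial
        M = np.bincount(t_idx, w, minlength=n_trials)  # H[b_gt, c_t]
        # eliminate c
        A1 = A - (Bc / Dc) @ Bc.T
        Bb1 = Bb - (Bc / Dc) @ _scatter_cols(M, trial_group, n_groups).T
        Db1 = Db - np.bincount(trial_group, M * M / Dc, minlength=n_groups)
        gb1 = grad_b - np.bincount(trial_group, M * grad_c / Dc, minlength=n_groups)
        gbeta1 = grad_beta - Bc @ (grad_c / Dc)
        S = A1 - (Bb1 / Db1) @ Bb1.T
        rhs = gbeta1 - Bb1 @ (gb1 / Db1)
        try:
            dbeta = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError:
            dbeta = np.linalg.lstsq(S, rhs, rcond=None)[0]
        db = (gb1 - Bb1.T @ dbeta) / Db1
        dc = (grad_c - Bc.T @ dbeta - M * db[trial_group]) / Dc
        t = 1.0
        for _ in range(40):
            cand_ll = pen_ll(beta + t * dbeta, b + t * db, c + t * dc)
            if cand_ll >= ll - 1e-12:
                break
            t *= 0.5
        beta, b, c = beta + t * dbeta, b + t * db, c + t * dc
        if abs(cand_ll - ll) < tol * (1.0 + abs(cand_ll)):
            eta = X @ beta + b[g] + c[t_idx]
            mu = special.expit(eta)
            w = tot * mu * (1.0 - mu)
            Dc = np.bincount(t_idx, w, minlength=n_trials)
            Db = np.bincount(g, w, minlength=n_groups)
            M = Dc  # same aggregation
            Dc_pen = Dc + 1.0 / s2_c
            Db1 = Db + 1.0 / s2_b - np.bincount(trial_group, M * M / Dc_pen, minlength=n_groups)
            logdet = float(
                np.sum(np.log(s2_c * Dc_pen)) + np.sum(np.log(s2_b * Db1))
            )
            return beta, b, c, cand_ll, logdet
        ll = cand_ll
    raise ConvergenceError(
        "penalized Newton (nested trial intercepts) did not converge", trace=[ll]
    )


def _scatter_cols(values: np.ndarray, col_group: np.ndarray, n_groups: int) -> np.ndarray:
    """Build the (n_groups, n_trials) cross block with one nonzero per column."""
    out = np.zeros((n_groups, len(values)))
    out[col_group, np.arange(len(values))] = values
    return out


# ---------------------------------------------------------------------------
# public model objects


@dataclass(frozen=True)
class GlmmFit:
    """A fitted random-intercept logistic model."""

    fixed_names: tuple[str, ...]
    fixed_effects: np.ndarray
    sd_participant: float
    sd_trial: float | None
    loglik: float
    converged: bool
    n_obs: int
    n_participants: int
    random_structure: str
    separation: bool = False

    def fixed_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": list(self.fixed_names), "estimate": self.fixed_effects}
        )


@dataclass(frozen=True)
class LrtResult:
    """A likelihood-ratio test of one factorial effect."""

    effect: str
    chisq: float
    df: int
    pvalue: float
    tested: bool = True


class RandomInterceptLogit(BaseEstimator):
    """Random-intercept logistic regression for factorial choice data.

    A scikit-learn-style estimator: ``fit(X, y, groups=...)`` where ``X``
    is a DataFrame carrying the three factor columns (``length_class``,
    ``angularity_class``, ``orientation_class``), ``y`` the binary outcome
    (1 = chosen most positive/safe, 0 = chosen most negative/threatening)
    and ``groups`` the participant of each row.

    Parameters
    ----------
    random_structure : {"participant", "participant+trial"}
        "participant" (default) fits one Gaussian intercept per
        participant.  "participant+trial" adds an intercept per trial
        nested in participant (requires ``trials=`` in ``fit``); with one
        positive and one negative outcome per trial that intercept is only
        weakly identified, which is why it is not the default.
    drop_effects : sequence of effect names
        Whole factorial effects to exclude from the fixed structure (used
        internally by the likelihood-ratio tests).
    sd_bounds : (float, float)
        Search bounds for the random-intercept standard deviation(s).

    Attributes
    ----------
    fixed_effects_ : (p,) ndarray of sum-coded fixed effects (with intercept)
    fixed_names_ : list of str
    sd_participant_ : float
    sd_trial_ : float or None
    loglik_ : float  (Bernoulli convention, comparable to plain logistic)
    converged_ : bool
    """

    def __init__(
        self,
        random_structure: Literal["participant", "participant+trial"] = "participant",
        drop_effects: Sequence[str] = (),
        sd_bounds: tuple[float, float] = (1e-3, 5.0),
        max_iter: int = 200,
    ) -> None:
        self.random_structure = random_structure
        self.drop_effects = drop_effects
        self.sd_bounds = sd_bounds
        self.max_iter = max_iter

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        X: pd.DataFrame,
        y: Sequence[int] | np.ndarray,
        groups: Sequence | np.ndarray = None,
        trials: Sequence | np.ndarray = None,
    ) -> "RandomInterceptLogit":
        if groups is None:
            raise ValueError("groups (participant ids) are required")
        y = np.asarray(y, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("outcomes must be binary 0/1")
        groups = np.asarray(groups)
        if len(np.unique(groups)) < 2:
            raise ValueError("need at least 2 participants")
        design, names, effect_cols = design_matrix(X, drop_effects=self.drop_effects)

        # cells with no data: flag the affected terms rather than fitting them
        cells = X[list(FACTOR_COLUMNS)].astype(str).agg("|".join, axis=1)
        self.missing_cells_ = 24 - cells.nunique()
        if self.missing_cells_ > 0:
            warnings.warn(
                f"{self.missing_cells_} of 24 design cells have no observations; "
                "higher-order terms may be inestimable",
                stacklevel=2,
            )

        if self.random_structure == "participant":
            self._fit_participant(design, y, groups)
        elif self.random_structure == "participant+trial":
            if trials is None:
                raise ValueError("random_structure='participant+trial' requires trials=")
            self._fit_nested(design, y, groups, np.asarray(trials))
        else:
            raise ValueError(f"unknown random_structure {self.random_structure!r}")

        self.fixed_names_ = names
        self.effect_columns_ = effect_cols
        self.n_obs_ = len(y)
        return self

    def _aggregate(self, design, y, groups):
        """Collapse Bernoulli rows sharing (participant, design row) to
        binomial counts."""
        codes, uniq = pd.factorize(groups, sort=True)
        df = pd.DataFrame(design)
        design_cols = list(df.columns)
        df["_g"] = codes
        df["_y"] = y
        agg = df.groupby(design_cols + ["_g"], sort=True, as_index=False).agg(
            _succ=("_y", "sum"), _n=("_y", "size")
        )
        Xa = agg[design_cols].to_numpy(float)
        return (
            Xa,
            agg["_succ"].to_numpy(float),
            agg["_n"].to_numpy(float),
            agg["_g"].to_numpy(int),
            len(uniq),
            uniq,
        )

    def _glm_start(self, X, succ, tot):
        beta, ll, ok = _glm_newton(X, succ, tot)
        separation = bool(np.max(np.abs(beta)) > 30.0) or not ok
        if separation:
            warnings.warn(
                "possible separation in the fixed-effect structure; "
                "refitting with a small ridge penalty",
                stacklevel=3,
            )
            beta, ll, _ = _glm_newton(X, succ, tot, ridge=1e-4)
            ll = _bernoulli_ll(X @ beta, succ, tot)
        return beta, ll, separation

    def _fit_participant(self, design, y, groups):
        Xa, succ, tot, g, n_groups, uniq = self._aggregate(design, y, groups)
        beta_glm, ll_glm, separation = self._glm_start(Xa, succ, tot)

        def neg(log_sd: float) -> float:
            ll, _, _ = _laplace_ll_participant(log_sd, Xa, succ, tot, g, n_groups, beta_glm)
            return -ll

        lo, hi = np.log(self.sd_bounds)
        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
        )
        ll_hat, beta_hat, b_hat = _laplace_ll_participant(
            float(res.x), Xa, succ, tot, g, n_groups, beta_glm
        )
        if ll_glm >= ll_hat:  # boundary: the GLM (sd = 0) is the optimum
            self.fixed_effects_ = beta_glm
            self.sd_participant_ = 0.0
            self.loglik_ = float(ll_glm)
            self.random_effects_ = pd.Series(np.zeros(n_groups), index=uniq)
        else:
            self.fixed_effects_ = beta_hat
            self.sd_participant_ = float(np.exp(res.x))
            self.loglik_ = float(ll_hat)
            self.random_effects_ = pd.Series(b_hat, index=uniq)
        self.sd_trial_ = None
        self.converged_ = bool(res.success)
        self.separation_ = separation
        self.n_participants_ = n_groups

    def _fit_nested(self, design, y, groups, trials):
        g_codes, g_uniq = pd.factorize(groups, sort=True)
        trial_key = pd.MultiIndex.from_arrays([groups, trials])
        t_codes, t_uniq = pd.factorize(trial_key, sort=True)
        trial_group = np.zeros(len(t_uniq), dtype=int)
        trial_group[t_codes] = g_codes
        succ = y
        tot = np.ones_like(y)
        beta_glm, ll_glm, separation = self._glm_start(design, succ, tot)

        def neg(x: np.ndarray) -> float:
            s2_b, s2_c = np.exp(2.0 * x)
            _, _, _, pen, logdet = _joint_mode_nested(
                design, succ, tot, g_codes, t_codes, trial_group,
                len(g_uniq), len(t_uniq), s2_b, s2_c, beta_glm,
            )
            return -(pen - 0.5 * logdet)

        lo, hi = np.log(self.sd_bounds)
        res = optimize.minimize(
            neg, x0=np.array([np.log(0.5), np.log(0.3)]), method="Nelder-Mead",
            bounds=[(lo, hi)] * 2, options={"xatol": 1e-4, "fatol": 1e-7},
        )
        s2_b, s2_c = np.exp(2.0 * res.x)
        beta, b, c, pen, logdet = _joint_mode_nested(
            design, succ, tot, g_codes, t_codes, trial_group,
            len(g_uniq), len(t_uniq), s2_b, s2_c, beta_glm,
        )
        ll_hat = pen - 0.5 * logdet
        if ll_glm >= ll_hat:
            self.fixed_effects_ = beta_glm
            self.sd_participant_ = 0.0
            self.sd_trial_ = 0.0
            self.loglik_ = float(ll_glm)
            self.random_effects_ = pd.Series(np.zeros(len(g_uniq)), index=g_uniq)
        else:
            self.fixed_effects_ = beta
            self.sd_participant_ = float(np.sqrt(s2_b))
            self.sd_trial_ = float(np.sqrt(s2_c))
            self.loglik_ = float(ll_hat)
            self.random_effects_ = pd.Series(b, index=g_uniq)
        self.converged_ = bool(res.success)
        self.separation_ = separation
        self.n_participants_ = len(g_uniq)

    # -- prediction / summary ----------------------------------------------

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Population-level (random intercept at 0) choice probabilities."""
        design, _, _ = design_matrix(X, drop_effects=self.drop_effects)
        return special.expit(design @ self.fixed_effects_)

    def result(self) -> GlmmFit:
        return GlmmFit(
            fixed_names=tuple(self.fixed_names_),
            fixed_effects=np.asarray(self.fixed_effects_),
            sd_participant=self.sd_participant_,
            sd_trial=self.sd_trial_,
            loglik=self.loglik_,
            converged=self.converged_,
            n_obs=self.n_obs_,
            n_participants=self.n_participants_,
            random_structure=self.random_structure,
            separation=self.separation_,
        )


# ---------------------------------------------------------------------------
# pipeline-facing functions


def build_choice_observations(
    trials: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Long-format binary observations from 4AFC trial records.

    Each trial contributes exactly two rows: the chosen-high image with
    outcome 1 and the chosen-low image with outcome 0; the two neutral
    images are excluded.  Factor levels are joined in from the stimulus
    manifest.
    """
    required = {"participant_id", "trial_index", "choice_high", "choice_low"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    img_cols = [c for c in ("img1", "img2", "img3", "img4") if c in trials.columns]

    same = trials["choice_high"] == trials["choice_low"]
    if same.any():
        row = trials[same].iloc[0]
        raise MalformedTrialError(
            f"trial {row['trial_index']} of participant {row['participant_id']} "
            "selects the same image as most-high and most-low"
        )
    if img_cols:
        shown = trials[img_cols].to_numpy()
        for col in ("choice_high", "choice_low"):
            ok = (trials[col].to_numpy()[:, None] == shown).any(axis=1)
            if not ok.all():
                row = trials[~ok].iloc[0]
                raise MalformedTrialError(
                    f"trial {row['trial_index']} of participant "
                    f"{row['participant_id']}: {col} is not among the shown images"
                )

    long = pd.concat(
        [
            trials[["participant_id", "trial_index", "choice_high"]]
            .rename(columns={"choice_high": "image_id"})
            .assign(outcome=1),
            trials[["participant_id", "trial_index", "choice_low"]]
            .rename(columns={"choice_low": "image_id"})
            .assign(outcome=0),
        ],
        ignore_index=True,
    )
    man = manifest[["image_id", *FACTOR_COLUMNS]]
    merged = long.merge(man, on="image_id", how="left", validate="m:1")
    unknown = merged[merged["length_class"].isna()]
    if len(unknown):
        raise ValueError(
            f"{len(unknown)} chosen image ids are absent from the manifest, "
            f"e.g. {sorted(unknown['image_id'].unique())[:5]}"
        )
    return merged.sort_values(
        ["participant_id", "trial_index", "outcome"],
        ascending=[True, True, False],
        ignore_index=True,
    )


def fit_logistic_glmm(
    observations: pd.DataFrame,
    random_structure: Literal["participant", "participant+trial"] = "participant",
    drop_effects: Sequence[str] = (),
) -> GlmmFit:
    """Fit the factorial random-intercept logistic model to observations."""
    model = RandomInterceptLogit(
        random_structure=random_structure, drop_effects=drop_effects
    )
    model.fit(
        observations,
        observations["outcome"],
        groups=observations["participant_id"],
        trials=observations.get("trial_index"),
    )
    return model.result()


def likelihood_ratio_tests(
    observations: pd.DataFrame,
    random_structure: Literal["participant", "participant+trial"] = "participant",
    effects: Sequence[str] = EFFECTS,
    full_fit: GlmmFit | None = None,
) -> pd.DataFrame:
    """Type-III-style likelihood-ratio test of each factorial effect.

    Each effect is tested by refitting the model without that effect's
    sum-coded columns (all other terms retained) and referring twice the
    log-likelihood difference to a chi-square with as many df as columns
    removed.  An effect whose reduced model fails to converge is flagged
    untested (chisq/p = NaN).
    """
    if full_fit is None:
        full_fit = fit_logistic_glmm(observations, random_structure)
    _, _, effect_cols = design_matrix(observations.iloc[:2])
    rows = []
    for effect in effects:
        df = len(effect_cols[effect])
        try:
            reduced = fit_logistic_glmm(
                observations, random_structure, drop_effects=(effect,)
            )
            chisq = max(0.0, 2.0 * (full_fit.loglik - reduced.loglik))
            rows.append(
                LrtResult(effect, chisq, df, float(stats.chi2.sf(chisq, df)))
            )
        except ConvergenceError:
            rows.append(LrtResult(effect, np.nan, df, np.nan, tested=False))
    return pd.DataFrame(
        {
            "effect": [r.effect for r in rows],
            "chisq": [r.chisq for r in rows],
            "df": [r.df for r in rows],
            "p": [r.pvalue for r in rows],
            "tested": [r.tested for r in rows],
        }
    )


def condition_summaries(
    observations: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed choice proportions per design cell.

    Returns a 24-row (non-empty cells) table of the proportion of modelled
    observations that are chosen-high, and a per-participant long table for
    interval plots.
    """
    if observations.empty:
        raise ValueError("no observations to summarise")
    cell = (
        observations.groupby(list(FACTOR_COLUMNS), as_index=False)
        .agg(n=("outcome", "size"), prop_positive=("outcome", "mean"))
    )
    per_participant = (
        observations.groupby(["participant_id", *FACTOR_COLUMNS], as_index=False)
        .agg(n=("outcome", "size"), prop_positive=("outcome", "mean"))
    )
    return cell, per_participant
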