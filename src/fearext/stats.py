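"""Moderated repeated-measures analysis for 2x2 within-subject designs.

The inferential machinery is a Condition (CS+, CS-) x Time (early, late)
repeated-measures ANCOVA with a continuous, mean-centered moderator
(intolerance of uncertainty, IU).  It is implemented through within-subject
orthogonal contrast scores: for each subject the four cell means collapse to

* G - the grand mean of the 4 cells (between-subject part),
* C - the condition effect,
* T - the time effect,
* X - the condition-by-time interaction,

and each score is regressed on (1, centered moderator).  The squared t of an
intercept gives the within-subject main-effect/interaction F; the squared t
of a slope gives the corresponding moderation F; the moderator's
between-subject F comes from the regression on G.  This is algebraically
the classical 2x2 RM-ANCOVA (both give df = (1, n - 2)).

Follow-ups evaluate estimated marginal means and pairwise contrasts at the
moderator mean and +/- 1 SD, from the same fitted regressions - a simple
slopes analysis.  Hierarchical regressions quantify the moderator's
incremental variance (delta R^2) over trait-anxiety covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

from .errors import InsufficientDataError, MissingCellError, RankDeficiencyError

#: wide-format cell columns for the extinction 2x2 design
CELLS_2X2 = ("csplus_early", "csminus_early", "csplus_late", "csminus_late")

#: the four follow-up difference scores
DIFFERENCE_SCORES = {
    "csplus_minus_csminus_early": (("csplus_early", 1.0), ("csminus_early", -1.0)),
    "csplus_minus_csminus_late": (("csplus_late", 1.0), ("csminus_late", -1.0)),
    "csplus_early_minus_late": (("csplus_early", 1.0), ("csplus_late", -1.0)),
    "csminus_early_minus_late": (("csminus_early", 1.0), ("csminus_late", -1.0)),
}


def mean_center(x) -> np.ndarray:
    """Center a covariate on the analyzed sample's mean."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)] if np.isnan(x).any() else x
    if x.size < 2:
        raise ValueError("need at least 2 finite values to center")
    return x - x.mean()


def partial_eta_squared(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be >= 0")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return F * df1 / (F * df1 + df2)


def delta_r_squared(r2_full: float, r2_reduced: float) -> float:
    """Increment in variance explained between nested regression steps."""
    for r2 in (r2_full, r2_reduced):
        if not 0 <= r2 <= 1:
            raise ValueError("R^2 must lie in [0, 1]")
    return r2_full - r2_reduced


def within_contrast_scores(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-subject G/C/T/X contrast scores from the four cell columns."""
    missing = [c for c in CELLS_2X2 if c not in cells.columns]
    if missing:
        raise MissingCellError(f"missing cell column(s) {missing}")
    pe, me, pl, ml = (cells[c].to_numpy(dtype=float) for c in CELLS_2X2)
    return pd.DataFrame({
        "G": (pe + me + pl + ml) / 4.0,
        "C": (pe + pl) / 2.0 - (me + ml) / 2.0,
        "T": (pe + me) / 2.0 - (pl + ml) / 2.0,
        "X": (pe - me) - (pl - ml),
    })


@dataclass
class _ContrastFit:
    """OLS fit of one per-subject score on (1, centered covariate)."""

    params: np.ndarray  # (intercept, slope)
    cov: np.ndarray     # 2x2 coefficient covariance
    df_resid: int

    def at(self, z: float):
        """Estimate and SE of the score evaluated at covariate value z."""
        est = float(self.params[0] + self.params[1] * z)
        var = self.cov[0, 0]
        if z:  # avoid 0 * inf when the covariate was constant
            var = var + 2 * z * self.cov[0, 1] + z * z * self.cov[1, 1]
        return est, float(np.sqrt(var))


def _fit_score(y: np.ndarray, zc: np.ndarray) -> _ContrastFit:
    if np.ptp(zc) == 0:
        # degenerate (constant) covariate: the moderation slope is
        # unidentified and the within-subject test reduces to a one-sample
        # t-test on the contrast score (df = n - 1)
        n = len(y)
        resid = y - y.mean()
        var_b0 = float(resid @ resid) / (n - 1) / n
        cov = np.array([[var_b0, 0.0], [0.0, np.inf]])
        return _ContrastFit(params=np.array([y.mean(), 0.0]), cov=cov,
                            df_resid=n - 1)
    X = sm.add_constant(zc)
    res = sm.OLS(y, X).fit()
    return _ContrastFit(params=np.asarray(res.params),
                        cov=np.asarray(res.cov_params()),
                        df_resid=int(res.df_resid))


def _effect_row(name, fit: _ContrastFit, which: int):
    denom = np.sqrt(fit.cov[which, which])
    t = fit.params[which] / denom if np.isfinite(denom) and denom > 0 else 0.0
    F = float(t ** 2)
    df2 = fit.df_resid
    p = float(2 * sstats.t.sf(abs(t), df2))
    return {"effect": name, "F": F, "df1": 1, "df2": df2, "p": p,
            "partial_eta_sq": partial_eta_squared(F, 1, df2)}


@dataclass
class RmAncovaResult:
    """Fitted moderated repeated-measures ANCOVA."""

    n: int
    covariate_sd: float
    effects: pd.DataFrame
    emm: pd.DataFrame
    contrasts: pd.DataFrame
    cell_fits: dict = field(default_factory=dict, repr=False)
    difference_fits: dict = field(default_factory=dict, repr=False)

    @property
    def df2(self) -> int:
        return self.n - 2


def fit_rm_ancova(cells: pd.DataFrame, covariate) -> RmAncovaResult:
    """Condition x Time x moderator repeated-measures ANCOVA.

    ``cells`` is wide per-subject data with the four columns of
    :data:`CELLS_2X2`; ``covariate`` is the moderator for the same subjects
    (centered internally on this sample).  Returns F/df/p/partial eta^2 for
    the seven effects, estimated marginal means at the moderator mean and
    +/- 1 SD, and pairwise follow-up contrasts at those moderator values.
    """
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != len(cells):
        raise ValueError("covariate length must match number of subjects")
    if np.isnan(cov).any() or cells[list(CELLS_2X2)].isna().any().any():
        raise ValueError("missing values; exclude incomplete subjects first")
    n = len(cells)
    if n < 4:
        raise InsufficientDataError(f"n={n} subjects; need at least 4")
    zc = mean_center(cov)
    sd = float(np.std(cov, ddof=1))

    scores = within_contrast_scores(cells)
    fits = {k: _fit_score(scores[k].to_numpy(), zc) for k in ("G", "C", "T", "X")}
    effects = pd.DataFrame([
        _effect_row("condition", fits["C"], 0),
        _effect_row("time", fits["T"], 0),
        _effect_row("condition_x_time", fits["X"], 0),
        _effect_row("iu", fits["G"], 1),
        _effect_row("condition_x_iu", fits["C"], 1),
        _effect_row("time_x_iu", fits["T"], 1),
        _effect_row("condition_x_time_x_iu", fits["X"], 1),
    ])

    cell_fits = {c: _fit_score(cells[c].to_numpy(dtype=float), zc)
                 for c in CELLS_2X2}
    emm_rows = []
    for label, z in (("-1sd", -sd), ("mean", 0.0), ("+1sd", sd)):
        for c in CELLS_2X2:
            est, se = cell_fits[c].at(z)
            emm_rows.append({"iu_level": label, "cell": c,
                             "estimate": est, "se": se})
    emm = pd.DataFrame(emm_rows)

    diffs = build_difference_scores(cells)
    difference_fits = {name: _fit_score(diffs[name].to_numpy(), zc)
                       for name in DIFFERENCE_SCORES}
    result = RmAncovaResult(n=n, covariate_sd=sd, effects=effects, emm=emm,
                            contrasts=pd.DataFrame(), cell_fits=cell_fits,
                            difference_fits=difference_fits)
    result.contrasts = simple_slope_contrasts(result, (-1.0, 0.0, 1.0))
    return result


def simple_slope_contrasts(result: RmAncovaResult,
                           at_sd=(-1.0, 1.0)) -> pd.DataFrame:
    """Pairwise follow-up contrasts at chosen moderator values.

    ``at_sd`` lists moderator positions in SD units (e.g. -1, +1).  For each
    position the four difference scores (CS+ vs CS- within each time; early
    vs late within each condition) are evaluated on the fitted regression
    line with a t test on n - 2 df.
    """
    rows = []
    for mult in at_sd:
        z = mult * result.covariate_sd
        label = "mean" if mult == 0 else f"{mult:+g}sd"
        for name, fit in result.difference_fits.items():
            est, se = fit.at(z)
            t = est / se if se > 0 else np.inf * np.sign(est)
            rows.append({
                "iu_level": label, "iu_sd_multiple": mult, "contrast": name,
                "estimate": est, "se": se, "t": float(t),
                "df": fit.df_resid,
                "p": float(2 * sstats.t.sf(abs(t), fit.df_resid)),
            })
    return pd.DataFrame(rows)


def fit_condition_ancova(cells: pd.DataFrame, covariate,
                         csplus_col: str = "acquisition_csplus",
                         csminus_col: str = "acquisition_csminus",
                         ) -> RmAncovaResult:
    """Condition x moderator ANCOVA for a single-factor (acquisition) phase.

    Effects: condition, iu (between), condition_x_iu; df = (1, n - 2).
    """
    cov = np.asarray(covariate, dtype=float)
    n = len(cells)
    if n < 4:
        raise InsufficientDataError(f"n={n} subjects; need at least 4")
    zc = mean_center(cov)
    sd = float(np.std(cov, ddof=1))
    plus = cells[csplus_col].to_numpy(dtype=float)
    minus = cells[csminus_col].to_numpy(dtype=float)
    fits = {"G": _fit_score((plus + minus) / 2.0, zc),
            "C": _fit_score(plus - minus, zc)}
    effects = pd.DataFrame([
        _effect_row("condition", fits["C"], 0),
        _effect_row("iu", fits["G"], 1),
        _effect_row("condition_x_iu", fits["C"], 1),
    ])
    emm_rows = []
    cell_fits = {csplus_col: _fit_score(plus, zc),
                 csminus_col: _fit_score(minus, zc)}
    for label, z in (("-1sd", -sd), ("mean", 0.0), ("+1sd", sd)):
        for c, fit in cell_fits.items():
            est, se = fit.at(z)
            emm_rows.append({"iu_level": label, "cell": c,
                             "estimate": est, "se": se})
    return RmAncovaResult(n=n, covariate_sd=sd, effects=effects,
                          emm=pd.DataFrame(emm_rows), contrasts=pd.DataFrame(),
                          cell_fits=cell_fits,
                          difference_fits={"csplus_minus_csminus": fits["C"]})


def build_difference_scores(cells: pd.DataFrame) -> pd.DataFrame:
    """The four named follow-up difference scores from the 2x2 cells."""
    missing = [c for c in CELLS_2X2 if c not in cells.columns]
    if missing:
        raise MissingCellError(f"missing cell column(s) {missing}")
    out = {}
    for name, terms in DIFFERENCE_SCORES.items():
        acc = np.zeros(len(cells))
        for col, w in terms:
            acc = acc + w * cells[col].to_numpy(dtype=float)
        out[name] = acc
    frame = pd.DataFrame(out)
    if "subject_id" in cells.columns:
        frame.insert(0, "subject_id", cells["subject_id"].to_numpy())
    return frame


# ---------------------------------------------------------------------------
# hierarchical regression

@dataclass
class HierRegStep:
    predictors: list[str]
    r_squared: float
    f: float
    df: tuple[int, int]
    p: float
    coefficients: pd.DataFrame  # predictor, B, SE_B, beta
    delta_r_sq: float
    f_change: float
    p_change: float


@dataclass
class HierRegResult:
    n: int
    steps: list[HierRegStep]

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.steps, start=1):
            for _, c in s.coefficients.iterrows():
                rows.append({
                    "step": i, "predictor": c["predictor"], "B": c["B"],
                    "SE_B": c["SE_B"], "beta": c["beta"],
                    "R2": s.r_squared, "F": s.f, "delta_R2": s.delta_r_sq,
                    "F_change": s.f_change, "p_change": s.p_change,
                })
        return pd.DataFrame(rows)


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify offending columns incrementally
    bad = []
    kept = X[:, :1]
    for j in range(1, X.shape[1]):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(names[j - 1])
        else:
            kept = cand
    raise RankDeficiencyError(
        f"design matrix is rank deficient; offending column(s): {bad}",
        columns=bad)


def hierarchical_regression(y, steps: list[pd.DataFrame]) -> HierRegResult:
    """OLS regression with predictors entered in nested steps.

    ``steps`` lists DataFrames of predictors; step k uses all predictors of
    steps 1..k.  Reports per step: R^2, overall F, unstandardized B with SE,
    standardized beta, and the step's delta R^2 with its F-change test.
    Raises :class:`RankDeficiencyError` naming collinear columns.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    frames = []
    for s in steps:
        frames.append(s.reset_index(drop=True))
    full = pd.concat(frames, axis=1)
    if full.isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values; provide complete cases")
    if n <= full.shape[1] + 1:
        raise InsufficientDataError(
            f"n={n} with {full.shape[1]} predictors; need n > k + 1")
    names = list(full.columns)
    X_all = sm.add_constant(full.to_numpy(dtype=float))
    _check_rank(X_all, names)

    sd_y = float(np.std(y, ddof=1))
    results: list[HierRegStep] = []
    prev_r2 = 0.0
    prev_k = 0
    used: list[str] = []
    for s in steps:
        used += list(s.columns)
        Xk = sm.add_constant(full[used].to_numpy(dtype=float))
        res = sm.OLS(y, Xk).fit()
        k = len(used)
        r2 = float(res.rsquared)
        dk = k - prev_k
        f_change = ((r2 - prev_r2) * (n - k - 1)) / ((1.0 - r2) * dk) \
            if r2 < 1.0 else float("inf")
        p_change = float(sstats.f.sf(f_change, dk, n - k - 1)) \
            if np.isfinite(f_change) else 0.0
        betas = [float(res.params[j + 1] * np.std(full[c], ddof=1) / sd_y)
                 for j, c in enumerate(used)]
        coef = pd.DataFrame({
            "predictor": used,
            "B": np.asarray(res.params[1:], dtype=float),
            "SE_B": np.asarray(res.bse[1:], dtype=float),
            "beta": betas,
        })
        results.append(HierRegStep(
            predictors=list(used), r_squared=r2, f=float(res.fvalue),
            df=(int(res.df_model), int(res.df_resid)),
            p=float(res.f_pvalue), coefficients=coef,
            delta_r_sq=delta_r_squared(r2, prev_r2),
            f_change=float(f_change), p_change=p_change))
        prev_r2, prev_k = r2, k
    return HierRegResult(n=n, steps=results)


# ---------------------------------------------------------------------------
# vectorized simple regressions for simulation studies

def batch_simple_regression(Y: np.ndarray, Z: np.ndarray) -> dict:
    """OLS of y on (1, z) for many replicates at once.

    ``Y`` and ``Z`` have shape (n_replicates, n).  ``Z`` is centered per
    replicate, so intercept and slope estimates are uncorrelated.  Returns
    arrays b0, b1, se0, se1, t1, p1 and the residual df.
    """
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n = Y.shape[1]
    zc = Z - Z.mean(axis=1, keepdims=True)
    szz = np.sum(zc ** 2, axis=1)
    ybar = Y.mean(axis=1)
    b1 = np.sum(zc * (Y - ybar[:, None]), axis=1) / szz
    b0 = ybar
    resid = Y - b0[:, None] - b1[:, None] * zc
    df = n - 2
    s2 = np.sum(resid ** 2, axis=1) / df
    se0 = np.sqrt(s2 / n)
    se1 = np.sqrt(s2 / szz)
    t1 = b1 / se1
    return {"b0": b0, "b1": b1, "se0": se0, "se1": se1,
            "t1": t1, "p1": 2 * sstats.t.sf(np.abs(t1), df), "df": df}


def batch_estimate_at(reg: dict, z: np.ndarray):
    """Estimate, SE, t and p of b0 + b1*z for each replicate (z per-rep)."""
    est = reg["b0"] + reg["b1"] * z
    se = np.sqrt(reg["se0"] ** 2 + z ** 2 * reg["se1"] ** 2)
    t = est / se
    p = 2 * sstats.t.sf(np.abs(t), reg["df"])
    return est, se, t, p
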