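"""Empirically ordered all-subsets regression (REVS) with a diagnostic battery.

With only a handful of census years and hundreds of candidate lagged
predictors, naive stepwise selection mines noise.  The procedure here
mirrors careful small-n practice:

1. *screen* every lagged predictor by Pearson correlation with the
   (log-transformed) response, keeping P < 0.05 and dropping predictors
   whose significance flips when any single year is left out (an automated
   stand-in for visual outlier assessment);
2. *group* the survivors by hierarchical clustering of 1 - |r| and cut at
   the 0.70 collinearity threshold, culling each group to its 4 members
   most correlated with the response (location statistics preferred over
   dispersion statistics);
3. for every combination taking one predictor per group, run *REVS*:
   exhaustive all-subsets OLS, rank predictors by how often they appear in
   the best model of each size, and emit the nested candidate sequence that
   adds predictors in importance order;
4. subject every candidate to a *diagnostic battery* (VIF, Mallows Cp,
   Shapiro-Wilk, Breusch-Pagan, Durbin-Watson, Cook's distance) plus AICc
   weights and leave-one-out cross-validation;
5. *select* among diagnostics-passing candidates by LOOCV RMSE, tie-broken
   by AICc, preferring location-statistic predictors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenResult",
    "CandidateModel",
    "DiagnosticThresholds",
    "screen",
    "collinearity_groups",
    "all_subsets",
    "revs",
    "fit_candidate",
    "diagnostics",
    "aicc_weights",
    "loocv_rmse",
    "select_best",
    "search",
]

DISPERSION_MARKERS = ("sdRWE", "mxRWE")  # dispersion statistics; location preferred


def _is_location(label: str) -> bool:
    return not any(label.startswith(m) for m in DISPERSION_MARKERS)


@dataclass
class ScreenResult:
    label: str
    r: float
    p: float
    n: int
    sign_flip: bool = False
    significance_flip: bool = False
    leverage_concentration: bool = False

    @property
    def stable(self) -> bool:
        return not (self.sign_flip or self.significance_flip or self.leverage_concentration)


LEVERAGE_SHARE_MAX = 0.5  # one year may carry at most half the predictor's spread


def _leverage_concentrated(x: np.ndarray) -> bool:
    """True when a single observation dominates the dispersion along the
    abscissa (its squared deviation exceeds half the total), the automated
    analogue of rejecting correlations driven by one extreme year."""
    d2 = (x - x.mean()) ** 2
    tot = d2.sum()
    return bool(tot > 0 and d2.max() / tot > LEVERAGE_SHARE_MAX)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _corr_pvals(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r and two-tailed P against a common response."""
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip((xc * yc[:, None]).sum(axis=0) / (sx * sy), -1, 1)
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return r, p


def screen(features: pd.DataFrame, response: pd.Series, alpha: float = 0.05) -> list[ScreenResult]:
    """Pearson screening with a leave-one-year-out stability filter.

    Returns results for predictors with P < alpha whose significance (and
    sign) survives removal of any single observation.  Constant predictors
    are excluded up front.
    """
    results: list[ScreenResult] = []
    complete = features.loc[response.dropna().index].notna().all(axis=0)
    y = response.dropna()

    # fast vectorized path over columns with no missing years
    fast_cols = [c for c in features.columns if complete[c]]
    if fast_cols:
        X = features.loc[y.index, fast_cols].to_numpy(dtype=float)
        yv = y.to_numpy(dtype=float)
        keep = np.ptp(X, axis=0) > 0
        r_all, p_all = _corr_pvals(X, yv)
        cand = np.nonzero(keep & (p_all < alpha))[0]
        n = len(yv)
        for j in cand:
            r, p = float(r_all[j]), float(p_all[j])
            sign_flip = sig_flip = False
            for i in range(n):
                sub = np.delete(X[:, j], i)
                if np.ptp(sub) == 0:
                    sig_flip = True
                    break
                ri, pi = _corr_pvals(sub[:, None], np.delete(yv, i))
                if np.sign(ri[0]) != np.sign(r):
                    sign_flip = True
                if pi[0] >= alpha:
                    sig_flip = True
            results.append(ScreenResult(fast_cols[j], r, p, n, sign_flip, sig_flip,
                                        _leverage_concentrated(X[:, j])))

    for label in (c for c in features.columns if not complete[c]):
        pair = pd.DataFrame({"x": features[label], "y": response}).dropna()
        n = len(pair)
        if n < 4:
            continue
        x, yv = pair["x"].to_numpy(), pair["y"].to_numpy()
        if np.ptp(x) == 0:
            continue
        r, p = _pearson(x, yv)
        if p >= alpha:
            continue
        sign_flip = sig_flip = False
        for i in range(n):
            keep_i = np.arange(n) != i
            if np.ptp(x[keep_i]) == 0:
                sig_flip = True
                break
            ri, pi = _pearson(x[keep_i], yv[keep_i])
            if np.sign(ri) != np.sign(r):
                sign_flip = True
            if pi >= alpha:
                sig_flip = True
        results.append(ScreenResult(label, r, p, n, sign_flip, sig_flip,
                                    _leverage_concentrated(x)))
    order = {c: k for k, c in enumerate(features.columns)}
    return sorted((res for res in results if res.stable), key=lambda s: order[s.label])


def _windows_overlap(a: str, b: str) -> bool:
    """Same-variable lag windows sharing any month are temporally redundant."""
    try:
        from .lagfeat import parse_label

        sa, sb = parse_label(a), parse_label(b)
    except ValueError:
        return False
    if sa.variable != sb.variable:
        return False
    return not (sa.end_offset > sb.start_offset or sb.end_offset > sa.start_offset)


def collinearity_groups(
    screened: list[ScreenResult], features: pd.DataFrame,
    threshold: float = 0.70, max_per_group: int = 4,
) -> list[list[str]]:
    """Group screened predictors by |r| >= threshold via UPGMA on 1 - |r|,
    then cull each group to the ``max_per_group`` members most correlated
    with the response, preferring location over dispersion statistics.

    Same-variable windows that overlap in time are forced into one group
    (temporal redundancy) regardless of their sample correlation.
    """
    if not screened:
        raise ValueError("no screened predictors to group")
    labels = [s.label for s in screened]
    if len(labels) == 1:
        return [labels]
    X = features[labels].dropna()
    corr = np.abs(np.corrcoef(X.to_numpy(), rowvar=False))
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    dist = 1.0 - corr
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if _windows_overlap(labels[i], labels[j]):
                dist[i, j] = dist[j, i] = 0.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(Z, t=1.0 - threshold, criterion="distance")

    by_resp = {s.label: abs(s.r) for s in screened}
    groups: list[list[str]] = []
    for g in np.unique(assign):
        members = [labels[i] for i in np.nonzero(assign == g)[0]]
        members.sort(key=lambda l: (not _is_location(l), -by_resp[l]))
        groups.append(members[:max_per_group])
    return groups


@dataclass
class CandidateModel:
    """A fitted OLS candidate with its diagnostics."""

    predictors: tuple[str, ...]
    params: pd.Series
    cov: pd.DataFrame
    adj_r2: float
    r2: float
    aic: float
    aicc: float
    resid_var: float
    nobs: int
    vif: dict[str, float]
    cp: float
    shapiro_p: float
    bp_p: float
    dw: float
    max_cooks_d: float
    loocv_rmse: float
    loocv_se: float
    f_pvalue: float
    diag_pass: bool = False
    diag_fail_reasons: tuple[str, ...] = ()
    aicc_weight: float = float("nan")

    @property
    def k(self) -> int:
        """Parameter count for AICc: slopes + intercept + error variance."""
        return len(self.predictors) + 2


@dataclass(frozen=True)
class DiagnosticThresholds:
    """Pass/fail cutoffs for the battery (standard-practice defaults)."""

    vif_max: float = 10.0
    cp_band: float = 2.0  # |Cp - (p + 1)| <= band
    shapiro_alpha: float = 0.05
    bp_alpha: float = 0.05
    dw_range: tuple[float, float] = (1.0, 3.0)
    cooks_max: float = 1.0


def _design(features: pd.DataFrame, predictors: tuple[str, ...]) -> np.ndarray:
    X = features[list(predictors)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def _ols(X: np.ndarray, y: np.ndarray):
    """Plain least squares with hat diagonal; returns (beta, resid, hat, XtX_inv)."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    hat = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    return beta, resid, hat, XtX_inv


def loocv_rmse(features: pd.DataFrame, response: pd.Series, predictors: tuple[str, ...],
               check_identity: bool = False, return_se: bool = False):
    """Leave-one-out prediction RMSE via the hat-matrix shortcut
    sqrt(mean((e_i / (1 - h_ii))^2)); optionally verified against explicit
    single-holdout refits."""
    df = pd.concat([features[list(predictors)], response.rename("__y")], axis=1).dropna()
    y = df["__y"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), df[list(predictors)].to_numpy(dtype=float)])
    n, p1 = X.shape
    if n < p1 + 1:
        raise ValueError(f"LOOCV needs n >= k + 2 (n={n}, predictors={len(predictors)})")
    _, resid, hat, _ = _ols(X, y)
    press_terms = (resid / (1.0 - hat)) ** 2
    rmse = float(np.sqrt(press_terms.mean()))
    if return_se:
        # delta-method SE of the RMSE from the spread of per-holdout squared errors
        se_mse = float(press_terms.std(ddof=1) / np.sqrt(n))
        se = se_mse / (2.0 * rmse) if rmse > 0 else 0.0
        return rmse, se
    if check_identity:
        errs = []
        for i in range(n):
            keep = np.arange(n) != i
            if np.linalg.matrix_rank(X[keep]) < p1:
                raise ValueError(f"holdout {i} leaves a rank-deficient design")
            b = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            errs.append(y[i] - X[i] @ b)
        explicit = float(np.sqrt(np.mean(np.square(errs))))
        if not np.isclose(rmse, explicit, rtol=1e-10, atol=1e-12):
            raise AssertionError("hat-matrix LOOCV shortcut disagrees with explicit refits")
    return rmse


def fit_candidate(
    features: pd.DataFrame, response: pd.Series, predictors: tuple[str, ...],
    sigma2_full: float | None = None,
) -> CandidateModel:
    """Fit one OLS candidate and compute the full diagnostic set.

    ``sigma2_full`` is the residual variance of the largest model in the
    combination, used by Mallows Cp; defaults to this model's own (making
    Cp = p + 1 trivially when no fuller model exists).
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan
    from statsmodels.stats.outliers_influence import OLSInfluence
    from statsmodels.stats.stattools import durbin_watson

    df = pd.concat([features[list(predictors)], response.rename("__y")], axis=1).dropna()
    y = df["__y"]
    n, p = len(df), len(predictors)
    if n - p - 2 < 1:
        raise ValueError(f"model with {p} predictors unfittable at n={n}")
    X = sm.add_constant(df[list(predictors)].astype(float), has_constant="add")
    res = sm.OLS(y, X).fit()

    vif = {}
    Xp = df[list(predictors)].to_numpy(dtype=float)
    for j, lab in enumerate(predictors):
        if p == 1:
            vif[lab] = 1.0
        else:
            others = np.column_stack([np.ones(n), np.delete(Xp, j, axis=1)])
            bj = np.linalg.lstsq(others, Xp[:, j], rcond=None)[0]
            r2j = 1 - np.sum((Xp[:, j] - others @ bj) ** 2) / max(
                np.sum((Xp[:, j] - Xp[:, j].mean()) ** 2), 1e-300)
            vif[lab] = float(1.0 / max(1 - r2j, 1e-12))

    rss = float(res.ssr)
    s2 = sigma2_full if sigma2_full is not None else float(res.mse_resid)
    cp = rss / s2 - n + 2 * (p + 1)

    std_resid = OLSInfluence(res).resid_studentized_internal
    shapiro_p = float(stats.shapiro(std_resid).pvalue)
    bp_p = float(het_breuschpagan(res.resid, X.to_numpy())[1])
    dw = float(durbin_watson(res.resid))
    cooks = OLSInfluence(res).cooks_distance[0]

    k = p + 2
    aic = float(res.aic)
    aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else float("inf")

    return CandidateModel(
        predictors=tuple(predictors), params=res.params, cov=res.cov_params(),
        adj_r2=float(res.rsquared_adj), r2=float(res.rsquared), aic=aic, aicc=aicc,
        resid_var=float(res.mse_resid), nobs=n, vif=vif, cp=float(cp),
        shapiro_p=shapiro_p, bp_p=bp_p, dw=dw,
        max_cooks_d=float(np.max(cooks)),
        loocv_rmse=(lv := loocv_rmse(features, response, tuple(predictors), return_se=True))[0],
        loocv_se=lv[1],
        f_pvalue=float(res.f_pvalue),
    )


def diagnostics(model: CandidateModel, thresholds: DiagnosticThresholds | None = None) -> CandidateModel:
    """Apply the pass/fail battery; returns the model with flags set."""
    t = thresholds or DiagnosticThresholds()
    reasons = []
    if model.vif and max(model.vif.values()) >= t.vif_max:
        reasons.append("multicollinearity (VIF)")
    if abs(model.cp - (len(model.predictors) + 1)) > t.cp_band:
        reasons.append("model bias (Mallows Cp)")
    if model.shapiro_p <= t.shapiro_alpha:
        reasons.append("residual non-normality (Shapiro-Wilk)")
    if model.bp_p <= t.bp_alpha:
        reasons.append("heteroscedasticity (Breusch-Pagan)")
    if not (t.dw_range[0] <= model.dw <= t.dw_range[1]):
        reasons.append("residual autocorrelation (Durbin-Watson)")
    if model.max_cooks_d >= t.cooks_max:
        reasons.append("outlier influence (Cook's D)")
    model.diag_pass = not reasons
    model.diag_fail_reasons = tuple(reasons)
    return model


def all_subsets(
    features: pd.DataFrame, response: pd.Series, predictors: list[str],
) -> dict[int, tuple[tuple[str, ...], float]]:
    """Best subset (by R^2) of every size; exhaustive enumeration."""
    df = pd.concat([features[predictors], response.rename("__y")], axis=1).dropna()
    y = df["__y"].to_numpy(dtype=float)
    n = len(df)
    best: dict[int, tuple[tuple[str, ...], float]] = {}
    tss = float(np.sum((y - y.mean()) ** 2))
    for size in range(1, len(predictors) + 1):
        if size > n - 2:
            break
        for combo in itertools.combinations(predictors, size):
            X = np.column_stack([np.ones(n), df[list(combo)].to_numpy(dtype=float)])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r2 = 1.0 - float(np.sum((y - X @ beta) ** 2)) / tss
            if size not in best or r2 > best[size][1]:
                best[size] = (combo, r2)
    return best


def _importance_order(
    features: pd.DataFrame, response: pd.Series, predictors: list[str],
) -> list[str]:
    """REVS importance: frequency of appearance among best-of-size subsets,
    ties broken by mean |standardized coefficient| across those subsets."""
    best = all_subsets(features, response, predictors)
    freq = {p: 0 for p in predictors}
    std_coefs: dict[str, list[float]] = {p: [] for p in predictors}
    df = pd.concat([features[predictors], response.rename("__y")], axis=1).dropna()
    y = df["__y"].to_numpy(dtype=float)
    sy = y.std(ddof=1)
    for combo, _ in best.values():
        X = np.column_stack([np.ones(len(df)), df[list(combo)].to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        for j, lab in enumerate(combo):
            freq[lab] += 1
            sx = df[lab].std(ddof=1)
            std_coefs[lab].append(abs(beta[j + 1]) * sx / sy if sy > 0 else 0.0)
    mean_std = {p: (np.mean(v) if v else 0.0) for p, v in std_coefs.items()}
    return sorted(predictors, key=lambda p: (-freq[p], -mean_std[p], p))


def _budget_groups(
    groups: list[list[str]], features: pd.DataFrame, response: pd.Series,
    max_combinations: int,
) -> list[list[str]]:
    """Deterministically truncate groups so the one-per-group combination
    count stays within budget: groups are ranked by their best member's |r|
    with the response and the least relevant are reduced toward their top
    member first."""
    rel = {}
    for g in groups:
        rs = []
        for lab in g:
            pair = pd.DataFrame({"x": features[lab], "y": response}).dropna()
            rs.append(abs(_pearson(pair["x"].to_numpy(), pair["y"].to_numpy())[0]))
        rel[tuple(g)] = max(rs)
    ordered = sorted(groups, key=lambda g: -rel[tuple(g)])
    out, product = [], 1
    for g in ordered:
        allow = max(1, max_combinations // product)
        take = min(len(g), allow)
        if take < len(g):
            warnings.warn(
                f"group {g} truncated to its top {take} member(s) to respect the "
                f"combination budget ({max_combinations})")
        out.append(g[:take])
        product *= take
    return out


def revs(
    groups: list[list[str]], features: pd.DataFrame, response: pd.Series,
    thresholds: DiagnosticThresholds | None = None,
    max_combinations: int = 256,
    max_groups: int = 6,
) -> list[CandidateModel]:
    """Empirically ordered all-subsets regression over every combination of
    one predictor per collinearity group.

    For each combination the predictors are ranked by all-subsets importance
    and the nested model sequence (top-1, top-2, ...) is fit; candidates are
    pooled across combinations, deduplicated, diagnosed, and AICc-weighted.
    Combinations with more predictors than n - 2 are skipped with a warning;
    group membership is truncated deterministically (most response-relevant
    first) if the combination count would exceed ``max_combinations``.
    """
    n = len(features)
    if len(groups) > max_groups:
        # keep the most response-relevant groups; the rest never had an
        # analogue in the original few-group setting
        ranked = _budget_groups(groups, features, response, max_combinations=10**9)
        groups = ranked[:max_groups]
        warnings.warn(f"{len(ranked) - max_groups} least-relevant collinearity "
                      f"group(s) dropped to keep the subset search exhaustive")
    if int(np.prod([len(g) for g in groups])) > max_combinations:
        groups = _budget_groups(groups, features, response, max_combinations)
    seen: set[tuple[str, ...]] = set()
    candidates: list[CandidateModel] = []
    for combo in itertools.product(*groups):
        combo = list(dict.fromkeys(combo))
        if len(combo) > n - 2:
            warnings.warn(f"combination {combo} has p > n - 2; skipped")
            continue
        order = _importance_order(features, response, combo)
        sigma2_full = None
        try:
            full = fit_candidate(features, response, tuple(order))
            sigma2_full = full.resid_var
        except ValueError:
            pass
        for depth in range(1, len(order) + 1):
            key = tuple(sorted(order[:depth]))
            if key in seen:
                continue
            seen.add(key)
            try:
                m = fit_candidate(features, response, tuple(order[:depth]), sigma2_full)
            except ValueError as exc:
                warnings.warn(str(exc))
                continue
            candidates.append(diagnostics(m, thresholds))
    candidates.sort(key=lambda m: -m.adj_r2)
    for m, w in zip(candidates, aicc_weights(candidates)):
        m.aicc_weight = w
    return candidates


def aicc_weights(models: list[CandidateModel]) -> np.ndarray:
    """Akaike weights from AICc differences: w_i = exp(-d_i/2) / sum exp(-d_j/2).
    Models with an undefined correction (n - k - 1 <= 0) get weight 0 with a flag."""
    aiccs = np.array([m.aicc for m in models], dtype=float)
    finite = np.isfinite(aiccs)
    if not finite.any():
        return np.full(len(models), np.nan)
    if not finite.all():
        warnings.warn("models with n - k - 1 <= 0 excluded from the AICc weight set")
    d = aiccs - np.nanmin(aiccs[finite])
    w = np.where(finite, np.exp(-d / 2.0), 0.0)
    return w / w.sum()


def select_best(models: list[CandidateModel]) -> tuple[CandidateModel, pd.DataFrame]:
    """Among diagnostics-passing candidates: lowest LOOCV RMSE under the
    one-standard-error rule — candidates within one SE (of the best model's
    cross-validation score) of the best RMSE are treated as ties and resolved
    by parsimony (fewest predictors), then AICc, then a preference for
    all-location-statistic predictor sets.  Returns the winner and the full
    audit ranking."""
    passers = [m for m in models if m.diag_pass]
    if not passers:
        fails = {m.predictors: m.diag_fail_reasons for m in models}
        raise ValueError(f"no candidate passed diagnostics; failure modes: {fails}")
    champion = min(passers, key=lambda m: m.loocv_rmse)
    band = champion.loocv_rmse + champion.loocv_se
    ranked = sorted(passers, key=lambda m: (
        m.loocv_rmse > band, len(m.predictors) if m.loocv_rmse <= band else 0,
        round(m.loocv_rmse, 12), round(m.aicc, 12),
        sum(not _is_location(p) for p in m.predictors),
    ))
    audit = pd.DataFrame([{
        "predictors": "+".join(m.predictors), "adj_r2": m.adj_r2, "aicc": m.aicc,
        "aicc_weight": m.aicc_weight, "loocv_rmse": m.loocv_rmse,
        "diag_pass": m.diag_pass, "fail_reasons": "; ".join(m.diag_fail_reasons),
    } for m in sorted(models, key=lambda m: m.loocv_rmse)])
    return ranked[0], audit


def write_candidate_ledger(models: list[CandidateModel], path) -> None:
    """One CSV row per candidate: predictors, diagnostics, AICc, weight, LOOCV."""
    rows = [{
        "predictors": "+".join(m.predictors), "n_predictors": len(m.predictors),
        "adj_r2": m.adj_r2, "r2": m.r2, "aic": m.aic, "aicc": m.aicc,
        "aicc_weight": m.aicc_weight, "cp": m.cp, "max_vif": max(m.vif.values()),
        "shapiro_p": m.shapiro_p, "bp_p": m.bp_p, "dw": m.dw,
        "max_cooks_d": m.max_cooks_d, "loocv_rmse": m.loocv_rmse,
        "diag_pass": m.diag_pass, "fail_reasons": "; ".join(m.diag_fail_reasons),
    } for m in models]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_selection_report(best: CandidateModel, path) -> None:
    import json

    payload = {
        "predictors": list(best.predictors),
        "coefficients": {k: float(v) for k, v in best.params.items()},
        "adj_r2": best.adj_r2, "aicc": best.aicc, "aicc_weight": best.aicc_weight,
        "loocv_rmse": best.loocv_rmse, "nobs": best.nobs,
        "diagnostics": {
            "vif": best.vif, "cp": best.cp, "shapiro_p": best.shapiro_p,
            "bp_p": best.bp_p, "durbin_watson": best.dw,
            "max_cooks_d": best.max_cooks_d, "pass": best.diag_pass,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def search(
    features: pd.DataFrame, response: pd.Series,
    alpha: float = 0.05, threshold: float = 0.70, max_per_group: int = 4,
    thresholds: DiagnosticThresholds | None = None,
    max_combinations: int = 256, max_groups: int = 6,
) -> tuple[CandidateModel, pd.DataFrame, list[CandidateModel]]:
    """Full chain: screen -> collinearity groups -> REVS -> select."""
    screened = screen(features, response, alpha)
    if not screened:
        raise ValueError("no predictor survived screening")
    groups = collinearity_groups(screened, features, threshold, max_per_group)
    candidates = revs(groups, features, response, thresholds, max_combinations, max_groups)
    best, audit = select_best(candidates)
    return best, audit, candidates
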