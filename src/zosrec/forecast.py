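"""Recruitment forecasts from selected (or published) regression models.

A :class:`ForecastModel` is a linear model of log recruitment rate (natural
logarithm throughout — note this choice rescales natural-scale predictions)
on named lagged predictors.  ``published_nsd_model`` and ``published_rsd_model``
reproduce the published coefficient sets:

    log(NSD) = -8.72710*10C_p1yNOS + 0.00139*rain_p2yJDN
               + 8.48952*eastness_p36mo - 4.37839
    log(RSD) = -0.23381*d16000_pAprToNov - 0.54899*mWindSpd_pMay
               - 0.00107*d2000_pFeb + 8.07992

Predictions carry 95% confidence intervals (uncertainty of the fitted mean)
and prediction intervals (plus residual scatter) when the model's estimate
covariance and residual variance are known; inputs outside the observed
monthly ranges (the Table-1 validity envelope) are flagged, never refused.
"""

from __future__ import annotations

import argparse
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lagfeat import parse_label

__all__ = [
    "ForecastModel",
    "Prediction",
    "published_nsd_model",
    "published_rsd_model",
    "predict",
    "relative_importance",
    "envelope_check",
    "TABLE1_RANGES",
    "main",
]

# Observed 2004-2014 monthly ranges (validity envelope); variable -> 12 x (lo, hi).
_Z = (0.0, 0.0)
TABLE1_RANGES: dict[str, list[tuple[float, float]]] = {
    "25C": [_Z, _Z, _Z, _Z, _Z, _Z, (0, .52), (0, .52), (0, .13), (0, .07), _Z, _Z],
    "20C": [_Z, _Z, _Z, _Z, (0, .10), (.10, .60), (.90, 1), (.87, 1), (.18, .90), (0, .33), _Z, _Z],
    "optimal": [(0, .16), _Z, (0, .19), (.03, .60), (.77, 1), (.40, .90), (0, .10), (0, .13),
                (.10, .82), (.53, 1), (.50, .93), (.03, .35)],
    "10C": [(.84, 1), (1, 1), (.81, 1), (.40, .97), (0, .23), _Z, _Z, _Z, (0, .07), (0, .14),
            (.07, .50), (.65, .97)],
    "5C": [(.32, .92), (.48, .96), (.16, .90), (0, .23), _Z, _Z, _Z, _Z, _Z, _Z, (0, .07), (.06, .68)],
    "0C": [(0, .32), (0, .18), (0, .13), _Z, _Z, _Z, _Z, _Z, _Z, _Z, _Z, _Z],
    "rain": [(553, 1065), (320, 1580), (253, 2391), (389, 1852), (380, 1494), (314, 2241),
             (532, 1655), (67, 2939), (333, 1896), (56, 3574), (486, 1160), (545, 2242)],
    "eastness": [(-.51, -.11), (-.59, -.14), (-.43, .11), (-.37, .17), (-.29, .21), (-.33, .19),
                 (-.44, -.00), (-.24, .02), (-.26, .18), (-.34, .04), (-.40, .05), (-.51, -.17)],
    "northness": [(.02, .46), (.04, .39), (-.04, .45), (-.25, .20), (-.35, .16), (-.51, -.01),
                  (-.54, -.13), (-.40, .01), (-.19, .14), (-.18, .31), (-.18, .48), (-.03, .37)],
    "mWindSpd": [(4, 5), (5, 6), (4, 6), (4, 5), (4, 5), (3, 4), (3, 4), (3, 4), (4, 4), (4, 5),
                 (4, 5), (4, 6)],
    "mRWE": [(318, 603), (428, 1057), (292, 967), (232, 635), (165, 763), (119, 424), (51, 224),
             (49, 195), (69, 262), (120, 652), (174, 677), (255, 794)],
    "sdRWE": [(93, 227), (131, 465), (99, 383), (55, 208), (42, 278), (23, 125), (13, 58),
              (13, 54), (13, 69), (28, 243), (44, 249), (65, 296)],
    "mxRWE": [(425, 853), (605, 1556), (402, 1376), (283, 846), (220, 1065), (141, 549),
              (74, 283), (69, 290), (88, 367), (146, 924), (252, 941), (321, 1115)],
    "a_mRWE": [(309, 624), (381, 1126), (279, 1023), (233, 653), (141, 792), (119, 424),
               (43, 221), (43, 195), (62, 231), (120, 689), (152, 704), (251, 837)],
    "b_mRWE": [(280, 520), (405, 847), (268, 779), (221, 581), (149, 663), (123, 400), (44, 207),
               (42, 189), (69, 254), (113, 541), (175, 586), (237, 655)],
    "c_mRWE": [(355, 697), (451, 1291), (333, 1169), (253, 733), (176, 905), (122, 471),
               (59, 252), (57, 208), (73, 262), (133, 785), (168, 795), (283, 952)],
    "d_mRWE": [(397, 793), (543, 1450), (377, 1294), (272, 802), (209, 994), (131, 523),
               (63, 269), (60, 236), (78, 319), (140, 856), (209, 885), (305, 1044)],
    "e_mRWE": [(195, 257), (235, 384), (134, 350), (135, 313), (113, 304), (86, 248), (38, 160),
               (36, 171), (59, 203), (95, 268), (139, 290), (190, 340)],
    "f_mRWE": [(18, 28), (22, 34), (21, 32), (23, 32), (20, 31), (18, 28), (10, 24), (16, 27),
               (18, 25), (16, 31), (20, 31), (23, 33)],
    "d2000": [(266, 488), (411, 876), (333, 758), (186, 495), (143, 590), (92, 328), (70, 198),
              (90, 203), (95, 287), (101, 567), (181, 502), (225, 631)],
    "d4000": [(147, 270), (175, 458), (159, 435), (126, 293), (96, 376), (62, 190), (37, 198),
              (52, 261), (87, 352), (44, 634), (121, 477), (115, 345)],
    "d6000": [(67, 106), (78, 195), (60, 148), (52, 124), (51, 145), (32, 88), (17, 80),
              (23, 113), (34, 117), (24, 204), (61, 174), (55, 135)],
    "d8000": [(119, 171), (134, 253), (119, 226), (78, 167), (62, 177), (47, 117), (28, 87),
              (38, 94), (47, 133), (37, 218), (88, 186), (88, 199)],
    "d10000": [(88, 138), (101, 242), (85, 209), (67, 144), (59, 189), (36, 105), (22, 95),
               (27, 125), (44, 172), (29, 277), (77, 226), (65, 175)],
    "d12000": [(43, 79), (54, 131), (48, 137), (41, 77), (31, 126), (18, 61), (12, 60), (16, 82),
               (27, 123), (15, 177), (36, 138), (35, 111)],
    "d14000": [(7, 11), (8, 20), (6, 19), (8, 19), (6, 15), (3, 9), (2, 9), (3, 13), (5, 15),
               (3, 18), (7, 15), (7, 16)],
    "d16000": [(17, 28), (24, 62), (20, 50), (15, 35), (11, 40), (7, 21), (4, 14), (7, 13),
               (7, 17), (7, 44), (11, 32), (16, 43)],
}


@dataclass
class ForecastModel:
    """Linear model of a log recruitment rate on named lagged predictors."""

    response: str  # "NSD" | "RSD"
    labels: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    cov: np.ndarray | None = None  # (p+1) x (p+1), intercept first
    resid_var: float | None = None
    nobs: int | None = None
    envelope: dict | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.labels):
            raise ValueError("one coefficient per predictor label required")

    @classmethod
    def from_candidate(cls, response: str, model) -> "ForecastModel":
        """Build from a fitted :class:`zosrec.modelsearch.CandidateModel`."""
        labels = model.predictors
        order = ["const", *labels]
        params = model.params[order]
        cov = model.cov.loc[order, order].to_numpy()
        return cls(response=response, labels=tuple(labels),
                   coefficients=params[list(labels)].to_numpy(),
                   intercept=float(params["const"]), cov=cov,
                   resid_var=model.resid_var, nobs=model.nobs)


@dataclass
class Prediction:
    log_point: float
    log_ci: tuple[float, float]
    log_pi: tuple[float, float]
    natural_point: float
    log_se_mean: float
    envelope_flags: dict[str, str] = field(default_factory=dict)


def published_nsd_model() -> ForecastModel:
    """The published naked-seed-dispersal model (adj-R^2 0.998 as reported)."""
    return ForecastModel(
        response="NSD",
        labels=("10C_p1yNOS", "rain_p2yJDN", "eastness_p36mo"),
        coefficients=np.array([-8.72710, 0.00139, 8.48952]),
        intercept=-4.37839,
        envelope=TABLE1_RANGES,
    )


def published_rsd_model() -> ForecastModel:
    """The published rafted-seed-dispersal model (98.1% variance explained)."""
    return ForecastModel(
        response="RSD",
        labels=("d16000_pAprToNov", "mWindSpd_pMay", "d2000_pFeb"),
        coefficients=np.array([-0.23381, -0.54899, -0.00107]),
        intercept=8.07992,
        envelope=TABLE1_RANGES,
    )


def envelope_check(x: dict[str, float], envelope: dict | None = None) -> dict[str, str]:
    """Flag each lagged feature against the relevant monthly ranges.

    A windowed mean is compared against the loosest bound over its window's
    calendar months ([min lo, max hi]); variables absent from the envelope
    are flagged ``unknown``.  Returns label -> 'in' | 'out' | 'unknown'.
    """
    envelope = envelope if envelope is not None else TABLE1_RANGES
    flags = {}
    for label, value in x.items():
        try:
            spec = parse_label(label)
        except ValueError:
            flags[label] = "unknown"
            continue
        ranges = envelope.get(spec.variable)
        if not ranges:
            flags[label] = "unknown"
            continue
        months = {p.month for p in spec.months(2000)}
        lo = min(ranges[m - 1][0] for m in months)
        hi = max(ranges[m - 1][1] for m in months)
        flags[label] = "in" if lo <= value <= hi else "out"
    return flags


def predict(model: ForecastModel, x: dict[str, float], level: float = 0.95) -> Prediction:
    """Point prediction with CI/PI on the log scale; natural scale by exp.

    Out-of-envelope inputs are flagged, not refused.  Intervals require the
    model's estimate covariance and residual variance; otherwise NaN.
    """
    missing = [l for l in x if l not in model.labels]
    if missing:
        raise KeyError(f"unknown predictor label(s) {missing}; model uses {model.labels}")
    if set(x) != set(model.labels):
        raise KeyError(f"features incomplete: need {model.labels}")
    xv = np.array([x[l] for l in model.labels], dtype=float)
    point = float(model.intercept + model.coefficients @ xv)

    se_mean = var_pred = np.nan
    ci = pi = (np.nan, np.nan)
    if model.cov is not None and model.resid_var is not None:
        x1 = np.concatenate([[1.0], xv])
        var_mean = float(x1 @ model.cov @ x1)
        se_mean = float(np.sqrt(var_mean))
        var_pred = var_mean + model.resid_var
        if model.nobs is not None:
            df = model.nobs - len(model.labels) - 1
            q = stats.t.ppf(0.5 + level / 2, df)
        else:
            q = stats.norm.ppf(0.5 + level / 2)
        ci = (point - q * se_mean, point + q * se_mean)
        pi = (point - q * np.sqrt(var_pred), point + q * np.sqrt(var_pred))
    flags = envelope_check(x, model.envelope) if model.envelope else {}
    return Prediction(point, ci, pi, float(np.exp(point)), se_mean, flags)


def relative_importance(
    nsd_model: ForecastModel, rsd_model: ForecastModel,
    x_nsd: dict[str, float], x_rsd: dict[str, float],
    reference: dict[str, float],
    nsd_se: float | None = None, rsd_se: float | None = None,
) -> tuple[float, float]:
    """NSD:RSD recruitment ratio at fixed reference areas, with propagated error.

    Rates are de-standardized to counts: NSD count = exp(logNSD) * bare6 *
    source, RSD count = exp(logRSD) * bare_beyond.  ``reference`` carries the
    fixed 'bare6', 'source' and 'bare_beyond' areas (m^2).  The variance of
    the log ratio is the sum of the two prediction variances (independent
    models, first-order delta).
    """
    p_nsd = predict(nsd_model, x_nsd)
    p_rsd = predict(rsd_model, x_rsd)
    nsd_count = p_nsd.natural_point * reference["bare6"] * reference["source"]
    rsd_count = p_rsd.natural_point * reference["bare_beyond"]
    if rsd_count <= 0:
        raise ValueError("de-standardized RSD prediction must be positive")
    ratio = nsd_count / rsd_count
    se_n = nsd_se if nsd_se is not None else p_nsd.log_se_mean
    se_r = rsd_se if rsd_se is not None else p_rsd.log_se_mean
    var_log_ratio = float(se_n**2 + se_r**2)
    return float(ratio), var_log_ratio


# ---------------------------------------------------------------------------
# model JSON I/O and CLI
# ---------------------------------------------------------------------------

def save_model(model: ForecastModel, path) -> None:
    payload = {
        "response": model.response, "labels": list(model.labels),
        "coefficients": list(map(float, model.coefficients)),
        "intercept": model.intercept,
        "cov": None if model.cov is None else np.asarray(model.cov).tolist(),
        "resid_var": model.resid_var, "nobs": model.nobs,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> ForecastModel:
    with open(path) as fh:
        d = json.load(fh)
    return ForecastModel(
        response=d["response"], labels=tuple(d["labels"]),
        coefficients=np.array(d["coefficients"]), intercept=d["intercept"],
        cov=None if d.get("cov") is None else np.array(d["cov"]),
        resid_var=d.get("resid_var"), nobs=d.get("nobs"), envelope=TABLE1_RANGES,
    )


def main(argv: list[str] | None = None) -> int:
    ap = argparse.ArgumentParser(
        prog="zosrec-forecast",
        description="Predict log recruitment rates from a features CSV.")
    ap.add_argument("--model", required=True,
                    help="'nsd', 'rsd' (published models) or a model JSON path")
    ap.add_argument("--features", required=True, help="CSV with one row per case")
    ap.add_argument("--out", required=True, help="output CSV path")
    ap.add_argument("--level", type=float, default=0.95)
    args = ap.parse_args(argv)

    if args.model.lower() == "nsd":
        model = published_nsd_model()
    elif args.model.lower() == "rsd":
        model = published_rsd_model()
    else:
        model = load_model(args.model)

    feats = pd.read_csv(args.features)
    rows = []
    for _, row in feats.iterrows():
        x = {l: float(row[l]) for l in model.labels}
        p = predict(model, x, args.level)
        rows.append({
            **{c: row[c] for c in feats.columns if c not in model.labels},
            **x, "log_pred": p.log_point, "pred": p.natural_point,
            "ci_lo": p.log_ci[0], "ci_hi": p.log_ci[1],
            "pi_lo": p.log_pi[0], "pi_hi": p.log_pi[1],
            "out_of_envelope": ";".join(k for k, v in p.envelope_flags.items() if v == "out"),
        })
    pd.DataFrame(rows).to_csv(args.out, index=False)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
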