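"""Refits of the published models on their raw data tables.

These helpers re-estimate the published regressions from the raw
supplementary tables (recruitment model data; daily bottom-temperature
data) when those files are available, reporting the fit statistics the
original analysis printed (adjusted R^2, overall P).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .climate import OffsetModel, fit_offset_model, read_offset_table

__all__ = ["read_recruitment_table", "refit_printed_model", "refit_offset_table"]


def read_recruitment_table(path) -> pd.DataFrame:
    """Raw census-year table for the recruitment models (XLSX or CSV):
    one row per census year, response columns (NSD/RSD counts or rates) and
    lag-grammar predictor columns."""
    sp = str(path)
    df = pd.read_excel(sp) if sp.endswith((".xlsx", ".xls")) else pd.read_csv(sp)
    return df


def refit_printed_model(
    data: pd.DataFrame, response: str, labels: tuple[str, ...], log_response: bool = True,
):
    """OLS of (log) response on the given predictor labels.

    Returns the statsmodels results object; ``rsquared_adj`` and
    ``f_pvalue`` are the quantities to compare with the published fit.
    """
    df = data[[response, *labels]].dropna()
    y = np.log(df[response].astype(float)) if log_response else df[response].astype(float)
    X = sm.add_constant(df[list(labels)].astype(float))
    return sm.OLS(y, X).fit()


def refit_offset_table(path) -> OffsetModel:
    """Fit the saturated bottom-water temperature offset model on a raw
    daily table (see :func:`zosrec.climate.read_offset_table` for layout)."""
    raw = read_offset_table(path)
    return fit_offset_model(raw["site_temp"], raw["sst"], raw["air"], raw["wind"])
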