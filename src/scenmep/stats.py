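"""Donor-blocked differential marker testing.

Treatment contrasts (e.g. control vs vitamin-D3 at one maturation stage)
are tested per marker on per-donor group summaries (arcsinh medians or
gMFIs) with an ordinary-least-squares model containing the treatment
indicator and donor fixed effects. With the small donor numbers typical of
these designs (3–6), donor fixed effects are the standard blocking
approximation to a random-intercept mixed model. P-values are two-sided on
the treatment coefficient; Benjamini–Hochberg adjustment is applied across
markers within the contrast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ValidationError


def differential_markers(summaries: pd.DataFrame, contrast: tuple[str, str],
                         markers=None, group_col: str = "group",
                         donor_col: str = "donor_id",
                         alpha: float = 0.05) -> pd.DataFrame:
    """Donor-blocked differential test of *contrast* = (reference, test).

    ``summaries`` holds one row per (donor, group) with marker summary
    columns. Donors observed in only one arm are dropped with a warning;
    fewer than two complete donors is an error. The effect estimate is the
    treatment coefficient (difference of donor-adjusted means, in the
    summary's units, test − reference). A zero-variance marker reports
    effect 0 and p = 1 by convention.

    Returns one row per marker: effect, p_raw, p_adj (BH), significant.
    """
    ref, alt = contrast
    sub = summaries[summaries[group_col].isin([ref, alt])].copy()
    if sub.empty:
        raise InsufficientDataError(f"no rows for contrast {contrast}")
    arms_per_donor = sub.groupby(donor_col)[group_col].nunique()
    incomplete = arms_per_donor[arms_per_donor < 2].index.tolist()
    if incomplete:
        warnings.warn(f"dropping donor(s) present in only one arm: "
                      f"{incomplete}", stacklevel=2)
        sub = sub[~sub[donor_col].isin(incomplete)]
    donors = sub[donor_col].unique()
    if len(donors) < 2:
        raise InsufficientDataError(
            f"contrast {contrast}: fewer than 2 donors in both arms")

    if markers is None:
        markers = [c for c in sub.columns
                   if c not in (group_col, donor_col)
                   and pd.api.types.is_numeric_dtype(sub[c])]

    treatment = (sub[group_col] == alt).astype(float).to_numpy()
    donor_dummies = pd.get_dummies(sub[donor_col], drop_first=True,
                                   dtype=float)
    design = sm.add_constant(
        np.column_stack([treatment, donor_dummies.to_numpy()]),
        has_constant="add")

    rows = []
    for marker in markers:
        y = sub[marker].to_numpy(dtype=float)
        if np.any(~np.isfinite(y)):
            raise ValidationError(f"non-finite summary for {marker!r}")
        if np.ptp(y) == 0:
            rows.append({"marker": marker, "effect": 0.0, "p_raw": 1.0})
            continue
        fit = sm.OLS(y, design).fit()
        rows.append({"marker": marker,
                     "effect": float(fit.params[1]),
                     "p_raw": float(fit.pvalues[1])})
    out = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")
    out["p_adj"] = p_adj
    out["significant"] = out["p_adj"] < alpha
    return out
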