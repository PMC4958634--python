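"""Per-gene quadrant ANOVA with least-squares means, planned contrasts and BH FDR.

The expression model has the Cartesian quadrant (HH, HL, LL, LH) as a single fixed
effect with one observation per animal, i.e. an ordinary one-way ANOVA per gene:
the overall quadrant effect is the 3-df F test, least-squares means equal arithmetic
group means in this balanced layout, and three 1-df planned contrasts are tested
against the residual variance:

* gain:        (HH + HL)/2 - (LL + LH)/2
* intake:      (HH + LH)/2 - (HL + LL)/2
* interaction: ((HH + LL) - (HL + LH)) / 2

Raw overall p-values are corrected by Benjamini-Hochberg step-up, by default over the
full number of genes on the platform rather than the number actually tested.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phenotypes import QUADRANTS

__all__ = ["fit_quadrant_model", "adjust_fdr", "CONTRAST_COEFS"]

log = logging.getLogger(__name__)

#: Contrast coefficients on the quadrant LS means, ordered (HH, HL, LL, LH).
CONTRAST_COEFS: dict[str, np.ndarray] = {
    "gain": np.array([0.5, 0.5, -0.5, -0.5]),
    "intake": np.array([0.5, -0.5, -0.5, 0.5]),
    "interaction": np.array([0.5, -0.5, 0.5, -0.5]),
}


def fit_quadrant_model(
    values: pd.DataFrame,
    sample_quadrants: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """One-way quadrant ANOVA for every gene of a log2 expression matrix.

    Parameters
    ----------
    values
        genes x samples log2 expression, no missing values.
    sample_quadrants
        Map from sample id to quadrant code; every sample must be mapped and each
        quadrant needs at least 2 samples.

    Returns
    -------
    DataFrame indexed by gene with columns ``lsmean_HH`` .. ``lsmean_LH``, ``F``,
    ``p_overall``, per-contrast ``contrast_<name>`` / ``p_<name>``, ``fold_change``
    (maximum pairwise LS-mean difference, log2 units) and ``q`` (BH over the number
    of genes supplied; rerun :func:`adjust_fdr` for a platform-wide m).

    Genes with zero residual variance are assigned ``p_overall`` 0 (or 1 when the
    group means are also all equal) and logged as a warning.
    """
    quad = pd.Series(sample_quadrants)
    missing = [s for s in values.columns if s not in quad.index]
    if missing:
        raise ValueError(f"samples without quadrant label: {missing[:5]}")
    quad = quad.loc[values.columns]
    counts = quad.value_counts()
    if set(QUADRANTS) - set(counts.index) or (counts < 2).any():
        raise ValueError(f"every quadrant needs >=2 samples, got {counts.to_dict()}")

    X = values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("expression matrix contains missing values")
    n = X.shape[1]
    k = len(QUADRANTS)
    df_between, df_within = k - 1, n - k

    group_idx = [np.flatnonzero((quad == q).to_numpy()) for q in QUADRANTS]
    n_g = np.array([len(ix) for ix in group_idx])
    means = np.column_stack([X[:, ix].mean(axis=1) for ix in group_idx])  # (G, 4)
    grand = X.mean(axis=1)

    ss_between = (n_g * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_total = ((X - grand[:, None]) ** 2).sum(axis=1)
    ss_within = ss_total - ss_between
    # guard tiny negative values from cancellation
    ss_within = np.maximum(ss_within, 0.0)
    ms_within = ss_within / df_within

    zero_var = ms_within <= 1e-300
    if zero_var.any():
        log.warning(
            "%d gene(s) with zero residual variance; p set to 0 (or 1 when flat)",
            int(zero_var.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_between) / ms_within
    p = stats.f.sf(F, df_between, df_within)
    flat = zero_var & (ss_between <= 1e-300)
    p = np.where(zero_var, 0.0, p)
    p = np.where(flat, 1.0, p)
    F = np.where(zero_var, np.inf, F)
    F = np.where(flat, np.nan, F)

    out = pd.DataFrame(index=values.index)
    for j, q in enumerate(QUADRANTS):
        out[f"lsmean_{q}"] = means[:, j]
    out["F"] = F
    out["p_overall"] = p

    for name, c in CONTRAST_COEFS.items():
        est = means @ c
        se2 = ms_within * float((c**2 / n_g).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / np.sqrt(se2)
        pc = 2 * stats.t.sf(np.abs(t), df_within)
        pc = np.where(zero_var, np.where(np.abs(est) > 0, 0.0, 1.0), pc)
        out[f"contrast_{name}"] = est
        out[f"p_{name}"] = pc

    out["fold_change"] = means.max(axis=1) - means.min(axis=1)
    out["q"] = adjust_fdr(out["p_overall"].to_numpy())
    return out


def adjust_fdr(p_values: Sequence[float] | np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with an explicit test count m.

    ``m`` defaults to the number of p-values but may be larger — e.g. the number of
    genes on the platform when only a filtered subset was tested — in which case
    each q-value is inflated accordingly. q-values are monotone in p, never below
    the raw p, and capped at 1.

    Raises
    ------
    ValueError
        If any p lies outside [0, 1] or m is smaller than the number of p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than the number of p-values ({p.size})")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def expected_null_positives(alpha: float, m: int) -> float:
    """Expected number of nominally significant genes under the global null (alpha * m)."""
    return alpha * m
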