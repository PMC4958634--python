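"""Expression-activity scoring: probability that a gene is actively expressed.

Each array sample's log2 intensity distribution is modelled as a two-component
Gaussian mixture — an inactive background component and an expressed component with
the higher mean — and every gene receives a score u in [0, 1], the posterior
probability of the expressed component. A gene is called expressed in the tissue if
u exceeds a threshold (default 0.3, strict) in at least one sample; intersecting that
set with the CNV gene set yields the expressed CNV genes.

Intensities are standardised per sample before the fit and the EM is initialised
deterministically from quantiles, so scores are invariant to shifting or rescaling a
sample's intensities and involve no random seed.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["activity_scores", "expressed_genes", "expressed_cnv_genes"]

log = logging.getLogger(__name__)

MIN_GENES = 100


def _fit_two_gaussians(
    z: np.ndarray, max_iter: int = 500, tol: float = 1e-10, sep_tol: float = 0.2
) -> np.ndarray | None:
    """EM for a 1-D two-component Gaussian mixture on standardised values.

    Returns the posterior of the higher-mean component, or None when the fitted
    components are too close to separate (means within ``sep_tol`` pooled sd).
    """
    lo, hi = np.quantile(z, [0.25, 0.75])
    mu = np.array([lo, hi])
    sd = np.array([z.std(), z.std()]) / 2 + 1e-6
    w = np.array([0.5, 0.5])
    prev = -np.inf
    for _ in range(max_iter):
        logp = np.log(w)[:, None] + stats.norm.logpdf(z[None, :], mu[:, None], sd[:, None])
        m = logp.max(axis=0)
        norm = m + np.log(np.exp(logp - m).sum(axis=0))
        g = np.exp(logp - norm)  # (2, n)
        ll = norm.sum()
        nk = g.sum(axis=1)
        w = nk / len(z)
        mu = (g @ z) / nk
        sd = np.sqrt((g @ z**2) / nk - mu**2)
        sd = np.maximum(sd, 1e-4)
        if abs(ll - prev) < tol * max(abs(ll), 1.0):
            break
        prev = ll
    pooled = float(np.sqrt((w * sd**2).sum()))
    if abs(mu[1] - mu[0]) < sep_tol * pooled:
        return None
    top = int(np.argmax(mu))
    return g[top]


def activity_scores(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample activity score u in [0, 1] for every gene of a log2 matrix.

    Parameters
    ----------
    expr
        genes x samples log2 intensities; at least 100 genes per sample are required
        for a stable mixture fit.

    Returns
    -------
    genes x samples DataFrame of scores. Samples whose mixture fit is degenerate
    (components not separated) fall back to a rank-based score rank/(n+1) with a
    warning.
    """
    if len(expr) < MIN_GENES:
        raise ValueError(f"need >= {MIN_GENES} genes per sample, got {len(expr)}")
    out = pd.DataFrame(index=expr.index, columns=expr.columns, dtype=float)
    for sample in expr.columns:
        v = expr[sample].to_numpy(dtype=float)
        z = (v - v.mean()) / (v.std() + 1e-12)
        u = _fit_two_gaussians(z)
        if u is None:
            log.warning("sample %s: degenerate mixture; using rank-based scores", sample)
            u = stats.rankdata(z) / (len(z) + 1)
        out[sample] = u
    return out


def expressed_genes(scores: pd.DataFrame, threshold: float = 0.3) -> list[str]:
    """Genes whose activity score strictly exceeds ``threshold`` in at least one sample."""
    mask = (scores > threshold).any(axis=1)
    return sorted(scores.index[mask].astype(str))


def expressed_cnv_genes(expressed: Iterable[str], cnv_genes: Iterable[str]) -> list[str]:
    """Intersection of the expressed gene set with the CNV gene set, sorted."""
    return sorted(set(expressed) & set(cnv_genes))
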