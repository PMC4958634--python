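"""Multi-sample read-depth decomposition into integer copy numbers.

The model class follows multi-sample Poisson-mixture CNV detection on windowed read
depth: within each genomic window the counts of the samples are modelled as a mixture
over integer copy numbers cn in {0..8},

    count_j ~ Poisson(lambda * s_j * cn / 2),        cn >= 1
    count_j ~ Poisson(lambda * s_j * eps),           cn = 0  (residual mapping noise)

with the mixture weights alpha_c shared across samples within the window, a per-window
expected diploid rate lambda, and per-sample size factors s_j (median-of-ratios,
normalised to mean 1). The EM fit is a MAP fit with a small Dirichlet pseudo-count on
the diploid component, which encodes that most windows in most samples are copy-number
neutral and controls false calls under the all-diploid null. A window's
informativeness is the total deviation of the fitted weights from the all-diploid
configuration (1 - alpha_2).

Per-sample calls are maximal runs of consecutive windows sharing the same non-diploid
posterior-mode copy number; to pool evidence across adjacent windows — the role
segmentation plays in read-depth callers — log-posteriors are summed over a short
centred sliding window before modes are taken (width 1 disables this).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "estimate_size_factors",
    "decompose",
    "decompose_window",
    "segment_calls",
    "call_cnvs",
    "DecomposeResult",
]

CN_GRID = np.arange(9)  # copy numbers 0..8
DIPLOID = 2


@dataclass
class DecomposeResult:
    """Per-window mixture fit: posteriors (windows x samples x cn), weights, rates."""

    posterior: np.ndarray
    weights: np.ndarray
    lam: np.ndarray
    informativeness: np.ndarray

    def modes(self, tie_tol: float = 1e-9) -> np.ndarray:
        """Posterior-mode copy number per (window, sample); ties resolved toward diploid."""
        return _modes_from_logpost(np.log(np.maximum(self.posterior, 1e-300)), tie_tol)


def _modes_from_logpost(logpost: np.ndarray, tie_tol: float = 1e-9) -> np.ndarray:
    modes = np.argmax(logpost, axis=-1)
    top = np.take_along_axis(logpost, modes[..., None], axis=-1)[..., 0]
    near_diploid = logpost[..., DIPLOID] >= top - tie_tol
    return np.where(near_diploid, DIPLOID, modes)


def estimate_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, normalised to mean 1.

    The reference profile is the per-window geometric mean across samples (windows
    containing zeros are excluded from the medians, as usual); robust to a minority
    of copy-number-variable windows.
    """
    X = np.asarray(counts, dtype=float)
    ok = (X > 0).all(axis=1)
    if not ok.any():
        return np.ones(X.shape[1])
    logref = np.log(X[ok]).mean(axis=1)
    s = np.exp(np.median(np.log(X[ok]) - logref[:, None], axis=0))
    return s / s.mean()


def decompose(
    counts: np.ndarray,
    size_factors: np.ndarray | None = None,
    cn_grid: np.ndarray = CN_GRID,
    eps: float = 0.05,
    diploid_prior: float = 1.0,
    weight_floor: float = 1e-2,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> DecomposeResult:
    """MAP-EM fit of the shared-weight Poisson copy-number mixture, window by window.

    Parameters
    ----------
    counts
        (windows, samples) non-negative read counts.
    size_factors
        Per-sample factors s_j; estimated by :func:`estimate_size_factors` if None.
    eps
        Relative rate of the cn=0 component (residual noise floor).
    diploid_prior
        Dirichlet pseudo-count added to the diploid component in the weight update.
    weight_floor
        Lower bound on mixture weights, keeping the log-weight penalty of rare
        components finite.
    tol
        EM stops when every window's relative log-likelihood change is below this
        (or after ``max_iter`` iterations).

    Windows whose counts are all zero are uninformative: posterior mass on diploid,
    informativeness 0.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("counts must be (windows, samples) with >=2 samples")
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    W, S = X.shape
    s = estimate_size_factors(X) if size_factors is None else np.asarray(size_factors, float)
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    C = len(cn_grid)
    mu = np.where(cn_grid == 0, eps, cn_grid / 2.0)  # relative rates per component
    idx2 = int(np.where(cn_grid == DIPLOID)[0][0])

    lam = (X / s).mean(axis=1)  # (W,)
    dead = lam <= 0
    alpha = np.full((W, C), 0.2 / (C - 1))
    alpha[:, idx2] = 0.8

    lgx = gammaln(X + 1.0)  # constant over components
    prev_ll = np.full(W, -np.inf)
    for _ in range(max_iter):
        rate = lam[:, None, None] * s[None, :, None] * mu[None, None, :]  # (W,S,C)
        logpmf = X[..., None] * np.log(np.maximum(rate, 1e-300)) - rate - lgx[..., None]
        logjoint = np.log(alpha)[:, None, :] + logpmf
        norm = logsumexp(logjoint, axis=2)  # (W,S)
        gamma = np.exp(logjoint - norm[..., None])
        ll = norm.sum(axis=1)

        resp = gamma.sum(axis=1)  # (W,C)
        resp[:, idx2] += diploid_prior
        alpha = resp / resp.sum(axis=1, keepdims=True)
        alpha = np.maximum(alpha, weight_floor)
        alpha /= alpha.sum(axis=1, keepdims=True)

        num = (gamma * X[..., None]).sum(axis=(1, 2))
        den = (gamma * (s[None, :, None] * mu[None, None, :])).sum(axis=(1, 2))
        lam = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)

        delta = np.abs(ll - prev_ll) / np.maximum(np.abs(ll), 1.0)
        prev_ll = ll
        if np.all(delta[~dead] < tol):
            break

    rate = lam[:, None, None] * s[None, :, None] * mu[None, None, :]
    logpmf = X[..., None] * np.log(np.maximum(rate, 1e-300)) - rate - lgx[..., None]
    logjoint = np.log(alpha)[:, None, :] + logpmf
    post = np.exp(logjoint - logsumexp(logjoint, axis=2, keepdims=True))

    if dead.any():  # all-zero windows: uninformative, diploid by convention
        post[dead] = 0.0
        post[dead, :, idx2] = 1.0
        alpha[dead] = 0.0
        alpha[dead, idx2] = 1.0

    informativeness = 1.0 - alpha[:, idx2]
    return DecomposeResult(posterior=post, weights=alpha, lam=lam, informativeness=informativeness)


def decompose_window(
    counts_w: np.ndarray, size_factors: np.ndarray | None = None, **kwargs
) -> tuple[np.ndarray, float]:
    """Posterior over copy numbers for the samples of a single window.

    Returns ``(posterior (samples x cn), informativeness)``.
    """
    res = decompose(np.asarray(counts_w, dtype=float)[None, :], size_factors, **kwargs)
    return res.posterior[0], float(res.informativeness[0])


def segment_calls(
    windows: pd.DataFrame,
    result: DecomposeResult,
    sample_ids: list[str] | None = None,
    min_windows: int = 3,
    smooth: int = 3,
    merge_gap: int = 2,
    tie_tol: float = 1e-9,
    posterior_floor: float = 1e-6,
) -> pd.DataFrame:
    """Per-sample CNV calls from maximal same-copy-number runs of window modes.

    Parameters
    ----------
    windows
        DataFrame with ``chrom``, ``start``, ``end`` aligned with the count matrix
        rows, sorted and non-overlapping within chromosome.
    result
        Output of :func:`decompose`.
    min_windows
        Minimum run length for a call.
    smooth
        Width (odd) of the centred sliding window over which log-posteriors are
        summed within a chromosome before modes are taken; 1 = raw per-window modes.
    merge_gap
        Runs of non-diploid modes separated by at most this many windows are
        bridged into one candidate span before the length filter; the span's copy
        number is the non-diploid state maximising the pooled log-posterior over
        the whole span. 0 disables bridging (each same-cn run stands alone).
    posterior_floor
        Posteriors are floored at this value before the log-sum, capping how much
        a single saturated window can outvote its neighbours at event boundaries.

    Returns
    -------
    DataFrame of calls: sample, chrom, start, end, cn, n_windows, score (mean raw
    posterior of the called cn over the span).
    """
    if smooth < 1 or smooth % 2 == 0:
        raise ValueError("smooth must be a positive odd integer")
    W, S, C = result.posterior.shape
    if sample_ids is None:
        sample_ids = [f"S{j}" for j in range(S)]
    logpost = np.log(np.maximum(result.posterior, posterior_floor))
    chrom_arr = windows["chrom"].to_numpy()
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()

    calls = []
    # process contiguous chromosome blocks in input order
    block_edges = np.flatnonzero(np.r_[True, chrom_arr[1:] != chrom_arr[:-1], True])
    for b0, b1 in zip(block_edges[:-1], block_edges[1:]):
        lp = logpost[b0:b1]
        if smooth > 1 and (b1 - b0) > 1:
            half = smooth // 2
            csum = np.cumsum(lp, axis=0)
            pad = np.concatenate([np.zeros((1, S, C)), csum], axis=0)
            lo = np.maximum(np.arange(b1 - b0) - half, 0)
            hi = np.minimum(np.arange(b1 - b0) + half + 1, b1 - b0)
            lp = pad[hi] - pad[lo]
        modes = _modes_from_logpost(lp, tie_tol)  # (w, S)
        raw_lp = np.log(np.maximum(result.posterior[b0:b1], posterior_floor))
        raw_modes = _modes_from_logpost(raw_lp, tie_tol)
        nondip = np.arange(C) != DIPLOID
        nb = b1 - b0
        for j in range(S):
            m = modes[:, j]
            # maximal runs of non-diploid modes (any length), then gap-bridging
            hot = np.flatnonzero(m != DIPLOID)
            if hot.size == 0:
                continue
            spans: list[list[int]] = [[int(hot[0]), int(hot[0])]]
            for w in hot[1:]:
                if w - spans[-1][1] - 1 <= merge_gap:
                    spans[-1][1] = int(w)
                else:
                    spans.append([int(w), int(w)])
            refined: list[tuple[int, int, int]] = []  # (w0, w1, cn) window indices
            for w0, w1 in spans:
                pooled = raw_lp[w0 : w1 + 1, j, :].sum(axis=0)
                cn = int(np.arange(C)[nondip][np.argmax(pooled[nondip])])
                # smoothing erodes boundary windows of weak events: win them back
                # while the raw per-window mode still agrees with the span state
                while w0 > 0 and raw_modes[w0 - 1, j] == cn:
                    w0 -= 1
                while w1 < nb - 1 and raw_modes[w1 + 1, j] == cn:
                    w1 += 1
                if refined and refined[-1][2] == cn and w0 <= refined[-1][1] + 1:
                    w0 = refined[-1][0]
                    refined.pop()
                if w1 - w0 + 1 >= min_windows:
                    refined.append((w0, w1, cn))
            for w0, w1, cn in refined:
                g0, g1 = b0 + w0, b0 + w1
                calls.append(
                    {
                        "sample": sample_ids[j],
                        "chrom": chrom_arr[b0],
                        "start": int(starts[g0]),
                        "end": int(ends[g1]),
                        "cn": cn,
                        "n_windows": w1 - w0 + 1,
                        "score": float(result.posterior[g0 : g1 + 1, j, cn].mean()),
                    }
                )
    cols = ["sample", "chrom", "start", "end", "cn", "n_windows", "score"]
    out = pd.DataFrame(calls, columns=cols)
    return out.sort_values(["chrom", "start", "sample"]).reset_index(drop=True)


def call_cnvs(
    windows: pd.DataFrame,
    counts: pd.DataFrame,
    min_windows: int = 3,
    smooth: int = 3,
    **decompose_kwargs,
) -> pd.DataFrame:
    """Convenience pipeline: size factors -> mixture decomposition -> segmentation.

    ``counts`` is a windows x samples DataFrame aligned with ``windows`` rows.
    """
    X = counts.to_numpy(dtype=float)
    res = decompose(X, **decompose_kwargs)
    return segment_calls(
        windows, res, sample_ids=list(counts.columns), min_windows=min_windows, smooth=smooth
    )
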