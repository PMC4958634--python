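"""Category over-representation: expected counts, fold enrichment, binomial p, Bonferroni.

For a gene list of size n drawn from a reference of N genes, of which K belong to a
category, the expected count is E = n*K/N and the fold enrichment FE = k/E. The raw
p-value is the classic binomial test used by annotation-enrichment tools: the upper
tail P(X >= k | n, K/N) for over-represented categories, the lower tail P(X <= k) for
depleted ones (k < E). A hypergeometric (Fisher exact, one-sided) alternative is
available. Family-wise correction is Bonferroni over the categories actually tested.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["enrichment_row", "overrepresentation", "bonferroni"]


def enrichment_row(
    K: int, N: int, k: int, n: int, method: str = "binomial"
) -> dict[str, float]:
    """Enrichment statistics for one category from its four counts.

    Parameters
    ----------
    K, N
        Category size and total size in the reference annotation.
    k, n
        Category hits and total size of the analyzed gene list.
    method
        ``binomial`` (default) or ``hypergeometric``.

    Returns
    -------
    dict with ``expected``, ``fold_enrichment`` (NaN when E = 0), ``p_raw`` and the
    tail that was used (``over`` when k >= E, else ``under``).
    """
    if K == 0 and k > 0:
        raise ValueError(f"annotation inconsistency: k={k} hits in a category with K=0")
    if not (0 <= K <= N and 0 <= k <= n):
        raise ValueError("counts must satisfy 0 <= K <= N and 0 <= k <= n")
    expected = n * K / N
    fe = k / expected if expected > 0 else float("nan")
    over = k >= expected
    if method == "binomial":
        p_cat = K / N
        p_raw = stats.binom.sf(k - 1, n, p_cat) if over else stats.binom.cdf(k, n, p_cat)
    elif method == "hypergeometric":
        p_raw = (
            stats.hypergeom.sf(k - 1, N, K, n) if over else stats.hypergeom.cdf(k, N, K, n)
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "expected": expected,
        "fold_enrichment": fe,
        "p_raw": float(p_raw),
        "tail": "over" if over else "under",
    }


def overrepresentation(
    list_genes: Iterable[str],
    category_map: Mapping[str, Iterable[str]] | pd.DataFrame,
    reference_size: int | None = None,
    method: str = "binomial",
) -> pd.DataFrame:
    """Per-category enrichment of a gene list against a reference annotation.

    Parameters
    ----------
    list_genes
        The analyzed gene list (e.g. DEGs or expressed CNV genes); must be a subset
        of the annotated reference.
    category_map
        Either a mapping category -> iterable of reference genes, or a two-column
        DataFrame (``gene``, ``category``).
    reference_size
        N, the total number of genes in the reference; defaults to the number of
        distinct genes in ``category_map``.
    """
    genes = set(list_genes)
    if isinstance(category_map, pd.DataFrame):
        cat_sets = {
            c: set(sub["gene"]) for c, sub in category_map.groupby("category", sort=True)
        }
        universe = set(category_map["gene"])
    else:
        cat_sets = {c: set(v) for c, v in category_map.items()}
        universe = set().union(*cat_sets.values()) if cat_sets else set()
    N = reference_size if reference_size is not None else len(universe)
    n = len(genes)
    rows = []
    for cat in sorted(cat_sets):
        members = cat_sets[cat]
        K, k = len(members), len(genes & members)
        if K == 0:
            continue
        row = enrichment_row(K, N, k, n, method=method)
        rows.append({"category": cat, "K": K, "N": N, "k": k, "n": n, **row})
    out = pd.DataFrame(rows)
    if len(out):
        out = bonferroni(out)
    return out


def bonferroni(rows: pd.DataFrame, m: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Add Bonferroni-corrected p-values and a significance flag.

    ``m`` defaults to the number of categories tested (rows). ``p_bonf`` is capped
    at 1 and never below the raw p.
    """
    if m is None:
        m = len(rows)
    if m < 1:
        raise ValueError("m must be >= 1")
    out = rows.copy()
    out["p_bonf"] = np.minimum(out["p_raw"] * m, 1.0)
    out["significant"] = out["p_bonf"] < alpha
    return out
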