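"""Livak relative quantification and microarray concordance classification.

qPCR threshold cycles (Cq) are reduced to log fold changes with the Livak 2^-ddCt
method: dCt = Cq(target) - Cq(reference) per sample, ddCt = dCt(sample) -
dCt(pooled control), and the reported value is log10(2^-ddCt) = -ddCt*log10(2).
Per-gene concordance with the array is the Pearson correlation between the four
quadrant means on the qPCR scale and on the array log2 scale; the correlation is
invariant to the log base, so the base only sets the printed magnitude.
"""

from __future__ import annotations

import logging
import math
import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .phenotypes import QUADRANTS

__all__ = ["livak", "concordance", "classify_r", "load_table"]

log = logging.getLogger(__name__)

REFERENCE_GENE = "RN18S"
POOLED_CONTROL = "POOL"


def livak(
    cq_table: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    pooled_control: str = POOLED_CONTROL,
    log_base: float = 10.0,
    replicate_range_warn: float = 1.0,
) -> pd.DataFrame:
    """Per-(gene, sample) log fold change from replicate Cq values.

    Parameters
    ----------
    cq_table
        Long table with columns ``gene``, ``sample``, ``cq`` (one row per technical
        replicate). The reference gene must be present for every sample, and the
        pooled control sample for every gene.
    log_base
        Base of the reported log fold change; 10 gives log10(2^-ddCt).
    replicate_range_warn
        Warn when the Cq range across replicates of one (gene, sample) exceeds this.

    Returns
    -------
    DataFrame genes x samples of log fold changes (pooled control column dropped).
    """
    required = {"gene", "sample", "cq"}
    if not required <= set(cq_table.columns):
        raise ValueError(f"cq_table needs columns {sorted(required)}")
    spread = cq_table.groupby(["gene", "sample"])["cq"].agg(lambda v: v.max() - v.min())
    wide = cq_table.groupby(["gene", "sample"])["cq"].mean().unstack("sample")
    if (spread > replicate_range_warn).any():
        log.warning(
            "%d gene x sample cells with replicate Cq range > %.2g",
            int((spread > replicate_range_warn).sum()),
            replicate_range_warn,
        )
    if reference_gene not in wide.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from Cq table")
    ref = wide.loc[reference_gene]
    if ref.isna().any():
        raise ValueError(
            f"reference gene missing for samples: {list(ref.index[ref.isna()])[:5]}"
        )
    targets = wide.drop(index=reference_gene)
    dct = targets.sub(ref, axis=1)
    if pooled_control not in dct.columns:
        raise ValueError(f"pooled control sample {pooled_control!r} absent from Cq table")
    ddct = dct.sub(dct[pooled_control], axis=0).drop(columns=pooled_control)
    return -ddct * math.log(2.0, log_base)


def classify_r(r: float, high: float = 0.85, moderate: float = 0.5) -> str:
    """Concordance class from the qPCR-array correlation r."""
    if np.isnan(r):
        return "other"
    if r > high:
        return "high"
    if r > moderate:
        return "moderate"
    if r < 0:
        return "opposite"
    return "other"


def concordance(
    qpcr_means: pd.DataFrame,
    array_means: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation across the four quadrant means, qPCR vs array, per gene.

    Both inputs are genes x quadrants (columns HH, HL, LL, LH) on their native
    scales (log fold change and log2 intensity). Genes present in both tables are
    scored; a gene with zero variance on either scale gets r = NaN and class
    ``other`` with a warning.

    Returns a DataFrame with columns ``r`` and ``concordance_class``; per-class
    counts are attached as ``.attrs['class_counts']``.
    """
    genes = qpcr_means.index.intersection(array_means.index)
    cols = list(QUADRANTS)
    rows = []
    for g in genes:
        x = qpcr_means.loc[g, cols].to_numpy(dtype=float)
        y = array_means.loc[g, cols].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            log.warning("gene %s has zero variance across quadrants; r undefined", g)
            r = float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = float(stats.pearsonr(x, y)[0])
        rows.append({"gene": g, "r": r, "concordance_class": classify_r(r)})
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["class_counts"] = out["concordance_class"].value_counts().to_dict()
    return out


def load_table(name: str) -> pd.DataFrame:
    """Load a packaged TSV fixture (e.g. ``table3`` with printed validation means)."""
    ref = resources.files("feedquad").joinpath("data", f"{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
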