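"""Feed-efficiency phenotypes: gain from serial weights, bivariate divergent selection.

Animals are weighed repeatedly over an 84-day feeding trial while cumulative dry-matter
intake is recorded. Total gain is taken from a quadratic regression of body weight on
days on study, each animal is placed in the (gain, intake) plane, and the most divergent
animals in each Cartesian quadrant (HH, HL, LL, LH: sign of the standardized gain and
intake deviations) are selected for tissue sampling, subject to a breed-balance rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GainFit",
    "fit_gain",
    "rank_bivariate",
    "select_divergent",
    "group_summary",
    "QUADRANTS",
]

#: Quadrant codes: first letter = gain side, second = intake side.
QUADRANTS = ("HH", "HL", "LL", "LH")

TRIAL_DAYS = 84


@dataclass(frozen=True)
class GainFit:
    """Quadratic growth-curve fit w(d) = b0 + b1*d + b2*d**2 and the derived total gain."""

    b0: float
    b1: float
    b2: float
    gain_total: float


def fit_gain(
    weights: Sequence[tuple[float, float]],
    animal_id: str | None = None,
    trial_days: int = TRIAL_DAYS,
    edge_window: int = 7,
) -> GainFit:
    """Fit body weight on (1, day, day^2) by OLS and return total gain over the trial.

    ``gain_total`` is the fitted weight at ``trial_days`` minus the fitted weight at
    day 0, i.e. ``b1*trial_days + b2*trial_days**2``.

    Parameters
    ----------
    weights
        Sequence of (day, body weight kg) pairs. At least 4 distinct days are
        required, including measurements within ``edge_window`` days of both the
        start and the end of the trial, so the fitted span is anchored.
    animal_id
        Used only to name the animal in error messages.

    Raises
    ------
    ValueError
        If fewer than 4 distinct days are present or the trial edges are not covered.
    """
    who = f" for animal {animal_id!r}" if animal_id is not None else ""
    arr = np.asarray(weights, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"weights must be (day, kg) pairs{who}")
    days, w = arr[:, 0], arr[:, 1]
    if np.unique(days).size < 4:
        raise ValueError(f"need >=4 distinct weigh days{who}, got {np.unique(days).size}")
    if days.min() > edge_window or days.max() < trial_days - edge_window:
        raise ValueError(
            f"weigh days must cover both trial edges (within {edge_window} d of 0 and "
            f"{trial_days}){who}; observed span [{days.min():g}, {days.max():g}]"
        )
    X = np.column_stack([np.ones_like(days), days, days**2])
    coef, _, rank, _ = np.linalg.lstsq(X, w, rcond=None)
    if rank < 3:
        raise ValueError(f"singular design in growth-curve fit{who}")
    b0, b1, b2 = coef
    return GainFit(float(b0), float(b1), float(b2), float(b1 * trial_days + b2 * trial_days**2))


def _quadrant(zg: np.ndarray, zi: np.ndarray) -> np.ndarray:
    gain_side = np.where(zg >= 0, "H", "L")
    intake_side = np.where(zi >= 0, "H", "L")
    return np.char.add(gain_side, intake_side)


def rank_bivariate(records: pd.DataFrame) -> pd.DataFrame:
    """Standardize (gain, intake), compute the bivariate distance d, and rank per quadrant.

    The distance is the Mahalanobis distance of the standardized pair under the sample
    gain-intake correlation r::

        d = sqrt((z_gain**2 - 2*r*z_gain*z_intake + z_intake**2) / (1 - r**2))

    which reduces to the Euclidean norm of (z_gain, z_intake) when r = 0. Animals are
    assigned to quadrants by the signs of (z_gain, z_intake) and ranked within quadrant
    by descending d (rank 1 = most divergent).

    Parameters
    ----------
    records
        DataFrame with columns ``gain_total`` and ``intake_total`` (one row per animal).

    Returns
    -------
    Copy of ``records`` with added columns ``z_gain``, ``z_intake``, ``d``,
    ``quadrant``, ``rank``.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to estimate means, sds and r")
    out = records.copy()
    g = out["gain_total"].to_numpy(dtype=float)
    i = out["intake_total"].to_numpy(dtype=float)
    sg, si = g.std(ddof=1), i.std(ddof=1)
    if sg <= 0 or si <= 0:
        raise ValueError("zero variance in gain or intake")
    zg = (g - g.mean()) / sg
    zi = (i - i.mean()) / si
    r = float(np.corrcoef(g, i)[0, 1])
    if abs(r) >= 1 - 1e-12:
        raise ValueError(f"degenerate bivariate normal: |r| = {abs(r):.6g} >= 1")
    d = np.sqrt((zg**2 - 2 * r * zg * zi + zi**2) / (1 - r**2))
    out["z_gain"] = zg
    out["z_intake"] = zi
    out["d"] = d
    out["quadrant"] = _quadrant(zg, zi)
    out["rank"] = (
        out.groupby("quadrant")["d"].rank(ascending=False, method="first").astype(int)
    )
    out.attrs["correlation"] = r
    return out


def dominant_breed(breed_fractions: Mapping[str, float]) -> str:
    """Breed with the largest composition fraction; ties broken lexicographically."""
    return min(breed_fractions, key=lambda b: (-breed_fractions[b], b))


def select_divergent(
    records: pd.DataFrame,
    k_per_quadrant: int = 4,
    max_per_breed: int = 2,
) -> pd.DataFrame:
    """Greedy divergent selection of ``k_per_quadrant`` animals per Cartesian quadrant.

    Within each quadrant, candidates are taken in descending order of d; a candidate
    whose dominant breed already has ``max_per_breed`` animals selected in that
    quadrant is skipped and the next rank is taken instead — the breed balance rule
    that avoids over-representing a sire breed within a phenotypic group.

    ``records`` must carry ``d``, ``quadrant`` and ``dominant_breed`` columns (the
    latter from :func:`dominant_breed` applied upstream) and, optionally, an
    ``excluded`` boolean column (health exclusions, dropped before ranking).

    Returns the selected rows with a ``selected`` flag set, sorted by quadrant then rank.
    """
    df = records
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    chosen: list[pd.Series] = []
    for quad in QUADRANTS:
        cand = df[df["quadrant"] == quad].sort_values("d", ascending=False)
        counts: dict[str, int] = {}
        taken = 0
        for _, row in cand.iterrows():
            breed = row["dominant_breed"]
            if counts.get(breed, 0) >= max_per_breed:
                continue
            counts[breed] = counts.get(breed, 0) + 1
            chosen.append(row)
            taken += 1
            if taken == k_per_quadrant:
                break
        if taken < k_per_quadrant:
            raise ValueError(
                f"quadrant {quad} exhausted: only {taken} of {k_per_quadrant} "
                f"selectable under max_per_breed={max_per_breed}"
            )
    out = pd.DataFrame(chosen)
    out["selected"] = True
    return out


def _round_half_even_int(x: float) -> int:
    # round-half-to-even at integer precision, as used for the reported kg values
    return int(np.rint(x))


def group_summary(selected: pd.DataFrame) -> pd.DataFrame:
    """Per-quadrant and pooled high/low mean, sd, min, max of gain and intake.

    Pooled rows (``Hg``/``Lg`` for gain, ``Hi``/``Li`` for intake) are computed over
    the union of the two constituent quadrants; with equal quadrant sizes this equals
    the average of the quadrant means. ``mean_kg`` columns are reported as integers
    with round-half-to-even; sd is reported to 1 decimal.
    """
    groups: dict[str, pd.DataFrame] = {}
    for quad in QUADRANTS:
        sub = selected[selected["quadrant"] == quad]
        if len(sub) == 0:
            raise ValueError(f"quadrant {quad} is empty")
        groups[quad] = sub
    groups["high_gain"] = pd.concat([groups["HH"], groups["HL"]])
    groups["low_gain"] = pd.concat([groups["LL"], groups["LH"]])
    groups["high_intake"] = pd.concat([groups["HH"], groups["LH"]])
    groups["low_intake"] = pd.concat([groups["HL"], groups["LL"]])

    rows = []
    for name, sub in groups.items():
        row: dict[str, object] = {"group": name, "n": len(sub)}
        for var, col in (("gain", "gain_total"), ("intake", "intake_total")):
            v = sub[col].to_numpy(dtype=float)
            row[f"{var}_mean_kg"] = _round_half_even_int(v.mean())
            row[f"{var}_sd"] = round(float(v.std(ddof=1)), 1)
            row[f"{var}_min"] = float(v.min())
            row[f"{var}_max"] = float(v.max())
        rows.append(row)
    return pd.DataFrame(rows)
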