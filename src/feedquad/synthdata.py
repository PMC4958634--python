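"""Synthetic study emulation: phenotypes, expression, qPCR and read-depth inputs.

Generates every input the pipeline consumes, with known ground truth, emulating a
divergent feed-efficiency design in beef steers: a cohort of ~148 animals phenotyped
for 84-day total gain and dry-matter intake (bivariate normal with a configurable
gain-intake correlation), a normalized log2 expression matrix over ~24,431 genes with
quadrant effects planted in a minority of genes, duplicate/triplicate qPCR Cq values
consistent with the expression matrix, and a windowed exome-like read-depth panel
near 20x coverage with implanted integer-copy-number variants covering ~0.45% of the
genome.

A single integer seed governs all randomness; each generator draws from its own
deterministically derived substream, so any output table is reproducible in isolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phenotypes import QUADRANTS, TRIAL_DAYS, dominant_breed

__all__ = ["SimConfig", "TruthSet", "simulate_phenotypes", "simulate_expression",
           "simulate_read_depth", "simulate_qpcr", "simulate_gene_annotation"]

log = logging.getLogger(__name__)

BREED_POOL = (
    "Angus", "Beefmaster", "Brahman", "Brangus", "Braunvieh", "Charolais",
    "Chiangus", "Gelbvieh", "Hereford", "Limousin", "MaineAnjou", "RedAngus",
    "Salers", "SantaGertrudis", "Shorthorn", "Simmental",
)

WEIGH_DAYS = (0, 1, 21, 42, 63, 83, 84)

# substream tags (second word of the rng seed sequence)
_STREAMS = {"pheno": 0, "expr": 1, "depth": 2, "qpcr": 3, "genes": 4}


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Phenotype defaults put the selected extreme quadrants near the reported group
    means (e.g. top-ranked high-gain-high-intake animals around 187 kg gain and
    1210 kg intake); expression defaults mirror the platform size (24,431 genes,
    16 arrays) with large planted effects (1-2 log2 units) against a 0.3 log2-unit
    residual; the read-depth panel uses ~40 reads per 300-bp window, the yield of a
    20x exome with 150-bp reads, and implants CNVs over 0.45% of the genome.
    """

    # phenotypes
    n_animals: int = 148
    pheno_mean_gain: float = 150.0     # kg over the 84-d trial
    pheno_mean_intake: float = 950.0   # kg dry matter
    pheno_sd_gain: float = 25.0
    pheno_sd_intake: float = 180.0
    pheno_correlation: float = 0.6
    weight_noise_sd: float = 2.0       # kg, per weigh day
    # expression
    n_genes: int = 24431
    n_arrays: int = 16
    de_fraction: float = 0.02
    de_effect_range: tuple[float, float] = (1.0, 2.0)  # log2 units
    residual_sd: float = 0.3
    # read depth
    n_depth_samples: int = 16
    genome_length: int = 30_000_000
    n_windows: int = 10_000
    window_size: int = 300
    mean_coverage: float = 40.0        # expected diploid reads per window
    cnv_fraction_of_genome: float = 0.0045
    cnv_copy_numbers: tuple[int, ...] = (0, 1, 3, 4)
    cnv_min_windows: int = 4
    cnv_max_windows: int = 12
    cnv_share_prob: float = 0.4        # chance a CNV locus is shared by 2-4 samples
    # qPCR
    qpcr_noise_sd: float = 0.15        # Cq units per replicate
    cq_anchor: float = 30.0            # Cq of a gene at log2 expression 0
    reference_cq: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if not -1 < self.pheno_correlation < 1:
            raise ValueError(
                f"pheno_correlation={self.pheno_correlation} gives a non-positive-"
                "definite covariance; need |rho| < 1"
            )
        for name in ("pheno_sd_gain", "pheno_sd_intake", "residual_sd", "qpcr_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_windows * self.window_size > self.genome_length:
            raise ValueError("n_windows * window_size exceeds genome_length")
        if not all(0 <= c <= 8 and c != 2 for c in self.cnv_copy_numbers):
            raise ValueError("cnv_copy_numbers must lie in [0, 8] and exclude diploid 2")
        if self.cnv_fraction_of_genome >= 0.1:
            raise ValueError("cnv_fraction_of_genome must be < 0.1")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-generator substream of the global seed."""
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class TruthSet:
    """Ground truth the generators expose for recovery experiments.

    ``de_effects`` maps DE gene id to its per-quadrant effect vector (HH, HL, LL, LH)
    in log2 units (zero for non-DE genes, which are simply absent); ``implanted_cnvs``
    has one row per (sample, locus) with half-open bp coordinates and the true copy
    number; ``expressed_genes`` are the genes drawn from the active baseline component.
    """

    de_effects: dict[str, np.ndarray] = field(default_factory=dict)
    implanted_cnvs: pd.DataFrame = field(default_factory=pd.DataFrame)
    expressed_genes: set[str] = field(default_factory=set)

    def cnv_loci(self) -> pd.DataFrame:
        """Distinct implanted loci (union over samples)."""
        if self.implanted_cnvs.empty:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return self.implanted_cnvs[["chrom", "start", "end"]].drop_duplicates()


def simulate_phenotypes(cfg: SimConfig) -> pd.DataFrame:
    """Cohort phenotypes: serial weights from quadratic growth curves plus intake.

    Total gain and total intake are drawn from the configured bivariate normal; each
    animal's body weight follows its own quadratic curve over days 0-84 (anchored so
    the curve's day-0 to day-84 difference equals the drawn gain) with measurement
    noise, so refitting with :func:`feedquad.phenotypes.fit_gain` recovers the gain.

    Returns one row per animal with ``animal_id``, ``weights`` (list of (day, kg)),
    ``intake_total``, ``gain_true``, ``breed_fractions`` (dict summing to 1),
    ``dominant_breed`` and an ``excluded`` health flag (all False here).
    """
    rng = cfg.rng("pheno")
    cov = np.array(
        [
            [cfg.pheno_sd_gain**2, cfg.pheno_correlation * cfg.pheno_sd_gain * cfg.pheno_sd_intake],
            [cfg.pheno_correlation * cfg.pheno_sd_gain * cfg.pheno_sd_intake, cfg.pheno_sd_intake**2],
        ]
    )
    gi = rng.multivariate_normal([cfg.pheno_mean_gain, cfg.pheno_mean_intake], cov, cfg.n_animals)
    days = np.array(WEIGH_DAYS, dtype=float)
    rows = []
    for i in range(cfg.n_animals):
        gain, intake = gi[i]
        w0 = rng.normal(330.0, 30.0)
        b2 = rng.normal(0.004, 0.002)
        b1 = (gain - b2 * TRIAL_DAYS**2) / TRIAL_DAYS
        curve = w0 + b1 * days + b2 * days**2
        noisy = curve + rng.normal(0.0, cfg.weight_noise_sd, len(days))
        breeds = rng.choice(len(BREED_POOL), size=3, replace=False)
        dom_frac = rng.uniform(0.5, 0.75)
        rest = rng.dirichlet([1.0, 1.0]) * (1.0 - dom_frac)
        fracs = {BREED_POOL[breeds[0]]: dom_frac,
                 BREED_POOL[breeds[1]]: rest[0],
                 BREED_POOL[breeds[2]]: rest[1]}
        rows.append(
            {
                "animal_id": f"A{i + 1:04d}",
                "weights": list(zip(days.tolist(), noisy.tolist())),
                "intake_total": float(intake),
                "gain_true": float(gain),
                "breed_fractions": fracs,
                "dominant_breed": dominant_breed(fracs),
                "excluded": False,
            }
        )
    return pd.DataFrame(rows)


_PATTERNS = ("gain", "intake", "interaction", "quadrant")


def _effect_vector(pattern: str, magnitude: float, rng: np.random.Generator) -> np.ndarray:
    e = np.zeros(4)  # (HH, HL, LL, LH)
    if pattern == "gain":
        e[[0, 1]] = magnitude
    elif pattern == "intake":
        e[[0, 3]] = magnitude
    elif pattern == "interaction":
        e[[0, 2]] = magnitude
    else:
        e[rng.integers(4)] = magnitude
    return e


def simulate_expression(
    cfg: SimConfig, quadrant_labels: dict[str, str] | None = None
) -> tuple[pd.DataFrame, TruthSet]:
    """Normalized log2 expression matrix with quadrant effects in a minority of genes.

    Baseline per-gene means are drawn from a two-component (inactive/active) mixture
    so that activity calling has real structure to find; a ``de_fraction`` subset of
    genes receives a signed per-quadrant effect (gain, intake, interaction or
    single-quadrant pattern, magnitude uniform in ``de_effect_range``); residuals are
    i.i.d. normal with sd ``residual_sd``.

    Parameters
    ----------
    quadrant_labels
        Map sample id -> quadrant covering all four quadrants; defaults to
        ``n_arrays`` samples split evenly over (HH, HL, LL, LH).
    """
    rng = cfg.rng("expr")
    if quadrant_labels is None:
        quadrant_labels = {
            f"S{i + 1:02d}": QUADRANTS[i % 4] for i in range(cfg.n_arrays)
        }
    if set(quadrant_labels.values()) != set(QUADRANTS):
        raise ValueError("quadrant_labels must cover all four quadrants")
    samples = list(quadrant_labels)
    qidx = np.array([QUADRANTS.index(quadrant_labels[s]) for s in samples])

    genes = np.array([f"gene_{i + 1:05d}" for i in range(cfg.n_genes)])
    active = rng.random(cfg.n_genes) < 0.6
    baseline = np.where(active, rng.normal(10.0, 1.0, cfg.n_genes), rng.normal(6.0, 1.0, cfg.n_genes))

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    if cfg.de_fraction > 0 and n_de == 0:
        warnings.warn("de_fraction * n_genes < 1; no DE genes planted", stacklevel=2)
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False) if n_de else np.array([], int)

    effects = np.zeros((cfg.n_genes, 4))
    truth = TruthSet()
    for gi in de_idx:
        pattern = _PATTERNS[rng.integers(len(_PATTERNS))]
        mag = rng.uniform(*cfg.de_effect_range) * rng.choice([-1.0, 1.0])
        effects[gi] = _effect_vector(pattern, mag, rng)
        truth.de_effects[genes[gi]] = effects[gi].copy()
    truth.expressed_genes = set(genes[active])

    values = (
        baseline[:, None]
        + effects[:, qidx]
        + rng.normal(0.0, cfg.residual_sd, (cfg.n_genes, len(samples)))
    )
    expr = pd.DataFrame(values, index=genes, columns=samples)
    expr.attrs["quadrants"] = dict(quadrant_labels)
    return expr, truth


def simulate_read_depth(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Windowed read-depth panel with implanted multi-window CNVs.

    Windows tile the start of the genome contiguously (``n_windows`` windows of
    ``window_size`` bp on chromosome ``1``). Counts for window w and sample j are
    Poisson with mean ``mean_coverage * s_j * CN(w, j) / 2``, with size factors s_j
    near 1; an implanted CN of 0 therefore yields exactly zero counts. CNV loci are
    non-overlapping (with a one-window gap), span ``cnv_min_windows`` to
    ``cnv_max_windows`` consecutive windows, and are shared across 2-4 samples with
    probability ``cnv_share_prob``; loci are drawn until their union covers
    ``cnv_fraction_of_genome`` of the genome.

    Returns ``(windows, counts, truth)``: windows (chrom/start/end), counts
    (windows x samples DataFrame), truth with one implanted row per (sample, locus).
    """
    rng = cfg.rng("depth")
    W, S = cfg.n_windows, cfg.n_depth_samples
    starts = np.arange(W) * cfg.window_size
    windows = pd.DataFrame(
        {"chrom": "1", "start": starts, "end": starts + cfg.window_size}
    )
    samples = [f"D{j + 1:03d}" for j in range(S)]

    budget = cfg.cnv_fraction_of_genome * cfg.genome_length / cfg.window_size
    occupied = np.zeros(W, dtype=bool)
    loci: list[tuple[int, int]] = []  # window index ranges [w0, w1)
    span = 0
    attempts = 0
    while span < budget - cfg.cnv_min_windows and attempts < 10_000:
        attempts += 1
        length = int(rng.integers(cfg.cnv_min_windows, cfg.cnv_max_windows + 1))
        length = min(length, int(np.ceil(budget - span)))
        if length < cfg.cnv_min_windows:
            break
        w0 = int(rng.integers(0, W - length))
        # one-window flanks keep loci from abutting
        lo, hi = max(w0 - 1, 0), min(w0 + length + 1, W)
        if occupied[lo:hi].any():
            continue
        occupied[lo:hi] = True
        loci.append((w0, w0 + length))
        span += length
    if cfg.cnv_fraction_of_genome > 0 and not loci:
        raise ValueError("window grid cannot accommodate any implanted CNV")

    cn = np.full((W, S), 2, dtype=int)
    truth_rows = []
    for w0, w1 in loci:
        copy = int(rng.choice(cfg.cnv_copy_numbers))
        if rng.random() < cfg.cnv_share_prob:
            carriers = rng.choice(S, size=int(rng.integers(2, min(4, S) + 1)), replace=False)
        else:
            carriers = [int(rng.integers(S))]
        for j in np.sort(np.asarray(carriers)):
            cn[w0:w1, j] = copy
            truth_rows.append(
                {
                    "sample": samples[int(j)],
                    "chrom": "1",
                    "start": int(starts[w0]),
                    "end": int(starts[w1 - 1] + cfg.window_size),
                    "cn": copy,
                }
            )
    truth = TruthSet(implanted_cnvs=pd.DataFrame(truth_rows))

    s_j = rng.uniform(0.9, 1.1, S)
    s_j /= s_j.mean()
    lam = cfg.mean_coverage * s_j[None, :] * cn / 2.0
    counts = pd.DataFrame(rng.poisson(lam), index=windows.index, columns=samples)
    return windows, counts, truth


def simulate_qpcr(
    expr: pd.DataFrame,
    genes: list[str],
    cfg: SimConfig,
    reference_gene: str = "RN18S",
    pooled_control: str = "POOL",
) -> pd.DataFrame:
    """Replicate Cq values consistent with an expression matrix.

    Cq is inversely linear in log2 expression with slope -1 (``cq_anchor`` minus the
    log2 value) plus per-replicate noise. Targets are measured in duplicate per
    sample and in triplicate for the pooled control; the reference gene is measured
    in triplicate for every sample and the pool, with no group effect. The pooled
    control's expression is the per-gene median across samples (a robust pool-level
    baseline, so a single divergent quadrant does not displace the control).

    Returns a long DataFrame with columns ``gene``, ``sample``, ``replicate``, ``cq``.
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    rng = cfg.rng("qpcr")
    rows = []

    def emit(gene: str, sample: str, level_cq: float, n_rep: int) -> None:
        for rep in range(n_rep):
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "replicate": rep + 1,
                    "cq": level_cq + rng.normal(0.0, cfg.qpcr_noise_sd),
                }
            )

    pooled = expr.loc[genes].median(axis=1)
    for g in genes:
        for s in expr.columns:
            emit(g, s, cfg.cq_anchor - float(expr.at[g, s]), 2)
        emit(g, pooled_control, cfg.cq_anchor - float(pooled[g]), 3)
    for s in list(expr.columns) + [pooled_control]:
        emit(reference_gene, s, cfg.reference_cq, 3)
    return pd.DataFrame(rows)


def simulate_gene_annotation(
    cfg: SimConfig, n_genes: int = 400, min_len: int = 1_000, max_len: int = 10_000
) -> pd.DataFrame:
    """Random non-overlapping gene spans over the genome (half-open coordinates).

    Gene ids follow the expression matrix naming so CNV-gene and expressed-gene sets
    intersect naturally.
    """
    rng = cfg.rng("genes")
    starts = np.sort(rng.choice(cfg.genome_length - max_len, size=n_genes, replace=False))
    lengths = rng.integers(min_len, max_len, n_genes)
    ends = np.minimum(starts + lengths, np.r_[starts[1:], cfg.genome_length])
    ok = ends > starts
    return pd.DataFrame(
        {
            "chrom": "1",
            "start": starts[ok],
            "end": ends[ok],
            "gene": [f"gene_{i + 1:05d}" for i in range(int(ok.sum()))],
        }
    )
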