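"""Synthetic case-control study generator.

Null model: per-site minor allele frequencies drawn from a density
proportional to 1/x (approximating a neutral allele-frequency spectrum)
truncated to [1/(2N), maf_max], or uniform; genotypes are independent
Hardy-Weinberg dosage draws Binomial(2, MAF); sites are independent (no
linkage disequilibrium); labels carry no information.

Disease model: a window of w consecutive variants on one chromosome is
causal. Each causal variant is independently detrimental (probability pdv,
per-allele odds ratio drawn uniformly from an interval), neutral
(probability pnv, OR = 1) or protective (the reciprocal of an interval
draw). Disease risk follows a logistic model
P(case) = expit(beta0 + sum_v dosage_v * ln OR_v), with beta0 solved so the
population prevalence equals K; cases and controls are collected by
rejection sampling from the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .io import GenotypeTable, Phenotype, orient_and_filter
from .permutation import sma_min_p
from .scan import study_min_p

__all__ = [
    "NullSimConfig",
    "DiseaseSimConfig",
    "CausalTruth",
    "PowerEstimate",
    "simulate_null_study",
    "simulate_disease_study",
    "estimate_power",
    "solve_beta0",
]

_POS_GAP = (100, 10_000)  # base-pair gaps between adjacent simulated sites


@dataclass
class NullSimConfig:
    """Null-model study design.

    chrom_lengths gives the number of variant sites per chromosome; maf_max
    bounds the simulated MAFs (default 0.05, the largest scan threshold);
    the 1/x spectrum is truncated below at 1/(2N) (one allele copy).
    """

    n_individuals: int
    n_case: int
    chrom_lengths: Sequence[int] = (500, 500)
    maf_max: float = 0.05
    maf_spectrum: str = "one_over_x"
    maf_min: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if not (1 <= self.n_case < self.n_individuals):
            raise ValueError("need 1 <= n_case < n_individuals")
        if any(int(c) < 1 for c in self.chrom_lengths):
            raise ValueError("all chromosome variant counts must be >= 1")
        if not (0 < self.maf_max <= 0.5):
            raise ValueError("maf_max must be in (0, 0.5]")
        if self.maf_spectrum not in ("one_over_x", "uniform"):
            raise ValueError(f"unknown maf_spectrum: {self.maf_spectrum!r}")


@dataclass
class DiseaseSimConfig:
    """Disease-model study design on top of a null design.

    prevalence K is the population disease probability; window_size is the
    number of consecutive causal variants; pdv/pnv are the proportions of
    detrimental/neutral variants in the window (remainder protective);
    or_interval bounds the per-allele odds ratio of detrimental variants.
    """

    base: NullSimConfig
    prevalence: float = 0.01
    window_size: int = 20
    pdv: float = 0.7
    pnv: float = 0.3
    or_interval: Tuple[float, float] = (1.5, 1.5)
    causal_chrom: int = 0
    window_start: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if self.pdv < 0 or self.pnv < 0 or self.pdv + self.pnv > 1 + 1e-12:
            raise ValueError("need pdv, pnv >= 0 and pdv + pnv <= 1")
        lo, hi = self.or_interval
        if not (1 <= lo <= hi):
            raise ValueError("or_interval must satisfy 1 <= low <= high")
        if self.window_size > self.base.chrom_lengths[self.causal_chrom]:
            raise ValueError("causal window longer than its chromosome")


@dataclass
class CausalTruth:
    """Ground truth of a simulated disease study."""

    chrom: str
    window_indices: Tuple[int, int]  # 0-based inclusive, within chromosome
    window_positions: Tuple[int, int]
    or_values: np.ndarray  # per causal variant
    roles: list[str]  # 'detrimental' | 'neutral' | 'protective'
    beta0: float


@dataclass
class PowerEstimate:
    """Monte-Carlo power of the exhaustive scan and of single-marker
    analysis on the same replicates."""

    power_gecs: float
    power_sma: float
    se_gecs: float
    se_sma: float
    n_reps: int


def _draw_mafs(config: NullSimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lo = config.maf_min if config.maf_min is not None else 1.0 / (2 * config.n_individuals)
    hi = config.maf_max
    if lo >= hi:
        raise ValueError("maf_min must be below maf_max")
    u = rng.random(n)
    if config.maf_spectrum == "one_over_x":
        return lo * (hi / lo) ** u  # inverse CDF of density ~ 1/x on [lo, hi]
    return lo + (hi - lo) * u


def _site_table(chrom_lengths: Sequence[int], rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for c, n_var in enumerate(chrom_lengths, start=1):
        gaps = rng.integers(_POS_GAP[0], _POS_GAP[1] + 1, size=int(n_var))
        pos = np.cumsum(gaps)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": str(c),
                    "pos": pos,
                    "id": [f"sim{c}_{k}" for k in range(int(n_var))],
                    "ref": "A",
                    "alt": "T",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_null_study(
    config: NullSimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[GenotypeTable, Phenotype]:
    """Generate a null study: HW genotypes, uninformative labels (the first
    n_case individuals are labeled cases)."""
    rng = _rng(rng, config.seed)
    sites = _site_table(config.chrom_lengths, rng)
    mafs = _draw_mafs(config, len(sites), rng)
    dosages = rng.binomial(2, mafs[:, None], size=(len(sites), config.n_individuals))
    gt = GenotypeTable(sites=sites, dosages=dosages.astype(np.int8), samples=_sample_ids(config.n_individuals))
    labels = np.zeros(config.n_individuals, dtype=np.int8)
    labels[: config.n_case] = 1
    return gt, Phenotype(labels)


def _sample_ids(n: int) -> list[str]:
    return [f"S{k:05d}" for k in range(n)]


def _rng(rng, seed) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def solve_beta0(
    mafs: np.ndarray,
    log_ors: np.ndarray,
    prevalence: float,
    rng: np.random.Generator,
    n_mc: int = 200_000,
) -> float:
    """Intercept of the logistic disease model such that the population
    prevalence equals ``prevalence``.

    With no causal effects the closed form logit(K) is returned; otherwise
    the expectation of expit(beta0 + s) over the Hardy-Weinberg genotype
    distribution of the causal sites is estimated with ``n_mc`` Monte-Carlo
    draws and beta0 solved by bisection.
    """
    log_ors = np.asarray(log_ors, dtype=np.float64)
    if log_ors.size == 0 or np.all(log_ors == 0):
        return float(logit(prevalence))
    dos = rng.binomial(2, np.asarray(mafs)[None, :], size=(n_mc, log_ors.size))
    s = dos @ log_ors

    def g(b0):
        return float(expit(b0 + s).mean() - prevalence)

    lo, hi = -45.0, 45.0
    if g(lo) > 0 or g(hi) < 0:
        raise ValueError("prevalence unattainable for the given effect sizes")
    return float(brentq(g, lo, hi, xtol=1e-10))


def simulate_disease_study(
    config: DiseaseSimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[GenotypeTable, Phenotype, CausalTruth]:
    """Generate a case-control study under the logistic disease model.

    Individuals are drawn from the population and accepted as case/control
    by rejection sampling until the design quotas (n_case, N - n_case) are
    filled; cases are placed first in the sample order.
    """
    rng = _rng(rng, config.seed)
    base = config.base
    sites = _site_table(base.chrom_lengths, rng)
    mafs = _draw_mafs(base, len(sites), rng)

    chrom_label = str(config.causal_chrom + 1)
    chrom_offset = int(np.sum([base.chrom_lengths[c] for c in range(config.causal_chrom)]))
    n_chrom = int(base.chrom_lengths[config.causal_chrom])
    w = int(config.window_size)
    if config.window_start is None:
        w0 = int(rng.integers(0, n_chrom - w + 1))
    else:
        w0 = int(config.window_start)
        if not (0 <= w0 <= n_chrom - w):
            raise ValueError("window_start out of range")
    causal = np.arange(chrom_offset + w0, chrom_offset + w0 + w)

    u_role = rng.random(w)
    roles = np.where(
        u_role < config.pdv,
        "detrimental",
        np.where(u_role < config.pdv + config.pnv, "neutral", "protective"),
    )
    lo, hi = config.or_interval
    draws = rng.uniform(lo, hi, size=w)
    or_values = np.where(
        roles == "detrimental", draws, np.where(roles == "neutral", 1.0, 1.0 / draws)
    )
    log_ors = np.log(or_values)
    beta0 = solve_beta0(mafs[causal], log_ors, config.prevalence, rng)

    n_case, n_ctrl = base.n_case, base.n_individuals - base.n_case
    case_cols: list[np.ndarray] = []
    ctrl_cols: list[np.ndarray] = []
    expected_draws = max(n_case / config.prevalence, n_ctrl / (1 - config.prevalence))
    batch = int(min(65_536, max(4096, expected_draws / 8)))
    max_draws = 50 * expected_draws + 10 * batch
    drawn = 0
    while len(case_cols) < n_case or len(ctrl_cols) < n_ctrl:
        g = rng.binomial(2, mafs[None, :], size=(batch, len(sites))).astype(np.int8)
        s = g[:, causal].astype(np.float64) @ log_ors
        is_case = rng.random(batch) < expit(beta0 + s)
        for idx in np.nonzero(is_case)[0]:
            if len(case_cols) < n_case:
                case_cols.append(g[idx])
        for idx in np.nonzero(~is_case)[0]:
            if len(ctrl_cols) < n_ctrl:
                ctrl_cols.append(g[idx])
        drawn += batch
        if drawn > max_draws and (len(case_cols) < n_case or len(ctrl_cols) < n_ctrl):
            raise RuntimeError("rejection sampling did not reach design quotas")

    genos = np.vstack(case_cols[:n_case] + ctrl_cols[:n_ctrl]).T.copy()  # variants x N
    gt = GenotypeTable(
        sites=sites, dosages=genos.astype(np.int8), samples=_sample_ids(base.n_individuals)
    )
    labels = np.zeros(base.n_individuals, dtype=np.int8)
    labels[:n_case] = 1
    pos = sites["pos"].to_numpy()
    truth = CausalTruth(
        chrom=chrom_label,
        window_indices=(w0, w0 + w - 1),
        window_positions=(int(pos[causal[0]]), int(pos[causal[-1]])),
        or_values=or_values.astype(np.float64),
        roles=list(roles),
        beta0=beta0,
    )
    return gt, Phenotype(labels), truth


def estimate_power(
    config: DiseaseSimConfig,
    alpha_gecs: float,
    alpha_sma: float,
    n_reps: int,
    rng: Optional[np.random.Generator] = None,
    maf_thresholds: Sequence[float] = (0.01, 0.03, 0.05),
) -> PowerEstimate:
    """Monte-Carlo power at pre-computed significance thresholds.

    Power is the fraction of replicates whose genome-wide minimum p
    (combined over MAF thresholds for the scan; over all sites for SMA)
    falls strictly below the respective threshold. Both methods are
    evaluated on the same replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = _rng(rng, config.seed)
    hits_gecs = 0
    hits_sma = 0
    for _ in range(n_reps):
        gt, ph, _ = simulate_disease_study(config, rng)
        panels = [p for t in maf_thresholds for p in orient_and_filter(gt, t)]
        if study_min_p(panels, ph) < alpha_gecs:
            hits_gecs += 1
        if sma_min_p(gt, ph) < alpha_sma:
            hits_sma += 1
    p_g = hits_gecs / n_reps
    p_s = hits_sma / n_reps
    return PowerEstimate(
        power_gecs=p_g,
        power_sma=p_s,
        se_gecs=float(np.sqrt(p_g * (1 - p_g) / n_reps)),
        se_sma=float(np.sqrt(p_s * (1 - p_s) / n_reps)),
        n_reps=n_reps,
    )
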