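"""Synthetic inputs: genotype tables and statistic populations.

Two generators cover everything the package's experiments consume:

* :func:`simulate_tables` draws per-SNP case/control genotype counts
  from Hardy-Weinberg proportions at a uniform minor-allele frequency
  in [0.05, 0.5] (the post-QC MAF range of a typical GWAS), with an
  optional per-allele genotype relative risk tilting the case group;
* :func:`simulate_statistic_population` draws large populations of test
  statistics directly from their null reference distributions (1- or
  2-df chi-square, optionally pushed through the P-value map, or a
  half-normal on the -log10 P scale), the construction used for the
  threshold-sweep experiments.

Both are fully deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tables import GenotypeTable, build_genotype_table
from .teststats import neg_log10_p_from_chi2

_MAX_RETRIES = 1000

#: Half-normal scale for the -log10 P population, chosen so the mass
#: above the genome-wide threshold 7.3 equals the nominal 5e-8.
HALF_NORMAL_SIGMA = 7.3 / stats.norm.isf(5e-8 / 2)

STATISTIC_KINDS = ("chi2_df1", "chi2_df2", "neg_log10_p_df1", "neg_log10_p_df2",
                   "half_normal_neg_log10_p")


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation settings.

    ``relative_risk`` is the per-minor-allele multiplicative genotype
    risk in cases (1.0 = no association, the null).
    """

    n_individuals: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    relative_risk: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals % 2 or self.n_individuals < 4:
            raise ValueError(f"n_individuals must be even and >= 4, got {self.n_individuals}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        lo, hi = self.maf_range
        if not 0.05 <= lo <= hi <= 0.5:
            raise ValueError(f"maf_range must lie within [0.05, 0.5], got {self.maf_range}")
        if not self.relative_risk > 0:
            raise ValueError("relative_risk must be positive")


def _genotype_probs(maf: float, relative_risk: float) -> tuple[np.ndarray, np.ndarray]:
    """(control, case) genotype probabilities at one SNP.

    Controls follow Hardy-Weinberg proportions; cases reweight genotype
    g by relative_risk**g and renormalize (multiplicative risk model).
    """
    q = maf
    hw = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    w = hw * relative_risk ** np.arange(3)
    return hw, w / w.sum()


def simulate_tables(cfg: SimConfig) -> list[GenotypeTable]:
    """Draw one valid genotype table per SNP.

    Case and control genotype counts are multinomial with exactly N/2
    individuals per group (the balanced-margins design).  Tables with a
    zero row margin are rejected and redrawn at the same MAF, up to a
    retry cap; exceeding the cap (which indicates a near-degenerate
    configuration, e.g. tiny N at the low end of the MAF range) is an
    error rather than a silent bias.
    """
    rng = np.random.default_rng(cfg.seed)
    half = cfg.n_individuals // 2
    out: list[GenotypeTable] = []
    for _ in range(cfg.n_snps):
        maf = rng.uniform(*cfg.maf_range)
        ctrl_p, case_p = _genotype_probs(maf, cfg.relative_risk)
        for attempt in range(_MAX_RETRIES):
            case = rng.multinomial(half, case_p)
            ctrl = rng.multinomial(half, ctrl_p)
            try:
                out.append(build_genotype_table(tuple(case), tuple(ctrl)))
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(
                f"could not draw a positive-margin table in {_MAX_RETRIES} tries "
                f"(N={cfg.n_individuals}, maf={maf:.3f})")
    return out


def simulate_statistic_population(kind: str, size: int, seed: int = 0) -> np.ndarray:
    """Population of statistics drawn from a null reference distribution.

    ``chi2_df1`` / ``chi2_df2`` are raw chi-square draws;
    ``neg_log10_p_df1`` / ``neg_log10_p_df2`` push those draws through
    the matching survival function in log space; and
    ``half_normal_neg_log10_p`` is the alternative -log10 P generator, a
    half-normal scaled so its tail above 7.3 carries the nominal 5e-8
    mass.
    """
    if size < 1:
        raise ValueError("size must be positive")
    rng = np.random.default_rng(seed)
    if kind == "chi2_df1":
        return rng.chisquare(1, size)
    if kind == "chi2_df2":
        return rng.chisquare(2, size)
    if kind == "neg_log10_p_df1":
        return neg_log10_p_from_chi2(rng.chisquare(1, size), 1)
    if kind == "neg_log10_p_df2":
        return neg_log10_p_from_chi2(rng.chisquare(2, size), 2)
    if kind == "half_normal_neg_log10_p":
        return np.abs(rng.normal(0.0, HALF_NORMAL_SIGMA, size))
    raise ValueError(f"unknown population kind {kind!r}; expected one of {STATISTIC_KINDS}")
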