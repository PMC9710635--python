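"""Laplace mechanism for epsilon-differentially private statistic release.

A statistic f with sensitivity ``delta`` is released as
``f(D) + Laplace(0, delta / epsilon)``, which satisfies
epsilon-differential privacy under the single-individual neighbor model
of :mod:`dpgwas.tables`.  Deterministic post-processing (clamping a
noisy P-value back into [0, 1], rounding a negative noisy -log10 P up
to 0) cannot weaken the guarantee and is applied by default for the
bounded forms.

Noise is generated by inverse-CDF transform of a named, seeded uniform
stream (numpy ``Philox``-family ``default_rng``), so a release is
bit-reproducible from ``(seed, inputs)`` across platforms.  Batch
releases derive one sub-stream per record from a hash of
``(seed, record id)``: each SNP's noise depends only on its own
identity, never on its position in the file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sensitivity import closed_form_sensitivity
from .tables import Table
from .teststats import ReleasedForm, TestKind, as_released_form, as_test_kind, run_test

logger = logging.getLogger(__name__)

#: epsilon range commonly studied for differentially private GWAS
#: releases; values outside it are accepted but logged.
EPSILON_CUSTOMARY_RANGE = (0.1, 10.0)


@dataclass(frozen=True)
class ClampPolicy:
    """Deterministic post-processing bounds for a released form.

    Clamping is applied after noise addition, so it preserves the
    privacy guarantee; it can only move the released value toward the
    truth (both lie on the same side of a violated bound).
    """

    lower: float
    upper: float
    enabled: bool = True

    @classmethod
    def for_form(cls, form: ReleasedForm | str) -> "ClampPolicy":
        """Defaults: P in [0, 1] and -log10 P >= 0 are clamped (a noisy
        probability below zero is meaningless), raw statistics are not."""
        form = as_released_form(form)
        if form is ReleasedForm.P_VALUE:
            return cls(0.0, 1.0, enabled=True)
        if form is ReleasedForm.NEG_LOG10_P:
            return cls(0.0, math.inf, enabled=True)
        return cls(0.0, math.inf, enabled=False)

    def apply(self, value: float) -> tuple[float, bool]:
        if not self.enabled:
            return value, False
        clamped = min(max(value, self.lower), self.upper)
        return clamped, clamped != value


@dataclass(frozen=True)
class PrivateRelease:
    """One noisy released value and the parameters that produced it."""

    test: TestKind
    form: ReleasedForm
    n_total: int
    epsilon: float
    scale: float
    true_value: float
    raw_noisy: float
    released: float
    clamped: bool
    seed: int
    snp_id: str | None = None


def laplace_quantile(u, scale):
    """Quantile function of Laplace(0, scale) (array-safe).

    ``-scale * sign(u - 1/2) * ln(1 - 2|u - 1/2|)`` for u in (0, 1);
    the median maps to 0 and the function is antisymmetric about it.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale}")
    half = u - 0.5
    out = -scale * np.sign(half) * np.log1p(-2.0 * np.abs(half))
    return float(out) if out.ndim == 0 else out


def laplace_noise(rng: np.random.Generator, scale: float, size=None):
    """Seeded Laplace(0, scale) draws by inverse CDF of ``rng``'s uniforms."""
    u = rng.random(size)
    if np.ndim(u) == 0:
        u = min(max(float(u), 1e-300), 1.0 - 1e-16)
    else:
        u = np.clip(u, 1e-300, 1.0 - 1e-16)
    return laplace_quantile(u, scale)


def _check_epsilon(epsilon: float) -> None:
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    lo, hi = EPSILON_CUSTOMARY_RANGE
    if not lo <= epsilon <= hi:
        logger.warning("epsilon=%g lies outside the customary [%g, %g] range",
                       epsilon, lo, hi)


def release_value(true_value: float, test: TestKind | str, form: ReleasedForm | str,
                  N: int, epsilon: float, clamp: ClampPolicy | None = None,
                  seed: int = 0) -> PrivateRelease:
    """Release one statistic with epsilon-differential privacy.

    Noise scale is ``closed_form_sensitivity(test, form, N) / epsilon``;
    identical ``(seed, inputs)`` give an identical release.
    """
    test = as_test_kind(test)
    form = as_released_form(form)
    _check_epsilon(epsilon)
    if clamp is None:
        clamp = ClampPolicy.for_form(form)
    scale = closed_form_sensitivity(test, form, N) / epsilon
    rng = np.random.default_rng(seed)
    noisy = float(true_value) + float(laplace_noise(rng, scale))
    released, clamped = clamp.apply(noisy)
    return PrivateRelease(test=test, form=form, n_total=N, epsilon=epsilon,
                          scale=scale, true_value=float(true_value),
                          raw_noisy=noisy, released=released, clamped=clamped,
                          seed=seed)


def _record_seed(seed: int, key: str) -> int:
    """Stable 63-bit sub-seed for one record, from the master seed and an id."""
    digest = hashlib.sha256(f"{seed}|{key}".encode()).digest()
    return int.from_bytes(digest[:8], "little") >> 1


def release_batch(tables: Sequence[Table], test: TestKind | str,
                  form: ReleasedForm | str, epsilon: float, seed: int,
                  ids: Sequence[str] | None = None,
                  clamp: ClampPolicy | None = None,
                  catt_df: int = 2) -> list[PrivateRelease]:
    """Independent private release of one statistic per table.

    All tables must share the same N.  Each record's noise stream is
    keyed by ``(seed, id)`` (ids default to the table's canonical
    counts), so permuting the input permutes the output identically.

    The epsilon budget is *per SNP*: releasing many SNPs about the same
    individuals composes, and no composition accounting is done here —
    a warning is logged to that effect.
    """
    test = as_test_kind(test)
    form = as_released_form(form)
    if len(tables) == 0:
        raise ValueError("empty table batch")
    n_values = {t.N for t in tables}
    if len(n_values) != 1:
        raise ValueError(f"tables have heterogeneous N: {sorted(n_values)}")
    if ids is None:
        ids = [repr(t) for t in tables]
        # disambiguate duplicate tables so their noise draws stay independent
        seen: dict[str, int] = {}
        uniq = []
        for s in ids:
            k = seen.get(s, 0)
            seen[s] = k + 1
            uniq.append(s if k == 0 else f"{s}#{k}")
        ids = uniq
    elif len(ids) != len(tables):
        raise ValueError("ids and tables differ in length")
    logger.warning("per-SNP epsilon=%g: releasing %d SNPs does NOT compose to a "
                   "total budget of %g", epsilon, len(tables), epsilon)
    out = []
    for table, key in zip(tables, ids):
        result = run_test(table, test, catt_df=catt_df)
        true_value = {ReleasedForm.STATISTIC: result.statistic,
                      ReleasedForm.P_VALUE: result.p,
                      ReleasedForm.NEG_LOG10_P: result.neg_log10_p}[form]
        if true_value is None:
            raise ValueError(f"{test.value} has no raw statistic to release")
        rel = release_value(true_value, test, form, table.N, epsilon,
                            clamp=clamp, seed=_record_seed(seed, str(key)))
        out.append(dataclasses.replace(rel, snp_id=str(key), seed=seed))
    return out


def empirical_dp_check(value_a: float, value_b: float, scale: float,
                       epsilon: float, n_draws: int = 10**6, bins: int = 50,
                       seed: int = 0, z: float = 4.0) -> tuple[bool, float]:
    """Empirically audit the epsilon-DP bound on a neighboring pair.

    Draws ``n_draws`` mechanism outputs centered at each of two
    neighboring true values (whose gap should be at most the sensitivity
    ``scale * epsilon``), histograms both samples on shared bins, and
    checks that no bin's log count ratio exceeds epsilon beyond binomial
    sampling slack (``z`` standard errors on add-one-smoothed counts).

    Returns ``(passed, worst_excess)`` where ``worst_excess`` is the
    largest slack-adjusted violation of epsilon in nats (negative when
    the bound holds everywhere).
    """
    rng_a = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    rng_b = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    sample_a = value_a + laplace_noise(rng_a, scale, n_draws)
    sample_b = value_b + laplace_noise(rng_b, scale, n_draws)
    lo = min(sample_a.min(), sample_b.min())
    hi = max(sample_a.max(), sample_b.max())
    edges = np.linspace(lo, hi, bins + 1)
    count_a, _ = np.histogram(sample_a, bins=edges)
    count_b, _ = np.histogram(sample_b, bins=edges)
    ca = count_a + 1.0
    cb = count_b + 1.0
    log_ratio = np.abs(np.log(ca) - np.log(cb))
    slack = z * np.sqrt(1.0 / ca + 1.0 / cb)
    excess = float(np.max(log_ratio - slack) - epsilon)
    return excess <= 0.0, excess
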