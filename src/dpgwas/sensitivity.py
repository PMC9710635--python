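"""Sensitivities of GWAS contingency-table statistics.

The global sensitivity of a statistic f is the largest change
``|f(D) - f(D')|`` over neighboring cohorts — cohorts differing in a
single individual's genotype, with group sizes fixed at N/2 cases and
N/2 controls.  The Laplace mechanism calibrated with scale
``sensitivity / epsilon`` then releases f with epsilon-differential
privacy.

Two routes are provided:

* :func:`closed_form_sensitivity` — exact closed forms for every
  supported (test, released-form) pair;
* :func:`brute_force_sensitivity` — an exhaustive oracle that
  enumerates every valid table at a given N, applies every
  single-individual move, and reports the maximum observed change.
  It reports separately (i) the restricted move class used in the
  closed-form derivations (the double allele flip ``(a, m) ->
  (a-2, m-2)`` on 2x2 tables, the genotype-0 -> genotype-2 move
  ``(a, b, m, n) -> (a-1, b, m-1, n)`` on 3x2 tables) and (ii) all
  single-individual moves, so the closed forms can be certified rather
  than trusted.

Closed forms (statistic / P-value / -log10 P-value per test):

===========  ==========================  ================================
test         form                        sensitivity
===========  ==========================  ================================
chi2_3x2     statistic                   4N / (N+2)
chi2_3x2     neg_log10_p                 log10(e) * 2N / (N+2)
chi2_2x2     statistic                   8N / (N+2)
chi2_2x2     p_value                     chi2_1 CDF at N/(N-2) (integral)
chi2_2x2     neg_log10_p                 2.33 (constant upper bound)
fisher_2x2   p_value                     N(7N-3) / (8(2N-1)(2N-3))
fisher_2x2   neg_log10_p                 log10((N+1)(N+2)/2)
fisher_3x2   neg_log10_p                 log10(N/2 + 1)
catt         statistic                   16N(N^2+6N+4) / ((N+18)(N^2+8N-4))
catt         neg_log10_p                 log10(e)/2 times the above
===========  ==========================  ================================

Pairs absent from the table (raw P-values for the 2-df tests, where the
noise would swamp the value; any form of a test with no useful bound)
are rejected explicitly rather than approximated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .teststats import (
    LOG10E,
    ReleasedForm,
    TestKind,
    as_released_form,
    as_test_kind,
    catt_from_counts,
    chi2_allele_from_counts,
    chi2_genotype_from_counts,
    log10_fisher_p_allele_from_counts,
    log10_fisher_p_genotype_from_counts,
    neg_log10_p_from_chi2,
)

#: Laplace scale used to release -log10 P for the 1-df chi-square test.
#: The exact sensitivity has no closed form; this constant upper bound
#: is what calibrates the mechanism (a looser scale never weakens the
#: privacy guarantee).  The tighter computed bound is available from
#: :func:`log10p_bound_2x2`.
CHI2_2X2_NEG_LOG10_P_BOUND = 2.33

_ENUM_LIMIT_2X2 = 200
_ENUM_LIMIT_3X2 = 100


@dataclass(frozen=True)
class SensitivitySpec:
    """A sensitivity value with its provenance.

    ``source`` names the derivation: a closed form, the constant bound,
    or the brute-force oracle.
    """

    test: TestKind
    form: ReleasedForm
    n_total: int
    delta: float
    source: str

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"sensitivity must be positive, got {self.delta}")


def sensitivity_spec(test: TestKind | str, form: ReleasedForm | str,
                     N: int) -> SensitivitySpec:
    """Closed-form sensitivity with provenance for a supported pair."""
    test = as_test_kind(test)
    form = as_released_form(form)
    if N % 2 or N < 4:
        raise ValueError(f"N must be an even integer >= 4, got {N}")
    key = (test, form)
    if key == (TestKind.CHI2_3X2, ReleasedForm.STATISTIC):
        return SensitivitySpec(test, form, N, 4.0 * N / (N + 2),
                               "3x2 chi-square statistic closed form")
    if key == (TestKind.CHI2_3X2, ReleasedForm.NEG_LOG10_P):
        return SensitivitySpec(test, form, N, LOG10E * 2.0 * N / (N + 2),
                               "3x2 chi-square log10 P closed form")
    if key == (TestKind.CHI2_2X2, ReleasedForm.STATISTIC):
        return SensitivitySpec(test, form, N, 8.0 * N / (N + 2),
                               "2x2 chi-square statistic closed form")
    if key == (TestKind.CHI2_2X2, ReleasedForm.P_VALUE):
        return SensitivitySpec(test, form, N, pvalue_sensitivity_integral_2x2(N),
                               "2x2 chi-square P-value integral")
    if key == (TestKind.CHI2_2X2, ReleasedForm.NEG_LOG10_P):
        return SensitivitySpec(test, form, N, CHI2_2X2_NEG_LOG10_P_BOUND,
                               "2x2 chi-square log10 P constant bound")
    if key == (TestKind.FISHER_2X2, ReleasedForm.P_VALUE):
        return SensitivitySpec(test, form, N,
                               N * (7.0 * N - 3) / (8.0 * (2 * N - 1) * (2 * N - 3)),
                               "2x2 exact-test P-value closed form")
    if key == (TestKind.FISHER_2X2, ReleasedForm.NEG_LOG10_P):
        return SensitivitySpec(test, form, N,
                               math.log10(0.5 * (N + 1) * (N + 2)),
                               "2x2 exact-test log10 P closed form")
    if key == (TestKind.FISHER_3X2, ReleasedForm.NEG_LOG10_P):
        return SensitivitySpec(test, form, N, math.log10(N / 2 + 1),
                               "3x2 exact-test log10 P closed form")
    if key == (TestKind.CATT, ReleasedForm.STATISTIC):
        return SensitivitySpec(test, form, N, _catt_stat_sensitivity(N),
                               "trend-test statistic closed form")
    if key == (TestKind.CATT, ReleasedForm.NEG_LOG10_P):
        return SensitivitySpec(test, form, N, LOG10E / 2.0 * _catt_stat_sensitivity(N),
                               "trend-test log10 P closed form")
    raise ValueError(
        f"no sensitivity is available for ({test.value}, {form.value}): releasing "
        "this form is not supported (for the 2-df tests the raw P-value carries "
        "noise far larger than any significant P-value, and no bound is derived "
        "for it)")


def closed_form_sensitivity(test: TestKind | str, form: ReleasedForm | str,
                            N: int) -> float:
    """The sensitivity value alone; see :func:`sensitivity_spec`."""
    return sensitivity_spec(test, form, N).delta


def _catt_stat_sensitivity(N: int) -> float:
    return 16.0 * N * (N**2 + 6.0 * N + 4) / ((N + 18.0) * (N**2 + 8.0 * N - 4))


def pvalue_sensitivity_integral_2x2(N: int) -> float:
    """P-value sensitivity of the 2x2 chi-square test, by quadrature.

    ``(1/sqrt(2 pi)) * int_0^{N/(N-2)} x^(-1/2) e^(-x/2) dx`` — the gap
    between P = 1 (a null table) and the P-value of its worst neighbor,
    whose statistic is N/(N-2).  Numerically this equals the 1-df
    chi-square CDF at N/(N-2) and tends to ~0.6827 as N grows.
    """
    if N <= 2:
        raise ValueError(f"N must exceed 2, got {N}")
    upper = N / (N - 2.0)
    # substitute x = t^2 to remove the integrable x^(-1/2) singularity at 0
    val, err = integrate.quad(lambda t: 2.0 * math.exp(-t * t / 2.0),
                              0.0, math.sqrt(upper), epsabs=1e-12)
    if err > 1e-10:
        raise RuntimeError(f"quadrature did not converge: error estimate {err}")
    return val / math.sqrt(2.0 * math.pi)


def log10p_bound_2x2() -> tuple[float, float]:
    """(computed, released) bound on the 2x2 chi-square -log10 P sensitivity.

    A one-individual change moves the 1-df statistic by less than 8, and
    ``-log10 sf(x, 1)`` changes fastest at x = 0, so the sensitivity is
    below ``log10(sf(0,1) / sf(8,1))`` ~ 2.3299.  The mechanism releases
    with the slightly looser published constant 2.33.
    """
    computed = float(neg_log10_p_from_chi2(8.0, 1) - neg_log10_p_from_chi2(0.0, 1))
    released = CHI2_2X2_NEG_LOG10_P_BOUND
    assert computed < released
    return computed, released


# ---------------------------------------------------------------------------
# brute-force oracle

@dataclass(frozen=True)
class OracleResult:
    """Exhaustive-enumeration sensitivity certificate at one N.

    ``proof_max`` / ``proof_argmax`` are the maximum change and a
    maximizing (table, neighbor) pair over the restricted move class
    used in the closed-form derivations; ``all_max`` / ``all_argmax``
    the same over every single-individual move.  Tables are given as
    canonical count tuples ``(a, m)`` or ``(a, b, m, n)``.
    """

    test: TestKind
    form: ReleasedForm
    n_total: int
    proof_max: float
    proof_argmax: tuple[tuple[int, ...], tuple[int, ...]]
    all_max: float
    all_argmax: tuple[tuple[int, ...], tuple[int, ...]]


# single-individual moves on the canonical lattices (see tables module)
_MOVES_2X2 = [(-1, -1), (1, 1), (-2, -2), (2, 2),
              (0, -1), (0, 1), (0, -2), (0, 2)]
_PROOF_MOVES_2X2 = [(-2, -2)]

_MOVES_3X2 = [(-1, 1, -1, 1), (1, -1, 1, -1), (-1, 0, -1, 0), (1, 0, 1, 0),
              (0, -1, 0, -1), (0, 1, 0, 1),
              (0, 0, -1, 1), (0, 0, 1, -1), (0, 0, -1, 0), (0, 0, 1, 0),
              (0, 0, 0, -1), (0, 0, 0, 1)]
_PROOF_MOVES_3X2 = [(-1, 0, -1, 0)]

_2X2_TESTS = {TestKind.CHI2_2X2, TestKind.FISHER_2X2}


def brute_force_sensitivity(test: TestKind | str, form: ReleasedForm | str,
                            N: int) -> OracleResult:
    """Certify a sensitivity by exhaustive enumeration.

    Enumerates every valid table with N individuals (vectorized over the
    ``(a, m)`` / ``(a, b, m, n)`` lattice), applies every
    single-individual move whose endpoint is also valid, and returns the
    maximum absolute change of the released quantity together with a
    maximizing pair — split by move class as described in
    :class:`OracleResult`.

    N is capped (200 for 2x2 tests, 100 for 3x2 tests) to keep the scan
    exhaustive yet fast; the closed forms themselves are derived for
    N >= 100, so N = 100 is the canonical certification point.
    """
    test = as_test_kind(test)
    form = as_released_form(form)
    if N % 2 or N < 8:
        raise ValueError(f"N must be an even integer >= 8, got {N}")
    if test in _2X2_TESTS:
        if N > _ENUM_LIMIT_2X2:
            raise ValueError(f"2x2 enumeration capped at N={_ENUM_LIMIT_2X2}, got {N}")
        values = _values_2x2(test, form, N)
        proof_max, proof_arg = _max_shift_diff(values, _PROOF_MOVES_2X2)
        all_max, all_arg = _max_shift_diff(values, _MOVES_2X2)
    else:
        if N > _ENUM_LIMIT_3X2:
            raise ValueError(f"3x2 enumeration capped at N={_ENUM_LIMIT_3X2}, got {N}")
        values = _values_3x2(test, form, N)
        proof_max, proof_arg = _max_shift_diff(values, _PROOF_MOVES_3X2)
        all_max, all_arg = _max_shift_diff(values, _MOVES_3X2)
    return OracleResult(test, form, N, proof_max, proof_arg, all_max, all_arg)


def _values_2x2(test: TestKind, form: ReleasedForm, N: int) -> np.ndarray:
    """Released value on the dense (a, m) lattice; NaN outside the domain."""
    a = np.arange(N + 1, dtype=float)[:, None]
    m = np.arange(2 * N + 1, dtype=float)[None, :]
    valid = (m >= 3) & (m <= 2 * N - 3) & (a <= m) & (m - a <= N)
    valid = np.broadcast_to(valid, (N + 1, 2 * N + 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        if test is TestKind.CHI2_2X2:
            stat = chi2_allele_from_counts(a, m, N)
            v = _from_chi2(stat, 1, form)
        elif form is ReleasedForm.P_VALUE:
            v = 10.0 ** log10_fisher_p_allele_from_counts(a, m, N)
        elif form is ReleasedForm.NEG_LOG10_P:
            v = -log10_fisher_p_allele_from_counts(a, m, N)
        else:
            raise ValueError(f"exact test has no '{form.value}' form")
    v = np.broadcast_to(v, valid.shape)
    return np.where(valid, v, np.nan)


def _values_3x2(test: TestKind, form: ReleasedForm, N: int) -> np.ndarray:
    """Released value on the dense (a, b, m, n) lattice; NaN outside the domain."""
    half = N // 2
    a = np.arange(half + 1, dtype=float)[:, None, None, None]
    b = np.arange(half + 1, dtype=float)[None, :, None, None]
    m = np.arange(N, dtype=float)[None, None, :, None]
    n = np.arange(N, dtype=float)[None, None, None, :]
    valid = ((m >= 1) & (n >= 1) & (m + n <= N - 1) & (a <= m) & (b <= n)
             & (a + b <= half) & (m + n - a - b <= half))
    with np.errstate(divide="ignore", invalid="ignore"):
        if test is TestKind.CHI2_3X2:
            v = _from_chi2(chi2_genotype_from_counts(a, b, m, n, N), 2, form)
        elif test is TestKind.CATT:
            v = _from_chi2(catt_from_counts(a, b, m, n, N), 2, form)
        elif test is TestKind.FISHER_3X2:
            # clip lattice points outside the domain before the gamma calls;
            # they are masked out below anyway
            aa = np.minimum(a, m)
            bb = np.minimum(b, n)
            logp = log10_fisher_p_genotype_from_counts(
                np.broadcast_to(aa, valid.shape).clip(min=0),
                np.broadcast_to(bb, valid.shape).clip(min=0),
                np.broadcast_to(m, valid.shape).clip(min=1),
                np.broadcast_to(n, valid.shape).clip(min=1), N)
            logp = np.where(valid, logp, np.nan)
            if form is ReleasedForm.P_VALUE:
                v = 10.0 ** logp
            elif form is ReleasedForm.NEG_LOG10_P:
                v = -logp
            else:
                raise ValueError(f"exact test has no '{form.value}' form")
        else:
            raise ValueError(f"{test.value} is not a 3x2 test")
    v = np.broadcast_to(v, valid.shape)
    return np.where(valid, v, np.nan)


def _from_chi2(stat, df: int, form: ReleasedForm):
    if form is ReleasedForm.STATISTIC:
        return stat
    if form is ReleasedForm.P_VALUE:
        return stats.chi2.sf(stat, df)
    if form is ReleasedForm.NEG_LOG10_P:
        safe = np.where(np.isfinite(stat) & (stat >= 0), stat, 0.0)
        return np.where(np.isfinite(stat), neg_log10_p_from_chi2(safe, df), np.nan)
    raise ValueError(f"unknown form {form}")


def _max_shift_diff(values: np.ndarray, moves: list[tuple[int, ...]]):
    """Max |f(table) - f(table + move)| over a move class, with an argmax pair.

    ``values`` holds f on the dense count lattice with NaN outside the
    valid domain, so a shifted absolute difference is NaN unless both
    endpoints are valid tables.
    """
    best = -np.inf
    best_pair = None
    for move in moves:
        src = tuple(slice(max(0, -d), values.shape[ax] - max(0, d))
                    for ax, d in enumerate(move))
        dst = tuple(slice(max(0, d), values.shape[ax] + min(0, d))
                    for ax, d in enumerate(move))
        diff = np.abs(values[src] - values[dst])
        if not np.any(np.isfinite(diff)):
            continue
        flat = np.nanargmax(diff)
        cand = diff.ravel()[flat]
        if cand > best:
            best = float(cand)
            idx = np.unravel_index(flat, diff.shape)
            src_pt = tuple(int(i + max(0, -d)) for i, d in zip(idx, move))
            dst_pt = tuple(int(p + d) for p, d in zip(src_pt, move))
            best_pair = (src_pt, dst_pt)
    if best_pair is None:
        raise RuntimeError("no valid neighboring pair found")
    return best, best_pair
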