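"""Case-control contingency tables for balanced GWAS association tests.

A single-SNP case-control association test is run on one of two table
shapes:

* a 3x2 **genotype** table — rows are minor-allele dosage 0/1/2, columns
  are disease status, with exactly ``N/2`` individuals per column;
* a 2x2 **allele** table — rows are major/minor allele, columns are
  disease status, with ``N`` alleles per column (each of the ``N``
  individuals contributes two alleles).

Both tables are stored in a canonical reduced form (the free cells plus
row margins); the remaining cells are derived views.  All margins are
required to be positive, which is the regime of a GWAS that has already
filtered out SNPs with minor allele frequency below 0.05.

The module also defines the *neighboring-dataset* relation used for
differential privacy: two tables are neighbors when they differ by a
change of a single individual's genotype, which leaves both column
totals fixed.  On the allele table a one-individual genotype change
moves one or two alleles, so allele-table neighbors carry deltas of
magnitude 1 or 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union


class SmallCohortWarning(UserWarning):
    """A table has N < 100 individuals.

    The closed-form sensitivities are stated for cohorts of at least 100
    individuals; smaller tables are still valid inputs (and the
    brute-force oracle uses them), but released values should not be
    trusted to the same guarantees.
    """


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class GenotypeTable:
    """3x2 genotype-by-status contingency table with balanced columns.

    Canonical fields are ``(a, b, m, n, N)``: ``a`` and ``b`` are the
    genotype-0 and genotype-1 counts in the first status column, ``m``
    and ``n`` the genotype-0 and genotype-1 row totals, and ``N`` the
    total number of individuals (``N/2`` per status column).  The four
    remaining cells are derived.

    The two status columns enter every statistic in this package
    symmetrically, so which phenotype is mapped to the first column is a
    labeling convention only (:func:`build_genotype_table` puts cases
    first).
    """

    a: int
    b: int
    m: int
    n: int
    N: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "m", "n", "N"):
            v = getattr(self, name)
            _require(isinstance(v, (int,)) and not isinstance(v, bool),
                     f"{name} must be an integer, got {v!r}")
        a, b, m, n, N = self.a, self.b, self.m, self.n, self.N
        _require(N % 2 == 0, f"N must be even, got {N}")
        _require(a >= 0 and b >= 0, f"negative cell: a={a}, b={b}")
        _require(m > 0 and n > 0 and m + n < N,
                 f"all three row margins must be positive: m={m}, n={n}, N={N}")
        _require(a <= m and b <= n,
                 f"column cells exceed row margins: a={a}>m={m} or b={b}>n={n}")
        half = N // 2
        _require(a + b <= half,
                 f"first-column genotype-2 cell negative: a+b={a + b} > N/2={half}")
        _require(m + n - a - b <= half,
                 f"second-column genotype-2 cell negative: (m+n)-(a+b)={m + n - a - b} > N/2={half}")
        if N < 100:
            warnings.warn(f"table has N={N} < 100 individuals", SmallCohortWarning,
                          stacklevel=2)

    @property
    def half(self) -> int:
        return self.N // 2

    def cells(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        """Full 3x2 grid as ``((g0_col0, g0_col1), (g1_...), (g2_...))``."""
        a, b, m, n, half = self.a, self.b, self.m, self.n, self.half
        return ((a, m - a), (b, n - b), (half - a - b, half - m - n + a + b))

    def row_margins(self) -> tuple[int, int, int]:
        return (self.m, self.n, self.N - self.m - self.n)


@dataclass(frozen=True)
class AlleleTable:
    """2x2 allele-by-status contingency table with balanced columns.

    ``a`` is the major-allele count in the first status column, ``m``
    the major-allele row total, and ``N`` the number of *individuals*
    (each column holds ``N`` alleles, ``2N`` in total).  The domain
    constraints ``3 <= m <= 2N - 3`` come from requiring the underlying
    genotype table to have positive margins.
    """

    a: int
    m: int
    N: int

    def __post_init__(self) -> None:
        for name in ("a", "m", "N"):
            v = getattr(self, name)
            _require(isinstance(v, (int,)) and not isinstance(v, bool),
                     f"{name} must be an integer, got {v!r}")
        a, m, N = self.a, self.m, self.N
        _require(a >= 0, f"negative cell: a={a}")
        _require(3 <= m <= 2 * N - 3,
                 f"major-allele margin m={m} outside [3, 2N-3] for N={N}")
        _require(a <= m, f"a={a} exceeds margin m={m}")
        _require(a <= N, f"a={a} exceeds column total N={N}")
        _require(m - a <= N, f"second-column major cell m-a={m - a} exceeds N={N}")

    def cells(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Full 2x2 grid as ``((major_col0, major_col1), (minor_col0, minor_col1))``."""
        a, m, N = self.a, self.m, self.N
        return ((a, m - a), (N - a, N - m + a))


Table = Union[GenotypeTable, AlleleTable]


@dataclass(frozen=True)
class NeighborMove:
    """A single individual's genotype change.

    ``column`` is the status column (0 or 1) of the individual that
    changes; ``src``/``dst`` are the before/after genotypes for genotype
    tables (``None`` for allele tables, where only the induced allele
    deltas are determined); ``deltas`` are the induced integer changes
    on the canonical fields ``(a, b, m, n)`` or ``(a, m)``.
    """

    column: int
    src: int | None
    dst: int | None
    deltas: tuple[int, ...]


def build_genotype_table(case_counts: tuple[int, int, int],
                         control_counts: tuple[int, int, int]) -> GenotypeTable:
    """Build and validate a :class:`GenotypeTable` from per-group genotype counts.

    ``case_counts`` and ``control_counts`` are ``(g0, g1, g2)`` triples;
    both must sum to the same group size ``N/2``.  Cases occupy the
    first status column.
    """
    case = tuple(int(x) for x in case_counts)
    ctrl = tuple(int(x) for x in control_counts)
    _require(len(case) == 3 and len(ctrl) == 3, "expected (g0, g1, g2) triples")
    _require(all(x >= 0 for x in case + ctrl), f"negative genotype count in {case}/{ctrl}")
    _require(sum(case) == sum(ctrl),
             f"unbalanced columns: {sum(case)} cases vs {sum(ctrl)} controls")
    N = sum(case) + sum(ctrl)
    return GenotypeTable(a=case[0], b=case[1],
                         m=case[0] + ctrl[0], n=case[1] + ctrl[1], N=N)


def to_allele_table(gt: GenotypeTable) -> AlleleTable:
    """Collapse a genotype table to the 2x2 allele table for the same cohort.

    Each genotype-0 individual carries two major alleles and each
    genotype-1 individual one, so the major-allele cell of the first
    column is ``2a + b`` and its row total ``2m + n``.
    """
    return AlleleTable(a=2 * gt.a + gt.b, m=2 * gt.m + gt.n, N=gt.N)


# Induced (da, db, dm, dn) for a first-column individual moving genotype
# src -> dst; a second-column move touches only the margins (dm, dn).
_GENO_MOVE_DELTAS: dict[tuple[int, int], tuple[int, int, int, int]] = {
    (0, 1): (-1, +1, -1, +1),
    (1, 0): (+1, -1, +1, -1),
    (0, 2): (-1, 0, -1, 0),
    (2, 0): (+1, 0, +1, 0),
    (1, 2): (0, -1, 0, -1),
    (2, 1): (0, +1, 0, +1),
}

# Allele-count deltas (da, dm) induced by one individual's genotype change:
# a one-step genotype change moves one allele, 0<->2 moves two.  First
# column changes a and m together; second column changes m alone.
_ALLELE_MOVE_DELTAS_COL0 = [(-1, -1), (+1, +1), (-2, -2), (+2, +2)]
_ALLELE_MOVE_DELTAS_COL1 = [(0, -1), (0, +1), (0, -2), (0, +2)]


def enumerate_neighbors(table: Table) -> list[tuple[NeighborMove, Table]]:
    """All valid tables reachable by changing a single individual's genotype.

    Column margins are preserved by every move, and every emitted
    neighbor satisfies its table-type invariants; the relation is
    symmetric.
    """
    out: list[tuple[NeighborMove, Table]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallCohortWarning)
        if isinstance(table, GenotypeTable):
            for (src, dst), (da, db, dm, dn) in _GENO_MOVE_DELTAS.items():
                for col in (0, 1):
                    if col == 0:
                        deltas = (da, db, dm, dn)
                    else:
                        deltas = (0, 0, dm, dn)
                    try:
                        nb = GenotypeTable(a=table.a + deltas[0], b=table.b + deltas[1],
                                           m=table.m + deltas[2], n=table.n + deltas[3],
                                           N=table.N)
                    except ValueError:
                        continue
                    out.append((NeighborMove(column=col, src=src, dst=dst,
                                             deltas=deltas), nb))
        elif isinstance(table, AlleleTable):
            for col, moves in ((0, _ALLELE_MOVE_DELTAS_COL0),
                               (1, _ALLELE_MOVE_DELTAS_COL1)):
                for da, dm in moves:
                    try:
                        nb = AlleleTable(a=table.a + da, m=table.m + dm, N=table.N)
                    except ValueError:
                        continue
                    out.append((NeighborMove(column=col, src=None, dst=None,
                                             deltas=(da, dm)), nb))
        else:
            raise TypeError(f"not a contingency table: {table!r}")
    return out
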