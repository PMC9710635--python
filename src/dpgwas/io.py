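"""TSV input/output for genotype counts and private releases.

The input schema is one SNP per row with seven columns::

    snp_id  case_g0  case_g1  case_g2  ctrl_g0  ctrl_g1  ctrl_g2

where ``g0/g1/g2`` count individuals by minor-allele dosage.  Any
tabular genotype source (VCF, PLINK) is easily collapsed to this form.
Releases are written back as TSV with floats at 17 significant digits,
so a read-back round-trips bit-for-bit.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

from .mechanism import PrivateRelease
from .tables import GenotypeTable, build_genotype_table

COUNTS_COLUMNS = ["snp_id", "case_g0", "case_g1", "case_g2",
                  "ctrl_g0", "ctrl_g1", "ctrl_g2"]
RELEASE_COLUMNS = ["snp_id", "test", "form", "n_total", "epsilon", "scale",
                   "released", "clamped", "seed"]


def read_counts_tsv(path) -> list[tuple[str, GenotypeTable]]:
    """Read and validate per-SNP genotype counts.

    Raises ``ValueError`` naming the offending row/SNP and the violated
    rule on any malformed or invalid record; snp_ids must be unique.
    """
    path = Path(path)
    out: list[tuple[str, GenotypeTable]] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if header != COUNTS_COLUMNS:
            raise ValueError(f"{path}: malformed header {header!r}; "
                             f"expected {COUNTS_COLUMNS!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or row == [""]:
                continue
            if len(row) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(row)}")
            snp_id = row[0]
            if snp_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate snp_id {snp_id!r}")
            seen.add(snp_id)
            try:
                counts = [int(x) for x in row[1:]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer count in "
                                 f"SNP {snp_id!r}: {row[1:]!r}") from None
            if min(counts) < 0:
                raise ValueError(f"{path}:{lineno}: negative count in SNP {snp_id!r}")
            try:
                gt = build_genotype_table(tuple(counts[:3]), tuple(counts[3:]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: invalid table for SNP "
                                 f"{snp_id!r}: {exc}") from None
            out.append((snp_id, gt))
    return out


def write_counts_tsv(records: Sequence[tuple[str, GenotypeTable]], path) -> None:
    """Write per-SNP genotype counts in the schema read_counts_tsv expects."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COUNTS_COLUMNS)
        for snp_id, gt in records:
            (c0, t0), (c1, t1), (c2, t2) = gt.cells()
            writer.writerow([snp_id, c0, c1, c2, t0, t1, t2])


def write_release_tsv(records: Sequence[PrivateRelease], path) -> None:
    """Write private releases as TSV (floats at 17 significant digits)."""
    if not records:
        raise ValueError("no releases to write")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RELEASE_COLUMNS)
        for r in records:
            writer.writerow([r.snp_id if r.snp_id is not None else "",
                             r.test.value, r.form.value, r.n_total,
                             f"{r.epsilon:.17g}", f"{r.scale:.17g}",
                             f"{r.released:.17g}", int(r.clamped), r.seed])


def read_release_tsv(path) -> list[dict]:
    """Read back a release TSV as a list of plain dicts."""
    path = Path(path)
    out = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != RELEASE_COLUMNS:
            raise ValueError(f"{path}: malformed header {reader.fieldnames!r}")
        for row in reader:
            out.append({"snp_id": row["snp_id"], "test": row["test"],
                        "form": row["form"], "n_total": int(row["n_total"]),
                        "epsilon": float(row["epsilon"]),
                        "scale": float(row["scale"]),
                        "released": float(row["released"]),
                        "clamped": bool(int(row["clamped"])),
                        "seed": int(row["seed"])})
    return out
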