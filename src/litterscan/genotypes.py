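"""Genotype matrices in Structure format, sample metadata, and locus filters.

The central container is :class:`GenotypeMatrix`: samples x loci, each cell an
unordered pair of integer allele codes or missing.  Everything downstream
(the paternal-allele scan, the sibship likelihoods, the simulator) consumes
this object.  Filters implement the standard pre-processing for a
mother+litter SNP panel: locus completeness (the ``r`` fraction of genotyped
individuals) and minor-allele-frequency thresholds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

MISSING_DEFAULT = -9

ROLE_MOTHER = "mother"
ROLE_OFFSPRING = "offspring"
SEXES = ("male", "female", "unknown")


class StructureParseError(ValueError):
    """Raised on malformed Structure files; message names the offending line."""


class ConfigError(ValueError):
    """Raised on invalid configuration values."""


@dataclass(frozen=True)
class StructureDialect:
    """Layout of a Structure-format text file.

    Parameters
    ----------
    rows_per_individual
        2 = classic layout, one allele row per haplotype; 1 = one row per
        individual with two adjacent columns per locus.
    header
        Whether the first non-blank line lists locus names.  Without a
        header, loci are auto-named ``L1..Ln`` on read.
    missing_code
        Integer sentinel for a missing allele (Structure convention: -9).
    """

    rows_per_individual: int = 2
    header: bool = False
    missing_code: int = MISSING_DEFAULT

    def __post_init__(self) -> None:
        if self.rows_per_individual not in (1, 2):
            raise ConfigError(
                f"rows_per_individual must be 1 or 2, got {self.rows_per_individual}"
            )


@dataclass
class SampleMeta:
    """Role and sex of one sample in a mother+litter analysis."""

    sample_id: str
    role: str
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.role not in (ROLE_MOTHER, ROLE_OFFSPRING):
            raise ConfigError(f"unknown role {self.role!r} for {self.sample_id}")
        if self.sex not in SEXES:
            raise ConfigError(f"unknown sex {self.sex!r} for {self.sample_id}")


def validate_metadata(meta: Sequence[SampleMeta]) -> SampleMeta:
    """Check that exactly one sample is the mother; return her record."""
    mothers = [m for m in meta if m.role == ROLE_MOTHER]
    if len(mothers) != 1:
        raise ConfigError(f"expected exactly one mother, found {len(mothers)}")
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate sample ids in metadata")
    return mothers[0]


@dataclass
class GenotypeMatrix:
    """Samples x loci table of unordered biallelic genotypes.

    ``calls`` has shape ``(n_samples, n_loci, 2)``; a missing cell holds
    ``missing_code`` in both slots.  Genotypes are stored as sorted pairs so
    that (a, b) and (b, a) compare equal.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    missing_code: int = MISSING_DEFAULT

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        half = (self.calls == self.missing_code).sum(axis=2) == 1
        if half.any():
            s, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing genotype at sample {self.sample_ids[s]!r}, "
                f"locus {self.locus_ids[l]!r}"
            )
        self.calls = np.sort(self.calls, axis=2)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci) array, True where the call is missing."""
        return (self.calls == self.missing_code).all(axis=2)

    def genotype(self, sample_id: str, locus_id: str) -> tuple[int, int] | None:
        """One cell as a sorted tuple, or None if missing."""
        i = self.sample_index(sample_id)
        j = self.locus_ids.index(locus_id)
        a, b = self.calls[i, j]
        if a == self.missing_code:
            return None
        return (int(a), int(b))

    def locus_alleles(self, j: int) -> list[int]:
        """Sorted distinct allele codes observed at locus column ``j``."""
        col = self.calls[:, j, :].ravel()
        return sorted(int(a) for a in np.unique(col) if a != self.missing_code)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(
            list(sample_ids), list(self.locus_ids), self.calls[idx].copy(), self.missing_code
        )

    def subset_loci(self, keep: Sequence[int]) -> "GenotypeMatrix":
        """New matrix keeping locus columns ``keep`` (indices, in given order)."""
        keep = list(keep)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.locus_ids[j] for j in keep],
            self.calls[:, keep, :].copy(),
            self.missing_code,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids), list(self.locus_ids), self.calls.copy(), self.missing_code
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and self.missing_code == other.missing_code
            and np.array_equal(self.calls, other.calls)
        )


# -- Structure-format I/O --------------------------------------------------


def _parse_int(token: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise StructureParseError(
            f"line {lineno}: unknown token {token!r} (expected integer allele code)"
        ) from None


def read_structure(path: str | Path, dialect: StructureDialect | None = None) -> GenotypeMatrix:
    """Read a Structure-format genotype file.

    Both common dialects are supported (see :class:`StructureDialect`).
    Genotypes are normalised to sorted pairs; the missing code in either
    allele slot of a cell requires the other slot to be missing too.
    """
    dialect = dialect or StructureDialect()
    lines: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            toks = raw.split()
            if toks:
                lines.append((lineno, toks))

    locus_ids: list[str] | None = None
    if dialect.header:
        if not lines:
            raise StructureParseError("line 1: empty file but header expected")
        _, toks = lines.pop(0)
        locus_ids = toks

    per_locus_cols = 1 if dialect.rows_per_individual == 2 else 2
    n_loci: int | None = None if locus_ids is None else len(locus_ids)

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []

    def parse_row(lineno: int, toks: list[str]) -> tuple[str, np.ndarray]:
        nonlocal n_loci
        sid, alleles = toks[0], toks[1:]
        if n_loci is None:
            if per_locus_cols == 2 and len(alleles) % 2 != 0:
                raise StructureParseError(
                    f"line {lineno}: odd allele count {len(alleles)} in one-row dialect"
                )
            n_loci = len(alleles) // per_locus_cols
        if len(alleles) != n_loci * per_locus_cols:
            raise StructureParseError(
                f"line {lineno}: ragged row for sample {sid!r}: expected "
                f"{n_loci * per_locus_cols} allele columns, got {len(alleles)}"
            )
        return sid, np.array([_parse_int(t, lineno) for t in alleles], dtype=np.int32)

    if dialect.rows_per_individual == 2:
        if len(lines) % 2 != 0:
            raise StructureParseError(
                f"line {lines[-1][0]}: odd number of data rows in two-row dialect"
            )
        for k in range(0, len(lines), 2):
            (ln1, t1), (ln2, t2) = lines[k], lines[k + 1]
            sid1, a1 = parse_row(ln1, t1)
            sid2, a2 = parse_row(ln2, t2)
            if sid1 != sid2:
                raise StructureParseError(
                    f"line {ln2}: row pair mismatch: {sid1!r} followed by {sid2!r}"
                )
            sample_ids.append(sid1)
            rows.append(np.stack([a1, a2], axis=1))
    else:
        for ln, toks in lines:
            sid, a = parse_row(ln, toks)
            sample_ids.append(sid)
            rows.append(a.reshape(-1, 2))

    if n_loci is None:
        n_loci = 0
    if locus_ids is None:
        locus_ids = [f"L{j + 1}" for j in range(n_loci)]
    calls = (
        np.stack(rows, axis=0)
        if rows
        else np.empty((0, n_loci, 2), dtype=np.int32)
    )
    mc = dialect.missing_code
    part = (calls == mc).sum(axis=2) == 1
    if part.any():
        i, j = np.argwhere(part)[0]
        raise StructureParseError(
            f"half-missing genotype for sample {sample_ids[i]!r} at locus column {j + 1}"
        )
    return GenotypeMatrix(sample_ids, locus_ids, calls, missing_code=mc)


def write_structure(
    matrix: GenotypeMatrix, path: str | Path, dialect: StructureDialect | None = None
) -> None:
    """Write ``matrix`` as a Structure file; inverse of :func:`read_structure`.

    The matrix's own missing code is translated to the dialect's.
    """
    dialect = dialect or StructureDialect()
    calls = matrix.calls
    if dialect.missing_code != matrix.missing_code:
        calls = calls.copy()
        calls[calls == matrix.missing_code] = dialect.missing_code
    with open(path, "w") as fh:
        if dialect.header:
            fh.write("\t".join(matrix.locus_ids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            if dialect.rows_per_individual == 2:
                for hap in range(2):
                    toks = [sid] + [str(a) for a in calls[i, :, hap]]
                    fh.write("\t".join(toks) + "\n")
            else:
                toks = [sid] + [str(a) for a in calls[i].ravel()]
                fh.write("\t".join(toks) + "\n")


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the JSON metadata sidecar: a list of {sample_id, role, sex}."""
    with open(path) as fh:
        records = json.load(fh)
    meta = [SampleMeta(r["sample_id"], r["role"], r.get("sex", "unknown")) for r in records]
    validate_metadata(meta)
    return meta


def write_sample_metadata(meta: Sequence[SampleMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [{"sample_id": m.sample_id, "role": m.role, "sex": m.sex} for m in meta],
            fh,
            indent=2,
        )
        fh.write("\n")


# -- locus filters ---------------------------------------------------------


def filter_complete_loci(matrix: GenotypeMatrix, r: float) -> GenotypeMatrix:
    """Keep loci genotyped in at least ``r * n_samples`` samples.

    With ``r = 1.0`` (the usual mother+litter setting) the output contains no
    missing cells.  Sample order and relative locus order are preserved.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    called = (~matrix.missing_mask()).sum(axis=0)
    # small epsilon guards float representation of r * n
    keep = np.nonzero(called >= r * matrix.n_samples - 1e-9)[0]
    return matrix.subset_loci(keep)


def minor_allele_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-locus MAF from allele counts over non-missing genotypes.

    Monomorphic loci get 0.0; loci with more than two observed alleles get
    NaN (the filters drop them, with a warning).
    """
    maf = np.zeros(matrix.n_loci)
    for j in range(matrix.n_loci):
        alleles = matrix.locus_alleles(j)
        if len(alleles) > 2:
            maf[j] = np.nan
            continue
        if len(alleles) < 2:
            maf[j] = 0.0
            continue
        col = matrix.calls[:, j, :].ravel()
        col = col[col != matrix.missing_code]
        c = int((col == alleles[0]).sum())
        maf[j] = min(c, col.size - c) / col.size
    return maf


def filter_maf(
    matrix: GenotypeMatrix, threshold: float, mode: str = "ge"
) -> GenotypeMatrix:
    """Keep loci by minor allele frequency.

    mode="ge" keeps MAF >= threshold; mode="eq" keeps MAF == threshold
    (within 1e-9).  Loci with more than two observed alleles are dropped with
    a warning: the downstream scan and sibship math assume biallelic SNPs.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    if mode not in ("ge", "eq"):
        raise ValueError(f"mode must be 'ge' or 'eq', got {mode!r}")
    maf = minor_allele_frequencies(matrix)
    multi = np.isnan(maf)
    if multi.any():
        names = [matrix.locus_ids[j] for j in np.nonzero(multi)[0]]
        warnings.warn(
            f"dropping {len(names)} loci with >2 observed alleles: {names[:5]}...",
            stacklevel=2,
        )
    if mode == "ge":
        ok = maf >= threshold - 1e-12
    else:
        ok = np.abs(maf - threshold) <= 1e-9
    keep = np.nonzero(ok & ~multi)[0]
    return matrix.subset_loci(keep)
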