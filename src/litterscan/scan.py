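"""Maternal-homozygosity paternal-allele scan and reproductive-mode call.

At a locus where the mother is homozygous, any other allele carried by an
offspring must be paternal (barring genotyping error).  The scan flags such
non-maternal alleles per offspring per locus, and summarises them two ways:
a liberal count (loci where ANY offspring is flagged) and a conservative
count (loci where ALL offspring are flagged), the latter being robust to
per-individual miscalls and the statistic used to demonstrate paternal
contribution.  A litter in which no offspring shows paternal alleles, and
whose offspring have reduced heterozygosity relative to the mother, matches
the automixis (facultative parthenogenesis) signature instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotypes import ConfigError, GenotypeMatrix, SampleMeta, ROLE_MOTHER, ROLE_OFFSPRING

FLAG_MISSING = -1

CALL_SEXUAL = "sexual"
CALL_PARTHENOGEN = "parthenogen"
CALL_AMBIGUOUS = "ambiguous"

LITTER_LTSS = "LTSS"
LITTER_FP = "FP"
LITTER_AMBIGUOUS = "ambiguous"

MISSING_POLICIES = ("strict", "evaluated_only")


@dataclass
class ScanResult:
    """Per-locus, per-offspring non-maternal-allele flags and summaries.

    ``flags`` is (n_offspring, n_maternal_homozygous_loci) with values
    1 (non-maternal allele present), 0 (maternal alleles only) or -1
    (genotype missing).  ``per_offspring_fraction`` is flagged / evaluated
    (non-missing) loci, NaN when nothing was evaluable.
    """

    mother_id: str
    offspring_ids: list[str]
    maternal_homozygous_loci: list[str]
    flags: np.ndarray
    per_offspring_fraction: dict[str, float]
    conservative_loci: list[str]
    conservative_count: int
    liberal_count: int
    missing_policy: str = "strict"

    def to_dict(self) -> dict:
        return {
            "mother_id": self.mother_id,
            "offspring_ids": self.offspring_ids,
            "n_maternal_homozygous_loci": len(self.maternal_homozygous_loci),
            "per_offspring_fraction": {
                k: (None if math.isnan(v) else v)
                for k, v in self.per_offspring_fraction.items()
            },
            "conservative_loci": self.conservative_loci,
            "conservative_count": self.conservative_count,
            "liberal_count": self.liberal_count,
            "missing_policy": self.missing_policy,
        }


def find_maternal_homozygous_loci(matrix: GenotypeMatrix, mother_id: str) -> list[str]:
    """Loci where the mother's two allele codes are equal (missing excluded)."""
    i = matrix.sample_index(mother_id)
    g = matrix.calls[i]
    hom = (g[:, 0] == g[:, 1]) & (g[:, 0] != matrix.missing_code)
    return [matrix.locus_ids[j] for j in np.nonzero(hom)[0]]


def scan_paternal_alleles(
    matrix: GenotypeMatrix,
    mother_id: str,
    offspring_ids: Sequence[str] | None = None,
    missing_policy: str = "strict",
) -> ScanResult:
    """Flag putative paternal alleles at maternal homozygous loci.

    An offspring is flagged at a locus when its (non-missing) genotype
    contains at least one allele different from the maternal allele.  The
    conservative set collects loci where every offspring is flagged; under
    the default "strict" policy a locus with ANY missing offspring call is
    excluded from it, under "evaluated_only" only the non-missing calls must
    all be flagged (and at least one must exist).
    """
    if missing_policy not in MISSING_POLICIES:
        raise ConfigError(f"missing_policy must be one of {MISSING_POLICIES}")
    mi = matrix.sample_index(mother_id)
    if offspring_ids is None:
        offspring_ids = [s for s in matrix.sample_ids if s != mother_id]
    offspring_ids = list(offspring_ids)
    if not offspring_ids:
        raise ValueError("offspring_ids must be non-empty")
    if mother_id in offspring_ids:
        raise ValueError("mother_id must not appear among offspring_ids")

    hom_loci = find_maternal_homozygous_loci(matrix, mother_id)
    if not hom_loci:
        warnings.warn("mother is homozygous at no locus; scan is empty", stacklevel=2)
    hom_idx = [matrix.locus_ids.index(l) for l in hom_loci]
    mat_allele = matrix.calls[mi, hom_idx, 0] if hom_idx else np.empty(0, dtype=np.int32)

    off_idx = [matrix.sample_index(s) for s in offspring_ids]
    calls = matrix.calls[np.ix_(off_idx, hom_idx)]  # (n_off, n_hom, 2)
    missing = (calls == matrix.missing_code).all(axis=2)
    nonmat = (calls != mat_allele[None, :, None]).any(axis=2)
    flags = np.where(missing, FLAG_MISSING, nonmat.astype(np.int8)).astype(np.int8)

    fractions: dict[str, float] = {}
    for k, sid in enumerate(offspring_ids):
        evaluated = int((flags[k] != FLAG_MISSING).sum())
        if evaluated == 0:
            if hom_loci:
                warnings.warn(f"offspring {sid!r} has no evaluable scanned loci", stacklevel=2)
            fractions[sid] = float("nan")
        else:
            fractions[sid] = float((flags[k] == 1).sum() / evaluated)

    if flags.size:
        all_flagged = (flags == 1).all(axis=0)
        none_unflagged = ~(flags == 0).any(axis=0)
        any_eval = (flags != FLAG_MISSING).any(axis=0)
        if missing_policy == "strict":
            conservative = all_flagged
        else:
            conservative = none_unflagged & any_eval
        liberal = (flags == 1).any(axis=0)
    else:
        conservative = np.zeros(len(hom_loci), dtype=bool)
        liberal = np.zeros(len(hom_loci), dtype=bool)

    conservative_loci = [hom_loci[j] for j in np.nonzero(conservative)[0]]
    return ScanResult(
        mother_id=mother_id,
        offspring_ids=offspring_ids,
        maternal_homozygous_loci=hom_loci,
        flags=flags,
        per_offspring_fraction=fractions,
        conservative_loci=conservative_loci,
        conservative_count=len(conservative_loci),
        liberal_count=int(liberal.sum()),
        missing_policy=missing_policy,
    )


def offspring_heterozygosity(
    matrix: GenotypeMatrix, sample_ids: Sequence[str] | None = None
) -> dict[str, float]:
    """Fraction of non-missing genotypes that are heterozygous, per sample.

    A sample with zero non-missing calls gets NaN with a warning rather than
    a silent 0.
    """
    if sample_ids is None:
        sample_ids = matrix.sample_ids
    out: dict[str, float] = {}
    for sid in sample_ids:
        i = matrix.sample_index(sid)
        g = matrix.calls[i]
        ok = g[:, 0] != matrix.missing_code
        n = int(ok.sum())
        if n == 0:
            warnings.warn(f"sample {sid!r} has no non-missing genotypes", stacklevel=2)
            out[sid] = float("nan")
        else:
            out[sid] = float(((g[:, 0] != g[:, 1]) & ok).sum() / n)
    return out


@dataclass
class ClassifierThresholds:
    """Decision thresholds for the per-offspring reproductive-mode call.

    An offspring is called sexual when its non-maternal-allele fraction is
    at least ``sexual_min_fraction`` and parthenogen when the fraction is at
    most ``parthenogen_max_fraction`` AND its heterozygosity does not exceed
    ``max(max_het_ratio * mother_het, het_floor)`` (automixis cannot raise
    heterozygosity above the mother's; the floor absorbs error-induced
    heterozygosity when the mother is nearly homozygous).  Defaults are
    derived from the genotyping-error model: with miscall rate eps, a
    parthenogen's expected fraction is about 2*eps/3 plus maternal-miscall
    leakage (roughly 0.012 at eps = 0.01), far below any sexual offspring's
    (>= 0.1 for realistic allele frequencies); 0.04/0.05 splits these with
    wide margins.  See the methods note for the derivation.
    """

    sexual_min_fraction: float = 0.05
    parthenogen_max_fraction: float = 0.04
    max_het_ratio: float = 1.0
    het_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.parthenogen_max_fraction > self.sexual_min_fraction:
            raise ConfigError(
                "parthenogen_max_fraction must not exceed sexual_min_fraction "
                f"({self.parthenogen_max_fraction} > {self.sexual_min_fraction})"
            )
        for name in ("sexual_min_fraction", "parthenogen_max_fraction", "het_floor"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.max_het_ratio < 0:
            raise ConfigError("max_het_ratio must be >= 0")


@dataclass
class ModeCall:
    """Litter- and offspring-level reproductive-mode classification."""

    litter_call: str
    per_offspring_call: dict[str, str]
    evidence: dict

    def to_dict(self) -> dict:
        return {
            "litter_call": self.litter_call,
            "per_offspring_call": self.per_offspring_call,
            "evidence": self.evidence,
        }


def classify_mode(
    scan: ScanResult,
    het: Mapping[str, float],
    meta: Sequence[SampleMeta],
    thresholds: ClassifierThresholds | None = None,
) -> ModeCall:
    """Call each offspring sexual / parthenogen / ambiguous and the litter
    LTSS / FP / ambiguous.

    The litter is LTSS iff at least one offspring is sexual (one genuine
    paternal contribution suffices to prove stored sperm was used), FP iff
    every offspring is parthenogen, ambiguous otherwise.  An all-male litter
    is reported as corroborating FP (ZW taxa produce only ZZ parthenogens)
    but never suffices on its own.
    """
    thresholds = thresholds or ClassifierThresholds()
    by_id = {m.sample_id: m for m in meta}
    mother_het = het.get(scan.mother_id, float("nan"))
    het_bound = thresholds.het_floor
    if not math.isnan(mother_het):
        het_bound = max(thresholds.max_het_ratio * mother_het, thresholds.het_floor)

    calls: dict[str, str] = {}
    for sid in scan.offspring_ids:
        frac = scan.per_offspring_fraction.get(sid, float("nan"))
        h = het.get(sid, float("nan"))
        if math.isnan(frac):
            calls[sid] = CALL_AMBIGUOUS
        elif frac >= thresholds.sexual_min_fraction:
            calls[sid] = CALL_SEXUAL
        elif frac <= thresholds.parthenogen_max_fraction and (
            not math.isnan(h) and h <= het_bound
        ):
            calls[sid] = CALL_PARTHENOGEN
        else:
            calls[sid] = CALL_AMBIGUOUS

    values = list(calls.values())
    if any(c == CALL_SEXUAL for c in values):
        litter = LITTER_LTSS
    elif values and all(c == CALL_PARTHENOGEN for c in values):
        litter = LITTER_FP
    else:
        litter = LITTER_AMBIGUOUS

    sexes = [by_id[sid].sex for sid in scan.offspring_ids if sid in by_id]
    all_male = bool(sexes) and all(s == "male" for s in sexes)
    evidence = {
        "per_offspring_fraction": {
            k: (None if math.isnan(v) else v)
            for k, v in scan.per_offspring_fraction.items()
        },
        "heterozygosity": {
            k: (None if math.isnan(v) else v) for k, v in het.items()
        },
        "mother_heterozygosity": None if math.isnan(mother_het) else mother_het,
        "het_bound": het_bound,
        "thresholds": {
            "sexual_min_fraction": thresholds.sexual_min_fraction,
            "parthenogen_max_fraction": thresholds.parthenogen_max_fraction,
            "max_het_ratio": thresholds.max_het_ratio,
            "het_floor": thresholds.het_floor,
        },
        "all_male_offspring": all_male,
        "note": (
            "all-male composition corroborates FP in ZW taxa but is never sufficient"
            if all_male
            else None
        ),
    }
    return ModeCall(litter_call=litter, per_offspring_call=calls, evidence=evidence)
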