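"""Synthetic mother+litter genotypes under sexual and parthenogenetic models.

Litters are simulated either by Mendelian inheritance from the mother and
one or more stored-sperm sires (the long-term sperm storage, LTSS, model) or
by automixis (facultative parthenogenesis, FP): terminal fusion, central
fusion, or gametic duplication.  In ZW snakes parthenogens are ZZ males, so
FP litters are all-male by construction.  A genotyping-error overlay adds
missingness, allelic dropout and miscalls in that order, mimicking the real
failure modes of reduced-representation SNP data.

Allele codes are 1 (reference) and 2 (alternate) at every locus.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .genotypes import ConfigError, GenotypeMatrix, SampleMeta, ROLE_MOTHER, ROLE_OFFSPRING

REF, ALT = 1, 2

MODE_LTSS = "ltss"
FP_MODES = ("fp_terminal_fusion", "fp_central_fusion", "fp_gametic_duplication")
MODES = (MODE_LTSS,) + FP_MODES

MOTHER_ID = "MOTHER"


@dataclass
class LitterSimConfig:
    """Full parameterisation of one synthetic litter.

    ``allele_freq_spec`` is either a fixed reference-allele frequency or
    ``("uniform", low, high)`` for per-locus frequencies drawn uniformly.
    ``het_retention`` is the per-locus probability that a maternally
    heterozygous locus stays heterozygous in an automictic offspring
    (terminal fusion keeps little heterozygosity, central fusion more; the
    default 0.1 is terminal-fusion-like).  ``n_sires`` applies only to LTSS
    and must be left None for FP modes.  Same seed + config gives
    byte-identical output.
    """

    n_loci: int = 500
    allele_freq_spec: float | tuple = ("uniform", 0.1, 0.5)
    n_offspring: int = 5
    sex_ratio: float = 0.5
    mode: str = MODE_LTSS
    n_sires: int | None = None
    sire_assignment: str | Sequence[int] = "random"
    het_retention: float = 0.1
    dropout_rate: float = 0.01
    miscall_rate: float = 0.005
    missing_rate: float = 0.01
    n_infertile_ova: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.mode == MODE_LTSS:
            if self.n_sires is None:
                self.n_sires = 1
            if self.n_sires < 1:
                raise ConfigError("n_sires must be >= 1 under ltss")
        elif self.n_sires is not None:
            raise ConfigError("n_sires must not be set under fp_* modes")
        for name in ("sex_ratio", "het_retention", "dropout_rate", "miscall_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_loci < 0 or self.n_offspring < 0:
            raise ConfigError("n_loci and n_offspring must be non-negative")
        if isinstance(self.allele_freq_spec, (int, float)):
            if not 0.0 <= self.allele_freq_spec <= 1.0:
                raise ConfigError("fixed allele frequency must be in [0, 1]")
        else:
            tag, lo, hi = self.allele_freq_spec
            if tag != "uniform" or not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"bad allele_freq_spec {self.allele_freq_spec!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["allele_freq_spec"], tuple):
            d["allele_freq_spec"] = list(d["allele_freq_spec"])
        if not isinstance(d["sire_assignment"], str):
            d["sire_assignment"] = list(d["sire_assignment"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LitterSimConfig":
        d = dict(d)
        spec = d.get("allele_freq_spec")
        if isinstance(spec, list):
            d["allele_freq_spec"] = tuple(spec)
        return cls(**d)


@dataclass
class SimResult:
    """A simulated litter plus its ground truth."""

    matrix: GenotypeMatrix
    meta: list[SampleMeta]
    config: LitterSimConfig
    freqs: np.ndarray
    sire_of: list[int] | None  # per-offspring sire index (LTSS) or None (FP)
    n_infertile_ova: int = 0

    @property
    def offspring_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta if m.role == ROLE_OFFSPRING]


def _rng(cfg_seed: int, stream: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream, salt])


def draw_allele_freqs(cfg: LitterSimConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.allele_freq_spec, (int, float)):
        return np.full(cfg.n_loci, float(cfg.allele_freq_spec))
    _, lo, hi = cfg.allele_freq_spec
    return rng.uniform(lo, hi, size=cfg.n_loci)


def _hwe_genotypes(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n_loci, 2) genotype: two independent allele draws with P(ref)=p."""
    g = np.where(rng.random((p.size, 2)) < p[:, None], REF, ALT).astype(np.int32)
    return np.sort(g, axis=1)


def simulate_parents(cfg: LitterSimConfig) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Draw the mother and (for LTSS) sire genotypes under Hardy-Weinberg.

    Returns ``(mother, sires, freqs)`` where mother and each sire are
    ``(n_loci, 2)`` sorted allele arrays and ``freqs`` the per-locus
    reference-allele frequencies used.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 1)
    freqs = draw_allele_freqs(cfg, rng)
    mother = _hwe_genotypes(freqs, rng)
    n_sires = cfg.n_sires if cfg.mode == MODE_LTSS else 0
    sires = [_hwe_genotypes(freqs, rng) for _ in range(n_sires or 0)]
    return mother, sires, freqs


def _build_matrix(cfg: LitterSimConfig, mother: np.ndarray, kids: np.ndarray,
                  sexes: list[str]) -> tuple[GenotypeMatrix, list[SampleMeta]]:
    sample_ids = [MOTHER_ID] + [f"O{i + 1}" for i in range(kids.shape[0])]
    locus_ids = [f"L{j + 1}" for j in range(cfg.n_loci)]
    calls = np.concatenate([mother[None, :, :], kids], axis=0) if kids.size or mother.size else \
        np.empty((1 + kids.shape[0], cfg.n_loci, 2), dtype=np.int32)
    meta = [SampleMeta(MOTHER_ID, ROLE_MOTHER, "female")] + [
        SampleMeta(sid, ROLE_OFFSPRING, sx) for sid, sx in zip(sample_ids[1:], sexes)
    ]
    return GenotypeMatrix(sample_ids, locus_ids, calls.astype(np.int32)), meta


def simulate_ltss_litter(
    cfg: LitterSimConfig, mother: np.ndarray, sires: Sequence[np.ndarray]
) -> tuple[GenotypeMatrix, list[SampleMeta], list[int]]:
    """Mendelian litter from the mother and her assigned sires.

    Each offspring receives one uniformly chosen maternal allele and one
    from its sire, independently across loci.  The error overlay is NOT
    applied here.  Returns the matrix (mother first), metadata, and the
    per-offspring sire indices.
    """
    cfg.validate()
    if cfg.mode != MODE_LTSS:
        raise ConfigError("simulate_ltss_litter requires mode='ltss'")
    rng = _rng(cfg.seed, 2)
    n, L = cfg.n_offspring, cfg.n_loci
    if isinstance(cfg.sire_assignment, str):
        if cfg.sire_assignment != "random":
            raise ConfigError(f"unknown sire_assignment {cfg.sire_assignment!r}")
        sire_of = rng.integers(len(sires), size=n).tolist() if sires else []
    else:
        sire_of = list(cfg.sire_assignment)
        if len(sire_of) != n:
            raise ConfigError("sire_assignment length must equal n_offspring")
        for s in sire_of:
            if not 0 <= s < len(sires):
                raise ConfigError(f"sire index {s} out of range for {len(sires)} sires")
    kids = np.empty((n, L, 2), dtype=np.int32)
    for i in range(n):
        mat = mother[np.arange(L), rng.integers(2, size=L)]
        pat = np.asarray(sires[sire_of[i]])[np.arange(L), rng.integers(2, size=L)]
        kids[i] = np.sort(np.stack([mat, pat], axis=1), axis=1)
    sexes = ["male" if u < cfg.sex_ratio else "female" for u in rng.random(n)]
    matrix, meta = _build_matrix(cfg, mother, kids, sexes)
    return matrix, meta, sire_of


def simulate_fp_litter(
    cfg: LitterSimConfig, mother: np.ndarray
) -> tuple[GenotypeMatrix, list[SampleMeta]]:
    """Automictic litter: every offspring allele comes from the mother.

    gametic_duplication: offspring homozygous everywhere for one uniformly
    chosen maternal allele.  terminal/central fusion: maternal homozygous
    loci are copied; maternal heterozygous loci stay heterozygous with
    probability ``het_retention``, else become homozygous for a uniformly
    chosen maternal allele.  All offspring are male (ZZ; WW is inviable).
    """
    cfg.validate()
    if cfg.mode not in FP_MODES:
        raise ConfigError("simulate_fp_litter requires an fp_* mode")
    rng = _rng(cfg.seed, 2)
    n, L = cfg.n_offspring, cfg.n_loci
    mom_het = mother[:, 0] != mother[:, 1]
    kids = np.empty((n, L, 2), dtype=np.int32)
    for i in range(n):
        if cfg.mode == "fp_gametic_duplication":
            a = mother[np.arange(L), rng.integers(2, size=L)]
            kids[i, :, 0] = kids[i, :, 1] = a
        else:
            kid = mother.copy()
            lose = mom_het & (rng.random(L) >= cfg.het_retention)
            a = mother[np.arange(L), rng.integers(2, size=L)]
            kid[lose, 0] = kid[lose, 1] = a[lose]
            kids[i] = kid
    matrix, meta = _build_matrix(cfg, mother, kids, ["male"] * n)
    return matrix, meta


def apply_error(
    matrix: GenotypeMatrix,
    cfg: LitterSimConfig,
    sample_ids: Sequence[str] | None = None,
    alleles: tuple[int, int] | None = (REF, ALT),
) -> GenotypeMatrix:
    """Overlay genotyping error: per cell, missingness, then allelic
    dropout (a heterozygote read as one of its homozygotes), then miscall
    (the genotype replaced by one drawn uniformly from the three biallelic
    genotypes).

    ``alleles`` fixes the biallelic universe used for miscalls; pass None to
    infer it per locus from the observed calls (loci with fewer than two
    observed alleles then only produce miscalls within the observed set).
    Randomness is keyed per sample id, so the overlay commutes with sample
    reordering; ``sample_ids`` restricts the overlay to a subset.
    """
    cfg.validate()
    out = matrix.copy()
    targets = matrix.sample_ids if sample_ids is None else list(sample_ids)
    L = matrix.n_loci
    if alleles is None:
        per_locus = [matrix.locus_alleles(j) for j in range(L)]
        lo = np.array([a[0] if a else REF for a in per_locus], dtype=np.int32)
        hi = np.array([a[-1] if a else REF for a in per_locus], dtype=np.int32)
    else:
        lo = np.full(L, alleles[0], dtype=np.int32)
        hi = np.full(L, alleles[1], dtype=np.int32)
    # three biallelic genotypes per locus, sorted pairs: (lo,lo) (lo,hi) (hi,hi)
    geno3 = np.stack(
        [np.stack([lo, lo], 1), np.stack([lo, hi], 1), np.stack([hi, hi], 1)], axis=0
    )  # (3, L, 2)
    mc = matrix.missing_code
    for sid in targets:
        i = out.sample_index(sid)
        salt = zlib.crc32(sid.encode()) & 0x7FFFFFFF
        rng = _rng(cfg.seed, 3, salt)
        u = rng.random((L, 3))
        drop_side = rng.integers(2, size=L)
        mis_pick = rng.integers(3, size=L)
        cell = out.calls[i]
        present = cell[:, 0] != mc
        make_missing = present & (u[:, 0] < cfg.missing_rate)
        cell[make_missing] = mc
        present &= ~make_missing
        het = present & (cell[:, 0] != cell[:, 1])
        drop = het & (u[:, 1] < cfg.dropout_rate)
        kept = cell[np.arange(L), drop_side]
        cell[drop, 0] = cell[drop, 1] = kept[drop]
        mis = present & ~drop & (u[:, 2] < cfg.miscall_rate)
        cell[mis] = geno3[mis_pick[mis], np.nonzero(mis)[0]]
    out.calls = np.sort(out.calls, axis=2)
    return out


def simulate_litter(cfg: LitterSimConfig) -> SimResult:
    """End-to-end litter simulation: parents, inheritance, error overlay."""
    cfg.validate()
    mother, sires, freqs = simulate_parents(cfg)
    if cfg.mode == MODE_LTSS:
        matrix, meta, sire_of = simulate_ltss_litter(cfg, mother, sires)
    else:
        matrix, meta = simulate_fp_litter(cfg, mother)
        sire_of = None
    matrix = apply_error(matrix, cfg)
    return SimResult(matrix, meta, cfg, freqs, sire_of, cfg.n_infertile_ova)
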