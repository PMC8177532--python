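"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results with naive loops and
explicit enumeration so the vectorised implementations are checked against
logic that shares no code with them.
"""

from __future__ import annotations

import numpy as np
import pytest

from litterscan import GenotypeMatrix

MISSING = -9

# (name, recognition, cut offset) for the default ddRAD enzyme pair
ENZ_DEFAULT = [("MspI", "CCGG", 1), ("PstI", "CTGCAG", 5)]


def random_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_loci: int,
    missing_frac: float = 0.1,
    alleles=(1, 2),
) -> GenotypeMatrix:
    """Random biallelic genotype matrix with missingness."""
    calls = rng.choice(alleles, size=(n_samples, n_loci, 2)).astype(np.int32)
    miss = rng.random((n_samples, n_loci)) < missing_frac
    calls[miss] = MISSING
    return GenotypeMatrix(
        [f"S{i}" for i in range(n_samples)],
        [f"L{j}" for j in range(n_loci)],
        calls,
        missing_code=MISSING,
    )


def naive_scan(matrix: GenotypeMatrix, mother_id: str, offspring_ids: list[str]):
    """Triple-loop recomputation of the paternal-allele scan (strict policy).

    Returns (hom_loci, flags dict[(offspring, locus)] -> 1/0/None,
    conservative_loci, liberal_loci).
    """
    mi = matrix.sample_ids.index(mother_id)
    hom_loci = []
    for j, locus in enumerate(matrix.locus_ids):
        a, b = matrix.calls[mi, j]
        if a != matrix.missing_code and a == b:
            hom_loci.append(locus)
    flags = {}
    for locus in hom_loci:
        j = matrix.locus_ids.index(locus)
        mat = int(matrix.calls[mi, j, 0])
        for sid in offspring_ids:
            i = matrix.sample_ids.index(sid)
            pair = [int(x) for x in matrix.calls[i, j]]
            if pair[0] == matrix.missing_code:
                flags[(sid, locus)] = None
            else:
                flags[(sid, locus)] = int(any(x != mat for x in pair))
    conservative, liberal = [], []
    for locus in hom_loci:
        vals = [flags[(sid, locus)] for sid in offspring_ids]
        if all(v == 1 for v in vals):
            conservative.append(locus)
        if any(v == 1 for v in vals):
            liberal.append(locus)
    return hom_loci, flags, conservative, liberal


def oracle_digest(seq: str, enzymes):
    """Naive string-scan digest: (cut position, enzyme) by explicit loop.

    ``enzymes`` is a list of (name, recognition, cut_offset); later entries
    win position ties, matching the implementation's documented tie-break.
    """
    cuts = {}
    for name, site, off in enzymes:
        for i in range(len(seq) - len(site) + 1):
            if seq[i : i + len(site)] == site:
                cuts[i + off] = name
    bounds = sorted(p for p in cuts if 0 < p < len(seq))
    frags = []
    prev, prev_lab = 0, "sequence-terminus"
    for pos in bounds + [len(seq)]:
        lab = cuts.get(pos, "sequence-terminus") if pos < len(seq) else "sequence-terminus"
        if pos > prev:
            frags.append((prev, pos, pos - prev, prev_lab, lab))
        prev, prev_lab = pos, cuts.get(pos, "sequence-terminus")
    return frags


def enumerate_pair_likelihoods(gm: int, oi: int, oj: int, q: float, eps: float):
    """Exhaustive enumeration of the full-sib and half-sib likelihoods for
    one locus; genotypes are alt-allele counts.  Independent of the package
    implementation (explicit gamete loops, no tensors)."""
    p = 1 - q
    hwe = {0: p * p, 1: 2 * p * q, 2: q * q}

    def gametes(g):
        return [(0, 1.0)] if g == 0 else ([(1, 1.0)] if g == 2 else [(0, 0.5), (1, 0.5)])

    def p_true(t, mom, dad):
        tot = 0.0
        for am, pm in gametes(mom):
            for af, pf in gametes(dad):
                if am + af == t:
                    tot += pm * pf
        return tot

    def p_obs(o, t):
        return (1 - eps) * (1.0 if o == t else 0.0) + eps / 3.0

    def child_term(obs, dad):
        return sum(p_true(t, gm, dad) * p_obs(obs, t) for t in (0, 1, 2))

    l_fs = sum(hwe[f] * child_term(oi, f) * child_term(oj, f) for f in (0, 1, 2))
    l_hs = sum(hwe[f] * child_term(oi, f) for f in (0, 1, 2)) * sum(
        hwe[f] * child_term(oj, f) for f in (0, 1, 2)
    )
    return l_fs, l_hs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
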