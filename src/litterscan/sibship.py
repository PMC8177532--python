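"""Minimum sire count via pairwise full-sib vs. half-sib likelihoods.

With the mother known, two offspring are full sibs iff they share the sire.
For each offspring pair the log-likelihood ratio (LLR) of full-sib versus
paternal-half-sib is accumulated over loci: per locus the joint probability
of the two observed genotypes given the maternal genotype is summed over the
unknown father genotype(s) under Hardy-Weinberg, sharing one father under
full-sib and drawing two independent fathers under half-sib.  Observations
pass through a symmetric error channel that replaces the true genotype with
one drawn uniformly from the three biallelic genotypes at rate ``error_rate``.
Offspring are then clustered by thresholding the LLR matrix and taking
connected components; the number of clusters is the minimum sire count.

This is a deliberate simplification of full pedigree-reconstruction MCMC
(as in COLONY): only the full-sib grouping and the minimum number of sires
are produced, not a pedigree posterior.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

# transmission tensor T[gm, f, t]: P(true offspring genotype t | mother gm, father f)
# genotype categories = count of the higher-coded allele (0, 1, 2)


def _transmission_tensor() -> np.ndarray:
    T = np.zeros((3, 3, 3))
    gamete = {0: [(0, 1.0)], 1: [(0, 0.5), (1, 0.5)], 2: [(1, 1.0)]}
    for gm in range(3):
        for f in range(3):
            for am, pm in gamete[gm]:
                for af, pf in gamete[f]:
                    T[gm, f, am + af] += pm * pf
    return T


_T = _transmission_tensor()


@dataclass
class SibshipPartition:
    """Offspring grouped into inferred paternal full-sibships."""

    clusters: list[list[str]]
    pairwise_llr: pd.DataFrame
    n_sires_min: int
    error_rate: float
    llr_threshold: float = 0.0

    def to_dict(self) -> dict:
        return {
            "clusters": self.clusters,
            "n_sires_min": self.n_sires_min,
            "error_rate": self.error_rate,
            "llr_threshold": self.llr_threshold,
            "pairwise_llr": {
                f"{i}|{j}": float(self.pairwise_llr.loc[i, j])
                for i, j in itertools.combinations(self.pairwise_llr.index, 2)
            },
        }


def _locus_categories(matrix: GenotypeMatrix):
    """Per-locus biallelic coding: (a_low, a_high, usable mask, genotype
    category array (n_samples, n_loci) with -1 for missing/unusable)."""
    n, L = matrix.n_samples, matrix.n_loci
    cat = np.full((n, L), -1, dtype=np.int8)
    usable = np.zeros(L, dtype=bool)
    counts_hi = np.zeros(L)
    counts_tot = np.zeros(L)
    for j in range(L):
        alleles = matrix.locus_alleles(j)
        if len(alleles) != 2:
            continue  # monomorphic loci carry no sibship information; >2 unusable
        lo, hi = alleles
        usable[j] = True
        col = matrix.calls[:, j, :]
        miss = (col == matrix.missing_code).all(axis=1)
        c = (col == hi).sum(axis=1).astype(np.int8)
        cat[:, j] = np.where(miss, -1, c)
        nm = col[~miss]
        counts_hi[j] = (nm == hi).sum()
        counts_tot[j] = nm.size
    q = np.divide(counts_hi, counts_tot, out=np.zeros(L), where=counts_tot > 0)
    return usable, cat, q


def estimate_allele_freqs(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-locus frequency of the higher-coded allele, counted over all
    samples (mother included; the resulting slight bias is documented)."""
    _, _, q = _locus_categories(matrix)
    return q


def _pair_llr(
    gm: np.ndarray, oi: np.ndarray, oj: np.ndarray, q: np.ndarray, eps: float
) -> float:
    """Vectorised LLR over loci; inputs are genotype-category arrays."""
    p = 1.0 - q
    w = np.stack([p * p, 2 * p * q, q * q], axis=1)  # (L, 3) father HWE prior
    Tg = _T[gm]  # (L, 3, 3): father f, true t
    eye = np.eye(3)
    Pi = (1 - eps) * eye[:, oi].T + eps / 3.0  # (L, 3) over true t
    Pj = (1 - eps) * eye[:, oj].T + eps / 3.0
    Ai = np.einsum("lft,lt->lf", Tg, Pi)
    Aj = np.einsum("lft,lt->lf", Tg, Pj)
    L_fs = (w * Ai * Aj).sum(axis=1)
    L_hs = (w * Ai).sum(axis=1) * (w * Aj).sum(axis=1)
    ok = (L_fs > 0) & (L_hs > 0)  # zero likelihoods only possible at eps == 0
    return float(np.log(L_fs[ok]).sum() - np.log(L_hs[ok]).sum())


def pairwise_sib_llr(
    matrix: GenotypeMatrix,
    mother_id: str,
    off_i: str,
    off_j: str,
    allele_freqs: np.ndarray | None = None,
    error_rate: float = 0.05,
) -> float:
    """Log-likelihood ratio full-sib vs. paternal-half-sib for one pair.

    Positive favours full-sib.  Loci are used when biallelic and non-missing
    in the mother and both offspring; with zero usable loci an error is
    raised rather than returning a silent 0.  ``allele_freqs`` (frequency of
    each locus's higher-coded allele) defaults to counting over all samples.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    usable, cat, q_est = _locus_categories(matrix)
    q = q_est if allele_freqs is None else np.asarray(allele_freqs, dtype=float)
    if q.shape != (matrix.n_loci,):
        raise ValueError("allele_freqs must have one entry per locus")
    mi = matrix.sample_index(mother_id)
    ii = matrix.sample_index(off_i)
    ji = matrix.sample_index(off_j)
    if ii > ji:  # canonical order makes the LLR exactly symmetric in float arithmetic
        ii, ji = ji, ii
    ok = usable & (cat[mi] >= 0) & (cat[ii] >= 0) & (cat[ji] >= 0)
    if not ok.any():
        raise ValueError(f"no usable loci for pair ({off_i}, {off_j})")
    return _pair_llr(cat[mi, ok], cat[ii, ok], cat[ji, ok], q[ok], error_rate)


def partition_sibships(
    matrix: GenotypeMatrix,
    mother_id: str,
    offspring_ids: Sequence[str] | None = None,
    allele_freqs: np.ndarray | None = None,
    error_rate: float = 0.05,
    llr_threshold: float = 0.0,
) -> SibshipPartition:
    """Cluster offspring into paternal full-sibships.

    Edges join pairs with LLR >= ``llr_threshold`` (a pair exactly at the
    threshold is joined); clusters are the connected components, so
    full-sibship is propagated transitively.  The number of clusters is the
    minimum number of sires consistent with the pairwise evidence.
    """
    if offspring_ids is None:
        offspring_ids = [s for s in matrix.sample_ids if s != mother_id]
    offspring_ids = list(offspring_ids)
    if len(offspring_ids) < 2:
        raise ValueError("partition_sibships requires at least two offspring")

    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    usable, cat, q_est = _locus_categories(matrix)
    q = q_est if allele_freqs is None else np.asarray(allele_freqs, dtype=float)
    mi = matrix.sample_index(mother_id)

    llr = pd.DataFrame(0.0, index=offspring_ids, columns=offspring_ids)
    g = nx.Graph()
    g.add_nodes_from(offspring_ids)
    for a, b in itertools.combinations(offspring_ids, 2):
        ii, ji = sorted((matrix.sample_index(a), matrix.sample_index(b)))
        ok = usable & (cat[mi] >= 0) & (cat[ii] >= 0) & (cat[ji] >= 0)
        if not ok.any():
            raise ValueError(f"no usable loci for pair ({a}, {b})")
        v = _pair_llr(cat[mi, ok], cat[ii, ok], cat[ji, ok], q[ok], error_rate)
        llr.loc[a, b] = llr.loc[b, a] = v
        if v >= llr_threshold:
            g.add_edge(a, b)
    order = {s: k for k, s in enumerate(offspring_ids)}
    clusters = [sorted(c, key=order.get) for c in nx.connected_components(g)]
    clusters.sort(key=lambda c: order[c[0]])
    return SibshipPartition(
        clusters=clusters,
        pairwise_llr=llr,
        n_sires_min=len(clusters),
        error_rate=error_rate,
        llr_threshold=llr_threshold,
    )
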