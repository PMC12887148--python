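"""Pedigree, genomic and combined relationship matrices.

* ``build_A`` — numerator relationship matrix by the tabular method, with
  inbreeding coefficients F (diag(A) = 1 + F).
* ``build_A_inverse`` — sparse A⁻¹ by Henderson's rules with inbreeding.
* ``build_G`` — VanRaden genomic relationship matrix
  G = (M − P)(M − P)′ / (2 Σ pⱼ(1 − pⱼ)), allele frequencies observed in
  the genotyped set.
* ``weighted_G`` — G* = Z D Z′ λ with per-SNP weights D and the
  normalising constant λ = 1 / Σ 2pᵢ(1 − pᵢ).
* ``blend_and_tune_G`` — tune G's mean diagonal/off-diagonal to A22, then
  blend G with A22 for invertibility.
* ``build_H_inverse`` — single-step combined inverse
  H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹] on the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import GenotypeMatrix, PedigreeTable
from .errors import ConfigError, DataError, NumericalError


def build_A(ped: PedigreeTable) -> tuple[np.ndarray, np.ndarray]:
    """Tabular-method A and per-animal inbreeding F (pedigree order).

    Row recurrence over ancestor-sorted animals:
    A[i, j<i] = (A[s, j] + A[d, j]) / 2 and A[i, i] = 1 + A[s, d] / 2.
    """
    n = len(ped)
    sire, dam = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    F = np.diag(A) - 1.0
    return A, F


def build_A_inverse(ped: PedigreeTable, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules, accounting for inbreeding.

    The Mendelian-sampling variance of animal i is
    d_i = 0.5 − 0.25 (F_s + F_d) with both parents known,
    0.75 − 0.25 F_p with one, and 1 with none.
    """
    n = len(ped)
    sire, dam = ped.parent_indices()
    if F is None:
        _, F = build_A(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        a = 1.0 / di
        add(i, i, a)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * a)
                add(p, i, -0.5 * a)
                add(p, p, 0.25 * a)
        if s >= 0 and d >= 0:
            add(s, d, 0.25 * a)
            add(d, s, 0.25 * a)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_G(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix from observed allele frequencies."""
    p = geno.allele_freqs()
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise DataError("need at least 2 polymorphic SNPs to build G")
    m = geno.imputed()[:, poly]
    pp = p[poly]
    Z = m - 2.0 * pp
    denom = 2.0 * np.sum(pp * (1.0 - pp))
    G = (Z @ Z.T) / denom
    return (G + G.T) / 2.0


def weighted_G(geno: GenotypeMatrix, weights: np.ndarray,
               lam: float | None = None) -> np.ndarray:
    """Weighted genomic relationship matrix G* = Z D Z′ λ.

    ``weights`` is the diagonal of D (one non-negative weight per SNP of
    ``geno``); λ defaults to 1 / Σ 2pᵢ(1 − pᵢ). With D = I this equals
    :func:`build_G`.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (geno.n_snps,):
        raise ConfigError("weights length must equal SNP count")
    if np.any(w < 0):
        raise ConfigError("SNP weights must be non-negative")
    p = geno.allele_freqs()
    poly = (p > 0) & (p < 1)
    m = geno.imputed()[:, poly]
    pp = p[poly]
    Z = m - 2.0 * pp
    if lam is None:
        lam = 1.0 / (2.0 * np.sum(pp * (1.0 - pp)))
    G = (Z * w[poly]) @ Z.T * lam
    return (G + G.T) / 2.0


def vanraden_lambda(freqs: np.ndarray) -> float:
    """λ = σ²_u / σ²_a = 1 / Σ 2pᵢ(1 − pᵢ), the SNP-to-animal variance ratio."""
    p = np.asarray(freqs, dtype=float)
    return 1.0 / (2.0 * np.sum(p * (1.0 - p)))


def blend_and_tune_G(G: np.ndarray, A22: np.ndarray, alpha: float = 0.05,
                     tune: bool = True) -> np.ndarray:
    """Adjust G towards compatibility with the pedigree block A22.

    With ``tune`` on, solve for a + bG matching A22's mean diagonal and
    mean off-diagonal (the usual single-step compatibility tuning); then
    return (1 − α) G + α A22, which is PD whenever A22 is PD and α > 0.
    """
    if not 0 <= alpha < 1:
        raise ConfigError("alpha must be in [0, 1)")
    if G.shape != A22.shape:
        raise ConfigError("G and A22 dimensions differ")
    n = G.shape[0]
    Gt = G
    if tune and n > 1:
        off = ~np.eye(n, dtype=bool)
        md_g, mo_g = np.mean(np.diag(G)), np.mean(G[off])
        md_a, mo_a = np.mean(np.diag(A22)), np.mean(A22[off])
        if abs(md_g - mo_g) < 1e-12:
            raise NumericalError("cannot tune G: degenerate diagonal/off-diagonal means")
        b = (md_a - mo_a) / (md_g - mo_g)
        a = md_a - b * md_g
        Gt = a + b * G
    return (1.0 - alpha) * Gt + alpha * A22


def build_H_inverse(A_inv: sp.spmatrix, A22_inv: np.ndarray,
                    G_adj_inv: np.ndarray, genotyped_idx: np.ndarray) -> sp.csr_matrix:
    """H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹] with the correction scattered onto
    the genotyped rows/columns given by ``genotyped_idx`` (pedigree order)."""
    idx = np.asarray(genotyped_idx, dtype=int)
    corr = np.asarray(G_adj_inv) - np.asarray(A22_inv)
    k = len(idx)
    block = sp.coo_matrix(
        (corr.ravel(), (np.repeat(idx, k), np.tile(idx, k))), shape=A_inv.shape
    )
    H = sp.csr_matrix(A_inv) + block.tocsr()
    return (H + H.T) * 0.5


def _inv_pd(mat: np.ndarray, what: str) -> np.ndarray:
    try:
        c = np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        raise NumericalError(
            f"{what} is not positive definite; raise the blending alpha"
        ) from None
    inv = np.linalg.inv(c)
    return inv.T @ inv


@dataclass
class RelationshipSet:
    """All relationship structures one evaluation needs."""

    A: np.ndarray
    A_inv: sp.csr_matrix
    F: np.ndarray
    genotyped_idx: np.ndarray  # pedigree-order rows of the genotyped animals
    A22: np.ndarray | None = None
    A22_inv: np.ndarray | None = None
    G: np.ndarray | None = None
    G_adj: np.ndarray | None = None
    H_inv: sp.csr_matrix | None = None


def build_relationships(ped: PedigreeTable, geno: GenotypeMatrix | None = None,
                        weights: np.ndarray | None = None,
                        alpha: float = 0.05, tune: bool = True) -> RelationshipSet:
    """Assemble A, A⁻¹, F and — when genotypes are given — G (optionally
    SNP-weighted), the tuned/blended G, and H⁻¹."""
    A, F = build_A(ped)
    A_inv = build_A_inverse(ped, F)
    if geno is None or geno.n_animals == 0:
        return RelationshipSet(A=A, A_inv=A_inv, F=F,
                               genotyped_idx=np.array([], dtype=int),
                               H_inv=A_inv)
    idx = ped.index_of(geno.ids)
    A22 = A[np.ix_(idx, idx)]
    A22_inv = _inv_pd(A22, "A22")
    G = build_G(geno) if weights is None else weighted_G(geno, weights)
    G_adj = blend_and_tune_G(G, A22, alpha=alpha, tune=tune)
    G_adj_inv = _inv_pd(G_adj, "blended G")
    H_inv = build_H_inverse(A_inv, A22_inv, G_adj_inv, idx)
    return RelationshipSet(A=A, A_inv=A_inv, F=F, genotyped_idx=idx,
                           A22=A22, A22_inv=A22_inv, G=G, G_adj=G_adj,
                           H_inv=H_inv)
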