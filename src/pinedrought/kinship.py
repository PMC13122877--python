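"""Genotype QC and additive relationship matrices (A and G).

The pedigree matrix A is built with the tabular recursion; the genomic
matrix G follows VanRaden's first method, Z Z' / (2 * sum p (1 - p)) with Z
the dosage matrix centred at twice the observed allele frequencies. ``tune_g``
blends G toward the identity (or A) to guarantee an invertible matrix for
the mixed-model equations.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import linalg

from .containers import GenotypeMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "qc_genotypes",
    "impute_simple",
    "a_matrix",
    "g_matrix",
    "tune_g",
    "gene_drop_a",
]

log = logging.getLogger(__name__)


def qc_genotypes(
    geno: GenotypeMatrix,
    max_missing: float = 0.4,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Drop SNPs by missingness, then by minor allele frequency.

    Mirrors the study's variant-QC thresholds (drop SNPs missing in more
    than 40% of individuals; keep MAF > 5%). MAF is computed after the
    missingness filter. Raises if nothing survives.
    """
    if not (0.0 <= max_missing <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    miss = geno.missing_rate()
    keep1 = miss <= max_missing
    n_miss_dropped = int((~keep1).sum())
    g1 = geno.subset_snps(keep1)
    maf = g1.minor_allele_frequencies()
    with np.errstate(invalid="ignore"):
        keep2 = np.nan_to_num(maf, nan=0.0) >= min_maf
    n_maf_dropped = int((~keep2).sum())
    out = g1.subset_snps(keep2)
    log.info(
        "genotype QC: %d SNPs dropped for missingness > %.2f, %d for MAF < %.2f, "
        "%d retained",
        n_miss_dropped, max_missing, n_maf_dropped, min_maf, out.n_snps,
    )
    if out.n_snps == 0:
        raise ValueError("all SNPs removed by QC")
    return out


def impute_simple(geno: GenotypeMatrix, method: str = "mean") -> GenotypeMatrix:
    """Fill missing dosages with the per-SNP mean or mode.

    A declared simple imputer standing in for LD-based imputation, which is
    out of scope here. The mean method yields fractional dosages in [0, 2].
    """
    if method not in ("mean", "mode"):
        raise ValueError("method must be 'mean' or 'mode'")
    X = geno.dosages.copy()
    nan = np.isnan(X)
    if not nan.any():
        return GenotypeMatrix(list(geno.ids), list(geno.snp_ids), X)
    if np.any(nan.all(axis=0)):
        bad = [s for s, b in zip(geno.snp_ids, nan.all(axis=0)) if b]
        raise ValueError(f"SNPs with all entries missing (run QC first): {bad[:5]}")
    if method == "mean":
        fill = np.nanmean(X, axis=0)
    else:
        fill = np.array(
            [
                np.bincount(col[~np.isnan(col)].astype(int), minlength=3).argmax()
                for col in X.T
            ],
            dtype=float,
        )
    X[nan] = np.take(fill, np.nonzero(nan)[1])
    frac = nan.mean()
    log.info("imputed %.2f%% of genotype entries (%s method)", 100 * frac, method)
    return GenotypeMatrix(list(geno.ids), list(geno.snp_ids), X)


def a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix by the tabular method.

    A_ii = 1 + 0.5 * A_{s(i),d(i)}; A_ij = 0.5 * (A_{j,s(i)} + A_{j,d(i)})
    for j < i, with an unknown parent contributing zero. Requires parents to
    precede offspring (enforced by the Pedigree container).
    """
    n = len(ped)
    parents = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = parents[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(kind="A", ids=list(ped.ids), values=A)


def g_matrix(geno: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    Z = dosages - 2p with p the observed allele frequencies;
    G = Z Z' / (2 * sum_j p_j (1 - p_j)). Requires a complete matrix with no
    monomorphic SNPs (both should be guaranteed by QC + imputation).
    """
    if geno.has_missing():
        raise ValueError("G matrix requires a complete (imputed) genotype matrix")
    if geno.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    p = geno.allele_frequencies()
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic SNPs present; run QC first")
    Z = geno.dosages - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(kind="G", ids=list(geno.ids), values=G)


def tune_g(
    G: RelationshipMatrix,
    blend_weight: float = 0.01,
    blend_target: str | RelationshipMatrix = "identity",
) -> RelationshipMatrix:
    """Blend G toward a positive-definite target for stable inversion.

    G* = (1 - w) G + w T with T the identity or a supplied A matrix (rows
    aligned by id). The result is verified positive definite by Cholesky
    factorization and its condition number recorded.
    """
    if not (0.0 <= blend_weight <= 0.1):
        raise ValueError("blend_weight must lie in [0, 0.1]")
    if isinstance(blend_target, RelationshipMatrix):
        T = blend_target.submatrix(list(G.ids)).values
    elif blend_target == "identity":
        T = np.eye(G.n)
    else:
        raise ValueError("blend_target must be 'identity' or a RelationshipMatrix")
    Gs = (1.0 - blend_weight) * G.values + blend_weight * T
    if blend_weight > 0.0:
        try:
            linalg.cholesky(Gs, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(
                f"tuned G still not positive definite at w={blend_weight}; "
                "increase blend_weight"
            ) from exc
    w_eig = np.linalg.eigvalsh(Gs)
    cond = float(w_eig[-1] / w_eig[0]) if w_eig[0] > 0 else np.inf
    log.info("tuned G: w=%.3g, condition number %.3g", blend_weight, cond)
    return RelationshipMatrix(
        kind="G-tuned" if blend_weight > 0 else G.kind,
        ids=list(G.ids),
        values=Gs,
        condition_number=cond,
    )


def gene_drop_a(
    ped: Pedigree, n_drops: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo estimate of the additive relationship matrix.

    Drops unique founder alleles through the pedigree ``n_drops`` times and
    estimates A_ij as twice the probability that a random allele from i and
    a random allele from j are identical by descent. Independent oracle for
    :func:`a_matrix` on small pedigrees.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    parents = ped.parent_indices()
    alleles = np.empty((n_drops, n, 2), dtype=np.int32)
    label = 0
    for i in range(n):
        s, d = parents[i]
        if s == -1 and d == -1:
            alleles[:, i, 0] = 2 * label
            alleles[:, i, 1] = 2 * label + 1
            label += 1
        else:
            pick = rng.integers(0, 2, size=(n_drops, 2))
            alleles[:, i, 0] = np.take_along_axis(
                alleles[:, s, :], pick[:, :1], axis=1
            )[:, 0]
            alleles[:, i, 1] = np.take_along_axis(
                alleles[:, d, :], pick[:, 1:], axis=1
            )[:, 0]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            share = 0.0
            for a in range(2):
                for b in range(2):
                    share += np.mean(alleles[:, i, a] == alleles[:, j, b])
            kin = share / 4.0
            if i == j:
                # self-kinship = (1 + F)/2 with F = P(the two own alleles IBD)
                A[i, i] = 2.0 * kin
            else:
                A[i, j] = A[j, i] = 2.0 * kin
    return A
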