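"""VanRaden genomic relationship matrix and its SVD for population structure.

G = Z Z' / k where column j of Z is the dosage vector centered by twice the
pooled allele frequency and k = 2 * sum_j p_j (1 - p_j) over retained SNPs.
Because G is symmetric positive semidefinite, its singular values equal its
eigenvalues and the left singular vectors are eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from driftscan.genotype_io import MISSING, GenotypeDataset


@dataclass
class GRM:
    values: np.ndarray
    sample_ids: list[str]
    populations: list[str]
    k_denominator: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM must be symmetric to 1e-10")
        if self.k_denominator <= 0:
            raise ValueError("k_denominator must be positive")
        self.values = v

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tpopulation\t" + "\t".join(self.sample_ids) + "\n")
            for i, (sid, pop) in enumerate(zip(self.sample_ids, self.populations)):
                row = "\t".join(f"{x:.8g}" for x in self.values[i])
                fh.write(f"{sid}\t{pop}\t{row}\n")

    def distance_matrix(self) -> np.ndarray:
        """1 - normalized GRM, a heatmap-ready dissimilarity (0 on the diagonal)."""
        d = np.sqrt(np.clip(np.diag(self.values), 1e-12, None))
        norm = self.values / np.outer(d, d)
        out = 1.0 - norm
        np.fill_diagonal(out, 0.0)
        return out


@dataclass
class SVDResult:
    components: np.ndarray  # samples x k, left singular vectors scaled by singular values
    vectors: np.ndarray  # samples x k, unit-norm left singular vectors
    singular_values: np.ndarray
    variance_explained: np.ndarray
    sample_ids: list[str]
    populations: list[str]

    def __post_init__(self) -> None:
        sv = np.asarray(self.singular_values, dtype=float)
        if (np.diff(sv) > 1e-9).any():
            raise ValueError("singular values must be non-increasing")
        if (sv < -1e-12).any():
            raise ValueError("singular values must be non-negative")
        if self.variance_explained.sum() > 1.0 + 1e-9:
            raise ValueError("variance_explained must sum to <= 1")

    def to_tsv(self, path: str | Path, scaled: bool = True) -> None:
        mat = self.components if scaled else self.vectors
        k = mat.shape[1]
        with open(path, "w") as fh:
            fh.write("sample_id\tpopulation\t" + "\t".join(f"PC{i + 1}" for i in range(k)) + "\n")
            for i, (sid, pop) in enumerate(zip(self.sample_ids, self.populations)):
                fh.write(f"{sid}\t{pop}\t" + "\t".join(f"{x:.8g}" for x in mat[i]) + "\n")


def compute_grm(dataset: GenotypeDataset) -> GRM:
    """VanRaden GRM from pooled-cohort allele frequencies.

    Missing dosages are mean-imputed to 2p (zero after centering); monomorphic
    SNPs contribute nothing and are excluded from both Z and k.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples")
    dos = dataset.dosages.astype(float)
    miss = dataset.dosages == MISSING
    called = ~miss
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        raise ValueError("SNP with no called genotypes; run QC first")
    p = np.where(called, dos, 0.0).sum(axis=0) / (2.0 * n_called)

    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; GRM undefined")

    p = p[poly]
    Z = dos[:, poly]
    Z[miss[:, poly]] = 0.0
    Z = np.where(miss[:, poly], 2.0 * p, Z) - 2.0 * p

    k = float(2.0 * np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / k
    G = (G + G.T) / 2.0  # enforce exact symmetry against FP noise
    return GRM(
        values=G,
        sample_ids=list(dataset.sample_ids),
        populations=list(dataset.populations),
        k_denominator=k,
    )


def svd_grm(grm: GRM, n_components: int | None = None) -> SVDResult:
    """SVD of the GRM; components are eigenvectors scaled by singular values.

    Sign convention: each component's largest-magnitude entry is positive.
    """
    n = grm.values.shape[0]
    if n_components is None:
        n_components = n
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > n:
        raise ValueError(f"n_components {n_components} exceeds sample count {n}")

    # symmetric PSD: eigh is the SVD up to sign/ordering
    eigvals, eigvecs = np.linalg.eigh(grm.values)
    order = np.argsort(eigvals)[::-1]
    sv = np.clip(eigvals[order], 0.0, None)
    U = eigvecs[:, order]

    for j in range(U.shape[1]):
        if U[np.argmax(np.abs(U[:, j])), j] < 0:
            U[:, j] = -U[:, j]

    total = sv.sum()
    varexp = sv / total if total > 0 else np.zeros_like(sv)
    return SVDResult(
        components=U[:, :n_components] * sv[:n_components],
        vectors=U[:, :n_components],
        singular_values=sv[:n_components],
        variance_explained=varexp[:n_components],
        sample_ids=list(grm.sample_ids),
        populations=list(grm.populations),
    )
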