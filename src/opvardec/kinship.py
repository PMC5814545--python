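"""Pedigree and marker-based relationship matrices.

Implements the kernels used in the four progeny-trial models:

* ``A`` — the pedigree numerator relationship matrix for open-pollinated
  families under the half-sib assumption (0.25 within a maternal family).
* ``G_add`` — the realized additive genomic relationship matrix,
  ``G = ZZ' / (2 * sum_i p_i (1 - p_i))`` with ``Z = M - 2p`` per marker
  (VanRaden-style centering by twice the allele frequency).
* ``G_dom`` — the dominance relationship matrix built from the orthogonal
  three-genotype coding ``{-2q^2, 2pq, -2p^2}`` with denominator
  ``sum_i (2 p_i q_i)^2`` (Vitezica parameterization).
* first-order epistatic kernels as Hadamard (element-wise) products:
  ``G_add # G_add``, ``G_dom # G_dom``, ``G_add # G_dom``.

Marker-based kernels are typically singular when individuals outnumber the
effective marker rank; ``condition_matrix`` bends the diagonal minimally so
the mixed model can invert them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, allele_frequencies

__all__ = [
    "RelationshipMatrix",
    "pedigree_A",
    "grm_additive",
    "grm_dominance",
    "hadamard_product",
    "condition_matrix",
    "standard_kernels",
]

_KINDS = ("A", "G_add", "G_dom", "AxA", "DxD", "AxD")


@dataclass
class RelationshipMatrix:
    """Symmetric relatedness kernel over an ordered id universe."""

    individual_ids: list[str]
    values: np.ndarray
    kind: str
    bending_applied: bool = False
    bending_epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")
        # enforce exact symmetry for downstream eigensolvers
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def submatrix(self, ids) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.individual_ids)}
        idx = np.array([pos[i] for i in ids])
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.individual_ids
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format (id1, id2, value) upper triangle including diagonal."""
        iu = np.triu_indices(self.n)
        ids = np.asarray(self.individual_ids)
        return pd.DataFrame(
            {"id1": ids[iu[0]], "id2": ids[iu[1]], "value": self.values[iu]}
        )


def pedigree_A(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix for OP families (sires unknown).

    Mothers are assumed unrelated and non-inbred, so A_ii = 1, A_ij = 0.25
    for two offspring of the same maternal family (nominal half-sibs) and 0
    across families.
    """
    if pedigree["individual"].duplicated().any():
        dup = pedigree.loc[pedigree["individual"].duplicated(), "individual"].iloc[0]
        raise ValueError(f"duplicate individual in pedigree: {dup!r}")
    ids = [str(i) for i in pedigree["individual"]]
    fam = pd.Categorical(pedigree["family"]).codes
    same_fam = fam[:, None] == fam[None, :]
    A = np.where(same_fam, 0.25, 0.0)
    np.fill_diagonal(A, 1.0)
    return RelationshipMatrix(ids, A, kind="A")


def _complete_codes(g: GenotypeMatrix) -> np.ndarray:
    if not g.is_complete():
        raise ValueError("genotype matrix has missing entries; impute first")
    return g.codes


def _polymorphic(p: np.ndarray, marker_ids) -> np.ndarray:
    poly = (p > 0.0) & (p < 1.0)
    n_mono = int((~poly).sum())
    if n_mono == len(p):
        raise ValueError("all markers are monomorphic; cannot build a GRM")
    if n_mono:
        warnings.warn(
            f"dropping {n_mono} monomorphic markers from the relationship matrix",
            UserWarning,
        )
    return poly


def grm_additive(
    g: GenotypeMatrix, freqs: pd.DataFrame | None = None
) -> RelationshipMatrix:
    """Additive genomic relationship matrix G = ZZ' / 2*sum(p(1-p))."""
    M = _complete_codes(g)
    if freqs is None:
        freqs = allele_frequencies(g)
    p = freqs["p"].to_numpy(dtype=float)
    poly = _polymorphic(p, g.marker_ids)
    Mp, pp = M[:, poly], p[poly]
    Z = Mp - 2.0 * pp[None, :]
    denom = 2.0 * np.sum(pp * (1.0 - pp))
    G = Z @ Z.T / denom
    return RelationshipMatrix(list(g.individual_ids), G, kind="G_add")


def grm_dominance(
    g: GenotypeMatrix, freqs: pd.DataFrame | None = None
) -> RelationshipMatrix:
    """Dominance relationship matrix G = WW' / sum((2pq)^2).

    W codes the reference homozygote as -2p^2, the heterozygote as 2pq and
    the alternative homozygote as -2q^2 per marker. The coding is defined for
    discrete genotypes, so fractional imputed codes are rounded to the
    nearest integer genotype before building W (allele frequencies are still
    taken from the fractional matrix).
    """
    M = _complete_codes(g)
    if freqs is None:
        freqs = allele_frequencies(g)
    p = freqs["p"].to_numpy(dtype=float)
    poly = _polymorphic(p, g.marker_ids)
    Mp, pp = M[:, poly], p[poly]
    qq = 1.0 - pp
    codes = np.clip(np.rint(Mp), 0, 2).astype(int)
    W = np.empty_like(Mp)
    W[codes == 0] = (-2.0 * pp**2)[np.nonzero(codes == 0)[1]]
    W[codes == 1] = (2.0 * pp * qq)[np.nonzero(codes == 1)[1]]
    W[codes == 2] = (-2.0 * qq**2)[np.nonzero(codes == 2)[1]]
    denom = np.sum((2.0 * pp * qq) ** 2)
    G = W @ W.T / denom
    return RelationshipMatrix(list(g.individual_ids), G, kind="G_dom")


_HADAMARD_KIND = {
    frozenset(["G_add"]): "AxA",
    frozenset(["G_dom"]): "DxD",
    frozenset(["G_add", "G_dom"]): "AxD",
    frozenset(["A"]): "AxA",
}


def hadamard_product(
    k1: RelationshipMatrix, k2: RelationshipMatrix
) -> RelationshipMatrix:
    """Element-wise product of two kernels over the same id universe."""
    if k1.individual_ids != k2.individual_ids:
        raise ValueError("kernels are defined over different individual ids")
    kind = _HADAMARD_KIND.get(frozenset([k1.kind, k2.kind]), f"{k1.kind}#{k2.kind}")
    return RelationshipMatrix(
        list(k1.individual_ids), k1.values * k2.values, kind=kind
    )


def condition_matrix(
    k: RelationshipMatrix, epsilon: float | None = None
) -> RelationshipMatrix:
    """Bend a kernel so its smallest eigenvalue is at least ``epsilon``.

    ``epsilon`` defaults to 1e-6 times the mean diagonal. If the smallest
    eigenvalue is already >= epsilon the matrix is returned unchanged
    (``bending_applied=False``); otherwise a constant is added to the
    diagonal to lift the smallest eigenvalue to epsilon.
    """
    if epsilon is None:
        epsilon = 1e-6 * float(np.mean(np.diag(k.values)))
    lam_min = float(np.linalg.eigvalsh(k.values)[0])
    if lam_min >= epsilon and epsilon > 0:
        return RelationshipMatrix(
            list(k.individual_ids), k.values.copy(), k.kind,
            bending_applied=False, bending_epsilon=0.0,
        )
    if epsilon <= 0:
        if lam_min > 0:
            return RelationshipMatrix(
                list(k.individual_ids), k.values.copy(), k.kind,
                bending_applied=False, bending_epsilon=0.0,
            )
        raise ValueError(
            "matrix is singular and epsilon <= 0; pass epsilon > 0 to bend it"
        )
    shift = epsilon - lam_min
    values = k.values + shift * np.eye(k.n)
    return RelationshipMatrix(
        list(k.individual_ids), values, k.kind,
        bending_applied=True, bending_epsilon=shift,
    )


def standard_kernels(
    g: GenotypeMatrix,
    pedigree: pd.DataFrame,
    condition: bool = True,
    epsilon: float | None = None,
) -> dict[str, RelationshipMatrix]:
    """Build the full kernel set used by the four models.

    Returns a dict with keys A, G_add, G_dom, AxA, DxD, AxD, all over the
    genotyped individuals (pedigree rows are aligned to the genotype ids).
    """
    ped = pedigree.set_index(pedigree["individual"].astype(str))
    ped = ped.loc[[str(i) for i in g.individual_ids]].reset_index(drop=True)
    kernels: dict[str, RelationshipMatrix] = {}
    kernels["A"] = pedigree_A(ped)
    g_add = grm_additive(g)
    g_dom = grm_dominance(g)
    kernels["G_add"] = g_add
    kernels["G_dom"] = g_dom
    kernels["AxA"] = hadamard_product(g_add, g_add)
    kernels["DxD"] = hadamard_product(g_dom, g_dom)
    kernels["AxD"] = hadamard_product(g_add, g_dom)
    if condition:
        kernels = {name: condition_matrix(k, epsilon) for name, k in kernels.items()}
    return kernels
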