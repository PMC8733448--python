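"""Kinship coefficients, pedigree recursion and allele-frequency weights.

The kinship coefficient Phi_xy is the probability that one allele sampled
from individual x and one from y are identical by descent (for x = y the
pair is sampled with replacement, so Phi_xx = (1/m)[1 + (m-1) f]).  These
coefficients drive the bias of every squared-frequency estimator through
the weighted mean pair kinship Phi2(P) of a sample.

Pedigree kinship is computed by the classical tabular recursion, for
autosomal loci and for X-linked loci (where males are haploid and carry a
maternal X, so male self-kinship is 1 and fathers transmit their X to all
daughters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import KinshipModel, Pedigree, self_kinship_value

__all__ = [
    "self_kinship",
    "pedigree_kinship",
    "sample_weights",
    "mean_pair_kinship",
    "WeightVector",
]


def self_kinship(m: int, f: float) -> float:
    """Self-kinship (1/m)[1 + (m-1) f]; equals 1 for haploids regardless of f."""
    if m not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    if not 0.0 <= f <= 1.0:
        raise ValueError("inbreeding coefficient must lie in [0, 1]")
    return float(self_kinship_value(m, f))


@dataclass
class WeightVector:
    """Per-individual allele-frequency weights phi_x(P) for one sample."""

    weights: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


def pedigree_kinship(pedigree: Pedigree, locus_class: str = "autosomal") -> KinshipModel:
    """Pairwise kinship, inbreeding and ploidy for all pedigree members.

    Founders are taken to be unrelated and noninbred (known founder
    inbreeding can be injected afterwards via a kinship-table override).
    For ``x_linked`` loci every individual needs a recorded sex; males are
    haploid with their single X inherited from the dam.
    """
    if locus_class not in ("autosomal", "x_linked"):
        raise ValueError("locus_class must be 'autosomal' or 'x_linked'")
    ids = pedigree.individuals  # topological: parents precede offspring
    n = len(ids)
    pos = {name: i for i, name in enumerate(ids)}
    x_linked = locus_class == "x_linked"

    male = np.zeros(n, dtype=bool)
    if x_linked:
        for name in ids:
            s = pedigree.sex[name]
            if s is None:
                raise ValueError(f"x_linked kinship requires a sex for {name}")
            male[pos[name]] = str(s).upper() in ("M", "MALE", "1")

    phi = np.zeros((n, n))
    f = np.zeros(n)

    def parent_indices(i: int) -> tuple[int | None, int | None]:
        name = ids[i]
        s, d = pedigree.sire[name], pedigree.dam[name]
        return (pos[s] if s is not None else None, pos[d] if d is not None else None)

    for i in range(n):
        si, di = parent_indices(i)
        founder = si is None and di is None
        # self terms
        if x_linked and male[i]:
            f[i] = 0.0
            phi[i, i] = 1.0  # haploid
        elif founder:
            phi[i, i] = 0.5
        else:
            par_phi = phi[si, di] if (si is not None and di is not None) else 0.0
            f[i] = par_phi
            phi[i, i] = 0.5 * (1.0 + par_phi)
        # pair terms against everything earlier in topological order
        for j in range(i):
            if founder:
                value = 0.0  # founders unrelated to all prior members
            elif x_linked and male[i]:
                value = phi[j, di] if di is not None else 0.0
            else:
                ps = phi[j, si] if si is not None else 0.0
                pd_ = phi[j, di] if di is not None else 0.0
                value = 0.5 * (ps + pd_)
            phi[i, j] = phi[j, i] = value

    m = np.where(x_linked & male, 1, 2).astype(np.int64) if x_linked else np.full(n, 2, np.int64)
    return KinshipModel(list(ids), phi, f, m, locus_class)


def sample_weights(ploidy: np.ndarray | list[int], kinship: KinshipModel | None = None,
                   scheme: str = "sample_proportion") -> WeightVector:
    """Allele-frequency weights for one locus.

    ``sample_proportion`` weights each individual by the share of alleles it
    contributes, phi_x = m_x / sum_k m_k.  ``blue`` uses the best linear
    unbiased estimator weights phi_x = sum_k (K^-1)_kx / (1' K^-1 1) with K
    the pairwise kinship matrix, and requires a kinship model.
    """
    m = np.asarray(ploidy, dtype=float)
    if scheme == "sample_proportion":
        return WeightVector(m / m.sum(), scheme)
    if scheme == "blue":
        if kinship is None:
            raise ValueError("blue weights require a kinship model")
        K = kinship.phi
        try:
            Kinv = np.linalg.inv(K)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "kinship matrix is singular (duplicated relatives such as identical "
                "twins or repeated samples make BLUE weights undefined)") from exc
        w = Kinv.sum(axis=0) / Kinv.sum()
        return WeightVector(w, scheme)
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def mean_pair_kinship(phi: np.ndarray, weights: WeightVector | np.ndarray) -> float:
    """Weighted mean pair kinship Phi2 = sum_w sum_x phi_w phi_x Phi_wx.

    The double sum includes the self terms (w = x), which is why Phi2 is
    strictly positive even for unrelated noninbred samples — the source of
    the finite-sample bias of squared-frequency estimators.
    """
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (len(w), len(w)):
        raise ValueError("weights and kinship matrix must be indexed identically")
    return float(w @ phi @ w)
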