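"""Estimators of the Patterson F- and D-statistics.

Three estimator families are provided for the statistics that involve a
squared allele frequency from one population:

* ``hat`` — the plug-in estimator, obtained by substituting the sample
  frequency for the population frequency.  Upwardly biased for F2 and F3
  (downwardly for G), with the bias driven by the mean pair kinship
  Phi2(P_j) of the sample.
* ``breve`` — the finite-sample correction, unbiased when the sample holds
  unrelated, noninbred individuals (the correction 1/(sum_m - 1) depends
  only on the number of sampled alleles).
* ``tilde`` — the relatedness- and inbreeding-aware correction, unbiased
  for arbitrary kinship structure; it replaces 1/sum_m by Phi2(P_j).

When the sample is unrelated and noninbred with sample-proportion weights,
Phi2(P_j) = 1/sum_m and the tilde and breve estimators coincide exactly.

F4 needs no correction (one allele sampled per population per locus), and
the D statistic and the DFOIL ratios are approximately unbiased because
neither numerator nor denominator multiplies two frequencies drawn from
the same population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FrequencyPanel, FStatResult, GenotypeMatrix, KinshipModel
from .kinship import WeightVector, mean_pair_kinship, sample_weights

__all__ = [
    "LocusContext",
    "estimate_frequency",
    "locus_context",
    "context_from_panel",
    "g_stat",
    "h_stat",
    "f2",
    "f3",
    "f3_normalized",
    "f4",
    "f4_normalized",
    "d_stat",
    "dfoil",
    "jackknife_se",
]

VARIANTS = ("hat", "breve", "tilde")


@dataclass
class LocusContext:
    """Per-locus estimated frequency with the sample summaries the corrections need.

    ``phat`` is the weighted sample frequency per locus; ``phi2`` the mean
    pair kinship Phi2(P_j) of the individuals present at the locus; and
    ``sum_m`` the total number of sampled alleles at the locus.
    """

    population: str
    phat: np.ndarray
    phi2: np.ndarray | None = None
    sum_m: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phat = np.asarray(self.phat, dtype=float)
        if (self.phat < 0).any() or (self.phat > 1).any():
            raise ValueError("estimated frequencies must lie in [0, 1]")
        if self.phi2 is not None:
            self.phi2 = np.broadcast_to(np.asarray(self.phi2, float), self.phat.shape).copy()
            if (self.phi2 <= 0).any() or (self.phi2 > 1).any():
                raise ValueError("Phi2 must lie in (0, 1]")
        if self.sum_m is not None:
            self.sum_m = np.broadcast_to(np.asarray(self.sum_m, float), self.phat.shape).copy()

    @property
    def n_loci(self) -> int:
        return len(self.phat)

    def _need(self, variant: str) -> None:
        if variant == "tilde" and self.phi2 is None:
            raise ValueError(f"tilde estimator needs Phi2 for population {self.population}; "
                             "provide kinship information")
        if variant == "breve" and self.sum_m is None:
            raise ValueError(f"breve estimator needs allele totals for {self.population}")


def estimate_frequency(genotypes: GenotypeMatrix, weights: WeightVector | None = None) -> np.ndarray:
    """Weighted frequency estimate p-hat = sum_k phi_k X_k per locus.

    X_k is the individual frequency dosage_k / m_k.  With the default
    sample-proportion weights this is the plain allele proportion.  When
    explicit ``weights`` are given they are renormalized per locus over the
    individuals present at that locus.
    """
    present = ~genotypes.missing
    if not present.any(axis=1).all():
        bad = np.where(~present.any(axis=1))[0]
        raise ValueError(f"all individuals missing at locus indices {bad.tolist()}")
    if weights is None:
        w = (genotypes.ploidy * present).astype(float)
    else:
        w = np.broadcast_to(weights.weights, genotypes.dosages.shape) * present
    w = w / w.sum(axis=1, keepdims=True)
    x = np.where(present, genotypes.dosages / np.maximum(genotypes.ploidy, 1), 0.0)
    return (w * x).sum(axis=1)


def locus_context(genotypes: GenotypeMatrix, kinship: KinshipModel | None = None,
                  scheme: str = "sample_proportion") -> LocusContext:
    """Build the per-locus estimation context for one population.

    Missing individuals are dropped per locus; weights, Phi2(P_j) and the
    allele total are recomputed over the individuals present at each locus.
    Without a kinship model the sample is treated as unrelated, noninbred
    diploid/haploid per the genotype ploidy.
    """
    if kinship is None:
        kinship = KinshipModel.unrelated(genotypes.individuals,
                                         ploidy=genotypes.ploidy.max(axis=0))
    else:
        kinship = kinship.subset(genotypes.individuals)
    present = ~genotypes.missing
    sum_m = (genotypes.ploidy * present).sum(axis=1).astype(float)
    if (sum_m == 0).any():
        raise ValueError("locus with no non-missing individuals")

    phi = kinship.phi
    n_loci = genotypes.n_loci
    phat = np.empty(n_loci)
    phi2 = np.empty(n_loci)
    x = np.where(present, genotypes.dosages / np.maximum(genotypes.ploidy, 1), 0.0)

    # loci sharing a missingness-and-ploidy pattern share weights; group to vectorize
    keys = np.concatenate([present, genotypes.ploidy], axis=1)
    patterns, inverse = np.unique(keys, axis=0, return_inverse=True)
    n_ind = genotypes.n_individuals
    for pi, pat in enumerate(patterns):
        rows = np.where(inverse == pi)[0]
        idx = np.where(pat[:n_ind].astype(bool))[0]
        sub_kin = kinship.subset([genotypes.individuals[i] for i in idx])
        m_here = genotypes.ploidy[rows[0], idx]
        w = sample_weights(m_here, sub_kin, scheme=scheme)
        phat[rows] = x[np.ix_(rows, idx)] @ w.weights
        phi2[rows] = mean_pair_kinship(sub_kin.phi, w)
    return LocusContext(genotypes.population, phat, phi2, sum_m)


def context_from_panel(panel: FrequencyPanel, population: str) -> LocusContext:
    """Wrap one population of a frequency panel as a LocusContext."""
    return LocusContext(population, panel.freq[population],
                        panel.phi2.get(population), panel.sum_m.get(population))


# ---------------------------------------------------------------------------
# per-locus building blocks
# ---------------------------------------------------------------------------

def _g_per_locus(ctx: LocusContext, variant: str) -> np.ndarray:
    ctx._need(variant)
    g_hat = ctx.phat * (1.0 - ctx.phat)
    if variant == "hat":
        return g_hat
    if variant == "tilde":
        if (ctx.phi2 >= 1.0).any():
            raise ValueError("Phi2 = 1 at a locus: a single haploid sample has no "
                             "estimable heterozygosity under the tilde correction")
        return g_hat / (1.0 - ctx.phi2)
    if variant == "breve":
        if (ctx.sum_m < 2).any():
            raise ValueError("breve correction needs at least 2 sampled alleles per locus")
        return g_hat * ctx.sum_m / (ctx.sum_m - 1.0)
    raise ValueError(f"unknown variant {variant!r}")


def _g_correction(ctx: LocusContext, variant: str) -> np.ndarray:
    """The per-locus term subtracted once per squared-frequency population."""
    if variant == "hat":
        return np.zeros(ctx.n_loci)
    if variant == "tilde":
        return ctx.phi2 * _g_per_locus(ctx, "tilde")
    if variant == "breve":
        ctx._need("breve")
        return _g_per_locus(ctx, "hat") / (ctx.sum_m - 1.0)
    raise ValueError(f"unknown variant {variant!r}")


def _result(statistic: str, variant: str, pops: tuple[str, ...],
            per_locus: np.ndarray) -> FStatResult:
    per_locus = np.asarray(per_locus, dtype=float)
    return FStatResult(statistic, variant, pops, float(per_locus.mean()),
                       per_locus, len(per_locus))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def g_stat(ctx: LocusContext, variant: str = "hat") -> FStatResult:
    """G(P) = mean of p(1-p): half the expected heterozygosity of P."""
    return _result("G", variant, (ctx.population,), _g_per_locus(ctx, variant))


def h_stat(ctx_a: LocusContext, ctx_b: LocusContext, ctx_c: LocusContext,
           ctx_d: LocusContext) -> FStatResult:
    """H, the normalizer of D: (a+b-2ab)(c+d-2cd) averaged over loci (unbiased)."""
    a, b, c, d = ctx_a.phat, ctx_b.phat, ctx_c.phat, ctx_d.phat
    per = (a + b - 2 * a * b) * (c + d - 2 * c * d)
    pops = (ctx_a.population, ctx_b.population, ctx_c.population, ctx_d.population)
    return _result("H", "hat", pops, per)


def f2(ctx_a: LocusContext, ctx_b: LocusContext, variant: str = "hat") -> FStatResult:
    """F2(A,B): mean squared frequency difference, with both populations corrected."""
    per = (ctx_a.phat - ctx_b.phat) ** 2
    per = per - _g_correction(ctx_a, variant) - _g_correction(ctx_b, variant)
    return _result("F2", variant, (ctx_a.population, ctx_b.population), per)


def f3(ctx_a: LocusContext, ctx_b: LocusContext, ctx_c: LocusContext,
       variant: str = "hat") -> FStatResult:
    """F3(A;B,C): drift on the branch to target A; only A contributes correction."""
    per = (ctx_a.phat - ctx_b.phat) * (ctx_a.phat - ctx_c.phat)
    per = per - _g_correction(ctx_a, variant)
    pops = (ctx_a.population, ctx_b.population, ctx_c.population)
    return _result("F3", variant, pops, per)


def f3_normalized(ctx_a: LocusContext, ctx_b: LocusContext, ctx_c: LocusContext,
                  variant: str = "hat") -> FStatResult:
    """Normalized F3: ratio of locus means F3(A;B,C) / (2 G(A)), variant-matched."""
    num = f3(ctx_a, ctx_b, ctx_c, variant)
    den = 2.0 * g_stat(ctx_a, variant).estimate
    if den == 0.0:
        raise ZeroDivisionError("normalizing 2 G(A) is zero (all loci fixed in A)")
    pops = (ctx_a.population, ctx_b.population, ctx_c.population)
    return FStatResult("F3_norm", variant, pops, num.estimate / den, None, num.n_loci)


def f4(ctx_a: LocusContext, ctx_b: LocusContext, ctx_c: LocusContext,
       ctx_d: LocusContext) -> FStatResult:
    """F4(A,B;C,D): mean of (a-b)(c-d); unbiased, no correction variants."""
    per = (ctx_a.phat - ctx_b.phat) * (ctx_c.phat - ctx_d.phat)
    pops = (ctx_a.population, ctx_b.population, ctx_c.population, ctx_d.population)
    return _result("F4", "hat", pops, per)


def f4_normalized(ctx_a: LocusContext, ctx_b: LocusContext, ctx_c: LocusContext,
                  ctx_d: LocusContext, normalizing: str, variant: str = "hat") -> FStatResult:
    """Normalized F4: F4(A,B;C,D) / G(P) for a normalizing population P.

    Unlike normalized F3 there is no factor 2 in the denominator.  The
    numerator is always the plug-in F4 (itself unbiased); only the
    denominator G(P) is variant-corrected.
    """
    ctxs = {c.population: c for c in (ctx_a, ctx_b, ctx_c, ctx_d)}
    if normalizing not in ctxs:
        raise ValueError(f"normalizing population {normalizing!r} not among "
                         f"{list(ctxs)}")
    num = f4(ctx_a, ctx_b, ctx_c, ctx_d)
    den = g_stat(ctxs[normalizing], variant).estimate
    if den == 0.0:
        raise ZeroDivisionError("normalizing G(P) is zero")
    pops = (ctx_a.population, ctx_b.population, ctx_c.population, ctx_d.population)
    return FStatResult("F4_norm", variant, pops, num.estimate / den, None, num.n_loci)


def d_stat(ctx_a: LocusContext, ctx_b: LocusContext, ctx_c: LocusContext,
           ctx_d: LocusContext) -> FStatResult:
    """D(A,B,C,D) = -F4(A,B;C,D) / H(A,B,C,D); constrained to [-1, 1]."""
    num = f4(ctx_a, ctx_b, ctx_c, ctx_d)
    den = h_stat(ctx_a, ctx_b, ctx_c, ctx_d)
    if den.estimate == 0.0:
        raise ZeroDivisionError("H(A,B,C,D) is zero")
    pops = (ctx_a.population, ctx_b.population, ctx_c.population, ctx_d.population)
    return FStatResult("D", "hat", pops, -num.estimate / den.estimate, None, num.n_loci)


def dfoil(ctx_a: LocusContext, ctx_b: LocusContext, ctx_c: LocusContext,
          ctx_d: LocusContext) -> dict[str, FStatResult]:
    """The four DFOIL gene-flow-direction ratios on the symmetric topology ((A,B),(C,D)).

    Each is a ratio of locus sums; none multiplies two frequencies sampled
    from the same population, so the plug-in forms are approximately
    unbiased even with related or inbred individuals.
    """
    a, b, c, d = ctx_a.phat, ctx_b.phat, ctx_c.phat, ctx_d.phat
    den_cd = np.sum(c + d - 2 * c * d)
    den_ab = np.sum(a + b - 2 * a * b)
    pops = (ctx_a.population, ctx_b.population, ctx_c.population, ctx_d.population)
    specs = {
        "DFO": (np.sum((1 - 2 * a) * (d - c)), den_cd),
        "DIL": (np.sum((1 - 2 * b) * (d - c)), den_cd),
        "DFI": (np.sum((1 - 2 * c) * (b - a)), den_ab),
        "DOL": (np.sum((1 - 2 * d) * (b - a)), den_ab),
    }
    out = {}
    for name, (num, den) in specs.items():
        if den == 0.0:
            raise ZeroDivisionError(f"zero denominator for {name}")
        out[name] = FStatResult("DFOIL", name, pops, float(num / den), None, len(a))
    return out


def jackknife_se(per_locus_num: np.ndarray, per_locus_den: np.ndarray | None = None,
                 block_size: int = 1, scale: float = 1.0) -> float:
    """Delete-one-block jackknife standard error over contiguous locus blocks.

    For plain (non-ratio) statistics pass the per-locus values.  For ratio
    statistics pass numerator and denominator per-locus arrays; the full
    ratio is recomputed for every deletion.  ``scale`` multiplies the
    statistic (e.g. -1 for D).  SE = sqrt(((B-1)/B) * sum_b (theta_b -
    theta_bar)^2) over B blocks.
    """
    num = np.asarray(per_locus_num, dtype=float)
    j = len(num)
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    bounds = list(range(0, j, block_size))
    nblocks = len(bounds)
    if nblocks < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    den = None if per_locus_den is None else np.asarray(per_locus_den, dtype=float)
    total_num = num.sum()
    total_den = None if den is None else den.sum()
    thetas = np.empty(nblocks)
    for bi, start in enumerate(bounds):
        sl = slice(start, start + block_size)
        keep = j - (min(start + block_size, j) - start)
        if den is None:
            thetas[bi] = scale * (total_num - num[sl].sum()) / keep
        else:
            thetas[bi] = scale * (total_num - num[sl].sum()) / (total_den - den[sl].sum())
    mean = thetas.mean()
    return float(np.sqrt((nblocks - 1) / nblocks * np.sum((thetas - mean) ** 2)))
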