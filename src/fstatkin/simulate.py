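"""Synthetic-data generation: related samples, exact enumeration, and drift.

Three generators live here:

* genotype samples with a specified number of relative pairs, built by the
  identity-by-descent allele-copy procedure — a pair of a given type shares
  zero, one, or two alleles IBD at each locus with probabilities
  (Delta0, Delta1, Delta2); inbred full siblings are instead produced by
  explicit gene dropping through a full-sib-mating pedigree, because the
  Delta-copy construction is only defined for noninbred pairs;
* an exact enumeration oracle that computes expectations of any estimator
  over the full outcome space of small samples (the validator for the
  unbiasedness and bias results);
* a two-population divergence + admixture Wright-Fisher allele-frequency
  simulator (per-locus binomial resampling of 2Ne allele copies), standing
  in for sequence-level forward simulation.

All randomness flows from numpy Generators; helper entry points split a
single seed into per-population / per-replicate streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FrequencyPanel, GenotypeMatrix
from . import estimators as est

__all__ = [
    "RelativePairSpec",
    "RELATIVE_PAIRS",
    "SampleDesign",
    "DemographicModel",
    "draw_unrelated_sample",
    "impose_relative_pair",
    "simulate_phat",
    "enumeration_oracle",
    "population_phat_distribution",
    "wf_simulate",
    "true_fstat",
    "synthetic_divergence_panel",
]


@dataclass(frozen=True)
class RelativePairSpec:
    """One relative-pair type: IBD-sharing probabilities and implied kinship.

    ``delta`` = (Delta0, Delta1, Delta2) is defined over the two *ordered*
    alleles of the pair's genotypes: with probability Delta2 the whole
    genotype of x is copied to y, with probability Delta1 only the first
    allele.  For diploid noninbred pairs the implied kinship is
    Delta2/2 + Delta1/4; haploid and mixed-ploidy (X-linked) pairs follow
    their own allele-sampling arithmetic.
    """

    label: str
    delta: tuple[float, float, float] | None
    implied_phi: float
    inbreeding: tuple[float, float] = (0.0, 0.0)
    ploidy: tuple[int, int] = (2, 2)

    def __post_init__(self) -> None:
        if self.delta is not None and abs(sum(self.delta) - 1.0) > 1e-12:
            raise ValueError("Delta probabilities must sum to 1")

    def delta_implied_phi(self) -> float | None:
        """Kinship implied by the Delta-copy process, by allele-pair counting."""
        if self.delta is None:
            return None
        d0, d1, d2 = self.delta
        mx, my = self.ploidy
        # P(one random allele from x IBD one random allele from y)
        if (mx, my) == (2, 2):
            return d2 / 2.0 + d1 / 4.0
        if (mx, my) == (1, 1):
            return d2 + d1  # a copy of either kind shares the single allele
        if (mx, my) in ((1, 2), (2, 1)):
            return (d2 + d1) / 2.0  # shared allele picked on the diploid side w.p. 1/2
        raise ValueError("unsupported ploidy pair")


RELATIVE_PAIRS: dict[str, RelativePairSpec] = {
    "parent_offspring": RelativePairSpec("parent_offspring", (0.0, 1.0, 0.0), 0.25),
    "full_sibling": RelativePairSpec("full_sibling", (0.25, 0.5, 0.25), 0.25),
    "avuncular": RelativePairSpec("avuncular", (0.5, 0.5, 0.0), 0.125),
    # offspring of a full-sib mating: gene-dropped, not Delta-copied
    "inbred_full_sibling": RelativePairSpec("inbred_full_sibling", None, 0.375,
                                            inbreeding=(0.25, 0.25)),
    # X-linked full siblings (brothers haploid; fathers pass their X to daughters)
    "mm_sibling_x": RelativePairSpec("mm_sibling_x", (0.5, 0.5, 0.0), 0.5, ploidy=(1, 1)),
    "mf_sibling_x": RelativePairSpec("mf_sibling_x", (0.5, 0.5, 0.0), 0.25, ploidy=(1, 2)),
    "ff_sibling_x": RelativePairSpec("ff_sibling_x", (0.0, 0.5, 0.5), 0.375, ploidy=(2, 2)),
}


@dataclass
class SampleDesign:
    """Composition of one population sample: unrelated individuals plus pairs."""

    n_unrelated: int = 0
    pairs: list[RelativePairSpec] = field(default_factory=list)
    unrelated_ploidy: int = 2

    @property
    def sum_m(self) -> int:
        return self.n_unrelated * self.unrelated_ploidy + sum(
            sum(p.ploidy) for p in self.pairs)

    @property
    def n_individuals(self) -> int:
        return self.n_unrelated + 2 * len(self.pairs)

    def phi2(self) -> float:
        """Mean pair kinship under sample-proportion weights.

        Self terms contribute m_x^2 * Phi_xx = m_x (1 + (m_x - 1) f_x);
        each related pair contributes 2 m_x m_y Phi_xy.
        """
        total = float(self.sum_m)  # noninbred self terms sum to sum_m
        for spec in self.pairs:
            fx, fy = spec.inbreeding
            mx, my = spec.ploidy
            total += mx * (mx - 1) * fx + my * (my - 1) * fy
            total += 2.0 * mx * my * spec.implied_phi
        return total / self.sum_m ** 2


@dataclass
class DemographicModel:
    """Two-population divergence followed by admixture founding a third.

    An ancestral frequency is drawn at the split, ``t_split`` generations
    before sampling; the B- and C-lineages drift independently; at
    ``t_admix`` generations before sampling population A is founded with
    frequency alpha * b + (1 - alpha) * c; all three lineages then drift to
    the present.  Drift is per-generation binomial resampling of 2*Ne
    allele copies.
    """

    ne: int = 10_000
    t_split: int = 2000
    t_admix: int = 400
    alpha: float = 0.4
    n_loci: int = 10_000
    init_law: str = "neutral_sfs"  # or "uniform"

    def __post_init__(self) -> None:
        if not self.t_split >= self.t_admix >= 0:
            raise ValueError("need t_split >= t_admix >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# genotype sampling
# ---------------------------------------------------------------------------

def draw_unrelated_sample(freqs: np.ndarray, n: int, ploidy: int = 2,
                          rng: np.random.Generator | int | None = None,
                          population: str = "P") -> GenotypeMatrix:
    """Independent binomial(m, p) dosages for n unrelated individuals."""
    rng = np.random.default_rng(rng)
    freqs = np.asarray(freqs, dtype=float)
    dosages = rng.binomial(ploidy, freqs[:, None], size=(len(freqs), n))
    locus_ids = pd.DataFrame({"chrom": ["syn"] * len(freqs),
                              "pos": np.arange(1, len(freqs) + 1),
                              "ref": "A", "alt": "T"})
    return GenotypeMatrix(population, dosages,
                          np.full_like(dosages, ploidy),
                          np.zeros_like(dosages, dtype=bool),
                          locus_ids, [f"{population}_{i}" for i in range(n)])


def _ordered_alleles(dosages: np.ndarray, ploidy: np.ndarray,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random ordered allele pair consistent with each dosage (exchangeable)."""
    first = np.where(dosages == ploidy, 1, 0)
    het = (dosages == 1) & (ploidy == 2)
    coin = rng.random(dosages.shape) < 0.5
    first = np.where(het, coin.astype(int), first)
    second = np.where(ploidy == 2, dosages - first, 0)
    return first, second


def impose_relative_pair(sample: GenotypeMatrix, x: int, y: int,
                         spec: RelativePairSpec,
                         rng: np.random.Generator | int | None = None) -> GenotypeMatrix:
    """Turn individuals x and y into a relative pair by the IBD-copy procedure.

    Independently at each locus, with probability Delta2 y's genotype is
    replaced by x's, and with probability Delta1 y's first allele is
    replaced by x's first allele.  Genotypes are expanded to ordered
    alleles (uniformly at random given the dosage, which is exchangeable)
    before copying.
    """
    if x == y:
        raise ValueError("x and y must differ")
    if spec.delta is None:
        raise ValueError(f"{spec.label} has no Delta representation; use gene dropping "
                         "(simulate_phat or sib-mating construction)")
    rng = np.random.default_rng(rng)
    mx, my = sample.ploidy[:, x], sample.ploidy[:, y]
    if (mx != spec.ploidy[0]).any() or (my != spec.ploidy[1]).any():
        raise ValueError(f"ploidy of columns {x},{y} does not match spec {spec.label}")
    x1, x2 = _ordered_alleles(sample.dosages[:, x], mx, rng)
    y1, y2 = _ordered_alleles(sample.dosages[:, y], my, rng)
    u = rng.random(sample.n_loci)
    d0, d1, d2 = spec.delta
    copy_both = u < d2
    copy_first = (u >= d2) & (u < d2 + d1)
    new_y1 = np.where(copy_both | copy_first, x1, y1)
    new_y2 = np.where(copy_both & (my == 2), x2, y2)
    dosages = sample.dosages.copy()
    dosages[:, y] = new_y1 + new_y2
    return GenotypeMatrix(sample.population, dosages, sample.ploidy.copy(),
                          sample.missing.copy(), sample.locus_ids, sample.individuals)


def _pair_counts(p: np.ndarray, spec: RelativePairSpec, size: tuple[int, ...],
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized total reference-allele count of one relative pair."""
    if spec.delta is None:  # gene-dropped inbred full siblings
        founders = rng.random(size + (4,)) < p[..., None]
        pick = rng.random(size + (8,)) < 0.5
        s1 = np.stack([np.where(pick[..., 0], founders[..., 0], founders[..., 1]),
                       np.where(pick[..., 1], founders[..., 2], founders[..., 3])], axis=-1)
        s2 = np.stack([np.where(pick[..., 2], founders[..., 0], founders[..., 1]),
                       np.where(pick[..., 3], founders[..., 2], founders[..., 3])], axis=-1)
        y1 = (np.where(pick[..., 4], s1[..., 0], s1[..., 1]).astype(np.int64)
              + np.where(pick[..., 5], s2[..., 0], s2[..., 1]))
        y2 = (np.where(pick[..., 6], s1[..., 0], s1[..., 1]).astype(np.int64)
              + np.where(pick[..., 7], s2[..., 0], s2[..., 1]))
        return y1 + y2
    d0, d1, d2 = spec.delta
    mx, my = spec.ploidy
    x1 = (rng.random(size) < p).astype(np.int64)
    x2 = (rng.random(size) < p).astype(np.int64) if mx == 2 else np.zeros(size, np.int64)
    y1 = (rng.random(size) < p).astype(np.int64)
    y2 = (rng.random(size) < p).astype(np.int64) if my == 2 else np.zeros(size, np.int64)
    u = rng.random(size)
    copy_both = u < d2
    copy_first = (u >= d2) & (u < d2 + d1)
    new_y1 = np.where(copy_both | copy_first, x1, y1)
    new_y2 = np.where(copy_both, x2, y2) if my == 2 else y2
    return x1 + x2 + new_y1 + new_y2


def simulate_phat(freqs: np.ndarray, design: SampleDesign, n_reps: int,
                  rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Sample-proportion frequency estimates for replicated samples.

    Returns an (n_reps, n_loci) array of p-hat for a sample drawn from the
    given true frequencies with the given composition.  This is the
    vectorized Monte-Carlo kernel behind the bias/variance experiments.
    """
    rng = np.random.default_rng(rng)
    p = np.asarray(freqs, dtype=float)
    size = (n_reps, len(p))
    counts = np.zeros(size, dtype=np.int64)
    if design.n_unrelated:
        counts += rng.binomial(design.n_unrelated * design.unrelated_ploidy, p, size=size)
    for spec in design.pairs:
        counts += _pair_counts(p, spec, size, rng)
    return counts / design.sum_m


# ---------------------------------------------------------------------------
# exact enumeration
# ---------------------------------------------------------------------------

def _bern_probs(p: float, alleles: int) -> np.ndarray:
    """Probability of each 0/1 configuration of `alleles` iid Bernoulli(p) draws."""
    probs = np.ones(1)
    for _ in range(alleles):
        probs = np.concatenate([probs * (1 - p), probs * p]).reshape(-1)
    return probs


def _pair_count_pmf(p: float, spec: RelativePairSpec) -> np.ndarray:
    """Exact pmf of the pair's total reference-allele count."""
    if spec.delta is None:
        # gene dropping through a full-sib mating: 4 founder alleles x 8 picks
        pmf = np.zeros(5)
        for fbits in range(16):
            a = [(fbits >> k) & 1 for k in range(4)]
            pf = p ** sum(a) * (1 - p) ** (4 - sum(a))
            for picks in range(256):
                c = [(picks >> k) & 1 for k in range(8)]
                s1 = (a[0] if c[0] else a[1], a[2] if c[1] else a[3])
                s2 = (a[0] if c[2] else a[1], a[2] if c[3] else a[3])
                y1 = (s1[0] if c[4] else s1[1]) + (s2[0] if c[5] else s2[1])
                y2 = (s1[0] if c[6] else s1[1]) + (s2[0] if c[7] else s2[1])
                pmf[y1 + y2] += pf / 256.0
        return pmf
    d0, d1, d2 = spec.delta
    mx, my = spec.ploidy
    pmf = np.zeros(mx + my + 1)
    for xbits in range(2 ** mx):
        xa = [(xbits >> k) & 1 for k in range(mx)]
        px = p ** sum(xa) * (1 - p) ** (mx - sum(xa))
        for ybits in range(2 ** my):
            ya = [(ybits >> k) & 1 for k in range(my)]
            py = p ** sum(ya) * (1 - p) ** (my - sum(ya))
            x1 = xa[0]
            x2 = xa[1] if mx == 2 else 0
            # Delta0: y unchanged; Delta1: first allele copied; Delta2: both
            y_keep = sum(ya)
            y_first = x1 + (ya[1] if my == 2 else 0)
            y_both = x1 + (x2 if my == 2 else 0)
            base = sum(xa)
            w = px * py
            pmf[base + y_keep] += w * d0
            pmf[base + y_first] += w * d1
            pmf[base + y_both] += w * d2
    return pmf


def population_phat_distribution(p: float, design: SampleDesign
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the sample-proportion frequency estimate.

    Returns (values, probabilities) over the full outcome space of the
    generative model (binomial unrelated block convolved with each
    relative-pair block).
    """
    pmf = np.ones(1)
    if design.n_unrelated:
        n_alleles = design.n_unrelated * design.unrelated_ploidy
        pmf = np.convolve(pmf, stats.binom.pmf(np.arange(n_alleles + 1), n_alleles, p))
    for spec in design.pairs:
        pmf = np.convolve(pmf, _pair_count_pmf(p, spec))
    values = np.arange(len(pmf)) / design.sum_m
    return values, pmf


def enumeration_oracle(freqs: dict[str, float], designs: dict[str, SampleDesign],
                       functional: Callable[[dict[str, np.ndarray]], np.ndarray],
                       max_outcomes: int = 2_000_000) -> float:
    """Exact expectation of a per-locus estimator over the sampling model.

    ``functional`` receives a dict mapping population name to an array of
    frequency estimates (one entry per outcome) and must return the
    per-outcome estimator value; the probability-weighted sum is returned.
    Populations are independent, so the joint outcome space is the product
    of the per-population supports.
    """
    pops = list(freqs)
    supports, pmfs = [], []
    for pop in pops:
        v, q = population_phat_distribution(freqs[pop], designs[pop])
        supports.append(v)
        pmfs.append(q)
    total = int(np.prod([len(s) for s in supports]))
    if total > max_outcomes:
        raise ValueError(f"outcome space of size {total} too large for enumeration; "
                         "use Monte Carlo (simulate_phat)")
    grids = np.meshgrid(*supports, indexing="ij")
    prob = np.ones(())
    for q in pmfs:
        prob = np.multiply.outer(prob, q)
    values = functional({pop: g.ravel() for pop, g in zip(pops, grids)})
    return float(np.sum(prob.ravel() * np.asarray(values, dtype=float)))


# ---------------------------------------------------------------------------
# Wright-Fisher divergence + admixture
# ---------------------------------------------------------------------------

def _drift(p: np.ndarray, generations: int, two_ne: int,
           rng: np.random.Generator) -> np.ndarray:
    for _ in range(generations):
        p = rng.binomial(two_ne, p) / two_ne
    return p


def _initial_frequencies(model: DemographicModel, rng: np.random.Generator) -> np.ndarray:
    if model.init_law == "uniform":
        return rng.uniform(0.05, 0.95, size=model.n_loci)
    if model.init_law == "neutral_sfs":
        two_ne = 2 * model.ne
        counts = np.arange(1, two_ne)
        weights = 1.0 / counts
        weights /= weights.sum()
        return rng.choice(counts, size=model.n_loci, p=weights) / two_ne
    raise ValueError(f"unknown init_law {model.init_law!r}")


@dataclass
class WFResult:
    panel: FrequencyPanel
    polymorphic: np.ndarray  # loci segregating in the pooled three-population sample


def wf_simulate(model: DemographicModel,
                rng: np.random.Generator | int | None = None) -> WFResult:
    """Simulate the divergence/admixture model at the allele-frequency level.

    Loci are independent; each starts from the initial frequency law at the
    split, the B- and C-lineages drift for t_split - t_admix generations,
    population A is founded by admixture, and all three lineages drift for
    the final t_admix generations.  Loci fixed for the same allele in all
    three populations at sampling are flagged as non-polymorphic.
    """
    rng = np.random.default_rng(rng)
    two_ne = 2 * model.ne
    p0 = _initial_frequencies(model, rng)
    pre = model.t_split - model.t_admix
    b_mid = _drift(p0, pre, two_ne, rng)
    c_mid = _drift(p0, pre, two_ne, rng)
    a0 = model.alpha * b_mid + (1.0 - model.alpha) * c_mid
    a = _drift(a0, model.t_admix, two_ne, rng)
    b = _drift(b_mid, model.t_admix, two_ne, rng)
    c = _drift(c_mid, model.t_admix, two_ne, rng)
    panel = FrequencyPanel(freq={"A": a, "B": b, "C": c})
    fixed = ((a == 0) & (b == 0) & (c == 0)) | ((a == 1) & (b == 1) & (c == 1))
    return WFResult(panel, ~fixed)


def true_fstat(panel: FrequencyPanel, statistic: str, populations: Sequence[str],
               normalizing: str | None = None) -> float:
    """Population-level (parametric) value of a statistic from true frequencies."""
    ctx = [est.LocusContext(p, panel.freq[p]) for p in populations]
    stat = statistic.lower()
    if stat == "g":
        return est.g_stat(ctx[0], "hat").estimate
    if stat == "f2":
        return est.f2(ctx[0], ctx[1], "hat").estimate
    if stat == "f3":
        return est.f3(ctx[0], ctx[1], ctx[2], "hat").estimate
    if stat == "f3_norm":
        return est.f3_normalized(ctx[0], ctx[1], ctx[2], "hat").estimate
    if stat == "f4":
        return est.f4(*ctx).estimate
    if stat == "f4_norm":
        return est.f4_normalized(*ctx, normalizing=normalizing or populations[0]).estimate
    if stat == "h":
        return est.h_stat(*ctx).estimate
    if stat == "d":
        return est.d_stat(*ctx).estimate
    raise ValueError(f"unknown statistic {statistic!r}")


def synthetic_divergence_panel(n_loci: int, populations: Sequence[str],
                               drift_generations: int = 4000, ne: int = 10_000,
                               rng: np.random.Generator | int | None = None,
                               init_law: str = "uniform") -> FrequencyPanel:
    """Independent-drift frequency panel emulating diverged populations.

    Each population drifts independently from a shared ancestral frequency
    for ``drift_generations`` generations of a 2*Ne-copy Wright-Fisher
    population; loci fixed in any population are replaced by redrawing, so
    every frequency in the panel lies strictly in (0, 1) — the
    ascertainment the theory formulas assume.
    """
    rng = np.random.default_rng(rng)
    two_ne = 2 * ne
    freq = {p: np.empty(n_loci) for p in populations}
    filled = 0
    while filled < n_loci:
        need = n_loci - filled
        model_rng = rng
        if init_law == "uniform":
            p0 = model_rng.uniform(0.05, 0.95, size=need)
        else:
            counts = np.arange(1, two_ne)
            w = (1.0 / counts) / np.sum(1.0 / counts)
            p0 = model_rng.choice(counts, size=need, p=w) / two_ne
        drifted = [_drift(p0, drift_generations, two_ne, model_rng) for _ in populations]
        stacked = np.stack(drifted)
        keep = np.all((stacked > 0) & (stacked < 1), axis=0)
        kept = stacked[:, keep]
        take = min(kept.shape[1], need)
        for arr, pop in zip(kept, populations):
            freq[pop][filled:filled + take] = arr[:take]
        filled += take
    return FrequencyPanel(freq=freq)
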