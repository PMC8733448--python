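"""Closed-form bias, variance and MSE of every estimator variant.

Everything here is driven by the moments of the sample allele-frequency
estimator p-hat under the kinship structure of the sample,

    E[p-hat]   = p
    E[p-hat^2] = p^2 + Phi2 p(1-p)              (exact)
    E[p-hat^3] ~ p^3 + 3 Phi2 p^2(1-p)          (approximate)
    E[p-hat^4] ~ p^4 + 6 Phi2 p^3(1-p)          (approximate)

where Phi2 is the weighted mean pair kinship of the sample at the locus.
The third and fourth moments drop terms involving higher-order kinship
coefficients (trios, quadruples, pairs of pairs) and Phi2^2, which is the
standing assumption that every individual is related to at most one other
individual in its sample.

Bias formulas are evaluated from their closed forms.  Variances are
obtained by exact polynomial expectation of each per-locus estimator under
the moments above (populations independent, loci independent); ratio
statistics use the ratio-of-means delta approximation.  A Monte-Carlo
oracle in the test suite validates these against simulation; because the
underlying moments drop higher-order kinship terms, the theoretical
variances slightly underestimate simulation when such terms are nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import RELATIVE_PAIRS, RelativePairSpec, SampleDesign

__all__ = [
    "ParametricConfig",
    "TheoreticalMoments",
    "BiasComponents",
    "expected_moments",
    "bias",
    "variance",
    "mse",
    "mse_scan",
]

RATIO_STATS = {"f3_norm", "f4_norm", "d"}
SUPPORTED = {
    "g": ("hat", "breve", "tilde"),
    "f2": ("hat", "breve", "tilde"),
    "f3": ("hat", "breve", "tilde"),
    "f3_norm": ("hat", "breve", "tilde"),
    "f4": ("hat",),
    "f4_norm": ("hat", "breve", "tilde"),
    "d": ("hat",),
}
_NPOPS = {"g": 1, "f2": 2, "f3": 3, "f3_norm": 3, "f4": 4, "f4_norm": 4, "d": 4}


def expected_moments(p, phi2):
    """First four moments of p-hat at true frequency p and mean kinship Phi2."""
    p = np.asarray(p, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    q = 1.0 - p
    return (p,
            p ** 2 + phi2 * p * q,
            p ** 3 + 3.0 * phi2 * p ** 2 * q,
            p ** 4 + 6.0 * phi2 * p ** 3 * q)


@dataclass
class ParametricConfig:
    """True frequencies and per-population sample summaries, per locus.

    ``freq`` maps population role (in statistic argument order) to an array
    broadcastable to (..., J); ``phi2`` and ``sum_m`` likewise.  Entries of
    phi2/sum_m may be omitted for populations that never contribute a
    squared frequency (then only hat/f4-type formulas are available).
    """

    freq: dict[str, np.ndarray]
    phi2: dict[str, np.ndarray] = field(default_factory=dict)
    sum_m: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freq = {k: np.asarray(v, dtype=float) for k, v in self.freq.items()}
        self.phi2 = {k: np.asarray(v, dtype=float) for k, v in self.phi2.items()}
        self.sum_m = {k: np.asarray(v, dtype=float) for k, v in self.sum_m.items()}
        for name, p in self.freq.items():
            if (p <= 0).any() or (p >= 1).any():
                raise ValueError(f"theory formulas need frequencies in (0,1); "
                                 f"population {name} violates this")

    @property
    def pops(self) -> list[str]:
        return list(self.freq)

    @property
    def n_loci(self) -> int:
        return np.broadcast_shapes(*(v.shape for v in self.freq.values()))[-1]

    def require(self, pop: str, what: str) -> np.ndarray:
        table = self.phi2 if what == "phi2" else self.sum_m
        if pop not in table:
            raise ValueError(f"config lacks {what} for population {pop}")
        return table[pop]


@dataclass
class TheoreticalMoments:
    statistic: str
    variant: str
    bias: float | np.ndarray
    variance: float | np.ndarray

    @property
    def mse(self):
        return self.variance + np.square(self.bias)


@dataclass
class BiasComponents:
    """The X(P), Y(P) ingredients of the breve ratio-statistic biases."""

    x: float | np.ndarray
    y: float | np.ndarray


# ---------------------------------------------------------------------------
# polynomial expectation engine
# ---------------------------------------------------------------------------
# A per-locus estimator is a polynomial in the independent per-population
# frequency estimates; its expectation factorizes into per-population
# moments.  Polynomials are dicts mapping exponent tuples to coefficients
# (scalars or arrays broadcastable to the locus axis).

def _pmul(p1: dict, p2: dict) -> dict:
    out: dict = {}
    for e1, c1 in p1.items():
        for e2, c2 in p2.items():
            key = tuple(a + b for a, b in zip(e1, e2))
            term = c1 * c2
            out[key] = out.get(key, 0.0) + term
    return out


def _padd(p1: dict, p2: dict, sign: float = 1.0) -> dict:
    out = dict(p1)
    for e, c in p2.items():
        out[e] = out.get(e, 0.0) + sign * c
    return out


def _pexpect(poly: dict, moments: list) -> np.ndarray:
    """E[polynomial] given per-population moment tables [1, E1, E2, E3, E4]."""
    total = 0.0
    for exps, coeff in poly.items():
        term = coeff
        for pop_i, k in enumerate(exps):
            if k:
                term = term * moments[pop_i][k]
        total = total + term
    return total


def _moment_tables(config: ParametricConfig, pops: Sequence[str]) -> list:
    """Per-population moment tables used by the variance engine.

    The second moment is the exact kinship-aware form (sigma^2 = Phi2
    p(1-p)).  Third and fourth moments use a cumulant closure: the
    Gaussian-sum terms (3 sigma^4 in the fourth moment, without which
    squared-frequency variances are underestimated whenever the frequency
    contrast is small) plus the finite-sample skewness/kurtosis of a plain
    allele count, kappa3 = pq(q-p)/S^2 and kappa4 = pq(1-6pq)/S^3 for S
    sampled alleles — both computable without higher-order kinship
    coefficients.  The relative-pair inflation of kappa3/kappa4 is a
    trio/quadruple identity-by-descent quantity and is dropped, consistent
    with treating kinship beyond pairs as negligible; the Monte-Carlo
    comparisons in the test suite bound the resulting error.
    """
    tables = []
    for pop in pops:
        p = config.freq[pop]
        q = 1.0 - p
        phi2 = config.phi2.get(pop)
        if phi2 is None:
            # populations sampled once per locus only ever need E[p-hat^1];
            # fall back to zero-kinship moments (unused beyond power 1)
            phi2 = np.zeros(())
        s = config.sum_m.get(pop)
        if s is None:
            kappa3 = np.zeros(())
            kappa4 = np.zeros(())
        else:
            kappa3 = p * q * (q - p) / s ** 2
            kappa4 = p * q * (1.0 - 6.0 * p * q) / s ** 3
        sigma2 = phi2 * p * q
        m1 = p
        m2 = p ** 2 + sigma2
        m3 = p ** 3 + 3.0 * p * sigma2 + kappa3
        m4 = (p ** 4 + 6.0 * p ** 2 * sigma2 + 3.0 * sigma2 ** 2
              + 4.0 * p * kappa3 + kappa4)
        tables.append([np.ones(()), m1, m2, m3, m4])
    return tables


def _e(npops: int, **powers: int) -> tuple:
    exps = [0] * npops
    for key, val in powers.items():
        exps[int(key[1:])] = val
    return tuple(exps)


def _g_poly(npops: int, i: int, scale) -> dict:
    """scale * (p_i - p_i^2)."""
    return {_e(npops, **{f"p{i}": 1}): scale, _e(npops, **{f"p{i}": 2}): -scale}


def _correction_scale(config: ParametricConfig, pop: str, variant: str):
    if variant == "hat":
        return None
    if variant == "tilde":
        phi2 = config.require(pop, "phi2")
        return phi2 / (1.0 - phi2)
    if variant == "breve":
        return 1.0 / (config.require(pop, "sum_m") - 1.0)
    raise ValueError(f"unknown variant {variant!r}")


def _per_locus_poly(statistic: str, variant: str, config: ParametricConfig,
                    pops: Sequence[str], normalizing: str | None = None):
    """Per-locus polynomial(s) of the estimator; (poly,) or (num, den) for ratios."""
    n = len(pops)
    idx = {pop: i for i, pop in enumerate(pops)}

    def var_poly(i, power=1, coeff=1.0):
        return {_e(n, **{f"p{i}": power}): coeff}

    if statistic == "g":
        if variant == "breve":
            s = config.require(pops[0], "sum_m")
            scale = s / (s - 1.0)
        elif variant == "tilde":
            scale = 1.0 / (1.0 - config.require(pops[0], "phi2"))
        else:
            scale = 1.0
        return (_g_poly(n, 0, scale),)

    if statistic == "f2":
        a, b = 0, 1
        poly = {_e(n, p0=2): 1.0, _e(n, p1=2): 1.0, _e(n, p0=1, p1=1): -2.0}
        for i in (a, b):
            scale = _correction_scale(config, pops[i], variant)
            if scale is not None:
                poly = _padd(poly, _g_poly(n, i, scale), sign=-1.0)
        return (poly,)

    if statistic == "f3":
        poly = {_e(n, p0=2): 1.0, _e(n, p0=1, p1=1): -1.0,
                _e(n, p0=1, p2=1): -1.0, _e(n, p1=1, p2=1): 1.0}
        scale = _correction_scale(config, pops[0], variant)
        if scale is not None:
            poly = _padd(poly, _g_poly(n, 0, scale), sign=-1.0)
        return (poly,)

    if statistic == "f4":
        return ({_e(n, p0=1, p2=1): 1.0, _e(n, p0=1, p3=1): -1.0,
                 _e(n, p1=1, p2=1): -1.0, _e(n, p1=1, p3=1): 1.0},)

    if statistic == "f3_norm":
        (num,) = _per_locus_poly("f3", variant, config, pops)
        (den,) = _per_locus_poly("g", variant,
                                 ParametricConfig({pops[0]: config.freq[pops[0]]},
                                                  {k: v for k, v in config.phi2.items() if k == pops[0]},
                                                  {k: v for k, v in config.sum_m.items() if k == pops[0]}),
                                 (pops[0],))
        den = {_e(n, p0=e[0]): 2.0 * c for e, c in den.items()}
        return (num, den)

    if statistic == "f4_norm":
        (num,) = _per_locus_poly("f4", "hat", config, pops)
        p_i = idx[normalizing]
        sub = ParametricConfig({normalizing: config.freq[normalizing]},
                               {k: v for k, v in config.phi2.items() if k == normalizing},
                               {k: v for k, v in config.sum_m.items() if k == normalizing})
        (den1,) = _per_locus_poly("g", variant, sub, (normalizing,))
        den = {}
        for e, c in den1.items():
            key = [0] * n
            key[p_i] = e[0]
            den[tuple(key)] = c
        return (num, den)

    if statistic == "d":
        (num,) = _per_locus_poly("f4", "hat", config, pops)
        num = {e: -c for e, c in num.items()}
        ab = {_e(n, p0=1): 1.0, _e(n, p1=1): 1.0, _e(n, p0=1, p1=1): -2.0}
        cd = {_e(n, p2=1): 1.0, _e(n, p3=1): 1.0, _e(n, p2=1, p3=1): -2.0}
        return (num, _pmul(ab, cd))

    raise ValueError(f"unknown statistic {statistic!r}")


def _check(statistic: str, variant: str) -> None:
    if statistic not in SUPPORTED:
        raise ValueError(f"unknown statistic {statistic!r}; supported: {sorted(SUPPORTED)}")
    if variant not in SUPPORTED[statistic]:
        raise ValueError(f"variant {variant!r} unsupported for {statistic}; "
                         f"supported: {SUPPORTED[statistic]}")


# ---------------------------------------------------------------------------
# bias (closed forms as printed)
# ---------------------------------------------------------------------------

def _locus_mean(arr, config: ParametricConfig):
    target = np.broadcast_shapes(np.shape(arr),
                                 *(v.shape for v in config.freq.values()))
    return np.broadcast_to(arr, target).mean(axis=-1)


def _g_true(config: ParametricConfig, pop: str):
    p = config.freq[pop]
    return _locus_mean(p * (1.0 - p), config)


def _hat_bias_weight(config, pop):
    return config.require(pop, "phi2")


def _breve_bias_weight(config, pop):
    phi2 = config.require(pop, "phi2")
    s = config.require(pop, "sum_m")
    return (phi2 * s - 1.0) / (s - 1.0)


def bias_components(config: ParametricConfig, pop: str) -> BiasComponents:
    """X(P) and Y(P) of the breve ratio-statistic bias formulas."""
    p = config.freq[pop]
    g = p * (1.0 - p)
    phi2 = config.require(pop, "phi2")
    s = config.require(pop, "sum_m")
    x = _locus_mean((phi2 * s - 1.0) / (s - 1.0) * g, config)
    y = _locus_mean((1.0 - phi2) * s / (s - 1.0) * g, config)
    return BiasComponents(x, y)


def bias(statistic: str, variant: str, config: ParametricConfig,
         normalizing: str | None = None):
    """Closed-form (approximate, for ratio statistics) bias of an estimator.

    Tilde variants are unbiased (exactly for G/F2/F3, approximately for the
    ratio statistics) and return 0; F4 and D are unbiased/approximately
    unbiased in their plug-in forms.
    """
    _check(statistic, variant)
    pops = config.pops
    if len(pops) != _NPOPS[statistic]:
        raise ValueError(f"{statistic} needs {_NPOPS[statistic]} populations, "
                         f"config has {len(pops)}")
    zero = np.zeros(np.broadcast_shapes(*(v.shape for v in config.freq.values()))[:-1])

    if variant == "tilde" and statistic in ("g", "f2", "f3", "f3_norm", "f4_norm"):
        return zero
    if statistic in ("f4", "d"):
        return zero

    if statistic == "g":
        w = _hat_bias_weight(config, pops[0]) if variant == "hat" \
            else _breve_bias_weight(config, pops[0])
        p = config.freq[pops[0]]
        return -_locus_mean(w * p * (1.0 - p), config)

    if statistic in ("f2", "f3"):
        contributing = pops[:2] if statistic == "f2" else pops[:1]
        total = zero
        for pop in contributing:
            w = _hat_bias_weight(config, pop) if variant == "hat" \
                else _breve_bias_weight(config, pop)
            p = config.freq[pop]
            total = total + _locus_mean(w * p * (1.0 - p), config)
        return total

    if statistic == "f3_norm":
        a = pops[0]
        p = config.freq[a]
        g_a = _g_true(config, a)
        f3_true = _locus_mean((config.freq[a] - config.freq[pops[1]])
                              * (config.freq[a] - config.freq[pops[2]]), config)
        f3n_true = f3_true / (2.0 * g_a)
        if variant == "hat":
            t = _locus_mean(config.require(a, "phi2") * p * (1.0 - p), config)
            return t / (g_a - t) * (f3n_true + 0.5)
        comp = bias_components(config, a)
        return 0.5 * (1.0 / comp.y - 1.0 / g_a) * f3_true + comp.x / (2.0 * comp.y)

    if statistic == "f4_norm":
        if normalizing is None:
            normalizing = pops[0]
        p = config.freq[normalizing]
        g_p = _g_true(config, normalizing)
        f4_true = _locus_mean((config.freq[pops[0]] - config.freq[pops[1]])
                              * (config.freq[pops[2]] - config.freq[pops[3]]), config)
        if variant == "hat":
            t = _locus_mean(config.require(normalizing, "phi2") * p * (1.0 - p), config)
            return t / (g_p - t) * (f4_true / g_p)
        comp = bias_components(config, normalizing)
        return (1.0 / comp.y - 1.0 / g_p) * f4_true

    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# variance (moment-engine evaluation)
# ---------------------------------------------------------------------------

def variance(statistic: str, variant: str, config: ParametricConfig,
             normalizing: str | None = None):
    """Approximate sampling variance of the J-locus estimator.

    Per-locus estimators are expanded as polynomials in the independent
    per-population frequency estimates and their second moments evaluated
    under the kinship-aware moment formulas; ratio statistics use the
    delta-method on the ratio of locus means.
    """
    _check(statistic, variant)
    pops = config.pops
    if len(pops) != _NPOPS[statistic]:
        raise ValueError(f"{statistic} needs {_NPOPS[statistic]} populations")
    moments = _moment_tables(config, pops)
    j = config.n_loci
    polys = _per_locus_poly(statistic, variant, config, pops, normalizing)

    def locus_var(poly):
        e1 = _pexpect(poly, moments)
        e2 = _pexpect(_pmul(poly, poly), moments)
        return e2 - e1 ** 2, e1

    if len(polys) == 1:
        v, _ = locus_var(polys[0])
        return np.sum(np.broadcast_to(v, np.broadcast_shapes(np.shape(v), (j,))), axis=-1) / j ** 2

    num, den = polys
    vn, en = locus_var(num)
    vd, ed = locus_var(den)
    cov_l = _pexpect(_pmul(num, den), moments) - en * ed

    def _sum(arr):
        return np.sum(np.broadcast_to(arr, np.broadcast_shapes(np.shape(arr), (j,))), axis=-1)

    mu_n = _sum(en) / j
    mu_d = _sum(ed) / j
    var_n = _sum(vn) / j ** 2
    var_d = _sum(vd) / j ** 2
    cov = _sum(cov_l) / j ** 2
    theta = mu_n / mu_d
    return (var_n - 2.0 * theta * cov + theta ** 2 * var_d) / mu_d ** 2


def mse(statistic: str, variant: str, config: ParametricConfig,
        normalizing: str | None = None) -> TheoreticalMoments:
    """Bias, variance and MSE = variance + bias^2 (tilde MSE equals its variance)."""
    b = bias(statistic, variant, config, normalizing)
    v = variance(statistic, variant, config, normalizing)
    return TheoreticalMoments(statistic, variant, b, v)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def _design_config(freq: dict[str, np.ndarray], phi2_by_pop: dict[str, np.ndarray],
                   sum_m_by_pop: dict[str, np.ndarray]) -> ParametricConfig:
    return ParametricConfig(freq,
                            {k: np.asarray(v, float) for k, v in phi2_by_pop.items()},
                            {k: np.asarray(v, float) for k, v in sum_m_by_pop.items()})


def _pair_design(counts: Sequence[int], types: Sequence[RelativePairSpec]) -> SampleDesign:
    pairs: list[RelativePairSpec] = []
    for cnt, spec in zip(counts, types):
        pairs.extend([spec] * int(cnt))
    return SampleDesign(n_unrelated=0, pairs=pairs)


def mse_scan(mode: str, statistic: str, freq: dict[str, np.ndarray],
             variants: Iterable[str] = ("hat", "breve", "tilde"),
             relative_types: Sequence[str] = ("parent_offspring", "full_sibling", "avuncular"),
             total_pairs: int = 50, max_pairs: int = 50,
             normalizing: str | None = None) -> pd.DataFrame:
    """Theoretical bias/variance/MSE over a grid of sampling conditions.

    ``composition_scan`` enumerates all nonnegative mixtures of three
    relative types summing to ``total_pairs`` (1326 combinations for 50
    pairs); ``sample_size_scan`` varies the number of relative pairs of a
    single type from 1 to ``max_pairs`` with every individual in a pair;
    ``true_value_scan`` expects ``freq`` arrays of shape (n_draws, J) and
    produces one row per draw.  All populations receive the same sample
    composition.
    """
    variants = [v for v in variants if v in SUPPORTED[statistic]]
    specs = [RELATIVE_PAIRS[t] for t in relative_types]
    rows = []

    def eval_point(design: SampleDesign, freqs, extra: dict):
        phi2 = design.phi2()
        s = float(design.sum_m)
        config = _design_config(freqs, {p: phi2 for p in freqs},
                                {p: s for p in freqs})
        row = dict(extra, n_individuals=design.n_individuals, phi2=phi2, sum_m=s)
        for var in variants:
            m = mse(statistic, var, config, normalizing)
            row[f"bias_{var}"] = np.asarray(m.bias).item() if np.ndim(m.bias) == 0 else m.bias
            row[f"var_{var}"] = np.asarray(m.variance).item() if np.ndim(m.variance) == 0 else m.variance
            row[f"mse_{var}"] = row[f"bias_{var}"] ** 2 + row[f"var_{var}"]
        rows.append(row)

    if mode == "composition_scan":
        if len(specs) != 3:
            raise ValueError("composition_scan needs exactly 3 relative types")
        for n1 in range(total_pairs + 1):
            for n2 in range(total_pairs - n1 + 1):
                n3 = total_pairs - n1 - n2
                design = _pair_design((n1, n2, n3), specs)
                eval_point(design, freq, {"n_" + t: c for t, c in
                                          zip(relative_types, (n1, n2, n3))})
    elif mode == "sample_size_scan":
        spec = specs[0]
        for npairs in range(1, max_pairs + 1):
            design = _pair_design((npairs,), (spec,))
            eval_point(design, freq, {"n_pairs": npairs, "relative_type": spec.label})
    elif mode == "true_value_scan":
        first = next(iter(freq.values()))
        if first.ndim != 2:
            raise ValueError("true_value_scan expects freq arrays of shape (n_draws, J)")
        design = _pair_design([total_pairs // len(specs)] * len(specs), specs)
        phi2 = design.phi2()
        s = float(design.sum_m)
        config = _design_config(freq, {p: phi2 for p in freq}, {p: s for p in freq})
        pops = list(freq)
        if statistic == "f2":
            true = ((freq[pops[0]] - freq[pops[1]]) ** 2).mean(axis=-1)
        elif statistic in ("f3", "f3_norm"):
            a, b, c = (freq[p] for p in pops[:3])
            true = ((a - b) * (a - c)).mean(axis=-1)
            if statistic == "f3_norm":
                true = true / (2.0 * (a * (1 - a)).mean(axis=-1))
        elif statistic in ("f4", "f4_norm", "d"):
            a, b, c, d = (freq[p] for p in pops[:4])
            true = ((a - b) * (c - d)).mean(axis=-1)
            if statistic == "f4_norm":
                pnorm = freq[normalizing or pops[0]]
                true = true / (pnorm * (1 - pnorm)).mean(axis=-1)
        else:
            raise ValueError(f"true_value_scan unsupported for {statistic}")
        out = {"true_value": true, "phi2": phi2, "sum_m": s}
        for var in variants:
            m = mse(statistic, var, config, normalizing)
            out[f"bias_{var}"] = np.broadcast_to(m.bias, true.shape)
            out[f"var_{var}"] = np.broadcast_to(m.variance, true.shape)
            out[f"mse_{var}"] = out[f"bias_{var}"] ** 2 + out[f"var_{var}"]
        return pd.DataFrame(out)
    else:
        raise ValueError(f"unknown scan mode {mode!r}")

    if not rows:
        raise ValueError("empty scan grid")
    return pd.DataFrame(rows)
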