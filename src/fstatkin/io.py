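"""Core data containers and readers/writers for the standard file formats.

The estimators in this package consume per-population genotype matrices
(reference-allele dosages with per-entry ploidy), pairwise kinship models,
and per-locus allele-frequency panels.  Genotypes are read from VCF
(biallelic SNPs only), kinship and pedigree information from tab-separated
tables, and results are written as tab-separated reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "KinshipModel",
    "FrequencyPanel",
    "FStatResult",
    "Pedigree",
    "read_vcf",
    "read_kinship_table",
    "write_kinship_table",
    "read_pedigree",
    "read_frequency_table",
    "write_report",
]


def self_kinship_value(m: np.ndarray | int, f: np.ndarray | float) -> np.ndarray | float:
    """Self-kinship Phi_xx = (1/m) * [1 + (m - 1) f] for ploidy m and inbreeding f."""
    m = np.asarray(m, dtype=float)
    f = np.asarray(f, dtype=float)
    out = (1.0 / m) * (1.0 + (m - 1.0) * f)
    return float(out) if out.ndim == 0 else out


@dataclass
class GenotypeMatrix:
    """Reference-allele dosages for one population.

    ``dosages``, ``ploidy`` and ``missing`` are (n_loci, n_individuals)
    arrays.  Dosage counts copies of the VCF REF allele; ploidy is the GT
    arity (1 or 2); missing entries are excluded from all per-locus sums.
    """

    population: str
    dosages: np.ndarray
    ploidy: np.ndarray
    missing: np.ndarray
    locus_ids: pd.DataFrame
    individuals: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int64)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int64)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.dosages.shape != self.ploidy.shape or self.dosages.shape != self.missing.shape:
            raise ValueError("dosages, ploidy and missing must share a shape")
        ok = self.missing | ((self.dosages >= 0) & (self.dosages <= self.ploidy))
        if not ok.all():
            raise ValueError("dosage outside [0, ploidy] at a non-missing entry")
        if not np.isin(self.ploidy, (1, 2)).all():
            raise ValueError("ploidy must be 1 or 2")

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]


@dataclass
class KinshipModel:
    """Pairwise kinship matrix with per-individual inbreeding and ploidy.

    The diagonal is constrained to Phi_xx = (1/m)[1 + (m-1) f]; haploid
    individuals therefore have Phi_xx = 1.  ``locus_class`` separates the
    autosomal model from the X-linked one (kinship differs between them).
    """

    individuals: list[str]
    phi: np.ndarray
    f: np.ndarray
    m: np.ndarray
    locus_class: str = "autosomal"

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.m = np.asarray(self.m, dtype=np.int64)
        n = len(self.individuals)
        if self.phi.shape != (n, n):
            raise ValueError("phi must be square over individuals")
        if not np.allclose(self.phi, self.phi.T):
            raise ValueError("phi must be symmetric")
        if (self.phi < 0).any() or (self.phi > 1).any():
            raise ValueError("kinship coefficients must lie in [0, 1]")
        if (self.f < 0).any() or (self.f > 1).any():
            raise ValueError("inbreeding coefficients must lie in [0, 1]")
        expected = self_kinship_value(self.m, self.f)
        if not np.allclose(np.diag(self.phi), expected, atol=1e-12):
            raise ValueError("diagonal of phi must equal (1/m)[1 + (m-1) f]")
        if self.locus_class not in ("autosomal", "x_linked"):
            raise ValueError("locus_class must be 'autosomal' or 'x_linked'")

    @classmethod
    def unrelated(cls, individuals: Sequence[str], ploidy: int | Sequence[int] = 2,
                  locus_class: str = "autosomal") -> "KinshipModel":
        """Unrelated, noninbred sample: phi is diagonal with Phi_xx = 1/m."""
        n = len(individuals)
        m = np.full(n, ploidy, dtype=np.int64) if np.isscalar(ploidy) else np.asarray(ploidy)
        f = np.zeros(n)
        phi = np.diag(1.0 / m)
        return cls(list(individuals), phi, f, m, locus_class)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {name: i for i, name in enumerate(self.individuals)}
        try:
            return np.array([lookup[i] for i in ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not in kinship model") from exc

    def subset(self, ids: Sequence[str]) -> "KinshipModel":
        idx = self.index_of(ids)
        return KinshipModel(list(ids), self.phi[np.ix_(idx, idx)], self.f[idx],
                            self.m[idx], self.locus_class)


@dataclass
class FrequencyPanel:
    """Per-locus reference-allele frequencies for up to four populations.

    A *parametric* panel carries true population frequencies only.  A panel
    derived from a sample additionally carries, per population and locus,
    the mean pair kinship Phi2(P_j) and the sampled-allele total sum_m.
    """

    freq: dict[str, np.ndarray]
    phi2: dict[str, np.ndarray] = field(default_factory=dict)
    sum_m: dict[str, np.ndarray] = field(default_factory=dict)
    locus_ids: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for pop, p in self.freq.items():
            p = np.asarray(p, dtype=float)
            if (p < 0).any() or (p > 1).any():
                raise ValueError(f"frequencies for {pop} outside [0, 1]")
            self.freq[pop] = p
        lengths = {len(p) for p in self.freq.values()}
        if len(lengths) > 1:
            raise ValueError("all populations must cover the same loci")
        for pop, v in self.phi2.items():
            v = np.asarray(v, dtype=float)
            if (v <= 0).any() or (v > 1).any():
                raise ValueError(f"Phi2 for {pop} must lie in (0, 1]")
            self.phi2[pop] = v

    @property
    def n_loci(self) -> int:
        return len(next(iter(self.freq.values())))

    @property
    def populations(self) -> list[str]:
        return list(self.freq)

    @property
    def parametric(self) -> bool:
        return not self.phi2 and not self.sum_m


@dataclass
class FStatResult:
    """One statistic estimate with its per-locus contributions.

    ``variant`` distinguishes the plug-in (``hat``), finite-sample-corrected
    (``breve``) and relatedness-corrected (``tilde``) estimators.  Ratio
    statistics carry no per-locus decomposition.
    """

    statistic: str
    variant: str
    populations: tuple[str, ...]
    estimate: float
    per_locus: np.ndarray | None
    n_loci: int
    jackknife_se: float | None = None

    def __post_init__(self) -> None:
        if self.per_locus is not None:
            self.per_locus = np.asarray(self.per_locus, dtype=float)
            if not np.isclose(self.estimate, self.per_locus.mean(), atol=1e-12):
                raise ValueError("estimate must equal the mean of per-locus values")
        if self.statistic in ("D", "DFOIL") and not -1.0 - 1e-12 <= self.estimate <= 1.0 + 1e-12:
            raise ValueError(f"{self.statistic} estimate outside [-1, 1]")

    @property
    def z(self) -> float | None:
        if self.jackknife_se is None or self.jackknife_se == 0:
            return None
        return self.estimate / self.jackknife_se


@dataclass
class Pedigree:
    """Parent records (individual, sire, dam, sex) in topological order."""

    individuals: list[str]
    sire: dict[str, str | None]
    dam: dict[str, str | None]
    sex: dict[str, str | None]

    def founders(self) -> list[str]:
        return [i for i in self.individuals
                if self.sire[i] is None and self.dam[i] is None]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, population_map: Mapping[str, str]) -> dict[str, GenotypeMatrix]:
    """Read biallelic SNP genotypes from a VCF into per-population matrices.

    ``population_map`` assigns each VCF sample to a population; every mapped
    individual must be present in the VCF.  Multiallelic and non-SNP records
    are skipped (and counted in the log).  REF is the counted allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing_ids = set(population_map) - set(samples)
    if missing_ids:
        raise ValueError(f"individuals not present in VCF: {sorted(missing_ids)}")

    sample_idx = [samples.index(i) for i in population_map]
    ids = list(population_map)

    rows_dos, rows_plo, rows_mis, loci = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        dos = np.zeros(len(ids), dtype=np.int64)
        plo = np.zeros(len(ids), dtype=np.int64)
        mis = np.zeros(len(ids), dtype=bool)
        for out_i, vcf_i in enumerate(sample_idx):
            gt = var.genotypes[vcf_i]
            alleles = [a for a in gt[:-1] if a is not None]
            plo[out_i] = max(len(alleles), 1)
            if any(a < 0 for a in alleles) or not alleles:
                mis[out_i] = True
            else:
                dos[out_i] = sum(1 for a in alleles if a == 0)
        rows_dos.append(dos)
        rows_plo.append(plo)
        rows_mis.append(mis)
        loci.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not loci:
        raise ValueError("no biallelic SNP records in VCF")

    locus_ids = pd.DataFrame(loci, columns=["chrom", "pos", "ref", "alt"])
    dosages = np.vstack(rows_dos)
    ploidy = np.vstack(rows_plo)
    missing = np.vstack(rows_mis)

    out: dict[str, GenotypeMatrix] = {}
    for pop in dict.fromkeys(population_map.values()):
        cols = [i for i, ind in enumerate(ids) if population_map[ind] == pop]
        out[pop] = GenotypeMatrix(
            population=pop,
            dosages=dosages[:, cols],
            ploidy=ploidy[:, cols],
            missing=missing[:, cols],
            locus_ids=locus_ids,
            individuals=[ids[i] for i in cols],
        )
    return out


def read_kinship_table(path: str | Path, individuals: Sequence[str] | None = None,
                       ploidy: int | Sequence[int] = 2,
                       locus_class: str = "autosomal") -> KinshipModel:
    """Read a pairwise kinship table (columns id1, id2, phi).

    Unlisted pairs default to 0 (unrelated); listed pairs are symmetrized.
    A diagonal row (id1 == id2) overrides the default self-kinship and the
    implied inbreeding coefficient f = (m*phi - 1)/(m - 1) is recorded.
    Defaults: diploid, noninbred, unrelated unless stated.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
    required = {"id1", "id2", "phi"}
    if not required.issubset(df.columns):
        raise ValueError(f"kinship table must have columns {sorted(required)}")
    if ((df["phi"] < 0) | (df["phi"] > 1)).any():
        raise ValueError("kinship coefficients must lie in [0, 1]")

    listed = set(df["id1"]) | set(df["id2"])
    if individuals is None:
        ids = sorted(set(df["id1"]) | set(df["id2"]))
    else:
        ids = list(individuals)
        unknown = listed - set(ids)
        if unknown:
            raise ValueError(f"kinship table names unknown individuals: {sorted(unknown)}")
    n = len(ids)
    m = np.full(n, ploidy, dtype=np.int64) if np.isscalar(ploidy) else np.asarray(ploidy)
    f = np.zeros(n)
    phi = np.diag(self_kinship_value(m, f) * np.ones(n))
    pos = {name: i for i, name in enumerate(ids)}

    seen: dict[tuple[int, int], float] = {}
    for id1, id2, value in df[["id1", "id2", "phi"]].itertuples(index=False):
        i, j = pos[id1], pos[id2]
        key = (min(i, j), max(i, j))
        if key in seen and not np.isclose(seen[key], value, atol=1e-12):
            raise ValueError(f"conflicting duplicate kinship entries for ({id1}, {id2})")
        seen[key] = value
        if i == j:
            if m[i] == 1:
                if not np.isclose(value, 1.0):
                    raise ValueError("haploid self-kinship must be 1")
            else:
                f[i] = (m[i] * value - 1.0) / (m[i] - 1.0)
                if not 0.0 <= f[i] <= 1.0:
                    raise ValueError(f"self-kinship {value} for {id1} implies f outside [0, 1]")
            phi[i, i] = value
        else:
            phi[i, j] = phi[j, i] = value
    return KinshipModel(ids, phi, f, m, locus_class)


def write_kinship_table(model: KinshipModel, path: str | Path) -> None:
    """Write the nonzero off-diagonal and non-default diagonal entries as TSV."""
    rows = []
    default = self_kinship_value(model.m, np.zeros(len(model.individuals)))
    for i, id1 in enumerate(model.individuals):
        if not np.isclose(model.phi[i, i], np.atleast_1d(default)[i]):
            rows.append((id1, id1, model.phi[i, i]))
        for j in range(i + 1, len(model.individuals)):
            if model.phi[i, j] != 0.0:
                rows.append((id1, model.individuals[j], model.phi[i, j]))
    pd.DataFrame(rows, columns=["id1", "id2", "phi"]).to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree TSV (individual, sire, dam[, sex]); missing parent is 0.

    Records may appear in any order; a topological sort over the parent
    graph is applied and cycles (an individual being its own ancestor) are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    cols = list(df.columns)
    if not {"individual", "sire", "dam"}.issubset(cols):
        raise ValueError("pedigree must have columns individual, sire, dam[, sex]")
    sire, dam, sex = {}, {}, {}
    for row in df.itertuples(index=False):
        ind = row.individual
        if ind in sire:
            raise ValueError(f"duplicate pedigree record for {ind}")
        sire[ind] = None if row.sire == "0" else row.sire
        dam[ind] = None if row.dam == "0" else row.dam
        sex[ind] = getattr(row, "sex", None)
        if sex[ind] in ("0", None):
            sex[ind] = None
    # parents referenced but not listed are implicit founders
    for parents in (sire, dam):
        for p in list(parents.values()):
            if p is not None and p not in sire:
                sire[p], dam[p], sex[p] = None, None, None
    order = _toposort(sire, dam)
    return Pedigree(order, sire, dam, sex)


def _toposort(sire: Mapping[str, str | None], dam: Mapping[str, str | None]) -> list[str]:
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(node: str, stack: tuple[str, ...]) -> None:
        if node in stack:
            raise ValueError(f"pedigree cycle involving {node}")
        if state.get(node) == 2:
            return
        state[node] = 1
        for parent in (sire[node], dam[node]):
            if parent is not None:
                visit(parent, stack + (node,))
        state[node] = 2
        order.append(node)

    for node in sire:
        visit(node, ())
    return order


def read_frequency_table(path: str | Path) -> FrequencyPanel:
    """Read a parametric frequency table: locus_id column then one column per population."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("frequency table needs a locus column and >=1 population column")
    locus_col = df.columns[0]
    freq = {pop: df[pop].to_numpy(dtype=float) for pop in df.columns[1:]}
    locus_ids = pd.DataFrame({"locus": df[locus_col]})
    return FrequencyPanel(freq=freq, locus_ids=locus_ids)


def write_frequency_table(panel: FrequencyPanel, path: str | Path) -> None:
    data = {"locus": (panel.locus_ids["locus"] if panel.locus_ids is not None
                      else np.arange(panel.n_loci))}
    data.update({pop: panel.freq[pop] for pop in panel.populations})
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_report(results: Iterable[FStatResult], path: str | Path,
                 header_lines: Sequence[str] = ()) -> None:
    """Write a TSV report: statistic, populations, variant, estimate, SE, Z, n_loci."""
    rows = []
    for r in results:
        se = "NA" if r.jackknife_se is None else repr(float(r.jackknife_se))
        z = "NA" if r.z is None else repr(float(r.z))
        rows.append((r.statistic, ",".join(r.populations), r.variant,
                     repr(float(r.estimate)), se, z, r.n_loci))
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("statistic\tpopulations\tvariant\testimate\tse\tz\tn_loci\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
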