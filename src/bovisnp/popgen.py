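"""Genepop-style validation statistics for biallelic markers.

Implements the exact tests used to validate breed-specific SNPs from
genotype call tables:

* per-breed genotype and allele frequencies;
* Pearson chi-square differentiation of a breeds x (alleles|genotypes)
  contingency table;
* Fisher's exact probability test on allele-count tables: the p-value is
  the total multivariate-hypergeometric mass (margins fixed) of all
  tables whose probability does not exceed the observed table's;
* the exact G test on genotype-count tables: same null distribution, the
  tail is all tables with G = 2 sum o ln(o/e) at least the observed G;
* the Hardy-Weinberg exact test conditional on allele counts, by complete
  enumeration over heterozygote counts of the correct parity, or by a
  Guo-Thompson-style Markov chain;
* Fisher's method for combining independent per-locus p-values.

Enumeration works in exact rational arithmetic so the null mass sums to
exactly 1.  When the enumeration would be too large, a Metropolis Markov
chain over fixed-margin tables is run in batches; the estimate carries a
standard error computed across batch means (dememorisation, batch count
and batch length default to the Genepop conventions: 10,000 / 20 /
5,000).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    GENOTYPES,
    Breed,
    GenotypeTable,
    ValidationError,
)

# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """Breeds x categories count table (categories = alleles or genotypes)."""

    row_labels: tuple
    col_labels: tuple
    counts: tuple  # tuple of row tuples, non-negative ints

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.row_labels):
            raise ValidationError("row count does not match row labels")
        for row in self.counts:
            if len(row) != len(self.col_labels):
                raise ValidationError("column count does not match col labels")
            if any(c < 0 for c in row):
                raise ValidationError("negative count in contingency table")
        if self.total < 1:
            raise ValidationError("contingency table needs a grand total >= 1")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def row_sums(self) -> tuple:
        return tuple(int(sum(row)) for row in self.counts)

    @property
    def col_sums(self) -> tuple:
        return tuple(int(sum(col)) for col in zip(*self.counts))

    @property
    def total(self) -> int:
        return int(sum(self.row_sums))


@dataclass
class McSettings:
    """Markov-chain settings (Genepop defaults); a seed is mandatory."""

    seed: int
    dememorization: int = 10_000
    batches: int = 20
    iterations_per_batch: int = 5_000


@dataclass
class ExactTestResult:
    p_value: float
    method: str                       # 'enumeration' | 'markov_chain'
    statistic: float                  # observed G, or observed table mass
    mc_std_error: Optional[float] = None
    settings: Optional[McSettings] = None

    def __post_init__(self) -> None:
        if (self.mc_std_error is not None) != (self.method == "markov_chain"):
            raise ValidationError(
                "mc_std_error must be present iff method='markov_chain'")


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def genotype_allele_frequencies(table: GenotypeTable) -> dict:
    """Per-breed genotype and allele frequencies.

    The reference-allele frequency is (2 RR + RA) / 2n over non-missing
    calls; a breed with no typed animals is excluded with a warning.
    """
    out: dict = {}
    for breed in table.breeds():
        counts = table.genotype_counts(breed)
        n = sum(counts.values())
        if n == 0:
            warnings.warn(f"{table.marker_id}: breed {breed.value} has no "
                          "typed animals; excluded")
            continue
        freq_r = (2 * counts["RR"] + counts["RA"]) / (2 * n)
        out[breed] = {
            "n": n,
            "genotype_counts": counts,
            "genotype_freqs": {g: counts[g] / n for g in GENOTYPES},
            "allele_freqs": {table.allele_ref: freq_r,
                             table.allele_alt: 1 - freq_r},
        }
    if not out:
        raise ValidationError(f"{table.marker_id}: no typed animals at all")
    return out


def allele_count_table(table: GenotypeTable) -> ContingencyTable:
    rows, labels = [], []
    for breed in table.breeds():
        c = table.genotype_counts(breed)
        if sum(c.values()) == 0:
            continue
        rows.append((2 * c["RR"] + c["RA"], 2 * c["AA"] + c["RA"]))
        labels.append(breed.value)
    return ContingencyTable(tuple(labels),
                            (table.allele_ref, table.allele_alt), tuple(rows))


def genotype_count_table(table: GenotypeTable) -> ContingencyTable:
    rows, labels = [], []
    for breed in table.breeds():
        c = table.genotype_counts(breed)
        if sum(c.values()) == 0:
            continue
        rows.append(tuple(c[g] for g in GENOTYPES))
        labels.append(breed.value)
    return ContingencyTable(tuple(labels), GENOTYPES, tuple(rows))


def marker_is_monomorphic(table: GenotypeTable) -> bool:
    """True when every typed animal in every breed carries the same
    homozygous genotype — such markers carry no information and are
    excluded from differentiation/HWE testing with a report line."""
    seen = {g for _, _, g in table.calls if g != "--"}
    return seen <= {"RR"} or seen <= {"AA"}


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def chi_square_differentiation(table: ContingencyTable):
    """Pearson chi-square on the contingency table, df = (r-1)(c-1).

    Warns when any expected count is below 5 (the exact tests are the
    appropriate tool there).
    """
    m = table.matrix
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("chi-square needs >= 2 rows and >= 2 columns")
    # drop all-zero rows/columns so df matches the attainable table
    m = m[m.sum(axis=1) > 0][:, m.sum(axis=0) > 0]
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValidationError("table is degenerate after removing zero margins")
    stat, p, dof, expected = stats.chi2_contingency(m, correction=False)
    if (expected < 5).any():
        warnings.warn("expected count < 5; prefer the exact tests")
    return float(stat), int(dof), float(p)


# ---------------------------------------------------------------------------
# fixed-margin enumeration (exact rational arithmetic)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _fact(n: int) -> int:
    return math.factorial(n)


def table_probability(rows: tuple, row_sums: tuple, col_sums: tuple,
                      total: int) -> Fraction:
    """Multivariate hypergeometric mass of a table given its margins."""
    num = 1
    for r in row_sums:
        num *= _fact(r)
    for c in col_sums:
        num *= _fact(c)
    den = _fact(total)
    for row in rows:
        for cell in row:
            den *= _fact(cell)
    return Fraction(num, den)


def enumerate_tables(row_sums: Sequence[int], col_sums: Sequence[int],
                     limit: Optional[int] = None):
    """Yield every non-negative integer table with the given margins.

    Raises ``OverflowError`` if more than ``limit`` tables exist.
    """
    row_sums = tuple(row_sums)
    col_sums = list(col_sums)
    n_emitted = 0

    def rows_for(remaining_cols: list, row_total: int):
        # compositions of row_total into len(cols) cells bounded above
        def rec(j: int, left: int, prefix: tuple):
            if j == len(remaining_cols) - 1:
                if left <= remaining_cols[j]:
                    yield prefix + (left,)
                return
            hi = min(left, remaining_cols[j])
            lo = max(0, left - sum(remaining_cols[j + 1:]))
            for v in range(lo, hi + 1):
                yield from rec(j + 1, left - v, prefix + (v,))
        yield from rec(0, row_total, ())

    def fill(i: int, cols_left: list, acc: tuple):
        nonlocal n_emitted
        if i == len(row_sums) - 1:
            if all(c >= 0 for c in cols_left):
                n_emitted += 1
                if limit is not None and n_emitted > limit:
                    raise OverflowError("enumeration limit exceeded")
                yield acc + (tuple(cols_left),)
            return
        for row in rows_for(cols_left, row_sums[i]):
            yield from fill(i + 1,
                            [c - v for c, v in zip(cols_left, row)],
                            acc + (row,))

    yield from fill(0, col_sums, ())


def g_statistic(rows, row_sums, col_sums, total) -> float:
    """G = 2 sum o ln(o / e) with e from the margins; zero cells skipped."""
    g = 0.0
    for i, row in enumerate(rows):
        for j, o in enumerate(row):
            if o > 0:
                e = row_sums[i] * col_sums[j] / total
                g += o * math.log(o / e)
    return 2.0 * g


_DEFAULT_ENUM_LIMIT = 200_000


def fisher_exact_probability(table: ContingencyTable,
                             mc_settings: Optional[McSettings] = None,
                             enumeration_limit: int = _DEFAULT_ENUM_LIMIT
                             ) -> ExactTestResult:
    """Fisher's exact probability test with fixed margins.

    p = total mass of all tables whose hypergeometric probability is <=
    the observed table's.  Exact enumeration when the table space is
    small enough, otherwise a Metropolis Markov chain (settings
    required).
    """
    return _exact_test(table, "probability", mc_settings, enumeration_limit)


def exact_g_test(table: ContingencyTable,
                 mc_settings: Optional[McSettings] = None,
                 enumeration_limit: int = _DEFAULT_ENUM_LIMIT
                 ) -> ExactTestResult:
    """Exact G test: tail = tables with G >= observed G, fixed margins."""
    return _exact_test(table, "g", mc_settings, enumeration_limit)


def _exact_test(table: ContingencyTable, kind: str,
                mc_settings: Optional[McSettings],
                enumeration_limit: int) -> ExactTestResult:
    rs, cs, total = table.row_sums, table.col_sums, table.total
    p_obs = table_probability(table.counts, rs, cs, total)
    g_obs = g_statistic(table.counts, rs, cs, total)
    statistic = g_obs if kind == "g" else float(p_obs)
    try:
        tables = list(enumerate_tables(rs, cs, limit=enumeration_limit))
    except OverflowError:
        if mc_settings is None:
            raise ValidationError(
                "table too large for enumeration; Markov-chain settings "
                "required") from None
        p, se = _contingency_mc(table, kind, g_obs, mc_settings)
        return ExactTestResult(p_value=p, method="markov_chain",
                               statistic=statistic, mc_std_error=se,
                               settings=mc_settings)
    tail = Fraction(0)
    for t in tables:
        pt = table_probability(t, rs, cs, total)
        if kind == "probability":
            if pt <= p_obs:
                tail += pt
        else:
            if g_statistic(t, rs, cs, total) >= g_obs - 1e-12:
                tail += pt
    return ExactTestResult(p_value=float(tail), method="enumeration",
                           statistic=statistic)


def _contingency_mc(table: ContingencyTable, kind: str, g_obs: float,
                    mc: McSettings) -> tuple[float, float]:
    """Metropolis chain over fixed-margin tables via 2x2 swap proposals."""
    rng = np.random.default_rng(mc.seed)
    m = [list(row) for row in table.counts]
    r, c = len(m), len(m[0])
    rs, cs, total = table.row_sums, table.col_sums, table.total

    def log_mass(mat) -> float:
        # log P(table) up to the margin constant, which cancels in all
        # comparisons along the chain
        s = 0.0
        for row in mat:
            for cell in row:
                s += math.lgamma(cell + 1)
        return -s

    obs_extra = log_mass(table.counts)
    cur_extra = obs_extra  # chain starts at the observed table

    def is_extreme(extra: float, mat) -> bool:
        if kind == "probability":
            return extra <= obs_extra + 1e-9
        return g_statistic(mat, rs, cs, total) >= g_obs - 1e-9

    def step():
        nonlocal cur_extra
        i, j = rng.choice(r, size=2, replace=False)
        k, l = rng.choice(c, size=2, replace=False)
        if m[i][l] == 0 or m[j][k] == 0:
            return
        ratio = (m[i][l] * m[j][k]) / ((m[i][k] + 1) * (m[j][l] + 1))
        if ratio >= 1 or rng.random() < ratio:
            m[i][k] += 1
            m[j][l] += 1
            m[i][l] -= 1
            m[j][k] -= 1
            cur_extra = log_mass(m)

    for _ in range(mc.dememorization):
        step()
    batch_means = []
    for _ in range(mc.batches):
        hits = 0
        for _ in range(mc.iterations_per_batch):
            step()
            if is_extreme(cur_extra, m):
                hits += 1
        batch_means.append(hits / mc.iterations_per_batch)
    p = float(np.mean(batch_means))
    se = float(np.std(batch_means, ddof=1) / math.sqrt(mc.batches))
    return p, se


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_heterozygote_distribution(n_r: int, n_a: int) -> dict[int, Fraction]:
    """Exact conditional distribution of the heterozygote count given
    allele counts (n_r reference, n_a alternate alleles; n_r + n_a = 2n).

    P(h) is proportional to n! 2^h / (n_RR! h! n_AA!); heterozygote
    counts share the parity of min(n_r, n_a).
    """
    if (n_r + n_a) % 2:
        raise ValidationError("allele counts must sum to an even number")
    n = (n_r + n_a) // 2
    h_max = min(n_r, n_a)
    masses: dict[int, Fraction] = {}
    for h in range(h_max % 2, h_max + 1, 2):
        n_rr = (n_r - h) // 2
        n_aa = (n_a - h) // 2
        masses[h] = Fraction(_fact(n) * 2**h,
                             _fact(n_rr) * _fact(h) * _fact(n_aa))
    z = sum(masses.values())
    return {h: m / z for h, m in masses.items()}


def hwe_exact_test(n_rr: int, n_ra: int, n_aa: int,
                   method: str = "enumeration",
                   mc_settings: Optional[McSettings] = None
                   ) -> ExactTestResult:
    """Exact test of Hardy-Weinberg proportions conditional on allele
    counts, for a biallelic marker.

    Enumeration sums P(h) over heterozygote counts whose conditional
    probability does not exceed the observed one.  The Markov-chain
    method walks heterozygote states with Metropolis steps (pairing two
    heterozygotes into the two homozygotes and back) and estimates the
    same tail with a batch standard error.
    """
    for name, v in (("n_RR", n_rr), ("n_RA", n_ra), ("n_AA", n_aa)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")
    if n_rr + n_ra + n_aa < 1:
        raise ValidationError("need at least one genotyped animal")
    n_r = 2 * n_rr + n_ra
    n_a = 2 * n_aa + n_ra
    dist = hwe_heterozygote_distribution(n_r, n_a)
    p_obs = dist[n_ra]
    if method == "enumeration":
        tail = sum((m for m in dist.values() if m <= p_obs), Fraction(0))
        return ExactTestResult(p_value=float(tail), method="enumeration",
                               statistic=float(p_obs))
    if method != "markov_chain":
        raise ValueError(f"unknown method {method!r}")
    if mc_settings is None:
        raise ValidationError("markov_chain method requires McSettings")
    extreme = {h for h, m in dist.items() if m <= p_obs}
    rng = np.random.default_rng(mc_settings.seed)
    h = n_ra
    rr, aa = n_rr, n_aa

    def step():
        nonlocal h, rr, aa
        if rng.random() < 0.5:
            if rr == 0 or aa == 0:
                return
            ratio = 4 * rr * aa / ((h + 2) * (h + 1))
            if ratio >= 1 or rng.random() < ratio:
                h += 2
                rr -= 1
                aa -= 1
        else:
            if h < 2:
                return
            ratio = h * (h - 1) / (4 * (rr + 1) * (aa + 1))
            if ratio >= 1 or rng.random() < ratio:
                h -= 2
                rr += 1
                aa += 1

    for _ in range(mc_settings.dememorization):
        step()
    batch_means = []
    for _ in range(mc_settings.batches):
        hits = 0
        for _ in range(mc_settings.iterations_per_batch):
            step()
            if h in extreme:
                hits += 1
        batch_means.append(hits / mc_settings.iterations_per_batch)
    p = float(np.mean(batch_means))
    se = float(np.std(batch_means, ddof=1) / math.sqrt(mc_settings.batches))
    return ExactTestResult(p_value=p, method="markov_chain",
                           statistic=float(p_obs), mc_std_error=se,
                           settings=mc_settings)


# ---------------------------------------------------------------------------
# global combination
# ---------------------------------------------------------------------------

def global_fisher_combine(p_values: Sequence[float],
                          mc_resolution: float = 1e-5) -> float:
    """Fisher's method across independent loci:
    X = -2 sum ln p ~ chi-square with 2k degrees of freedom.

    A p of exactly 0 (possible from a Markov-chain estimate) is clamped
    to the chain resolution with a warning.
    """
    if not p_values:
        raise ValidationError("global_fisher_combine needs >= 1 p-value")
    clean = []
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValidationError(f"p-value out of range: {p}")
        if p == 0:
            warnings.warn(f"p = 0 clamped to MC resolution {mc_resolution}")
            p = mc_resolution
        clean.append(p)
    x = -2.0 * sum(math.log(p) for p in clean)
    return float(stats.chi2.sf(x, df=2 * len(clean)))


# ---------------------------------------------------------------------------
# per-marker orchestration
# ---------------------------------------------------------------------------

def validate_markers(tables: Sequence[GenotypeTable],
                     mc_settings: McSettings) -> dict:
    """Run the full validation battery over a set of markers.

    Markers homozygous in every typed animal are excluded (reported, not
    tested); for the rest: frequencies, chi-square on genotypes, Fisher
    exact probability on alleles, exact G on genotypes and per-breed HWE;
    per-test global p-values combine loci by Fisher's method.
    """
    report: dict = {"excluded_monomorphic": [], "markers": {}}
    allele_ps, genotype_ps = [], []
    for i, table in enumerate(tables):
        if marker_is_monomorphic(table):
            report["excluded_monomorphic"].append(table.marker_id)
            continue
        freqs = genotype_allele_frequencies(table)
        alleles = allele_count_table(table)
        genotypes = genotype_count_table(table)
        mc = McSettings(seed=mc_settings.seed + i,
                        dememorization=mc_settings.dememorization,
                        batches=mc_settings.batches,
                        iterations_per_batch=mc_settings.iterations_per_batch)
        entry: dict = {"frequencies": freqs}
        if len(alleles.row_labels) >= 2:
            chi_stat, dof, chi_p = chi_square_differentiation(genotypes)
            genic = fisher_exact_probability(alleles, mc)
            genotypic = exact_g_test(genotypes, mc)
            entry.update(chi_square={"statistic": chi_stat, "df": dof,
                                     "p": chi_p},
                         genic_differentiation=genic,
                         genotypic_differentiation=genotypic)
            allele_ps.append(genic.p_value)
            genotype_ps.append(genotypic.p_value)
        entry["hwe"] = {
            breed.value: hwe_exact_test(
                f["genotype_counts"]["RR"], f["genotype_counts"]["RA"],
                f["genotype_counts"]["AA"])
            for breed, f in freqs.items()
        }
        report["markers"][table.marker_id] = entry
    if allele_ps:
        report["global"] = {
            "genic_p": global_fisher_combine(allele_ps),
            "genotypic_p": global_fisher_combine(genotype_ps),
        }
    return report
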