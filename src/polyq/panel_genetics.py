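"""Diversity-panel genetics for trinucleotide-repeat loci.

Fragment-analysis machines report amplicon sizes on (nominally) a 3-bp
grid: each extra CAG repeat unit adds one codon to the PCR product.
Observed sizes drift off-grid by sub-unit amounts because of the size
calibration, so alleles are identified by repeat-unit count, obtained by
snapping the size difference from a sequenced reference amplicon to the
nearest whole number of units.

The module covers the downstream genetics: allele-frequency tables per
subpopulation, exact r x c contingency tests of frequency
differentiation (with a seeded Monte Carlo fallback for tables too large
to enumerate), Mendelian consistency of parent-parent-offspring trios
(a child allele absent from both parents signals repeat instability),
and the regression of allelic diversity on repeat length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "LocusDef",
    "ContingencyResult",
    "RegressionResult",
    "AlleleCallError",
    "call_allele",
    "genotype_from_peaks",
    "allele_table",
    "fisher_exact_rxc",
    "mendelian_check",
    "diversity_regression",
]


class AlleleCallError(ValueError):
    """Observed size cannot be reconciled with a valid allele."""


@dataclass(frozen=True)
class LocusDef:
    """Reference calibration of one repeat locus.

    ``reference_amplicon_bp`` is the (sequenced) amplicon size of an
    allele with ``reference_repeat_units`` units; ``unit_bp`` is 3 for
    trinucleotide loci.
    """

    locus_id: str
    reference_amplicon_bp: int
    reference_repeat_units: int
    unit_bp: int = 3

    def __post_init__(self) -> None:
        if min(self.reference_amplicon_bp, self.reference_repeat_units, self.unit_bp) <= 0:
            raise ValueError(f"{self.locus_id}: all locus parameters must be positive")


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def call_allele(
    observed_bp: float, locus: LocusDef, tolerance_bp: float = 1.0
) -> tuple[int, bool]:
    """Convert an observed amplicon size to a repeat-unit count.

    Snaps ``observed - reference`` to the nearest whole number of repeat
    units (half away from zero).  The calibration warning is set when the
    residual off-grid distance exceeds ``tolerance_bp``.
    """
    if observed_bp <= 0:
        raise AlleleCallError(f"{locus.locus_id}: non-positive size {observed_bp}")
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    delta = observed_bp - locus.reference_amplicon_bp
    k = _round_half_away(delta / locus.unit_bp)
    units = locus.reference_repeat_units + k
    warning = abs(delta - locus.unit_bp * k) > tolerance_bp
    if units < 1:
        raise AlleleCallError(
            f"{locus.locus_id}: size {observed_bp} implies {units} repeat units"
        )
    return units, warning


def genotype_from_peaks(
    peaks: Sequence[float], locus: LocusDef, tolerance_bp: float = 1.0
) -> tuple[int, int, bool]:
    """Diploid genotype from 1 or 2 size peaks.

    A single peak is recorded as homozygous (fragment analysis does not
    resolve dosage).  Returns ``(allele1, allele2, warning)`` with
    allele1 <= allele2.
    """
    if not 1 <= len(peaks) <= 2:
        raise AlleleCallError(f"{locus.locus_id}: expected 1-2 peaks, got {len(peaks)}")
    calls = [call_allele(p, locus, tolerance_bp) for p in peaks]
    if len(calls) == 1:
        calls = calls * 2
    (a1, w1), (a2, w2) = calls
    return min(a1, a2), max(a1, a2), w1 or w2


PANEL_COLUMNS = ["animalId", "population", "subtype", "locusId", "allele1Units", "allele2Units"]


def allele_table(
    panel: pd.DataFrame, locus_id: str, group_by: str = "population"
) -> pd.DataFrame:
    """Allele-copy counts (rows: allele units ascending) per group.

    Each diploid animal contributes two copies, so column sums equal
    twice the number of genotyped animals in the group.
    """
    if group_by not in ("population", "subtype"):
        raise ValueError("group_by must be 'population' or 'subtype'")
    sub = panel[panel["locusId"] == locus_id]
    if sub.empty:
        raise ValueError(f"unknown locus {locus_id!r}")
    long = pd.concat(
        [
            sub[[group_by, "allele1Units"]].rename(columns={"allele1Units": "units"}),
            sub[[group_by, "allele2Units"]].rename(columns={"allele2Units": "units"}),
        ]
    )
    table = pd.crosstab(long["units"], long[group_by]).sort_index()
    if (table.sum(axis=0) == 0).any():
        raise ValueError(f"{locus_id}: empty group in allele table")
    table.index.name = "alleleUnits"
    return table


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    p_value: float
    method: str  # "exact" | "montecarlo"
    reps: int
    seed: int | None
    n_tables: int = 0  # tables enumerated (exact only)


def _log_table_prob(table: np.ndarray, logfact_margin: float) -> float:
    return logfact_margin - gammaln(table + 1).sum()


def _enumerate_exact(
    row_margins: np.ndarray, col_margins: np.ndarray, log_p_obs: float, max_tables: int
) -> tuple[float, int]:
    """Two-sided exact p by complete enumeration of fixed-margin tables.

    p = sum of probabilities of all tables no more probable than the
    observed one.  Raises OverflowError past ``max_tables``.
    """
    n = int(row_margins.sum())
    logfact_margin = (
        gammaln(row_margins + 1).sum() + gammaln(col_margins + 1).sum() - gammaln(n + 1)
    )
    r, c = len(row_margins), len(col_margins)
    p_total = 0.0
    count = 0
    table = np.zeros((r, c), dtype=np.int64)
    tol = 1e-7

    def rec(i: int, col_left: np.ndarray) -> None:
        nonlocal p_total, count
        if i == r - 1:
            table[i] = col_left
            count += 1
            if count > max_tables:
                raise OverflowError("too many tables")
            lp = _log_table_prob(table, logfact_margin)
            if lp <= log_p_obs + tol:
                p_total += math.exp(lp)
            return
        # enumerate row i cell by cell
        def fill(j: int, row_left: int) -> None:
            if j == c - 1:
                if row_left <= col_left[j]:
                    table[i, j] = row_left
                    col_left[j] -= row_left
                    rec(i + 1, col_left)
                    col_left[j] += row_left
                return
            # remaining columns after j can absorb at most their margins
            max_other = int(col_left[j + 1 :].sum())
            lo = max(0, row_left - max_other)
            hi = min(row_left, int(col_left[j]))
            for v in range(lo, hi + 1):
                table[i, j] = v
                col_left[j] -= v
                fill(j + 1, row_left - v)
                col_left[j] += v

        fill(0, int(row_margins[i]))

    rec(0, col_margins.astype(np.int64).copy())
    return min(p_total, 1.0), count


def fisher_exact_rxc(
    table: np.ndarray | pd.DataFrame | Sequence[Sequence[int]],
    max_tables: int = 200_000,
    reps: int = 100_000,
    seed: int | None = None,
) -> ContingencyResult:
    """Two-sided Fisher exact test for an r x c contingency table.

    Uses complete enumeration of fixed-margin tables when at most
    ``max_tables`` exist (probability-ordering definition of the
    two-sided p); otherwise a seeded Monte Carlo sample of fixed-margin
    tables with the add-one estimator (k+1)/(reps+1).  All-zero rows and
    columns are trimmed with a warning.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (tab < 0).any():
        raise ValueError("table entries must be nonnegative")
    if tab.sum() == 0:
        raise ValueError("all-zero table")
    keep_r = tab.sum(axis=1) > 0
    keep_c = tab.sum(axis=0) > 0
    if not (keep_r.all() and keep_c.all()):
        warnings.warn("trimming all-zero rows/columns from contingency table")
        tab = tab[keep_r][:, keep_c]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("table must be at least 2x2 after trimming")

    row_m = tab.sum(axis=1)
    col_m = tab.sum(axis=0)
    n = int(tab.sum())
    logfact_margin = gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum() - gammaln(n + 1)
    log_p_obs = _log_table_prob(tab, logfact_margin)

    try:
        p, count = _enumerate_exact(row_m, col_m, log_p_obs, max_tables)
        return ContingencyResult(tab, p, "exact", 0, None, count)
    except OverflowError:
        pass

    if reps < 1:
        raise ValueError("reps must be >= 1 for Monte Carlo")
    rng = np.random.default_rng(seed)
    dist = stats.random_table(row_m, col_m)
    samples = dist.rvs(reps, random_state=rng)
    logp = logfact_margin - gammaln(samples + 1).sum(axis=(1, 2))
    k = int((logp <= log_p_obs + 1e-7).sum())
    return ContingencyResult(tab, (k + 1) / (reps + 1), "montecarlo", reps, seed)


def mendelian_check(
    trios: Iterable[tuple[str, str, str]], panel: pd.DataFrame, locus_id: str
) -> pd.DataFrame:
    """Mendelian consistency of each (sire, dam, child) trio at a locus.

    A trio passes when the child's alleles can be split so one is carried
    by the sire and the other by the dam.  Trios with any ungenotyped
    member are marked ``untested``.
    """
    sub = panel[panel["locusId"] == locus_id]
    geno = {
        r.animalId: (r.allele1Units, r.allele2Units) for r in sub.itertuples()
    }
    rows = []
    for sire, dam, child in trios:
        if any(a not in geno for a in (sire, dam, child)):
            status = "untested"
        else:
            s, d, (c1, c2) = geno[sire], geno[dam], geno[child]
            ok = (c1 in s and c2 in d) or (c2 in s and c1 in d)
            status = "pass" if ok else "fail"
        rows.append({"sire": sire, "dam": dam, "child": child, "locusId": locus_id, "status": status})
    return pd.DataFrame(rows, columns=["sire", "dam", "child", "locusId", "status"])


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    flagged: bool = False  # True when y had zero variance (r set to 0)


def diversity_regression(pairs: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS of allele count on maximum repeat length.

    ``pairs`` are ``(max_repeat_units, allele_count)`` per locus.  With a
    constant response the fit degenerates: slope 0, r reported as 0 by
    convention and the result flagged.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (repeat length, allele count) pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in repeat lengths: slope undefined")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, flagged=True)
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept), float(fit.rvalue))
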