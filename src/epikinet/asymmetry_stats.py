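"""Side-to-side asymmetry indices and the group-level statistics.

The asymmetry index of a parameter measured in homologous regions of the
two hemispheres is::

    ASYM = (contralateral - ipsilateral) * 2 / (contralateral + ipsilateral)

a unitless, scale-invariant quantity in [-2, 2] for nonnegative inputs,
positive when the ipsilateral (focus) side is hypometabolic.  Scale
invariance is what makes an uncalibrated image-derived input function
admissible: any global scaling of the input rescales all fitted parameters
on both sides equally and cancels in ASYM.

Group comparisons use Wilcoxon rank tests: the rank-sum (Mann-Whitney) form
between independent groups, the signed-rank form for paired within-subject
comparisons.  For small samples p-values come from exact enumeration of the
permutation null (midranks under ties); larger samples use the normal
approximation with tie correction.  Inter-parameter association uses
Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AsymRecord",
    "GroupComparison",
    "CorrelationMatrix",
    "UndefinedIndexError",
    "asym_index",
    "control_mean_abs_asym",
    "compare_groups",
    "correlate_asym",
    "holm_correction",
    "PARAMETERS",
]

PARAMETERS = ("K1", "k2", "k3", "Ki", "staticAC")

EXACT_MAX_COMBINED_N = 12


class UndefinedIndexError(ZeroDivisionError):
    """ASYM is undefined when contralateral + ipsilateral == 0."""


def asym_index(contra: float, ipsi: float) -> float:
    """Signed asymmetry index (contra - ipsi)*2/(contra + ipsi)."""
    denom = contra + ipsi
    if denom == 0:
        raise UndefinedIndexError("ASYM undefined: contralateral + ipsilateral == 0")
    return (contra - ipsi) * 2.0 / denom


@dataclass(frozen=True)
class AsymRecord:
    """Per subject x region x parameter asymmetry observation."""

    subject_id: str
    region_id: str
    parameter: str
    ipsi: float
    contra: float

    @property
    def asym(self) -> float:
        return asym_index(self.contra, self.ipsi)

    @property
    def abs_asym(self) -> float:
        return abs(self.asym)

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "region_id": self.region_id,
            "parameter": self.parameter,
            "ipsi": self.ipsi,
            "contra": self.contra,
            "asym": self.asym,
            "abs_asym": self.abs_asym,
        }


def control_mean_abs_asym(records: pd.DataFrame, region_ids) -> pd.Series:
    """Per-parameter mean absolute left/right ASYM over the evaluation regions.

    ``records`` is the long-format table of one control subject with columns
    region_id, parameter, asym (or ipsi/contra).  Every configured region
    must be present; physiological left/right differences enter through the
    absolute value, so their sign cannot cancel.
    """
    region_ids = [str(r) for r in region_ids]
    df = records.copy()
    df["region_id"] = df["region_id"].astype(str)
    missing = set(region_ids) - set(df["region_id"])
    if missing:
        raise ValueError(f"incomplete subject: missing regions {sorted(missing)}")
    df = df[df["region_id"].isin(region_ids)]
    if "asym" not in df.columns:
        df = df.assign(asym=[asym_index(c, i) for c, i in zip(df["contra"], df["ipsi"])])
    return df.assign(abs_asym=df["asym"].abs()).groupby("parameter")["abs_asym"].mean()


# ---------------------------------------------------------------------------
# Wilcoxon rank tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple[str, str]
    means: tuple[float, float]
    test_name: str
    statistic: float
    pvalue: float
    exact: bool
    degenerate: bool = False


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating rank assignments.

    Uses midranks under ties; counts assignments whose U deviates from the
    null centre n1*n2/2 at least as much as the observed U.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    r1_obs = ranks[:n1].sum()
    center = n1 * (len(pooled) + 1) / 2.0  # E[R1]; U dev == R1 dev
    dev_obs = abs(r1_obs - center)
    idx = range(len(pooled))
    count = total = 0
    for subset in combinations(idx, n1):
        total += 1
        if abs(ranks[list(subset)].sum() - center) >= dev_obs - 1e-9:
            count += 1
    u_obs = r1_obs - n1 * (n1 + 1) / 2.0
    return float(u_obs), count / total


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Two-sided exact signed-rank p by enumerating the 2^n sign flips."""
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    center = n * (n + 1) / 4.0
    dev_obs = abs(w_obs - center)
    count = 0
    for bits in range(2 ** n):
        w = sum(ranks[i] for i in range(n) if bits >> i & 1)
        if abs(w - center) >= dev_obs - 1e-9:
            count += 1
    return float(w_obs), count / 2 ** n


def compare_groups(a, b, paired: bool = False) -> GroupComparison:
    """Wilcoxon rank test between two ASYM samples, two-sided.

    Unpaired: rank-sum (Mann-Whitney), exact enumeration when the combined
    sample is small (n <= 12), normal approximation with tie correction
    otherwise.  Paired: signed-rank with the same exact/approximate switch
    on the number of nonzero differences.  Degenerate all-tied samples are
    reported with p = 1 and a flag rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    means = (float(a.mean()), float(b.mean()))

    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        d = a - b
        nz = d[d != 0]
        if len(nz) == 0:
            return GroupComparison(("a", "b"), means, "wilcoxon_signed_rank",
                                   0.0, 1.0, exact=True, degenerate=True)
        if len(nz) <= EXACT_MAX_COMBINED_N:
            stat, p = _exact_signed_rank_p(d)
            return GroupComparison(("a", "b"), means, "wilcoxon_signed_rank",
                                   stat, p, exact=True)
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                             method="approx")
        return GroupComparison(("a", "b"), means, "wilcoxon_signed_rank",
                               float(res.statistic), float(res.pvalue), exact=False)

    if np.all(np.concatenate([a, b]) == np.concatenate([a, b])[0]):
        u = len(a) * len(b) / 2.0
        return GroupComparison(("a", "b"), means, "wilcoxon_rank_sum",
                               u, 1.0, exact=True, degenerate=True)
    if len(a) + len(b) <= EXACT_MAX_COMBINED_N:
        stat, p = _exact_ranksum_p(a, b)
        return GroupComparison(("a", "b"), means, "wilcoxon_rank_sum",
                               stat, p, exact=True)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupComparison(("a", "b"), means, "wilcoxon_rank_sum",
                           float(res.statistic), float(res.pvalue), exact=False)


# ---------------------------------------------------------------------------
# Spearman correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationMatrix:
    parameters: tuple[str, ...]
    rho: pd.DataFrame
    pvalues: pd.DataFrame


def correlate_asym(table: pd.DataFrame, parameters=PARAMETERS) -> CorrelationMatrix:
    """Pairwise Spearman rank correlations of per-subject ASYM values.

    ``table`` has one row per subject and one column per parameter.  Midrank
    tie handling; two-sided p via the t approximation (approximate for small
    n).  A constant column yields an undefined (NaN) correlation for its
    pairs, reported as missing rather than fabricated.
    """
    parameters = tuple(p for p in parameters if p in table.columns)
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 subjects for correlations")
    k = len(parameters)
    rho = np.full((k, k), np.nan)
    pv = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i] = 1.0
        pv[i, i] = 0.0
        for j in range(i + 1, k):
            x = table[parameters[i]].to_numpy(dtype=float)
            y = table[parameters[j]].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue  # undefined, left missing
            r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pv[i, j] = pv[j, i] = p
    idx = list(parameters)
    return CorrelationMatrix(parameters=parameters,
                             rho=pd.DataFrame(rho, index=idx, columns=idx),
                             pvalues=pd.DataFrame(pv, index=idx, columns=idx))


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj
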