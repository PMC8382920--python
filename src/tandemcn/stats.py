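"""Nonparametric group comparisons and correlation structure of copy numbers.

The repeat genes travel as one unit, so their copy-number estimates are not
independent; the comparative layer therefore tests a single representative
gene (5.8S for the 45S/histone block, 5S separately) with rank tests, and
reports the full Pearson matrix as the evidence that the unit moves together.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: combined sample size up to which the exact MWU null is used (no ties)
EXACT_MWU_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str
    group_sizes: tuple[int, ...]
    exact: bool
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def pearson_matrix(cn_values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p-values across gene columns.

    Requires at least three complete rows (lineages) and positive variance in
    every column; p-values come from the t transform of r.
    """
    if cn_values.isna().to_numpy().any():
        raise ValueError("missing copy-number cells; drop or restrict genes first")
    if len(cn_values) < 3:
        raise ValueError("need at least 3 lineages for correlations")
    variances = cn_values.var(axis=0)
    zero_var = variances[variances == 0]
    if len(zero_var):
        raise ValueError(f"zero-variance gene columns: {list(zero_var.index)}")
    genes = list(cn_values.columns)
    r = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
    p = pd.DataFrame(np.zeros((len(genes), len(genes))), index=genes, columns=genes)
    for a, b in combinations(genes, 2):
        res = sps.pearsonr(cn_values[a], cn_values[b])
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) != len(values)


def mwu_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U test; exact null for small tie-free samples.

    The exact distribution (full enumeration over rank assignments) is used
    when the combined sample size is at most 12 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    exact = combined.size <= EXACT_MWU_MAX_N and not _has_ties(combined)
    res = sps.mannwhitneyu(
        a,
        b,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method="mann-whitney-u",
        group_sizes=(a.size, b.size),
        exact=exact,
    )


def kw_test(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction; chi-squared reference.

    When every observation is identical the statistic is undefined; the test
    degenerates to p = 1 with an explanatory note rather than an error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    sizes = tuple(a.size for a in arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=0.0,
            pvalue=1.0,
            method="kruskal-wallis",
            group_sizes=sizes,
            exact=False,
            note="all observations identical; H undefined, p set to 1",
        )
    res = sps.kruskal(*arrays)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method="kruskal-wallis",
        group_sizes=sizes,
        exact=False,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


def compare_modes(
    cn_values: pd.DataFrame,
    metadata: pd.DataFrame,
    genes: Sequence[str] = ("5.8S", "5S"),
) -> pd.DataFrame:
    """The standard comparison battery on a copy-number table.

    For each representative gene: MWU sexual vs asexual, and KW across ploidy
    levels; BH adjustment is applied within the family of KW tests, as the
    rank tests on the two reproductive modes are reported raw.
    """
    meta = metadata.set_index("lineage").loc[cn_values.index]
    rows = []
    kw_ps = []
    for gene in genes:
        col = cn_values[gene].dropna()
        mode = meta.loc[col.index, "mode"]
        sexual = col[mode == "sexual"]
        asexual = col[mode == "asexual"]
        if len(sexual) and len(asexual):
            res = mwu_test(sexual, asexual)
            rows.append(
                {
                    "test": f"MWU:{gene}:sexual-vs-asexual",
                    "statistic": res.statistic,
                    "pvalue": res.pvalue,
                    "exact": res.exact,
                    "family": "mwu",
                }
            )
        ploidy = meta.loc[col.index, "ploidy"]
        levels = sorted(ploidy.unique())
        if len(levels) >= 2:
            res = kw_test([col[ploidy == lv].to_numpy() for lv in levels])
            rows.append(
                {
                    "test": f"KW:{gene}:across-ploidy",
                    "statistic": res.statistic,
                    "pvalue": res.pvalue,
                    "exact": False,
                    "family": "kw",
                }
            )
            kw_ps.append(len(rows) - 1)
    out = pd.DataFrame(rows)
    out["pvalue_adj"] = out["pvalue"]
    if kw_ps:
        out.loc[kw_ps, "pvalue_adj"] = bh_adjust(out.loc[kw_ps, "pvalue"].to_numpy())
    return out
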