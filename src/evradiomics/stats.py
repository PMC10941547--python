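"""Nonparametric association tests run per treatment arm.

The battery mirrors the analysis plan of the combined biomarker study:
Kruskal-Wallis of the model score across PR/SD/PD response categories,
Mann-Whitney U of tumor change (%) between high- and low-score patients,
and chi-square tests of the dichotomized score and of tissue PD-L1
positivity (TPS >= 1%) against durable response.  p-values are unadjusted
(a Benjamini-Hochberg flag is available but off by default), matching the
reporting convention of small exploratory cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .model import CombinedModel, score as model_score

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "mann_whitney",
    "chi_square",
    "run_association_suite",
]

logger = logging.getLogger(__name__)

EXACT_MW_MAX_N = 20
TPS_POSITIVE_THRESHOLD = 1.0


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value out of [0,1]: {self.p_value}")


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with the chi-square approximation.

    All observations identical is a degenerate (no-evidence) case reported
    as H = 0, p = 1.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    samples = [s for s in samples if s.size > 0]
    if len(samples) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 non-empty groups")
    sizes = tuple(int(s.size) for s in samples)
    if np.ptp(values) == 0:
        return TestResult("kruskal_wallis", 0.0, 1.0, sizes, note="all values identical")
    H, p = sps.kruskal(*samples)
    return TestResult("kruskal_wallis", float(H), float(p), sizes)


def mann_whitney(values_a: Sequence[float], values_b: Sequence[float],
                 exact_max_n: int = EXACT_MW_MAX_N) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration when the combined sample is small (n_a + n_b <=
    ``exact_max_n``) and tie-free; otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue),
                      (int(a.size), int(b.size)), note=method)


def chi_square(table: np.ndarray, yates: bool = False) -> TestResult:
    """Pearson chi-square on a contingency table (no continuity correction
    by default).  Warns through the note field when any expected count < 5."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(np.float64)
        if np.any(table < 0) or np.any(table != np.floor(table)):
            raise ValidationError("contingency table must hold nonnegative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("contingency table has a zero margin")
    stat, p, _, expected = sps.chi2_contingency(table, correction=yates)
    note = "expected count < 5" if np.any(expected < 5) else ""
    return TestResult("chi_square", float(stat), float(p),
                      tuple(int(v) for v in table.sum(axis=1)), note=note)


def _bh_adjust(results: pd.DataFrame) -> pd.DataFrame:
    ok = results["p_value"].notna()
    adj = np.full(len(results), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(results.loc[ok, "p_value"], method="fdr_bh")[1]
    results = results.copy()
    results["p_adjusted"] = adj
    return results

def run_association_suite(records: pd.DataFrame, model: CombinedModel | None = None,
                          score_col: str = "score",
                          tps_threshold: float = TPS_POSITIVE_THRESHOLD,
                          arms: Sequence[str] = ("ICI", "chemo"),
                          adjust: bool = False) -> pd.DataFrame:
    """Run the per-arm association battery on a scored cohort.

    ``records`` needs columns ``arm``, ``response_category``,
    ``durable_responder``, ``tumor_change_pct``, ``tissue_pdl1_tps`` and
    either a precomputed ``score_col`` or a fitted ``model`` (whose inputs
    must then be present).  Tests whose group structure is degenerate in an
    arm (a single response category, one empty score class, a zero margin)
    are skipped with a logged reason and reported with NaN statistics.
    """
    records = records.copy()
    if score_col not in records.columns:
        if model is None:
            raise ValidationError(f"no {score_col!r} column and no model provided")
        records[score_col] = model_score(model, records)
    if model is not None:
        cutoff = model.cutoff
    else:
        cutoff = float(np.median(records[score_col]))
    records["_high"] = records[score_col] >= cutoff

    rows = []

    def _skip(arm, name, reason):
        logger.info("%s arm %s: skipped (%s)", arm, name, reason)
        rows.append({"arm": arm, "test": name, "statistic": np.nan, "p_value": np.nan,
                     "group_sizes": (), "note": f"skipped: {reason}"})

    def _add(arm, name, result: TestResult):
        rows.append({"arm": arm, "test": name, "statistic": result.statistic,
                     "p_value": result.p_value, "group_sizes": result.group_sizes,
                     "note": result.note})

    for arm in arms:
        sub = records[records["arm"] == arm]
        if sub.empty:
            _skip(arm, "all", "no patients in arm")
            continue

        cats = sub["response_category"].unique()
        if len(cats) >= 2:
            _add(arm, "score_vs_response_category",
                 kruskal_wallis(sub[score_col], sub["response_category"]))
        else:
            _skip(arm, "score_vs_response_category", "single response category")

        hi = sub.loc[sub["_high"], "tumor_change_pct"]
        lo = sub.loc[~sub["_high"], "tumor_change_pct"]
        if len(hi) and len(lo):
            _add(arm, "tumor_change_vs_high_score", mann_whitney(hi, lo))
        else:
            _skip(arm, "tumor_change_vs_high_score", "one score class empty")

        resp = sub["durable_responder"].astype(bool)
        for name, flag in (("high_score_vs_response", sub["_high"]),
                           ("tps_positive_vs_response",
                            sub["tissue_pdl1_tps"] >= tps_threshold)):
            table = np.array([
                [int((flag & ~resp).sum()), int((flag & resp).sum())],
                [int((~flag & ~resp).sum()), int((~flag & resp).sum())],
            ])
            if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
                _add(arm, name, chi_square(table))
            else:
                _skip(arm, name, "zero margin in 2x2 table")

    out = pd.DataFrame(rows)
    if adjust:
        out = _bh_adjust(out)
    return out
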