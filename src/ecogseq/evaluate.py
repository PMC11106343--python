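"""Token error rate and the paired statistics used to compare conditions.

TER = 100 * (S + D + I) / N over a minimum-edit-distance alignment of the
hypothesis against the reference token sequence (unit costs), where N is the
reference token count.  Start/end markers are never scored, so N = 3 for this
corpus; insertions can push TER above 100%.

Condition comparisons use the one-sided Wilcoxon signed-rank test (exact
null distribution at these sample sizes, zero differences dropped) with
Holm-Bonferroni correction over the family of comparisons (default m = 6),
and Cohen's d as the effect size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .train import DecodeResult


@dataclass(frozen=True)
class TEREntry:
    substitutions: int
    deletions: int
    insertions: int
    n_tokens: int  # reference length

    @property
    def n_errors(self) -> int:
        return self.substitutions + self.deletions + self.insertions

    @property
    def ter(self) -> float:
        return 100.0 * self.n_errors / self.n_tokens


def ter(reference: Sequence[int], hypothesis: Sequence[int]) -> TEREntry:
    """Levenshtein alignment with unit costs; counts S, D, I by backtrace.

    Ties are resolved preferring substitution/match, then deletion, then
    insertion; the total S+D+I is the unique minimum edit distance either way.
    """
    ref = list(reference)
    hyp = list(hypothesis)
    if not ref:
        raise ValueError("reference must be non-empty")
    n, m = len(ref), len(hyp)
    d = np.zeros((n + 1, m + 1), dtype=np.int64)
    d[:, 0] = np.arange(n + 1)
    d[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = d[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1])
            d[i, j] = min(sub, d[i - 1, j] + 1, d[i, j - 1] + 1)
    i, j = n, m
    s = dele = ins = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and d[i, j] == d[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]):
            s += ref[i - 1] != hyp[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and d[i, j] == d[i - 1, j] + 1:
            dele += 1
            i -= 1
        else:
            ins += 1
            j -= 1
    return TEREntry(substitutions=int(s), deletions=int(dele), insertions=int(ins),
                    n_tokens=n)


def results_table(results: Sequence[DecodeResult]) -> pd.DataFrame:
    """Tidy per-result table: one row per decoded segment with S/D/I/TER."""
    rows = []
    for r in results:
        e = ter(r.reference, r.hypothesis)
        rows.append({
            "fold": r.fold, "repeat": r.repeat, "trial": r.trial, "task": r.task,
            "reference": " ".join(map(str, r.reference)),
            "hypothesis": " ".join(map(str, r.hypothesis)),
            "S": e.substitutions, "D": e.deletions, "I": e.insertions,
            "n_tok": e.n_tokens, "ter": e.ter,
        })
    return pd.DataFrame(rows)


def aggregate(results: Sequence[DecodeResult]) -> dict:
    """Mean TER across all decode results, with per-fold breakdown."""
    if not results:
        raise ValueError("no results to aggregate")
    df = results_table(results)
    return {
        "mean_ter": float(df.ter.mean()),
        "sd_ter": float(df.ter.std(ddof=1)) if len(df) > 1 else 0.0,
        "n_results": int(len(df)),
        "per_fold": {int(k): float(v) for k, v in df.groupby("fold").ter.mean().items()},
    }


@dataclass
class ComparisonResult:
    label: str
    p_value: float  # one-sided Wilcoxon signed-rank, H1: b < a
    p_adjusted: float  # Holm-Bonferroni over m comparisons
    cohens_d: float
    n: int
    m_comparisons: int


def wilcoxon_one_sided(a: np.ndarray, b: np.ndarray) -> float:
    """P-value for H1 'b is smaller than a' (i.e. condition b outperforms a,
    TERs being errors).  Exact distribution; zero differences dropped."""
    diff = np.asarray(a, float) - np.asarray(b, float)
    if np.all(diff == 0):
        raise ValueError("all paired differences are zero; test is degenerate")
    res = stats.wilcoxon(a, b, alternative="greater", zero_method="wilcox",
                         method="exact" if len(diff) <= 25 else "auto")
    return float(res.pvalue)


def cohens_d(a: np.ndarray, b: np.ndarray, paired: bool = False) -> float:
    """Pooled-SD Cohen's d by default; ``paired`` uses mean(diff)/sd(diff)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        diff = a - b
        return float(diff.mean() / diff.std(ddof=1))
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    return float((a.mean() - b.mean()) / pooled)


def compare(comparisons: dict[str, tuple[np.ndarray, np.ndarray]],
            m: int = 6, paired_d: bool = False) -> list[ComparisonResult]:
    """Run the family of paired one-sided comparisons with Holm correction.

    Each entry maps a label to paired per-unit TER vectors (a, b); the tested
    hypothesis is that b outperforms (is lower than) a.  ``m`` sets the
    correction family size; when larger than the number of comparisons given,
    the extra slots count as p = 1 placeholders (conservative).
    """
    labels = list(comparisons)
    raw = []
    ds = []
    for label in labels:
        a, b = comparisons[label]
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.shape != b.shape:
            raise ValueError(f"{label}: paired vectors differ in length")
        raw.append(wilcoxon_one_sided(a, b))
        ds.append(cohens_d(a, b, paired=paired_d))
    pad = max(0, m - len(labels))
    adj = multipletests(raw + [1.0] * pad, method="holm")[1][: len(labels)]
    return [
        ComparisonResult(label=lbl, p_value=p, p_adjusted=float(min(pa, 1.0)),
                         cohens_d=d, n=len(comparisons[lbl][0]), m_comparisons=m)
        for lbl, p, pa, d in zip(labels, raw, adj, ds)
    ]
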