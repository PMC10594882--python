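"""Comparison statistics: sensitivity with binomial confidence intervals,
positive rate, and two-sided Fisher exact tests on 2x2 tables.

The Fisher test uses the probability-mass two-sided rule (sum over all tables
with the same margins whose hypergeometric probability does not exceed the
observed table's), which is the common exact-test convention.  The confidence
interval method is configurable (Wilson score by default, Clopper-Pearson as
the alternative); no single method reproduces every published interval, so
neither is asserted as canonical.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.proportion import proportion_confint

from .filtering import CohortResult, FilterDecision

#: Relative slack when comparing table probabilities to the observed one
#: (same convention as R's fisher.test, guards against FP round-off).
_REL_ERR = 1e-7

CI_METHODS = {"wilson": "wilson", "clopper_pearson": "beta"}


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows are pipelines, columns retained / not retained."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table must have at least one positive margin")

    @property
    def counts(self) -> Tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclasses.dataclass(frozen=True)
class SensitivityResult:
    retained: int
    total: int
    estimate: float
    ci_low: float
    ci_high: float
    ci_method: str

    @property
    def percent(self) -> float:
        return 100.0 * self.estimate


def fisher_exact_two_sided(table: Union[ContingencyTable, Sequence[Sequence[int]]]) -> float:
    """Exact conditional two-sided p-value for a 2x2 table.

    Degenerate margins (an all-zero row or column) give p = 1.0.
    """
    if not isinstance(table, ContingencyTable):
        (a, b), (c, d) = table
        table = ContingencyTable(a, b, c, d)
    a, b, c, d = table.counts
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    selected = pmf <= p_obs * (1 + _REL_ERR)
    if selected.all():
        return 1.0
    return min(1.0, float(pmf[selected].sum()))


def _retained_keys(decisions: Union[CohortResult, Iterable[FilterDecision]]) -> Set[str]:
    if isinstance(decisions, CohortResult):
        decisions = decisions.decisions
    return {d.variant_key for d in decisions if d.retained}


def sensitivity_from_counts(
    retained: int, total: int, ci_method: str = "wilson", alpha: float = 0.05
) -> SensitivityResult:
    if total <= 0:
        raise ValueError("sensitivity requires a non-empty truth set")
    if not 0 <= retained <= total:
        raise ValueError("retained must lie in [0, total]")
    if ci_method not in CI_METHODS:
        raise ValueError(f"ci_method must be one of {sorted(CI_METHODS)}")
    low, high = proportion_confint(retained, total, alpha=alpha, method=CI_METHODS[ci_method])
    estimate = retained / total
    # guard against numerical dust from the interval routine at the boundaries
    low = min(max(float(low), 0.0), estimate)
    high = max(min(float(high), 1.0), estimate)
    return SensitivityResult(
        retained=retained,
        total=total,
        estimate=estimate,
        ci_low=low,
        ci_high=high,
        ci_method=ci_method,
    )


def sensitivity(
    decisions: Union[CohortResult, Iterable[FilterDecision]],
    truth: Iterable[str],
    ci_method: str = "wilson",
    alpha: float = 0.05,
) -> SensitivityResult:
    """Fraction of gold-positive variant keys retained, with a CI."""
    truth_keys = set(truth)
    if not truth_keys:
        raise ValueError("sensitivity requires a non-empty truth set")
    retained = len(truth_keys & _retained_keys(decisions))
    return sensitivity_from_counts(retained, len(truth_keys), ci_method=ci_method, alpha=alpha)


def positive_rate(result: Union[CohortResult, Iterable[FilterDecision]]) -> int:
    """Number of unique variant keys retained."""
    return len(_retained_keys(result))


def compare_pipelines(
    results: Mapping[str, CohortResult],
    truth: Optional[Iterable[str]] = None,
    ci_method: str = "wilson",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pipeline retention summary plus pairwise Fisher exact p-values.

    With ``truth`` given, the pairwise tables compare retained gold positives
    out of the truth set; otherwise they compare positive rates out of each
    pipeline's considered variants.
    """
    if len(results) < 2:
        raise ValueError("compare_pipelines requires at least two pipelines")
    truth_keys = set(truth) if truth is not None else None
    names = sorted(results)
    rows = []
    table_args: Dict[str, Tuple[int, int]] = {}
    for name in names:
        result = results[name]
        retained_all = positive_rate(result)
        row = {
            "pipeline": name,
            "considered": result.unique_variants_considered,
            "retained": retained_all,
        }
        if truth_keys is not None:
            sens = sensitivity(result, truth_keys, ci_method=ci_method)
            row.update(
                sensitivity=sens.estimate, ci_low=sens.ci_low, ci_high=sens.ci_high
            )
            table_args[name] = (sens.retained, sens.total - sens.retained)
        else:
            table_args[name] = (retained_all, result.unique_variants_considered - retained_all)
        rows.append(row)
    pairwise = [
        {
            "pipeline_a": a,
            "pipeline_b": b,
            "p_fisher": fisher_exact_two_sided(
                ContingencyTable(*table_args[a], *table_args[b])
            ),
        }
        for a, b in itertools.combinations(names, 2)
    ]
    return pd.DataFrame(rows), pd.DataFrame(pairwise)


def round_sig(p: float, digits: int = 2) -> float:
    """Round to significant figures for display (full precision kept upstream)."""
    if p == 0:
        return 0.0
    from math import floor, log10

    return round(p, -int(floor(log10(abs(p)))) + digits - 1)
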