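"""Assay-level call rates, run metrics and statistical comparisons.

Covers the evaluation layer of the pipeline: sex-aware call rates, the
dynamic "top-N best-covered SNPs" call rate used to put shallow shotgun
data on a comparable footing with targeted assays, run-level sequencing
metrics, an ordinary-least-squares screen of which sequencing parameters
drive SNP yield, and a one-way ANOVA with Tukey HSD post-hoc for
between-assay call-rate differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .calling import CallSet, CallingThresholds, classify_sites, _NO_CALL
from .concordance import round_half_up
from .panel import Panel

logger = logging.getLogger(__name__)

METRICS_COLUMNS = ["sample_id", "total_reads", "human_reads",
                   "duplicate_reads", "on_target_reads", "n_markers"]


@dataclass
class CallRateResult:
    """Typed markers over targetable markers, as a percent."""

    sample_id: str
    n_typed: int
    n_targetable: int

    def __post_init__(self) -> None:
        if self.n_targetable < 1:
            raise ValueError("n_targetable must be >= 1")
        if not 0 <= self.n_typed <= self.n_targetable:
            raise ValueError("n_typed must lie in [0, n_targetable]")

    @property
    def rate(self) -> float:
        return 100.0 * self.n_typed / self.n_targetable

    def rate_reported(self, ndigits: int = 1) -> float:
        return round_half_up(self.rate, ndigits)

    @classmethod
    def from_counts(cls, n_typed: int, n_targetable: int,
                    sample_id: str = "sample") -> "CallRateResult":
        return cls(sample_id, n_typed, n_targetable)


def call_rate(callset: CallSet, panel: Panel, sex: str = "unknown") -> CallRateResult:
    """Call rate with a sex-adjusted denominator.

    Females cannot be typed at Y markers, so those leave the denominator;
    unknown sex keeps the full panel (conservative) with a logged warning.
    """
    if sex == "unknown":
        logger.warning(
            "sample %s: sex unknown; using the full panel (incl. Y) as "
            "call-rate denominator", callset.sample_id)
    n_targetable = panel.targetable_count(sex)
    return CallRateResult(callset.sample_id, callset.n_typed, n_targetable)


def dynamic_top_n_call_rate(reads: pd.DataFrame,
                            thresholds: CallingThresholds | None = None,
                            n: int = 5000,
                            sample_id: str = "sample") -> CallRateResult:
    """Call rate over the ``n`` best-covered SNPs, with ``n`` as denominator.

    The per-sample top-``n`` markers by total read count (ties broken by
    marker_id) are called with the diploid threshold rules; the denominator
    stays ``n`` even when fewer markers have any coverage, so shallow
    samples are not flattered.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    thresholds = thresholds or CallingThresholds()
    tab = reads.assign(
        depth=reads["n_ref"] + reads["n_alt"] + reads["n_other"]
    ).sort_values(["depth", "marker_id"], ascending=[False, True],
                  kind="mergesort").head(n)
    call, _ = classify_sites(tab["n_ref"], tab["n_alt"], tab["n_other"],
                             tab["n_fwd"], tab["n_rev"], tab["mean_q"],
                             thresholds, np.zeros(len(tab), dtype=bool))
    n_typed = int((call != _NO_CALL).sum())
    return CallRateResult(sample_id, n_typed, n)


@dataclass
class RunMetrics:
    """Run-level sequencing summary for one sample."""

    sample_id: str
    total_reads: int
    proportion_human: float
    proportion_on_target: float
    proportion_duplicates: float
    mean_coverage: float

    def __post_init__(self) -> None:
        for prop in (self.proportion_human, self.proportion_on_target,
                     self.proportion_duplicates):
            if not 0.0 <= prop <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")


def summarize_run(record: Mapping[str, float] | pd.Series) -> RunMetrics:
    """Derive proportions from a bookkeeping row.

    ``proportion_human`` is human/total reads; duplicates and on-target
    are fractions of the human reads; ``mean_coverage`` is unique
    on-target reads per panel marker.
    """
    record = dict(record)
    missing = [c for c in METRICS_COLUMNS if c not in record]
    if missing:
        raise ValueError(f"metrics record missing fields: {missing}")
    total = float(record["total_reads"])
    human = float(record["human_reads"])
    on_target = float(record["on_target_reads"])
    dup = float(record["duplicate_reads"])
    markers = float(record["n_markers"])
    return RunMetrics(
        sample_id=str(record["sample_id"]),
        total_reads=int(total),
        proportion_human=human / total if total else 0.0,
        proportion_on_target=on_target / human if human else 0.0,
        proportion_duplicates=dup / human if human else 0.0,
        mean_coverage=on_target / markers if markers else 0.0,
    )


@dataclass
class ComparisonStats:
    """Outputs of the regression and/or ANOVA comparison stages."""

    regression: pd.DataFrame | None = None   # coef, p_value per predictor
    anova_p: float | None = None
    tukey: pd.DataFrame | None = None        # group_a, group_b, mean_diff, p_adj


def regress_called_snps(metrics: pd.DataFrame,
                        n_called: Sequence[float] | pd.Series) -> ComparisonStats:
    """OLS of per-sample SNP yield on sequencing predictors.

    All columns of ``metrics`` enter as predictors with an intercept;
    per-coefficient p-values are two-sided t-tests.  A rank-deficient
    design is rejected with advice rather than silently pseudo-inverted.
    """
    y = np.asarray(n_called, dtype=float)
    X = metrics.astype(float)
    if len(X) < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} samples for {X.shape[1]} predictors")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; remove collinear predictors")
    fit = sm.OLS(y, design).fit()
    table = pd.DataFrame({"coef": fit.params, "p_value": fit.pvalues})
    table = table.drop(index="const")
    return ComparisonStats(regression=table)


def compare_call_rates(groups: Mapping[str, Sequence[float]]) -> ComparisonStats:
    """One-way ANOVA across assays plus Tukey HSD pairwise post-hoc.

    Tukey uses the studentized-range distribution in its Tukey-Kramer form,
    valid for unequal group sizes.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
    anova_p = float(stats.f_oneway(*arrays.values()).pvalue)
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * arrays[k].size for k in arrays])
    res = pairwise_tukeyhsd(values, labels)
    tukey = pd.DataFrame({
        "group_a": res.groupsunique[res._multicomp.pairindices[0]],
        "group_b": res.groupsunique[res._multicomp.pairindices[1]],
        "mean_diff": res.meandiffs,
        "p_adj": res.pvalues,
    })
    return ComparisonStats(anova_p=anova_p, tukey=tukey)
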