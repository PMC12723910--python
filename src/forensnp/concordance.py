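"""Pairwise genotype concordance, discordance classes and truth accuracy.

"Typed" always means the call is not a no-call; only markers typed in both
call sets enter a comparison.  A discordant diploid pair is either a
*false homozygote* (one call heterozygous, the other homozygous - the
signature of allele drop-in/drop-out in low-template data) or a
*contradictory homozygote* (opposite homozygotes).  Haploid calls compare
against diploid ones through their allele: hap_ref matches hom_ref,
hap_alt matches hom_alt, and a haploid call against a heterozygote counts
as a false homozygote.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import CallSet

#: allele-equivalence class used for concordance (ploidy-blind)
_ALLELE_CLASS = {"hom_ref": 0, "hap_ref": 0, "het": 1, "hom_alt": 2, "hap_alt": 2}

#: ploidy-aware expected dosage used for accuracy against latent truth
_TRUTH_DOSAGE = {"hom_ref": 0, "het": 1, "hom_alt": 2, "hap_ref": 0, "hap_alt": 1}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used for reported rates."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConcordanceResult:
    """Agreement between two call sets over their typed overlap."""

    n_overlap: int
    n_concordant: int
    n_false_homozygote: int
    n_contradictory_homozygote: int
    y_excluded: bool = False
    sample_a: str = ""
    sample_b: str = ""

    def __post_init__(self) -> None:
        if self.n_concordant + self.n_false_homozygote + \
                self.n_contradictory_homozygote != self.n_overlap:
            raise ValueError("discordance classes must partition the overlap")

    @property
    def n_discordant(self) -> int:
        return self.n_false_homozygote + self.n_contradictory_homozygote

    @property
    def rate(self) -> float | None:
        """Concordance percent at full precision; None when no overlap."""
        if self.n_overlap == 0:
            return None
        return 100.0 * self.n_concordant / self.n_overlap

    @property
    def rate_reported(self) -> float | None:
        """Concordance percent rounded half-up to one decimal."""
        return None if self.rate is None else round_half_up(self.rate, 1)

    @classmethod
    def from_counts(cls, n_overlap: int, n_concordant: int,
                    n_false_homozygote: int | None = None,
                    n_contradictory_homozygote: int = 0,
                    **kw) -> "ConcordanceResult":
        """Build a result from summary counts (discordance defaults to the
        false-homozygote class, the dominant error mode)."""
        if n_false_homozygote is None:
            n_false_homozygote = (n_overlap - n_concordant
                                  - n_contradictory_homozygote)
        return cls(n_overlap, n_concordant, n_false_homozygote,
                   n_contradictory_homozygote, **kw)


def compare_callsets(a: CallSet, b: CallSet,
                     exclude_y: bool = False) -> ConcordanceResult:
    """Concordance of two call sets over markers typed in both.

    With ``exclude_y`` the haploid Y markers - identical for all
    male-line relatives and therefore concordance-inflating - are dropped
    from the overlap before counting.
    """
    shared = a.calls.index.intersection(b.calls.index)
    if len(shared) == 0:
        raise ValueError(
            f"call sets {a.sample_id!r} and {b.sample_id!r} share no markers")
    ca = a.calls.loc[shared, "call"].to_numpy()
    cb = b.calls.loc[shared, "call"].to_numpy()
    keep = (ca != "no_call") & (cb != "no_call")
    if exclude_y:
        y_ids = set(a.panel.frame.loc[a.panel.is_y, "marker_id"]) | \
            set(b.panel.frame.loc[b.panel.is_y, "marker_id"])
        if y_ids:
            keep &= ~np.asarray(shared.isin(y_ids))
    ga = pd.Series(ca[keep]).map(_ALLELE_CLASS).to_numpy()
    gb = pd.Series(cb[keep]).map(_ALLELE_CLASS).to_numpy()
    concordant = int((ga == gb).sum())
    het_involved = int((((ga == 1) | (gb == 1)) & (ga != gb)).sum())
    contradictory = int((np.abs(ga - gb) == 2).sum())
    return ConcordanceResult(
        n_overlap=int(keep.sum()), n_concordant=concordant,
        n_false_homozygote=het_involved,
        n_contradictory_homozygote=contradictory,
        y_excluded=exclude_y, sample_a=a.sample_id, sample_b=b.sample_id)


def pairwise_concordance_matrix(callsets: Sequence[CallSet],
                                exclude_y: bool = False) -> pd.DataFrame:
    """Concordance for every unordered pair of call sets."""
    if len(callsets) < 2:
        raise ValueError("need at least 2 call sets")
    rows = []
    for a, b in combinations(callsets, 2):
        r = compare_callsets(a, b, exclude_y=exclude_y)
        rows.append((r.sample_a, r.sample_b, r.n_overlap, r.n_concordant,
                     r.n_false_homozygote, r.n_contradictory_homozygote,
                     r.rate, r.rate_reported))
    return pd.DataFrame(rows, columns=[
        "sample_a", "sample_b", "n_overlap", "n_concordant",
        "n_false_homozygote", "n_contradictory_homozygote",
        "rate", "rate_reported"])


@dataclass
class AccuracyResult:
    """Agreement of a call set with a reference truth genotype map."""

    sample_id: str
    n_typed: int
    n_correct: int
    n_not_in_reference: int = 0

    @property
    def accuracy(self) -> float | None:
        if self.n_typed == 0:
            return None
        return 100.0 * self.n_correct / self.n_typed

    @property
    def accuracy_reported(self) -> float | None:
        return None if self.accuracy is None else round_half_up(self.accuracy, 1)


def accuracy_vs_reference(calls: CallSet,
                          reference: Mapping[str, int] | pd.Series) -> AccuracyResult:
    """Genotype accuracy against a reference dosage map.

    Typed markers absent from the reference are excluded from the
    denominator and counted separately.  Zero evaluable markers give a
    not-available (None) accuracy rather than an error.
    """
    ref = pd.Series(reference, dtype="float")
    typed = calls.calls[calls.calls["call"] != "no_call"]
    in_ref = typed.index.intersection(ref.index)
    n_outside = len(typed) - len(in_ref)
    if len(in_ref) == 0:
        return AccuracyResult(calls.sample_id, 0, 0, n_outside)
    expected = ref.loc[in_ref].to_numpy()
    observed = typed.loc[in_ref, "call"].map(_TRUTH_DOSAGE).to_numpy()
    n_correct = int((observed == expected).sum())
    return AccuracyResult(calls.sample_id, len(in_ref), n_correct, n_outside)


@dataclass
class PooledDiscordance:
    """Discordance pooled over many comparisons (counts, then division)."""

    n_discordant: int
    n_overlap: int

    @property
    def percent(self) -> float | None:
        if self.n_overlap == 0:
            return None
        return 100.0 * self.n_discordant / self.n_overlap

    @property
    def percent_reported(self) -> float | None:
        return None if self.percent is None else round_half_up(self.percent, 1)


def aggregate_discordance(results: Iterable[ConcordanceResult]) -> PooledDiscordance:
    """Pool discordant and overlap counts before dividing.

    This is the correct pooled rate and in general differs from the mean
    of per-pair rates.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one concordance result")
    return PooledDiscordance(
        n_discordant=sum(r.n_discordant for r in results),
        n_overlap=sum(r.n_overlap for r in results))
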