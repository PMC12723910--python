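"""Direct-match likelihood ratios from per-allele read depths.

For two samples the hypotheses are

* H1 - the samples originate from the same donor,
* H2 - the samples originate from two different, unrelated donors.

No genotypes are called first.  At each autosomal SNP with population
alternate-allele frequency ``p`` the genotype likelihood of dosage ``g``
given ``a`` alternate reads out of ``n = n_ref + n_alt`` is the binomial
kernel ``q^a (1-q)^(n-a)`` with alt-read probability

    q(0) = eps,   q(1) = 1/2,   q(2) = 1 - eps,

``eps`` being the effective per-read error.  With Hardy-Weinberg priors
``pi(g)`` the per-SNP likelihood ratio factorises as

    LR = sum_g pi(g) La(g) Lb(g)
         / ( [sum_g pi(g) La(g)] [sum_g pi(g) Lb(g)] )

and a site with no informative read in either sample contributes exactly
LR = 1.  SNPs are treated as unlinked and their log contributions summed;
binomial coefficients are omitted throughout since they cancel within
every per-SNP ratio (individual likelihood values are therefore comparable
only within a site).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .calling import SiteReadData
from .panel import Panel

MATCH = "match"
NO_MATCH = "no_match"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class ErrorModel:
    """Per-read error settings for the genotype likelihoods.

    ``sample_error_factor`` multiplies the base sequencing/mapping error to
    absorb sample-specific noise (degradation, mapping artifacts); the
    effective error is capped below 0.5.  Allele frequencies are clamped to
    ``[freq_floor, 1 - freq_floor]`` so monomorphic markers cannot produce
    infinite penalties.
    """

    base_error: float = 0.01
    sample_error_factor: float = 2.0
    freq_floor: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.base_error < 0.5:
            raise ValueError("base_error must lie in (0, 0.5)")
        if self.sample_error_factor < 1.0:
            raise ValueError("sample_error_factor must be >= 1")
        if not 0.0 < self.freq_floor < 0.5:
            raise ValueError("freq_floor must lie in (0, 0.5)")

    @property
    def effective_error(self) -> float:
        return min(self.base_error * self.sample_error_factor, 0.49)

    def clamp_freq(self, p):
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        return np.clip(p, self.freq_floor, 1.0 - self.freq_floor)


@dataclass(frozen=True)
class MatchRules:
    """Classification thresholds for a pairwise comparison."""

    min_snps: int = 150
    ln_lr_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.min_snps < 0:
            raise ValueError("min_snps must be >= 0")
        if self.ln_lr_threshold < 0:
            raise ValueError("ln_lr_threshold must be >= 0")


@dataclass
class MatchResult:
    sample_a: str
    sample_b: str
    ln_lr: float
    n_snps_used: int
    classification: str
    per_snp: Mapping[str, float] | None = None


def _log_genotype_likelihoods(n_alt: np.ndarray, n: np.ndarray,
                              eps: float) -> np.ndarray:
    """(3, m) log-likelihood table for dosages 0, 1, 2 (coefficient-free)."""
    q = np.array([eps, 0.5, 1.0 - eps])[:, None]
    return n_alt[None, :] * np.log(q) + (n - n_alt)[None, :] * np.log1p(-q)


def genotype_likelihood(site: SiteReadData, g: int, err: ErrorModel) -> float:
    """Unnormalised likelihood of dosage ``g`` for one site.

    Flat (equal to 1) when the site has no informative read.
    """
    if g not in (0, 1, 2):
        raise ValueError("dosage must be 0, 1 or 2")
    n = site.n_ref + site.n_alt
    logl = _log_genotype_likelihoods(np.array([site.n_alt], dtype=float),
                                     np.array([n], dtype=float),
                                     err.effective_error)
    return float(np.exp(logl[g, 0]))


def per_snp_ln_lr_array(alt_a, n_a, alt_b, n_b, p, err: ErrorModel) -> np.ndarray:
    """Vectorised per-SNP ln(LR) over marker arrays.

    Entirely in log space (log-sum-exp over the three genotypes), so the
    result stays finite at any depth - opposite homozygotes at depth
    hundreds would underflow in linear arithmetic.
    """
    alt_a = np.asarray(alt_a, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    alt_b = np.asarray(alt_b, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    p = err.clamp_freq(np.broadcast_to(np.asarray(p, dtype=float), n_a.shape))
    eps = err.effective_error

    log_pi = np.stack([2.0 * np.log1p(-p),
                       np.log(2.0 * p * (1.0 - p)),
                       2.0 * np.log(p)])
    la = _log_genotype_likelihoods(alt_a, n_a, eps)
    lb = _log_genotype_likelihoods(alt_b, n_b, eps)
    ln_num = logsumexp(log_pi + la + lb, axis=0)
    ln_den = logsumexp(log_pi + la, axis=0) + logsumexp(log_pi + lb, axis=0)
    ln_lr = ln_num - ln_den
    ln_lr[(n_a == 0) | (n_b == 0)] = 0.0
    return ln_lr


def per_snp_lr_array(alt_a, n_a, alt_b, n_b, p, err: ErrorModel) -> np.ndarray:
    """Per-SNP LR on the natural scale (exactly 1 at uncovered sites)."""
    return np.exp(per_snp_ln_lr_array(alt_a, n_a, alt_b, n_b, p, err))


def per_snp_lr(site_a: SiteReadData, site_b: SiteReadData, p: float,
               err: ErrorModel) -> float:
    """LR contribution of one SNP for a sample pair."""
    return float(per_snp_lr_array(
        [site_a.n_alt], [site_a.n_ref + site_a.n_alt],
        [site_b.n_alt], [site_b.n_ref + site_b.n_alt], [p], err)[0])


def select_snps(reads: pd.DataFrame, panel: Panel, n_select: int) -> list[str]:
    """Pick the autosomal SNPs with the highest total read count.

    ``reads`` is a long multi-sample table (``sample_id`` column).  Only
    autosomal markers with a defined alt frequency are eligible; ranking is
    by summed read count across all samples, descending, ties broken
    lexicographically by marker_id.  Returns at most ``n_select`` ids.
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    eligible = panel.frame.loc[
        panel.is_autosomal & np.isfinite(panel.alt_freq), "marker_id"]
    if eligible.empty:
        raise ValueError("panel has no autosomal markers with allele frequencies")
    depth = reads.assign(
        depth=reads["n_ref"] + reads["n_alt"] + reads["n_other"]
    ).groupby("marker_id", sort=False)["depth"].sum()
    depth = depth.reindex(eligible, fill_value=0)
    order = depth.reset_index().sort_values(
        ["depth", "marker_id"], ascending=[False, True], kind="mergesort")
    return order["marker_id"].head(n_select).tolist()


def _aligned_counts(reads: pd.DataFrame, marker_ids: Sequence[str],
                    label: str) -> tuple[np.ndarray, np.ndarray]:
    tab = reads.set_index("marker_id")
    missing = pd.Index(marker_ids).difference(tab.index)
    if len(missing):
        raise KeyError(
            f"{len(missing)} selected marker(s) missing from read table "
            f"{label!r}: {list(missing[:5])}"
        )
    tab = tab.loc[list(marker_ids)]
    return (tab["n_alt"].to_numpy(dtype=float),
            (tab["n_ref"] + tab["n_alt"]).to_numpy(dtype=float))


def direct_match(reads_a: pd.DataFrame, reads_b: pd.DataFrame, panel: Panel,
                 markers: Sequence[str] | None = None,
                 err: ErrorModel | None = None,
                 rules: MatchRules | None = None,
                 sample_a: str = "A", sample_b: str = "B",
                 keep_per_snp: bool = False) -> MatchResult:
    """Total ln(LR) of H1 (same donor) vs H2 (unrelated) for one pair.

    ``markers`` defaults to every autosomal panel marker.  A comparison is
    inconclusive when fewer than ``rules.min_snps`` markers carry at least
    one informative read in both samples, or when |ln LR| falls below the
    configured threshold; otherwise the sign of ln LR decides.
    """
    err = err or ErrorModel()
    rules = rules or MatchRules()
    if markers is None:
        markers = panel.frame.loc[panel.is_autosomal, "marker_id"].tolist()
    markers = list(markers)
    sub = panel.subset(markers)
    freq = sub.frame.set_index("marker_id").loc[markers, "alt_freq"].to_numpy()
    alt_a, n_a = _aligned_counts(reads_a, markers, sample_a)
    alt_b, n_b = _aligned_counts(reads_b, markers, sample_b)

    ln_contrib = per_snp_ln_lr_array(alt_a, n_a, alt_b, n_b, freq, err)
    ln_lr = float(ln_contrib.sum())
    used = int(((n_a > 0) & (n_b > 0)).sum())
    if used < rules.min_snps or abs(ln_lr) < rules.ln_lr_threshold:
        cls = INCONCLUSIVE
    else:
        cls = MATCH if ln_lr > 0 else NO_MATCH
    per_snp = dict(zip(markers, ln_contrib)) if keep_per_snp else None
    return MatchResult(sample_a, sample_b, ln_lr, used, cls, per_snp)


def pairwise_match_matrix(reads: Mapping[str, pd.DataFrame] | pd.DataFrame,
                          panel: Panel,
                          markers: Sequence[str] | None = None,
                          err: ErrorModel | None = None,
                          rules: MatchRules | None = None) -> pd.DataFrame:
    """Direct-match results for every unordered sample pair.

    ``reads`` is either a mapping sample_id -> per-sample table or a long
    table with a ``sample_id`` column.  Returns one row per pair with
    columns sample_a, sample_b, ln_lr, n_snps_used, classification; the
    implied ln(LR) matrix is symmetric by construction.
    """
    err = err or ErrorModel()
    rules = rules or MatchRules()
    if isinstance(reads, pd.DataFrame):
        reads = {sid: tab.drop(columns=["sample_id"])
                 for sid, tab in reads.groupby("sample_id", sort=False)}
    ids = list(reads)
    if len(ids) < 2:
        raise ValueError("pairwise matching needs at least 2 samples")
    if markers is None:
        markers = panel.frame.loc[panel.is_autosomal, "marker_id"].tolist()
    markers = list(markers)
    sub = panel.subset(markers)
    freq = sub.frame.set_index("marker_id").loc[markers, "alt_freq"].to_numpy()

    aligned = {sid: _aligned_counts(tab, markers, sid)
               for sid, tab in reads.items()}
    rows = []
    for a, b in itertools.combinations(ids, 2):
        alt_a, n_a = aligned[a]
        alt_b, n_b = aligned[b]
        ln_lr = float(per_snp_ln_lr_array(alt_a, n_a, alt_b, n_b, freq, err).sum())
        used = int(((n_a > 0) & (n_b > 0)).sum())
        if used < rules.min_snps or abs(ln_lr) < rules.ln_lr_threshold:
            cls = INCONCLUSIVE
        else:
            cls = MATCH if ln_lr > 0 else NO_MATCH
        rows.append((a, b, ln_lr, used, cls))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "ln_lr", "n_snps_used",
                       "classification"])
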