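"""Threshold-based genotype calling from per-site read counts.

Calls are made by a fixed cascade of hard filters followed by an
allelic-balance decision:

1. depth ``d = n_ref + n_alt`` below ``min_depth``        -> no_call(low_depth)
2. mean Phred below ``min_quality``                       -> no_call(low_quality)
3. other-base fraction ``n_other / (d + n_other)`` above
   ``max_other_fraction``                                 -> no_call(excess_other)
4. at depth >= ``strand_check_min_depth``, minority-strand
   fraction below ``strand_min_fraction``                 -> no_call(strand_imbalance)
5. allelic balance ``ab = n_alt / d``:
   diploid   ab <= hom_ab_max            -> hom_ref
             ab >= 1 - hom_ab_max        -> hom_alt
             het_ab_low <= ab <= het_ab_high -> het
             otherwise                   -> no_call(ambiguous_balance)
   haploid   ab <= hom_ab_max -> hap_ref; ab >= 1 - hom_ab_max -> hap_alt;
             otherwise no_call(ambiguous_balance)

The gap between ``hom_ab_max`` and ``het_ab_low`` deliberately yields a
no-call rather than a forced genotype: in low-template typing an
intermediate balance is exactly where allele drop-in/drop-out lives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import Panel

DIPLOID = "diploid"
HAPLOID = "haploid"

CALLS = ["hom_ref", "het", "hom_alt", "hap_ref", "hap_alt", "no_call"]
NO_CALL_REASONS = [
    "none", "low_depth", "low_quality", "strand_imbalance",
    "ambiguous_balance", "excess_other", "wrong_ploidy", "replicate_discordant",
]

# integer codes used by the vectorised classifier
_HOM_REF, _HET, _HOM_ALT, _HAP_REF, _HAP_ALT, _NO_CALL = range(6)
_CALL_NAMES = np.array(CALLS)
_REASON_NAMES = np.array(NO_CALL_REASONS)
(_R_NONE, _R_DEPTH, _R_QUAL, _R_STRAND, _R_AB, _R_OTHER, _R_PLOIDY,
 _R_REPDISC) = range(8)

#: call -> alt-allele dosage, ploidy-aware (used for truth comparisons)
CALL_DOSAGE = {"hom_ref": 0, "het": 1, "hom_alt": 2, "hap_ref": 0, "hap_alt": 1}


@dataclass(frozen=True)
class CallingThresholds:
    """Hard-filter settings for the threshold caller.

    Defaults follow common forensic MPS practice; the ``force_like`` and
    ``twist_like`` profiles exist so assay-specific validated values can be
    dropped in without touching code.
    """

    min_depth: int = 10
    min_quality: float = 20.0
    het_ab_low: float = 0.30
    het_ab_high: float = 0.70
    hom_ab_max: float = 0.10
    strand_min_fraction: float = 0.10
    strand_check_min_depth: int = 20
    max_other_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0.0 <= self.hom_ab_max < self.het_ab_low
                <= self.het_ab_high < 1.0 - self.hom_ab_max):
            raise ValueError(
                "allelic-balance bounds must satisfy "
                "0 <= hom_ab_max < het_ab_low <= het_ab_high < 1 - hom_ab_max"
            )
        if not 0.0 <= self.strand_min_fraction <= 0.5:
            raise ValueError("strand_min_fraction must lie in [0, 0.5]")
        if not 0.0 <= self.max_other_fraction < 1.0:
            raise ValueError("max_other_fraction must lie in [0, 1)")

    @classmethod
    def force_like(cls, **overrides) -> "CallingThresholds":
        return replace(cls(), **overrides)

    @classmethod
    def twist_like(cls, **overrides) -> "CallingThresholds":
        return replace(cls(), **overrides)


@dataclass(frozen=True)
class SiteReadData:
    """Observed read evidence at one marker in one sample."""

    marker_id: str
    n_ref: int
    n_alt: int
    n_other: int = 0
    n_fwd: int = 0
    n_rev: int = 0
    mean_q: float = 0.0

    def __post_init__(self) -> None:
        counts = (self.n_ref, self.n_alt, self.n_other, self.n_fwd, self.n_rev)
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.marker_id}: negative read count")
        if self.n_fwd + self.n_rev != self.n_ref + self.n_alt + self.n_other:
            raise ValueError(
                f"{self.marker_id}: strand counts ({self.n_fwd}+{self.n_rev}) "
                f"do not sum to allele counts "
                f"({self.n_ref}+{self.n_alt}+{self.n_other})"
            )
        if self.mean_q < 0:
            raise ValueError(f"{self.marker_id}: negative mean quality")

    @property
    def depth(self) -> int:
        """Depth used for the balance decision (ref + alt reads only)."""
        return self.n_ref + self.n_alt


@dataclass(frozen=True)
class GenotypeCall:
    marker_id: str
    call: str
    no_call_reason: str = "none"

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")
        if self.no_call_reason not in NO_CALL_REASONS:
            raise ValueError(f"unknown no-call reason {self.no_call_reason!r}")
        if (self.call == "no_call") == (self.no_call_reason == "none"):
            raise ValueError("no_call_reason must be set iff call is no_call")

    @property
    def typed(self) -> bool:
        return self.call != "no_call"


def classify_sites(n_ref, n_alt, n_other, n_fwd, n_rev, mean_q,
                   thresholds: CallingThresholds,
                   haploid) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised caller core.

    Returns integer (call_code, reason_code) arrays; filters are applied in
    the fixed order depth -> quality -> other -> strand -> balance so every
    no-call has one unambiguous reason.
    """
    n_ref = np.asarray(n_ref, dtype=np.int64)
    n_alt = np.asarray(n_alt, dtype=np.int64)
    n_other = np.asarray(n_other, dtype=np.int64)
    n_fwd = np.asarray(n_fwd, dtype=np.int64)
    n_rev = np.asarray(n_rev, dtype=np.int64)
    mean_q = np.asarray(mean_q, dtype=float)
    haploid = np.asarray(haploid, dtype=bool)
    if np.any(n_ref < 0) or np.any(n_alt < 0) or np.any(n_other < 0) \
            or np.any(n_fwd < 0) or np.any(n_rev < 0):
        raise ValueError("negative read counts")
    if np.any(n_fwd + n_rev != n_ref + n_alt + n_other):
        raise ValueError("strand counts do not sum to allele counts")

    t = thresholds
    d = n_ref + n_alt
    call = np.full(d.shape, _NO_CALL, dtype=np.int8)
    reason = np.full(d.shape, _R_NONE, dtype=np.int8)
    undecided = np.ones(d.shape, dtype=bool)

    def _fail(mask, code):
        hit = undecided & mask
        reason[hit] = code
        undecided[hit] = False

    _fail(d < t.min_depth, _R_DEPTH)
    _fail(mean_q < t.min_quality, _R_QUAL)
    with np.errstate(divide="ignore", invalid="ignore"):
        other_frac = np.where(d + n_other > 0, n_other / (d + n_other), 0.0)
    _fail(other_frac > t.max_other_fraction, _R_OTHER)
    total_strand = n_fwd + n_rev
    with np.errstate(divide="ignore", invalid="ignore"):
        minority = np.where(total_strand > 0,
                            np.minimum(n_fwd, n_rev) / np.maximum(total_strand, 1),
                            0.0)
    _fail((d >= t.strand_check_min_depth) & (minority < t.strand_min_fraction),
          _R_STRAND)

    ab = np.where(d > 0, n_alt / np.maximum(d, 1), 0.0)
    low = ab <= t.hom_ab_max
    high = ab >= 1.0 - t.hom_ab_max
    het = (ab >= t.het_ab_low) & (ab <= t.het_ab_high)

    dip = undecided & ~haploid
    call[dip & low] = _HOM_REF
    call[dip & high] = _HOM_ALT
    call[dip & het & ~low & ~high] = _HET
    hap = undecided & haploid
    call[hap & low] = _HAP_REF
    call[hap & high] = _HAP_ALT
    decided = undecided & (call != _NO_CALL)
    reason[undecided & ~decided] = _R_AB
    return call, reason


def call_genotype(site: SiteReadData, thresholds: CallingThresholds,
                  ploidy: str = DIPLOID) -> GenotypeCall:
    """Call one site; pure function of (site, thresholds, ploidy)."""
    if ploidy not in (DIPLOID, HAPLOID):
        raise ValueError(f"unknown ploidy {ploidy!r}")
    call, reason = classify_sites(
        [site.n_ref], [site.n_alt], [site.n_other], [site.n_fwd], [site.n_rev],
        [site.mean_q], thresholds, [ploidy == HAPLOID],
    )
    return GenotypeCall(site.marker_id, str(_CALL_NAMES[call[0]]),
                        str(_REASON_NAMES[reason[0]]))


@dataclass
class CallSet:
    """Genotype calls for one sample over a full panel.

    ``calls`` is indexed by marker_id with columns ``call`` and
    ``no_call_reason``; every panel marker has exactly one row.
    """

    sample_id: str
    panel: Panel
    calls: pd.DataFrame
    thresholds: CallingThresholds = field(default_factory=CallingThresholds)

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.panel) or \
                not self.calls.index.equals(pd.Index(self.panel.marker_ids)):
            raise ValueError("calls must cover the panel exactly, in panel order")

    @property
    def typed_mask(self) -> np.ndarray:
        return (self.calls["call"] != "no_call").to_numpy()

    @property
    def n_typed(self) -> int:
        return int(self.typed_mask.sum())

    def call_of(self, marker_id: str) -> GenotypeCall:
        row = self.calls.loc[marker_id]
        return GenotypeCall(marker_id, row["call"], row["no_call_reason"])

    def to_frame(self) -> pd.DataFrame:
        out = self.calls.reset_index()
        out.insert(0, "sample_id", self.sample_id)
        return out


def call_sample(reads: pd.DataFrame, panel: Panel,
                thresholds: CallingThresholds | None = None,
                sex: str = "unknown", sample_id: str = "sample") -> CallSet:
    """Call every panel marker for one sample from its read-count table.

    Ploidy follows sex: autosomes (and X in females) are diploid, Y and X
    in males haploid.  Y markers in females or unknown-sex samples are
    no-calls with reason ``wrong_ploidy``.  Markers absent from the table
    count as zero-depth.
    """
    thresholds = thresholds or CallingThresholds()
    if sex not in ("male", "female", "unknown"):
        raise ValueError(f"unknown sex {sex!r}")
    required = {"marker_id", "n_ref", "n_alt", "n_other", "n_fwd", "n_rev", "mean_q"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    unknown = set(reads["marker_id"]) - set(panel.marker_ids)
    if unknown:
        raise ValueError(
            f"read table contains {len(unknown)} marker(s) not in panel "
            f"{panel.name!r}: {sorted(unknown)[:5]}"
        )
    if reads["marker_id"].duplicated().any():
        dups = reads.loc[reads["marker_id"].duplicated(), "marker_id"]
        raise ValueError(f"duplicate marker rows: {sorted(set(dups))[:5]}")

    aligned = (reads.set_index("marker_id")
               .reindex(panel.marker_ids, fill_value=0))
    haploid = (panel.is_y | panel.is_x) if sex == "male" \
        else np.zeros(len(panel), dtype=bool)
    call, reason = classify_sites(
        aligned["n_ref"], aligned["n_alt"], aligned["n_other"],
        aligned["n_fwd"], aligned["n_rev"], aligned["mean_q"],
        thresholds, haploid,
    )
    if sex != "male":
        y = panel.is_y
        call[y] = _NO_CALL
        reason[y] = _R_PLOIDY
    frame = pd.DataFrame(
        {"call": _CALL_NAMES[call], "no_call_reason": _REASON_NAMES[reason]},
        index=pd.Index(panel.marker_ids, name="marker_id"),
    )
    frame.loc[frame["call"] != "no_call", "no_call_reason"] = "none"
    return CallSet(sample_id=sample_id, panel=panel, calls=frame,
                   thresholds=thresholds)


def consensus_replicates(a: CallSet, b: CallSet) -> CallSet:
    """Keep only genotypes reproduced identically in both replicates.

    A marker is typed in the consensus iff it is typed with the same call
    in both inputs.  Markers typed discordantly become no-calls with the
    dedicated reason ``replicate_discordant``; markers untyped in either
    input inherit that input's no-call reason (a's, when both are untyped).
    """
    if not (a.panel is b.panel or a.panel == b.panel):
        raise ValueError("replicate call sets are on different panels")
    ca, cb = a.calls["call"].to_numpy(), b.calls["call"].to_numpy()
    ra, rb = a.calls["no_call_reason"].to_numpy(), b.calls["no_call_reason"].to_numpy()
    typed_a, typed_b = ca != "no_call", cb != "no_call"
    agree = typed_a & typed_b & (ca == cb)
    call = np.where(agree, ca, "no_call")
    reason = np.where(agree, "none",
                      np.where(typed_a & typed_b, "replicate_discordant",
                               np.where(~typed_a, ra, rb)))
    frame = pd.DataFrame(
        {"call": call, "no_call_reason": reason},
        index=pd.Index(a.panel.marker_ids, name="marker_id"),
    )
    return CallSet(sample_id=f"{a.sample_id}+{b.sample_id}", panel=a.panel,
                   calls=frame, thresholds=a.thresholds)


def calls_to_dosage(calls: pd.Series) -> pd.Series:
    """Map typed calls to ploidy-aware alt dosage; no-calls become NA."""
    return calls.map(CALL_DOSAGE).astype("Int64")
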