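"""SNP panels, simulated donors and ground-truth bookkeeping.

A :class:`Panel` is an ordered set of biallelic markers (autosomal and/or
Y-chromosomal) each carrying a population alternate-allele frequency ``p``.
Latent donor genotypes are drawn under Hardy-Weinberg equilibrium:
``P(0) = (1-p)^2``, ``P(1) = 2p(1-p)``, ``P(2) = p^2`` for diploid markers
and ``Bernoulli(p)`` for haploid ones.  The :class:`TruthSet` keeps the
latent dosages and the same-donor / unrelated structure of every sample
pair so that downstream calling, matching and concordance stages can be
scored against a known answer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

AUTOSOME = "autosome"
X_CHROM = "X"
Y_CHROM = "Y"

SAME_DONOR = "same_donor"
UNRELATED = "unrelated"

#: unordered base pairs subject to the deamination-like damage term
_DAMAGE_PAIRS = frozenset({frozenset({"C", "T"}), frozenset({"G", "A"})})

_VALID_BASES = frozenset("ACGT")


def chrom_class(chrom: str) -> str:
    """Classify a chromosome label as autosome, X or Y."""
    label = str(chrom).removeprefix("chr")
    if label.upper() == "Y":
        return Y_CHROM
    if label.upper() == "X":
        return X_CHROM
    return AUTOSOME


@dataclass(frozen=True)
class SNPMarker:
    """A single biallelic SNP with its population alternate-allele frequency."""

    marker_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    alt_freq: float

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"marker {self.marker_id}: ref and alt alleles are both "
                f"{self.ref_allele!r}"
            )
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in _VALID_BASES:
                raise ValueError(
                    f"marker {self.marker_id}: allele {allele!r} is not a "
                    "single nucleotide"
                )
        if not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError(
                f"marker {self.marker_id}: alt_freq {self.alt_freq} outside [0, 1]"
            )
        if self.pos < 1:
            raise ValueError(f"marker {self.marker_id}: pos must be 1-based")

    @property
    def chrom_class(self) -> str:
        return chrom_class(self.chrom)

    @property
    def damage_prone(self) -> bool:
        """True for C/T- and G/A-typed markers, the targets of the damage term."""
        return frozenset({self.ref_allele, self.alt_allele}) in _DAMAGE_PAIRS


class Panel:
    """Ordered collection of :class:`SNPMarker`, backed by a DataFrame.

    The tabular backing keeps million-marker panels practical; the
    :meth:`markers` iterator provides the object view when convenient.
    """

    COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt", "alt_freq"]

    def __init__(self, frame: pd.DataFrame, name: str = "panel"):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"panel frame missing columns: {missing}")
        frame = frame[self.COLUMNS].reset_index(drop=True)
        dup = frame["marker_id"][frame["marker_id"].duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicate marker_id in panel: {sorted(set(dup))[:5]}"
            )
        bad_freq = frame["alt_freq"].to_numpy(dtype=float)
        if np.any(~np.isfinite(bad_freq)) or bad_freq.min() < 0 or bad_freq.max() > 1:
            raise ValueError("panel alt_freq values must lie in [0, 1]")
        same = frame["ref"] == frame["alt"]
        if same.any():
            raise ValueError(
                f"ref == alt for markers {frame.loc[same, 'marker_id'].tolist()[:5]}"
            )
        self._frame = frame
        self.name = name
        self._classes = frame["chrom"].map(chrom_class).to_numpy()
        self._index = pd.Index(frame["marker_id"])

    @classmethod
    def from_markers(cls, markers: Iterable[SNPMarker], name: str = "panel") -> "Panel":
        rows = [
            (m.marker_id, m.chrom, m.pos, m.ref_allele, m.alt_allele, m.alt_freq)
            for m in markers
        ]
        if not rows:
            raise ValueError("a panel requires at least one marker")
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS), name=name)

    # -- tabular views ---------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def marker_ids(self) -> pd.Index:
        return self._index

    @property
    def alt_freq(self) -> np.ndarray:
        return self._frame["alt_freq"].to_numpy(dtype=float)

    @property
    def is_y(self) -> np.ndarray:
        return self._classes == Y_CHROM

    @property
    def is_x(self) -> np.ndarray:
        return self._classes == X_CHROM

    @property
    def is_autosomal(self) -> np.ndarray:
        return self._classes == AUTOSOME

    @property
    def damage_prone(self) -> np.ndarray:
        ref = self._frame["ref"].to_numpy()
        alt = self._frame["alt"].to_numpy()
        ct = ((ref == "C") & (alt == "T")) | ((ref == "T") & (alt == "C"))
        ga = ((ref == "G") & (alt == "A")) | ((ref == "A") & (alt == "G"))
        return ct | ga

    # -- counts ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    @property
    def n_y(self) -> int:
        return int(self.is_y.sum())

    def targetable_count(self, sex: str) -> int:
        """Panel size a sample of the given sex can actually be typed at.

        Y markers are untargetable in females; unknown sex keeps the full
        panel (the conservative, lower-call-rate denominator).
        """
        if sex == "female":
            return len(self) - self.n_y
        return len(self)

    def markers(self) -> Iterator[SNPMarker]:
        for row in self._frame.itertuples(index=False):
            yield SNPMarker(row.marker_id, row.chrom, row.pos, row.ref, row.alt,
                            float(row.alt_freq))

    def subset(self, marker_ids: Iterable[str], name: str | None = None) -> "Panel":
        ids = pd.Index(marker_ids)
        unknown = ids.difference(self._index)
        if len(unknown):
            raise KeyError(f"markers not in panel: {list(unknown[:5])}")
        keep = self._frame[self._frame["marker_id"].isin(set(ids))]
        return Panel(keep, name=name or f"{self.name}-subset")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return self._frame.equals(other._frame)


@dataclass
class Individual:
    """A simulated donor: sex plus latent alt-allele dosages.

    ``dosage`` is aligned to the panel's marker order; -1 marks markers the
    individual does not carry (Y markers in females).
    """

    sample_id: str
    sex: str
    dosage: np.ndarray

    def genotypes(self, panel: Panel) -> Mapping[str, int]:
        """Dosage keyed by marker_id (markers not carried are omitted)."""
        d = self.dosage
        return {
            mid: int(d[i]) for i, mid in enumerate(panel.marker_ids) if d[i] >= 0
        }


class PairLabels:
    """Same-donor / unrelated labels over all unordered sample pairs.

    Only same-donor pairs are stored; every other distinct pair is
    unrelated, which keeps the structure O(#replicate pairs) even for
    thousands of simulated donors.
    """

    def __init__(self, sample_ids: list[str],
                 same_donor: set[frozenset] | None = None):
        self._ids = list(sample_ids)
        self._same = set(same_donor or ())

    def label(self, a: str, b: str) -> str:
        if a == b:
            raise ValueError("pair labels are defined for distinct samples")
        for s in (a, b):
            if s not in self._ids:
                raise KeyError(f"unknown sample {s!r}")
        return SAME_DONOR if frozenset({a, b}) in self._same else UNRELATED

    def __getitem__(self, pair) -> str:
        a, b = tuple(pair)
        return self.label(a, b)

    def __len__(self) -> int:
        n = len(self._ids)
        return n * (n - 1) // 2

    def items(self) -> Iterator[tuple[tuple[str, str], str]]:
        for a, b in itertools.combinations(self._ids, 2):
            yield (a, b), self.label(a, b)

    def same_donor_pairs(self) -> set[frozenset]:
        return set(self._same)

    def mark_same_donor(self, a: str, b: str) -> None:
        self.label(a, b)  # validates ids
        self._same.add(frozenset({a, b}))

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, lab) for (a, b), lab in self.items()]
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "relation"])


@dataclass
class TruthSet:
    """Simulated donors plus the latent pair structure."""

    panel: Panel
    individuals: list[Individual]
    pair_labels: PairLabels = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pair_labels is None:
            self.pair_labels = PairLabels(self.sample_ids)

    @property
    def sample_ids(self) -> list[str]:
        return [ind.sample_id for ind in self.individuals]

    def get(self, sample_id: str) -> Individual:
        for ind in self.individuals:
            if ind.sample_id == sample_id:
                return ind
        raise KeyError(f"unknown sample {sample_id!r}")

    def dosage_frame(self) -> pd.DataFrame:
        """Long truth table: sample_id, marker_id, dosage (carried markers only)."""
        parts = []
        mids = self.panel.marker_ids.to_numpy()
        for ind in self.individuals:
            keep = ind.dosage >= 0
            parts.append(pd.DataFrame({
                "sample_id": ind.sample_id,
                "marker_id": mids[keep],
                "dosage": ind.dosage[keep].astype(int),
            }))
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _resolve_freq_model(freq_model):
    """Accept a scipy frozen distribution or a ('name', *params) tuple."""
    if hasattr(freq_model, "rvs"):
        return freq_model
    name, *params = freq_model
    if name == "uniform":
        low, high = params
        return stats.uniform(low, high - low)
    if name == "beta":
        a, b = params
        return stats.beta(a, b)
    raise ValueError(f"unknown frequency model {name!r}")


def build_panel(n_autosomal: int, n_y: int,
                freq_model=("uniform", 0.05, 0.95),
                seed: int = 0, name: str = "panel") -> Panel:
    """Build a synthetic panel of biallelic autosomal and Y markers.

    Alternate-allele frequencies are drawn i.i.d. from ``freq_model`` and
    clipped to [0.001, 0.999] so no marker is exactly monomorphic.
    Autosomal markers are spread round-robin over chromosomes 1-22.
    """
    if n_autosomal < 0 or n_y < 0:
        raise ValueError("marker counts must be non-negative")
    total = n_autosomal + n_y
    if total < 1:
        raise ValueError("a panel requires at least one marker")
    rng = np.random.default_rng(seed)
    dist = _resolve_freq_model(freq_model)
    freqs = np.clip(np.asarray(dist.rvs(size=total, random_state=rng), dtype=float),
                    1e-3, 1 - 1e-3)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=total)
    alt_shift = rng.integers(1, 4, size=total)
    alt_idx = (ref_idx + alt_shift) % 4

    width = max(6, len(str(total)))
    ids = [f"m{i:0{width}d}" for i in range(total)]
    chroms = [str(1 + i % 22) for i in range(n_autosomal)] + ["Y"] * n_y
    pos = np.arange(1, total + 1) * 1000
    frame = pd.DataFrame({
        "marker_id": ids,
        "chrom": chroms,
        "pos": pos,
        "ref": bases[ref_idx],
        "alt": bases[alt_idx],
        "alt_freq": freqs,
    })
    return Panel(frame, name=name)


def simulate_individuals(panel: Panel, n: int, sex_ratio: float = 0.5,
                         seed: int = 0) -> TruthSet:
    """Draw ``n`` unrelated individuals with HWE genotypes on ``panel``.

    ``sex_ratio`` is the probability a simulated individual is male.
    Diploid markers (autosomes; X in females) get Binomial(2, p) dosage,
    haploid ones (Y and X in males) Bernoulli(p); females carry no Y.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    if not 0.0 <= sex_ratio <= 1.0:
        raise ValueError("sex_ratio must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = panel.alt_freq
    is_y, is_x = panel.is_y, panel.is_x
    width = max(3, len(str(n)))
    individuals = []
    for i in range(n):
        sex = "male" if rng.random() < sex_ratio else "female"
        dosage = _draw_dosage(rng, p, is_y, is_x, sex)
        individuals.append(Individual(f"ind{i:0{width}d}", sex, dosage))
    return TruthSet(panel=panel, individuals=individuals)


def _draw_dosage(rng: np.random.Generator, p: np.ndarray,
                 is_y: np.ndarray, is_x: np.ndarray, sex: str) -> np.ndarray:
    haploid = is_y | is_x if sex == "male" else np.zeros_like(is_y)
    dosage = rng.binomial(2, p).astype(np.int8)
    if haploid.any():
        dosage[haploid] = rng.binomial(1, p[haploid]).astype(np.int8)
    if sex != "male" and is_y.any():
        dosage[is_y] = -1
    return dosage


def add_replicates(truth: TruthSet, sample_id: str, n_reps: int = 1) -> TruthSet:
    """Add technical replicates of one donor, sharing its latent genotypes.

    Replicates get ids ``<sample_id>-rep1`` and so on; every pair within
    the replicate group (source included) is labeled same-donor.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    source = truth.get(sample_id)  # raises KeyError for unknown ids
    new_ids = [f"{sample_id}-rep{i + 1}" for i in range(n_reps)]
    clash = set(new_ids) & set(truth.sample_ids)
    if clash:
        raise ValueError(f"replicate ids already present: {sorted(clash)}")
    individuals = list(truth.individuals) + [
        Individual(rid, source.sex, source.dosage.copy()) for rid in new_ids
    ]
    same = truth.pair_labels.same_donor_pairs()
    group = [sample_id] + new_ids
    for a, b in itertools.combinations(group, 2):
        same.add(frozenset({a, b}))
    labels = PairLabels([ind.sample_id for ind in individuals], same)
    return TruthSet(panel=truth.panel, individuals=individuals, pair_labels=labels)
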