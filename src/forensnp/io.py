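"""Readers and writers for the pipeline's tab-separated interchange files.

All files are UTF-8, tab-separated, header required, 1-based coordinates.
Writers emit a deterministic column order and ``\\n`` line endings;
readers validate rather than coerce, reporting the offending file line
(header = line 1) wherever a row is malformed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calling import CALLS, NO_CALL_REASONS, CallSet, CallingThresholds
from .panel import Panel
from .sim import READS_COLUMNS

PANEL_COLUMNS = Panel.COLUMNS
CALLS_COLUMNS = ["sample_id", "marker_id", "call", "no_call_reason"]
TRUTH_COLUMNS = ["sample_id", "marker_id", "dosage"]
PAIRS_COLUMNS = ["sample_a", "sample_b", "relation"]


def _read_tsv(path, required: list[str], dtypes: dict | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tab = pd.read_csv(path, sep="\t", dtype=dtypes or {},
                      float_precision="round_trip")
    missing = [c for c in required if c not in tab.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return tab


def _line_of(idx: int) -> int:
    # data row 0 sits on file line 2 (after the header)
    return idx + 2


def read_panel(path) -> Panel:
    """Read a panel TSV (marker_id, chrom, pos, ref, alt, alt_freq)."""
    tab = _read_tsv(path, PANEL_COLUMNS, {"marker_id": str, "chrom": str})
    dup = tab.index[tab["marker_id"].duplicated()]
    if len(dup):
        i = int(dup[0])
        raise ValueError(
            f"{path}: duplicate marker_id {tab.loc[i, 'marker_id']!r} "
            f"at line {_line_of(i)}")
    freq = pd.to_numeric(tab["alt_freq"], errors="coerce")
    bad = tab.index[~np.isfinite(freq) | (freq < 0) | (freq > 1)]
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"{path}: malformed alt_freq {tab.loc[i, 'alt_freq']!r} "
            f"at line {_line_of(i)}")
    tab["alt_freq"] = freq
    return Panel(tab, name=Path(path).stem)


def write_panel(panel: Panel, path) -> None:
    panel.frame[PANEL_COLUMNS].to_csv(path, sep="\t", index=False,
                                      lineterminator="\n")


def read_reads(path, long: bool = False) -> pd.DataFrame:
    """Read a read-count TSV; ``long`` expects a leading sample_id column.

    The strand-sum invariant (n_fwd + n_rev == n_ref + n_alt + n_other) is
    enforced row by row at read time.
    """
    cols = (["sample_id"] if long else []) + READS_COLUMNS
    tab = _read_tsv(path, cols, {"marker_id": str})
    counts = tab[["n_ref", "n_alt", "n_other", "n_fwd", "n_rev"]]
    neg = tab.index[(counts < 0).any(axis=1)]
    if len(neg):
        raise ValueError(f"{path}: negative count at line {_line_of(int(neg[0]))}")
    bad = tab.index[
        tab["n_fwd"] + tab["n_rev"] != tab["n_ref"] + tab["n_alt"] + tab["n_other"]]
    if len(bad):
        raise ValueError(
            f"{path}: strand counts do not sum to allele counts "
            f"at line {_line_of(int(bad[0]))}")
    return tab[cols]


def write_reads(reads: pd.DataFrame, path, long: bool | None = None) -> None:
    if long is None:
        long = "sample_id" in reads.columns
    cols = (["sample_id"] if long else []) + READS_COLUMNS
    reads[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_calls(path, panel: Panel | None = None,
               thresholds: CallingThresholds | None = None) -> list[CallSet] | pd.DataFrame:
    """Read a genotype TSV; with a panel, reconstruct per-sample CallSets."""
    tab = _read_tsv(path, CALLS_COLUMNS, {"marker_id": str, "sample_id": str})
    bad = tab.index[~tab["call"].isin(CALLS)]
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"{path}: unknown call {tab.loc[i, 'call']!r} at line {_line_of(i)}")
    bad = tab.index[~tab["no_call_reason"].isin(NO_CALL_REASONS)]
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"{path}: unknown no_call_reason {tab.loc[i, 'no_call_reason']!r} "
            f"at line {_line_of(i)}")
    if panel is None:
        return tab
    out = []
    for sid, sub in tab.groupby("sample_id", sort=False):
        frame = (sub.set_index("marker_id")[["call", "no_call_reason"]]
                 .reindex(panel.marker_ids))
        absent = frame.index[frame["call"].isna()]
        frame.loc[absent, ["call", "no_call_reason"]] = ["no_call", "low_depth"]
        out.append(CallSet(sample_id=str(sid), panel=panel, calls=frame,
                           thresholds=thresholds or CallingThresholds()))
    return out


def write_calls(callsets, path) -> None:
    if isinstance(callsets, CallSet):
        callsets = [callsets]
    frame = pd.concat([cs.to_frame() for cs in callsets], ignore_index=True)
    frame[CALLS_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_truth(path) -> pd.DataFrame:
    tab = _read_tsv(path, TRUTH_COLUMNS, {"marker_id": str, "sample_id": str})
    bad = tab.index[~tab["dosage"].isin([0, 1, 2])]
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"{path}: dosage must be 0/1/2, got {tab.loc[i, 'dosage']!r} "
            f"at line {_line_of(i)}")
    return tab


def write_truth(truth_frame: pd.DataFrame, path) -> None:
    truth_frame[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False,
                                      lineterminator="\n")


def read_pairs(path) -> pd.DataFrame:
    tab = _read_tsv(path, PAIRS_COLUMNS, {"sample_a": str, "sample_b": str})
    bad = tab.index[~tab["relation"].isin(["same_donor", "unrelated"])]
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"{path}: unknown relation {tab.loc[i, 'relation']!r} "
            f"at line {_line_of(i)}")
    return tab


def write_pairs(pairs_frame: pd.DataFrame, path) -> None:
    pairs_frame[PAIRS_COLUMNS].to_csv(path, sep="\t", index=False,
                                      lineterminator="\n")
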