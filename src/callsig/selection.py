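"""Note-selection and filtering rules applied before analysis.

Three rules: keep only each call's first note when it is well separated
from the preceding note (>= 30 ms gap); drop every individual that
contributed fewer than 45 notes; and, for the double-note analyses,
pair up the first two notes of multi-note calls into single rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectro import FEATURE_COLUMNS, LABEL_COLUMNS


def select_first_notes(table: pd.DataFrame, min_gap_ms: float = 30.0,
                       *, time_column: str = "t_onset_s",
                       file_column: str = "file") -> pd.DataFrame:
    """Keep first notes of calls separated by >= ``min_gap_ms`` from the
    previous note.

    A note is retained iff its ``note_index`` is 1 and its onset is at
    least ``min_gap_ms`` after the previous note's offset within the
    same recording.  When explicit onset/offset times are absent the
    gap is reconstructed from ``inter_note_interval_ms`` (first notes
    of distinct calls are assumed well separated, which holds for the
    synthetic generator's inter-call gaps).  Row order is preserved.
    """
    if "note_index" not in table.columns:
        raise ValueError("table must carry a note_index column")
    if table.empty:
        return table.copy()
    first = table["note_index"].astype(int) == 1
    has_times = (time_column in table.columns
                 and "duration_ms" in table.columns)
    if has_times:
        keep = pd.Series(first.to_numpy().copy(), index=table.index)
        groups = (table.groupby(file_column, sort=False)
                  if file_column in table.columns else [(None, table)])
        for _, grp in groups:
            onset = grp[time_column].to_numpy(float)
            offset = onset + grp["duration_ms"].to_numpy(float) / 1000.0
            order = np.argsort(onset, kind="stable")
            prev_off = -np.inf
            for k in order:
                row_idx = grp.index[k]
                gap_ms = (onset[k] - prev_off) * 1000.0
                if keep.loc[row_idx] and gap_ms < min_gap_ms:
                    keep.loc[row_idx] = False
                prev_off = max(prev_off, offset[k])
        return table.loc[keep.to_numpy()].copy()
    if "inter_note_interval_ms" in table.columns:
        gap = table["inter_note_interval_ms"].to_numpy(float)
        close = np.nan_to_num(gap, nan=np.inf) < min_gap_ms
        return table.loc[first.to_numpy() & ~close].copy()
    raise ValueError("table lacks timing information "
                     f"({time_column}/duration_ms or inter_note_interval_ms)")


def min_notes_filter(table: pd.DataFrame, threshold: int = 45,
                     *, subject_column: str = "individual"
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop all notes of individuals contributing fewer than ``threshold``
    notes; returns the filtered table and a report of dropped subjects."""
    if table.empty:
        return table.copy(), pd.DataFrame(columns=[subject_column, "n_notes"])
    counts = table[subject_column].value_counts()
    dropped = counts[counts < threshold]
    report = (dropped.rename("n_notes").rename_axis(subject_column)
              .reset_index().sort_values(subject_column)
              .reset_index(drop=True))
    kept = table[~table[subject_column].isin(dropped.index)].copy()
    return kept, report


def select_double_notes(table: pd.DataFrame,
                        *, reduced: bool = False) -> pd.DataFrame:
    """One row per multi-note call, concatenating the measurements of
    notes 1 and 2 plus the inter-note interval.

    Columns are suffixed ``_n1`` / ``_n2``; labels are taken from the
    first note.  With ``reduced=True`` the fundamental frequencies at
    the 20-80% interior positions (bar 50%) are omitted from both
    notes, mirroring the reduced variable set used when the full
    double-note vector would be rank-deficient.
    """
    if table.empty:
        return pd.DataFrame()
    feats = [c for c in FEATURE_COLUMNS if c in table.columns]
    if reduced:
        omit = {f"f0@{p:g}_khz" for p in (0.2, 0.3, 0.4, 0.7, 0.8)}
        feats = [c for c in feats if c not in omit]
    rows = []
    for call_id, grp in table.groupby("call_id", sort=False):
        grp = grp.sort_values("note_index")
        if len(grp) < 2 or int(grp["note_index"].iloc[0]) != 1:
            continue
        n1, n2 = grp.iloc[0], grp.iloc[1]
        row = {c: n1[c] for c in LABEL_COLUMNS if c in grp.columns}
        row.update({f"{c}_n1": n1[c] for c in feats})
        row.update({f"{c}_n2": n2[c] for c in feats})
        row["inter_note_interval_ms"] = n2.get("inter_note_interval_ms", np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def double_note_feature_columns(paired: pd.DataFrame) -> list[str]:
    """Measurement columns of a paired table (note-1, note-2, interval)."""
    return ([c for c in paired.columns if c.endswith("_n1") or c.endswith("_n2")]
            + ["inter_note_interval_ms"])
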