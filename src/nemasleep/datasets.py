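"""Bundled reference tables.

The only data shipped with the package is the published classification
bookkeeping of the optogenetic/light-stimulation experiments this pipeline
reanalyzes: for each experiment, the number of trials counted as wake,
sleep, or excluded, together with the percentages as printed in the source
report.  Recomputing the percentages from the counts is a self-consistency
audit of that bookkeeping (see
:func:`nemasleep.datasets.audit_classification_counts`); one printed entry
is internally inconsistent and is flagged, not reproduced.
"""

from __future__ import annotations

import pandas as pd

from .stimulus import round_half_up_pct

__all__ = ["published_classification_counts", "audit_classification_counts"]

# experiment, condition, n_total, n_wake, n_sleep, n_excluded,
# printed wake/sleep/excluded percentages
_BOOKKEEPING = [
    ("responsiveness_blue_light", "all", 600, 446, 98, 56, 74.3, 16.3, 9.3),
    ("reversibility_sra6",  "ATR+",    125,  70, 19,  36, 56.0, 15.2, 28.8),
    ("reversibility_sra6",  "ATR-",    273, 110, 40, 123, 40.3, 14.7, 40.1),
    ("reversibility_mec4",  "ATR+",    167, 101, 42,  24, 60.5, 25.1, 14.4),
    ("reversibility_mec4",  "ATR-",    297,  69, 85, 143, 23.2, 28.6, 48.1),
    ("reversibility_pooled", "all",    862, 350, 186, 326, 40.6, 21.6, 37.8),
    ("reversibility_dish",  "stim",    180,  80, 38,  62, 44.4, 21.1, 34.4),
    ("reversibility_dish",  "no_stim", 131,  32, 71,  28, 24.4, 54.2, 21.4),
]


def published_classification_counts() -> pd.DataFrame:
    """The printed wake/sleep/excluded bookkeeping, one row per experiment."""
    return pd.DataFrame(_BOOKKEEPING, columns=[
        "experiment", "condition", "n_total", "n_wake", "n_sleep",
        "n_excluded", "printed_pct_wake", "printed_pct_sleep",
        "printed_pct_excluded",
    ])


def audit_classification_counts() -> pd.DataFrame:
    """Recompute every percentage from its counts and flag mismatches.

    Adds ``pct_*`` columns (recomputed, round-half-up to one decimal) and a
    boolean ``consistent`` column; a row is consistent when all three
    recomputed percentages equal the printed ones.
    """
    df = published_classification_counts().copy()
    for part in ("wake", "sleep", "excluded"):
        df[f"pct_{part}"] = [
            round_half_up_pct(int(c), int(n))
            for c, n in zip(df[f"n_{part}"], df["n_total"])
        ]
    df["consistent"] = (
        (df["pct_wake"] == df["printed_pct_wake"])
        & (df["pct_sleep"] == df["printed_pct_sleep"])
        & (df["pct_excluded"] == df["printed_pct_excluded"])
    )
    return df
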