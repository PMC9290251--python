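"""Small reporting helpers for cohort summaries."""

from __future__ import annotations

from typing import Mapping

import pandas as pd


def cluster_proportions(counts: Mapping[str, int], decimals: int = 1) -> pd.Series:
    """Percentage share of each cluster from its member count.

    E.g. sizes {Methy-Low: 19, Methy-High: 26} of a 45-sample cohort give
    42.2% and 57.8%.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("cluster counts must sum to a positive total")
    return pd.Series({k: round(100.0 * v / total, decimals)
                      for k, v in counts.items()}, name="percent")


def assignment_summary(label: pd.Series) -> pd.Series:
    """Cluster sizes and percentage shares from per-sample labels."""
    counts = label.value_counts().to_dict()
    return cluster_proportions(counts)
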