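"""Label coercion helpers shared across modules."""
from __future__ import annotations

import pandas as pd


def to_binary(labels: pd.Series) -> pd.Series:
    """Map CIMP labels to 1 (positive) / 0 (negative).

    Accepts the string labels produced by CIMP calling or already-binary
    values; anything else is rejected.
    """
    s = pd.Series(labels)
    uniq = set(s.unique())
    if uniq <= {"positive", "negative"}:
        return (s == "positive").astype(int)
    if uniq <= {0, 1, True, False}:
        return s.astype(int)
    raise ValueError(f"cannot interpret CIMP labels: {sorted(map(str, uniq))[:5]}")
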