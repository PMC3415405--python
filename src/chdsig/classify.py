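"""Four-class dosage classification of DE genes.

A gene differentially expressed in the case group (case vs CHD-) is class I
when the case-vs-CHD- effect exceeds the CHD--vs-2N effect in |log2 ratio|,
class II otherwise. Subclass A/B comes from an equality criterion applied to
the CHD--vs-2N contrast (class I) or to the case-vs-2N contrast (class II):
"equal" means p >= alpha, a ratio inside the equality band, or both,
depending on ``equality_mode``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = ["ClassificationRules", "classify_gene", "classify_table", "CLASS_ORDER"]

CLASS_ORDER = ("IA", "IB", "IIA", "IIB")

#: required columns of the classification input frame
INPUT_COLUMNS = (
    "ratio_chd_2n", "p_chd_2n",
    "ratio_case_chd", "p_case_chd",
    "ratio_case_2n", "p_case_2n",
)


@dataclass(frozen=True)
class ClassificationRules:
    equality_band: tuple[float, float] = (0.95, 1.05)
    equality_mode: str = "pvalue"  # pvalue | ratio-band | both
    alpha: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.equality_band
        if not lo <= 1.0 <= hi:
            raise ConfigError("equality band must contain 1.0")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.equality_mode not in ("pvalue", "ratio-band", "both"):
            raise ConfigError(f"unknown equality_mode {self.equality_mode!r}")

    def is_equal(self, ratio: float, p: float) -> bool:
        lo, hi = self.equality_band
        by_p = p >= self.alpha
        by_band = lo <= ratio <= hi
        if self.equality_mode == "pvalue":
            return by_p
        if self.equality_mode == "ratio-band":
            return by_band
        return by_p and by_band


def classify_gene(
    ratio_chd_2n: float,
    p_chd_2n: float,
    ratio_case_chd: float,
    p_case_chd: float,
    ratio_case_2n: float,
    p_case_2n: float,
    rules: ClassificationRules = ClassificationRules(),
) -> tuple[str, bool]:
    """Class label for one gene plus a flag marking an exact magnitude tie.

    Returns ``("none", False)`` when the gene is not DE for case vs CHD-
    (p >= alpha). An exact tie of the two effect magnitudes is resolved
    conservatively to class II and flagged.
    """
    for r in (ratio_chd_2n, ratio_case_chd, ratio_case_2n):
        if not (r > 0 and math.isfinite(r)):
            raise DataError(f"ratios must be positive and finite (got {r})")
    if p_case_chd >= rules.alpha:
        return "none", False
    mag_case = abs(math.log2(ratio_case_chd))
    mag_base = abs(math.log2(ratio_chd_2n))
    tie = mag_case == mag_base
    if mag_case > mag_base:
        equal = rules.is_equal(ratio_chd_2n, p_chd_2n)
        return ("IB" if equal else "IA"), False
    equal = rules.is_equal(ratio_case_2n, p_case_2n)
    return ("IIB" if equal else "IIA"), tie


def classify_table(
    table: pd.DataFrame,
    rules: ClassificationRules = ClassificationRules(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every row of a contrast table.

    ``table`` must carry the six columns in :data:`INPUT_COLUMNS`;
    ``ratio_case_2n`` may be absent, in which case it is derived as the
    product of the other two ratios (log2-additivity of the contrasts).
    ``p_case_2n`` is required unless ``equality_mode="ratio-band"``.

    Returns the table with ``class_label`` and ``magnitude_tie`` columns
    appended, plus per-class counts (including ``none``).
    """
    df = table.copy()
    if "ratio_case_2n" not in df.columns:
        df["ratio_case_2n"] = df["ratio_chd_2n"] * df["ratio_case_chd"]
    if "p_case_2n" not in df.columns:
        if rules.equality_mode != "ratio-band":
            raise DataError(
                "p_case_2n column required unless equality_mode='ratio-band'"
            )
        df["p_case_2n"] = 1.0
    missing = set(INPUT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"classification input missing columns: {sorted(missing)}")
    labels, ties = [], []
    for row in df.itertuples():
        label, tie = classify_gene(
            row.ratio_chd_2n, row.p_chd_2n,
            row.ratio_case_chd, row.p_case_chd,
            row.ratio_case_2n, row.p_case_2n,
            rules,
        )
        labels.append(label)
        ties.append(tie)
    df["class_label"] = labels
    df["magnitude_tie"] = ties
    counts = {c: int((df["class_label"] == c).sum()) for c in (*CLASS_ORDER, "none")}
    return df, counts
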