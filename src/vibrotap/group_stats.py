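"""Group-level confrontation of VT2 BCI performance with diagnosis labels.

The packaged 12-patient cohort table carries, per patient, the behavioral
(CRS-R) diagnosis (4 MCS-, 8 UWS), the FDG-PET metabolic diagnosis
(6 MCS, 6 UWS), the VT2/VT3 detection percentages and rejected-trial
counts.  Group summaries use the median and the Tukey-hinge interquartile
range: the hinges are the medians of the lower and upper halves of the
sorted data, with the halves including the overall median when n is odd.
Among the common quartile conventions this is the one under which the
cohort's four group IQRs come out as round numbers, and it is the
convention this module standardizes on.

Group differences use the Wilcoxon rank-sum test in its normal
approximation with midranks and tie-corrected variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_patient_table",
    "median_iqr",
    "tukey_hinges",
    "rank_sum",
    "compare_groups",
    "GroupComparison",
]

GROUPING_COLUMNS = {"crsr": "diagnosis_crsr", "fdgpet": "diagnosis_fdgpet"}


def load_patient_table() -> pd.DataFrame:
    """The packaged per-patient cohort table (12 rows)."""
    with resources.files("vibrotap").joinpath("data/patients.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def tukey_hinges(values) -> tuple[float, float]:
    """Lower and upper Tukey hinges (median-inclusive halves)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty input")
    half = (n + 1) // 2
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def median_iqr(values) -> tuple[float, float]:
    """(median, IQR) with the IQR taken between Tukey hinges."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    lo, hi = tukey_hinges(x)
    return float(np.median(x)), hi - lo


def rank_sum(a, b, continuity: bool = False) -> tuple[float, float]:
    """Wilcoxon rank-sum Z and two-sided p (normal approximation).

    Ties get midranks and the variance is tie-corrected; ``continuity``
    applies the 0.5 correction toward zero.  Z is positive when sample
    ``a`` tends to rank higher.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([a, b]))
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 0.0, 1.0
    num = w - mu
    if continuity and num != 0:
        num -= 0.5 * np.sign(num)
    z = num / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class GroupComparison:
    """Per-group medians/IQRs of VT2 performance plus the rank-sum test.

    ``rank_sum_Z`` is computed for the MCS-type group against the UWS
    group (positive Z = MCS ranks higher).
    """

    grouping: str
    group_labels: tuple[str, str]  # (mcs-type label, uws label)
    medians: dict[str, float]
    iqrs: dict[str, float]
    n: dict[str, int]
    rank_sum_Z: float
    p_two_sided: float

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "group_labels": list(self.group_labels),
            "medians": self.medians,
            "iqrs": self.iqrs,
            "n": self.n,
            "rank_sum_Z": self.rank_sum_Z,
            "p_two_sided": self.p_two_sided,
        }


def compare_groups(records: pd.DataFrame | None = None,
                   grouping: str = "crsr") -> GroupComparison:
    """Split VT2 performance by diagnosis and summarize both groups.

    ``grouping='crsr'`` uses the behavioral diagnosis (MCS- vs UWS);
    ``'fdgpet'`` the metabolic one (MCS vs UWS).
    """
    if records is None:
        records = load_patient_table()
    try:
        col = GROUPING_COLUMNS[grouping]
    except KeyError:
        raise ValueError(f"grouping must be one of {sorted(GROUPING_COLUMNS)}")
    if col not in records.columns or "vt2_pct" not in records.columns:
        raise ValueError(f"table needs columns {col!r} and 'vt2_pct'")

    labels = records[col].astype(str)
    uws_mask = labels == "UWS"
    mcs_mask = ~uws_mask
    if not uws_mask.any() or not mcs_mask.any():
        raise ValueError("both diagnosis groups must be non-empty")
    mcs_label = labels[mcs_mask].unique()
    if len(mcs_label) != 1:
        raise ValueError(f"expected two diagnosis levels, got {sorted(set(labels))}")
    mcs_label = mcs_label[0]

    mcs = records.loc[mcs_mask, "vt2_pct"].to_numpy(dtype=float)
    uws = records.loc[uws_mask, "vt2_pct"].to_numpy(dtype=float)
    z, p = rank_sum(mcs, uws)
    med_m, iqr_m = median_iqr(mcs)
    med_u, iqr_u = median_iqr(uws)
    return GroupComparison(
        grouping=grouping,
        group_labels=(mcs_label, "UWS"),
        medians={mcs_label: med_m, "UWS": med_u},
        iqrs={mcs_label: iqr_m, "UWS": iqr_u},
        n={mcs_label: int(mcs_mask.sum()), "UWS": int(uws_mask.sum())},
        rank_sum_Z=z,
        p_two_sided=p,
    )
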