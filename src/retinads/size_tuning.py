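"""Bar-size tuning: amplitude and responsive-fraction summaries across a
bar-width series, with within-group (Friedman + Dunn) and between-group
(Mann-Whitney) rank tests.

Two width series mirror the stimulus design: the small range {2, 5, 10}
pixels and the large range {10, 50, 250} pixels (1 deg of visual angle per
pixel).  Every cell in a series is measured at every width, so the
within-series comparison is paired; all tests are rank-based and hence
invariant to monotone rescaling of the amplitudes.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import grubbs_iterative

__all__ = [
    "SizeTuningTable",
    "build_size_table",
    "within_series_test",
    "between_group_test",
    "dunn_posthoc",
]

SMALL_RANGE_PX = (2.0, 5.0, 10.0)
LARGE_RANGE_PX = (10.0, 50.0, 250.0)


@dataclass
class SizeTuningTable:
    """Long-format amplitude table: one row per (cell, width).

    Columns: ``cell_id, group, animal, width_px, amplitude, responsive``.
    ``fractions`` holds the per-animal responsive fraction at each width
    (responsive cells / imaged cells of that animal).
    """

    data: pd.DataFrame
    widths_px: tuple[float, ...]
    fractions: pd.DataFrame

    def amplitudes(self, group: str, width: float) -> np.ndarray:
        d = self.data
        rows = d[(d["group"] == group) & (d["width_px"] == width) & d["responsive"]]
        return rows["amplitude"].to_numpy(dtype=float)

    def paired_matrix(self, group: str) -> np.ndarray:
        """(n_cells, n_widths) amplitude matrix for cells of one group."""
        wide = (self.data[self.data["group"] == group]
                .pivot(index="cell_id", columns="width_px", values="amplitude")
                .reindex(columns=list(self.widths_px)))
        return wide.to_numpy(dtype=float)


def build_size_table(records: Sequence[Mapping]) -> SizeTuningTable:
    """Assemble a :class:`SizeTuningTable` from per-(cell, width) records.

    Each record needs keys ``cell_id, group, animal, width_px, amplitude,
    responsive``.  Every cell must be measured at every width of its series
    (the within-series test is paired).
    """
    df = pd.DataFrame(list(records))
    required = {"cell_id", "group", "animal", "width_px", "amplitude", "responsive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing keys {sorted(missing)}")
    widths = tuple(sorted(df["width_px"].unique()))
    counts = df.groupby("cell_id")["width_px"].nunique()
    if (counts != len(widths)).any():
        bad = counts[counts != len(widths)].index.tolist()
        raise ValueError(f"cells not measured at every width: {bad}")
    fr = (df.groupby(["group", "animal", "width_px"])["responsive"]
            .mean().rename("responsive_fraction").reset_index())
    return SizeTuningTable(data=df.reset_index(drop=True), widths_px=widths,
                           fractions=fr)


def dunn_posthoc(matrix: np.ndarray, alpha: float = 0.05,
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's multiple-comparisons test after a Friedman omnibus.

    Within-subject ranks (mean-tie ranks per row) are averaged per
    condition; the pairwise statistic is

        z = |Rbar_i - Rbar_j| / sqrt(k (k + 1) / (6 n))

    with k conditions and n subjects, compared against the standard normal;
    p-values are adjusted with the chosen method (default Bonferroni, the
    conventional companion to Dunn's procedure).
    """
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for i, j in combinations(range(k), 2):
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = 2 * stats.norm.sf(z)
        rows.append({"i": i, "j": j, "z": z, "pvalue": p})
    out = pd.DataFrame(rows)
    out["pvalue_adj"] = multipletests(out["pvalue"], method=adjust)[1]
    out["significant"] = out["pvalue_adj"] < alpha
    return out


def within_series_test(table: SizeTuningTable, group: str,
                       alpha: float = 0.05,
                       grubbs_alpha: float | None = None) -> dict:
    """Paired rank comparison of amplitudes across the width series.

    Friedman omnibus over the (cell x width) matrix, followed by Dunn's
    pairwise post hoc when the omnibus rejects.  ``grubbs_alpha`` optionally
    trims cells whose mean amplitude is an iterative-Grubbs outlier before
    testing (mirrors trimming group samples before statistics).
    """
    matrix = table.paired_matrix(group)
    if grubbs_alpha is not None and matrix.shape[0] >= 3:
        means = matrix.mean(axis=1)
        kept, _ = grubbs_iterative(means, grubbs_alpha)
        keep_mask = np.isin(means, kept)
        matrix = matrix[keep_mask]
    n, k = matrix.shape
    if n < 3:
        raise ValueError(f"need >= 3 paired measurements, got {n}")
    if np.all(matrix == matrix[:, :1]):
        # every cell flat across widths: omnibus statistic is 0 by construction
        omnibus_stat, omnibus_p = 0.0, 1.0
    else:
        res = stats.friedmanchisquare(*matrix.T)
        omnibus_stat, omnibus_p = float(res.statistic), float(res.pvalue)
    out = {
        "group": group,
        "n": int(n),
        "widths_px": list(table.widths_px),
        "friedman_statistic": omnibus_stat,
        "friedman_pvalue": omnibus_p,
        "pairwise": None,
    }
    if omnibus_p < alpha:
        pairs = dunn_posthoc(matrix, alpha=alpha)
        pairs = pairs.assign(
            width_i=[table.widths_px[i] for i in pairs["i"]],
            width_j=[table.widths_px[j] for j in pairs["j"]],
        )
        out["pairwise"] = pairs
    return out


def between_group_test(table: SizeTuningTable, width: float,
                       groups: tuple[str, str] | None = None,
                       grubbs_alpha: float | None = None) -> dict:
    """Mann-Whitney comparison of responsive-cell amplitudes at one width."""
    if groups is None:
        labels = sorted(table.data["group"].unique())
        if len(labels) != 2:
            raise ValueError("specify groups when the table has != 2 groups")
        groups = (labels[0], labels[1])
    a = table.amplitudes(groups[0], width)
    b = table.amplitudes(groups[1], width)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"empty group at width {width}")
    if grubbs_alpha is not None:
        a, _ = grubbs_iterative(a, grubbs_alpha)
        b, _ = grubbs_iterative(b, grubbs_alpha)
    underpowered = min(a.size, b.size) < 3
    if a.size == 1 and b.size == 1:
        u, p = float(a[0] > b[0]), 1.0
    else:
        mw = stats.mannwhitneyu(a, b, alternative="two-sided")
        u, p = float(mw.statistic), float(mw.pvalue)
    return {
        "width_px": float(width),
        "groups": groups,
        "n": (int(a.size), int(b.size)),
        "u": u,
        "pvalue": p,
        "median_diff": float(np.median(a) - np.median(b)),
        "underpowered": bool(underpowered),
    }
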