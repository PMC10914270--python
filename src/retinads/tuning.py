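"""Direction tuning: normalized vectors, preferred direction, DSI.

The representative response at each of the sampled motion directions
(default 12, 30 deg apart, 0 deg = leftward) is normalized to the sum over
directions, r_i = a_i / sum_j a_j, and the preferred direction (PD) is the
angle of the vector sum sum_i r_i * u(theta_i).  The direction-selectivity
index is

    DSI = (Pref - Null) / (Pref + Null)

where Pref is the larger of the raw responses at the sampled direction
nearest the PD and at its diametric opposite, and Null the smaller; DSI is
0 for untuned and 1 for fully selective responses, and an ROI is called
direction selective (DS) at DSI >= 0.5.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .response import ResponseCall

__all__ = [
    "DirectionTuning",
    "DsPopulationSummary",
    "compute_tuning",
    "summarize_population",
    "compare_dsi_distributions",
]

logger = logging.getLogger(__name__)

DS_THRESHOLD = 0.5


@dataclass
class DirectionTuning:
    """Direction-tuning summary for one ROI.

    ``preferred_direction_deg`` and ``dsi`` are NaN (and ``is_ds`` False)
    when all responses are zero, where the vector sum is undefined.
    """

    roi_id: str
    directions_deg: np.ndarray
    raw_responses: np.ndarray      # representative dF/F0 per direction, >= 0
    normalized_r: np.ndarray
    preferred_direction_deg: float
    vector_magnitude: float
    pref: float
    null: float
    dsi: float
    is_ds: bool

    @property
    def defined(self) -> bool:
        return not np.isnan(self.dsi)


@dataclass
class DsPopulationSummary:
    """Cohort composition and DSI distribution (donut/cumulative plots)."""

    n_total: int
    n_responsive: int
    n_ds: int
    ds_fraction: float
    dsi_values: np.ndarray
    pd_histogram: np.ndarray       # DS-ROI counts per direction bin
    pd_bin_edges_deg: np.ndarray


def _nearest_direction(directions: np.ndarray, responses: np.ndarray,
                       pd_deg: float) -> int:
    """Index of the sampled direction closest to pd_deg.

    At an exact tie (PD on the boundary between two sampled directions) the
    direction with the larger raw response wins; a further tie goes to the
    smaller angle.
    """
    dist = np.abs((directions - pd_deg + 180.0) % 360.0 - 180.0)
    best = dist.min()
    cand = np.nonzero(np.isclose(dist, best, atol=1e-9))[0]
    if cand.size > 1:
        cand = cand[responses[cand] == responses[cand].max()]
    return int(cand[0])


def compute_tuning(
    responses_by_direction: Mapping[float, float],
    ds_threshold: float = DS_THRESHOLD,
    roi_id: str = "",
) -> DirectionTuning:
    """Compute normalized tuning, vector-sum PD, and DSI for one ROI.

    ``responses_by_direction`` maps direction (degrees) to the
    representative dF/F0 at that direction.  Each direction must have its
    diametric opposite in the set (true for the default 12 at 30 deg).
    Negative responses (possible after noise) are floored at 0 before
    normalization so that sum r_i = 1 and DSI lies in [0, 1].
    """
    if len(responses_by_direction) < 2:
        raise ValueError("need responses at >= 2 directions")
    directions = np.asarray(sorted(responses_by_direction), dtype=float)
    responses = np.asarray([responses_by_direction[d] for d in directions], dtype=float)

    opposite_idx = np.empty(directions.size, dtype=int)
    for i, d in enumerate(directions):
        opp = (d + 180.0) % 360.0
        j = np.nonzero(np.isclose(directions, opp, atol=1e-9))[0]
        if j.size == 0:
            raise ValueError(f"direction {d} deg has no diametric opposite in the set")
        opposite_idx[i] = j[0]

    if np.any(responses < 0):
        logger.info("ROI %s: flooring %d negative responses at 0",
                    roi_id, int((responses < 0).sum()))
        responses = np.clip(responses, 0.0, None)

    total = responses.sum()
    if total == 0:
        nan = float("nan")
        return DirectionTuning(
            roi_id=roi_id, directions_deg=directions, raw_responses=responses,
            normalized_r=np.zeros_like(responses),
            preferred_direction_deg=nan, vector_magnitude=0.0,
            pref=nan, null=nan, dsi=nan, is_ds=False,
        )
    r = responses / total
    theta = np.deg2rad(directions)
    vx = float(np.sum(r * np.cos(theta)))
    vy = float(np.sum(r * np.sin(theta)))
    magnitude = float(np.hypot(vx, vy))
    if magnitude < 1e-12:
        # perfectly balanced tuning: vector sum vanishes and PD is undefined;
        # DSI is still well defined at the strongest direction (0 for flat
        # tuning, and 0 for any symmetric bimodal one)
        near = int(np.flatnonzero(responses == responses.max())[0])
        a, b = responses[near], responses[opposite_idx[near]]
        pref, null = (a, b) if a >= b else (b, a)
        dsi = float((pref - null) / (pref + null)) if pref + null > 0 else 0.0
        return DirectionTuning(
            roi_id=roi_id, directions_deg=directions, raw_responses=responses,
            normalized_r=r, preferred_direction_deg=float("nan"),
            vector_magnitude=0.0, pref=float(pref), null=float(null),
            dsi=dsi, is_ds=bool(dsi >= ds_threshold),
        )
    pd_deg = float(np.rad2deg(np.arctan2(vy, vx)) % 360.0)
    if pd_deg >= 360.0:  # float wrap of a tiny negative angle
        pd_deg = 0.0
    near = _nearest_direction(directions, responses, pd_deg)
    a, b = responses[near], responses[opposite_idx[near]]
    pref, null = (a, b) if a >= b else (b, a)
    dsi = float((pref - null) / (pref + null)) if pref + null > 0 else 0.0
    return DirectionTuning(
        roi_id=roi_id, directions_deg=directions, raw_responses=responses,
        normalized_r=r, preferred_direction_deg=pd_deg,
        vector_magnitude=magnitude, pref=float(pref), null=float(null),
        dsi=dsi, is_ds=bool(dsi >= ds_threshold),
    )


def summarize_population(
    tunings: Sequence[DirectionTuning],
    calls: Sequence[ResponseCall],
    bin_width_deg: float = 30.0,
) -> DsPopulationSummary:
    """Cohort summary: responsive/DS counts, DSI values, PD histogram.

    ``calls`` covers the whole imaged cohort (one per ROI); ``tunings``
    covers the qualified ROIs.  DS fraction is over the total cohort; DSI
    values are restricted to responsive ROIs; the PD histogram bins DS ROIs
    in ``bin_width_deg`` bins.
    """
    qualified_ids = {c.roi_id for c in calls if c.qualified}
    responsive = [t for t in tunings if t.roi_id in qualified_ids]
    ds = [t for t in responsive if t.is_ds]
    edges = np.arange(0.0, 360.0 + bin_width_deg, bin_width_deg)
    # bins centred on the sampled directions: PD within +/- half a bin of a
    # direction falls in that direction's bin
    pds = np.asarray([t.preferred_direction_deg for t in ds
                      if not np.isnan(t.preferred_direction_deg)])
    hist, _ = np.histogram((pds + bin_width_deg / 2) % 360.0, bins=edges)
    n_total = len(calls)
    return DsPopulationSummary(
        n_total=n_total,
        n_responsive=len(responsive),
        n_ds=len(ds),
        ds_fraction=(len(ds) / n_total) if n_total else 0.0,
        dsi_values=np.asarray([t.dsi for t in responsive if t.defined]),
        pd_histogram=hist,
        pd_bin_edges_deg=edges,
    )


def compare_dsi_distributions(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-sample distribution comparison of DSI (or amplitude) values.

    Returns the Kolmogorov-Smirnov statistic/p-value (cumulative-curve
    comparison) and the Mann-Whitney U statistic/p-value (rank-based
    location comparison).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ks = stats.ks_2samp(a, b)
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "mannwhitney_u": float(mw.statistic),
        "mannwhitney_pvalue": float(mw.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
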