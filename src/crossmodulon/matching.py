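"""Cross-omics module matching, DiMM/DiMA comparisons and dominance.

Proteome modules (piModulons) are matched to transcriptome modules
(tiModulons) by the Pearson correlation of their feature-weight vectors
restricted to the shared feature set; |r| >= 0.25 declares a match, and
one proteome module may match several transcriptome modules (a "lumped"
module).  Matched pairs are then compared by

* recall of each other's member sets (DiMM territory),
* replicate-averaged activities across condition-matched samples
  (DiMA): after per-axis standardization, conditions whose activity
  difference falls outside a significance band are "differentially
  activated", and
* a dominance class — transcriptome-dominant, proteome-dominant or
  neutral — from which layer carries the stronger signal at the
  differential conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

MATCH_R_MIN = 0.25
DIMA_BAND_SD = 1.5
DOMINANCE_MAJORITY = 2 / 3


@dataclass
class MatchedPair:
    """One proteome module linked to >= 1 transcriptome modules."""

    pi_index: str
    ti_indices: list
    pearson_r: dict  # ti index -> signed r on shared features
    both_genes: frozenset = frozenset()
    pi_recall: float = float("nan")
    ti_recall: float = float("nan")
    quadrant: str = ""

    @property
    def is_lumped(self) -> bool:
        return len(self.ti_indices) > 1


@dataclass
class DiMAResult:
    conditions: list
    ti_activity: pd.Series
    pi_activity: pd.Series
    differential: list
    correlation: float
    band: float
    diff_std: pd.Series
    dominance: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "ti_activity": self.ti_activity,
                "pi_activity": self.pi_activity,
                "std_difference": self.diff_std,
            }
        )
        df["differential"] = df.index.isin(self.differential)
        return df


def match_components(
    M_t: pd.DataFrame,
    M_p: pd.DataFrame,
    r_min: float = MATCH_R_MIN,
    *,
    members_t: dict | None = None,
    members_p: dict | None = None,
) -> list[MatchedPair]:
    """Match proteome components to transcriptome components by |r|.

    Correlations use only the features shared by the two weight
    matrices; matching is on |r| because component signs are arbitrary.
    Returns one :class:`MatchedPair` per proteome component with at
    least one match; recall fields are filled when member sets are
    supplied.
    """
    shared = M_t.index.intersection(M_p.index)
    if len(shared) == 0:
        raise ValueError("no shared features between the two weight matrices")
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared features; need >= 3")
    Wt = M_t.loc[shared]
    Wp = M_p.loc[shared]
    pairs = []
    for pi in Wp.columns:
        rs = {}
        for ti in Wt.columns:
            wt, wp = Wt[ti].to_numpy(), Wp[pi].to_numpy()
            if np.std(wt) == 0 or np.std(wp) == 0:
                continue
            r = float(np.corrcoef(wt, wp)[0, 1])
            if np.isfinite(r) and abs(r) >= r_min:
                rs[str(ti)] = r
        if not rs:
            continue
        order = sorted(rs, key=lambda t: -abs(rs[t]))
        pair = MatchedPair(pi_index=str(pi), ti_indices=order, pearson_r=rs)
        if members_t is not None and members_p is not None:
            union_ti = frozenset().union(
                *(frozenset(members_t.get(t, ())) for t in order)
            )
            pi_members = frozenset(members_p.get(str(pi), ()))
            pair.pi_recall, pair.ti_recall, pair.both_genes = compute_recall(
                pi_members, union_ti
            )
            pair.quadrant = recall_quadrant(pair.pi_recall, pair.ti_recall)
        pairs.append(pair)
    return pairs


def compute_recall(pi_members, ti_members):
    """(pi_recall, ti_recall, both) for two member sets.

    Recall is |both| over the size of that side's member set; an empty
    side makes its recall undefined (NaN).
    """
    pi_members = frozenset(pi_members)
    ti_members = frozenset(ti_members)
    both = pi_members & ti_members
    pi_recall = len(both) / len(pi_members) if pi_members else float("nan")
    ti_recall = len(both) / len(ti_members) if ti_members else float("nan")
    return pi_recall, ti_recall, frozenset(both)


def recall_quadrant(pi_recall: float, ti_recall: float, split: float = 0.5) -> str:
    """Quadrant label on the (ti_recall, pi_recall) plane at a 0.5 split."""
    if not (np.isfinite(pi_recall) and np.isfinite(ti_recall)):
        return "undefined"
    hi_pi = pi_recall >= split
    hi_ti = ti_recall >= split
    return {
        (True, True): "high/high",
        (True, False): "high-pi/low-ti",
        (False, True): "low-pi/high-ti",
        (False, False): "low/low",
    }[(hi_pi, hi_ti)]


def _replicate_average(A: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Average activity columns over replicates of each condition."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    cond = meta.loc[[c for c in A.columns if c in meta.index], "condition_id"]
    return A[cond.index].T.groupby(cond).mean().T


def dima(
    pair: MatchedPair,
    A_t: pd.DataFrame,
    A_p: pd.DataFrame,
    metadata_t: pd.DataFrame,
    metadata_p: pd.DataFrame,
    band: float = DIMA_BAND_SD,
    *,
    standardize: bool = True,
    relative: bool = False,
) -> DiMAResult:
    """Differential iModulon Activity comparison for one matched pair.

    Activities are replicate-averaged per condition; only conditions
    present in both compendia are used.  For a lumped pair the
    transcriptome activity is the sign-aligned sum of the matched
    transcriptome components.  After per-axis standardization (optional)
    a condition is differential when |pi - ti| exceeds ``band`` in
    standardized-activity units; with ``relative=True`` the band is
    instead ``band`` standard deviations of the per-condition
    difference series (a self-normalising rule that always flags a
    fixed tail even for identical series — use with care).
    """
    At = _replicate_average(A_t, metadata_t)
    Ap = _replicate_average(A_p, metadata_p)
    conditions = [c for c in At.columns if c in Ap.columns]
    if len(conditions) < 3:
        raise ValueError(
            f"only {len(conditions)} condition-matched samples; need >= 3"
        )
    # sign-align each matched ti component with the pi component before summing
    ti = sum(
        np.sign(pair.pearson_r[t]) * At.loc[t, conditions] for t in pair.ti_indices
    )
    pi = Ap.loc[pair.pi_index, conditions]
    if standardize:
        ti_std = (ti - ti.mean()) / (ti.std(ddof=0) or 1.0)
        pi_std = (pi - pi.mean()) / (pi.std(ddof=0) or 1.0)
    else:
        ti_std, pi_std = ti, pi
    diff = pi_std - ti_std
    scale = diff.std(ddof=0) if relative else 1.0
    if np.isfinite(band) and scale > 0:
        differential = list(diff.index[np.abs(diff) > band * scale])
    else:
        differential = []
    if ti.std(ddof=0) > 0 and pi.std(ddof=0) > 0:
        corr = float(scipy.stats.pearsonr(ti, pi)[0])
    else:
        corr = float("nan")
    res = DiMAResult(
        conditions=conditions,
        ti_activity=ti,
        pi_activity=pi,
        differential=differential,
        correlation=corr,
        band=band,
        diff_std=diff,
    )
    res.dominance = classify_dominance(
        res, ti_std=ti_std, pi_std=pi_std
    )
    return res


def classify_dominance(
    dima_result: DiMAResult,
    *,
    ti_std: pd.Series | None = None,
    pi_std: pd.Series | None = None,
    majority: float = DOMINANCE_MAJORITY,
) -> str:
    """Dominance class from the differential conditions of a DiMA result.

    Each differential condition sides with the layer whose standardized
    activity deviates more from its own mean; a >= 2/3 majority on one
    side names that layer dominant, anything else (including no
    differential conditions) is neutral.
    """
    diffs = dima_result.differential
    if not diffs:
        return "neutral"
    if ti_std is None or pi_std is None:
        ti = dima_result.ti_activity
        pi = dima_result.pi_activity
        ti_std = (ti - ti.mean()) / (ti.std(ddof=0) or 1.0)
        pi_std = (pi - pi.mean()) / (pi.std(ddof=0) or 1.0)
    ti_side = sum(1 for c in diffs if abs(ti_std[c]) > abs(pi_std[c]))
    pi_side = len(diffs) - ti_side
    if ti_side / len(diffs) >= majority:
        return "transcriptome-dominant"
    if pi_side / len(diffs) >= majority:
        return "proteome-dominant"
    return "neutral"


def dimm_table(
    pair: MatchedPair,
    M_t: pd.DataFrame,
    M_p: pd.DataFrame,
    members_t: dict,
    members_p: dict,
) -> pd.DataFrame:
    """Differential iModulon Membership table for one matched pair.

    One row per shared feature: the two weights (transcriptome weight
    summed over matched components, sign-aligned so the correlation is
    positive), and membership flags on each side and in both.
    """
    shared = M_t.index.intersection(M_p.index)
    ti_w = sum(
        np.sign(pair.pearson_r[t]) * M_t.loc[shared, t] for t in pair.ti_indices
    )
    pi_w = M_p.loc[shared, pair.pi_index]
    ti_members = frozenset().union(
        *(frozenset(members_t.get(t, ())) for t in pair.ti_indices)
    )
    pi_members = frozenset(members_p.get(pair.pi_index, ()))
    df = pd.DataFrame(
        {
            "ti_weight": ti_w,
            "pi_weight": pi_w,
            "in_ti": shared.isin(ti_members),
            "in_pi": shared.isin(pi_members),
        },
        index=shared,
    )
    df["in_both"] = df["in_ti"] & df["in_pi"]
    return df


def match_table(pairs: list[MatchedPair], dima_results: dict | None = None) -> pd.DataFrame:
    """Flat match-summary table (one row per pi-ti link)."""
    rows = []
    for pair in pairs:
        dom = (
            dima_results[pair.pi_index].dominance
            if dima_results and pair.pi_index in dima_results
            else ""
        )
        for ti in pair.ti_indices:
            rows.append(
                {
                    "pi": pair.pi_index,
                    "ti": ti,
                    "pearson_r": pair.pearson_r[ti],
                    "n_both": len(pair.both_genes),
                    "pi_recall": pair.pi_recall,
                    "ti_recall": pair.ti_recall,
                    "quadrant": pair.quadrant,
                    "lumped": pair.is_lumped,
                    "dominance": dom,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pi", "ti", "pearson_r", "n_both", "pi_recall",
            "ti_recall", "quadrant", "lumped", "dominance",
        ],
    )


def matched_subset(
    X_t: pd.DataFrame,
    metadata_t: pd.DataFrame,
    shared_features,
    matched_conditions,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict a transcriptome compendium to proteome-covered features
    and condition-matched samples, for recomputing the decomposition on
    the matched subset."""
    meta = metadata_t.set_index("sample_id", drop=False)
    keep_features = [f for f in X_t.index if f in set(shared_features)]
    matched_conditions = set(matched_conditions)
    keep_samples = [
        s
        for s in X_t.columns
        if s in meta.index and meta.loc[s, "condition_id"] in matched_conditions
    ]
    if not keep_features or not keep_samples:
        raise ValueError("matched subset is empty")
    return X_t.loc[keep_features, keep_samples], meta.loc[keep_samples]
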