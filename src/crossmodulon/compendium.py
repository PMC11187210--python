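"""Compendium assembly: coverage filtering, imputation, log transform,
replicate QC and reference centering.

The compilation order is fixed: features observed in fewer than half the
samples of the concatenated multi-batch table are removed; remaining
missing cells are imputed with the global minimum observed abundance;
per-sample fractions are rescaled to parts-per-million and transformed
log2(PPM + 1); replicate groups with pairwise squared Pearson
correlation below 0.9 are pruned; finally each batch is centered on the
mean log profile of its common reference condition, removing batch
offsets while preserving within-batch contrasts exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = ["sample_id", "condition_id", "replicate", "batch", "is_reference"]


@dataclass
class CompileReport:
    features_dropped: list = field(default_factory=list)
    samples_dropped: list = field(default_factory=list)
    global_min: float | None = None
    notices: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "features_dropped": list(self.features_dropped),
            "samples_dropped": list(self.samples_dropped),
            "global_min": self.global_min,
            "notices": list(self.notices),
        }


def validate_metadata(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Check metadata covers the matrix columns exactly once each."""
    meta = metadata.copy()
    if "sample_id" not in meta.columns:
        raise ValueError("metadata needs a sample_id column")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dup}")
    meta = meta.set_index("sample_id", drop=False)
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    if "batch" not in meta.columns:
        meta["batch"] = "batch0"
    if "is_reference" not in meta.columns:
        raise ValueError("metadata needs an is_reference column")
    meta["is_reference"] = meta["is_reference"].astype(bool)
    if not meta.loc[list(matrix.columns), "is_reference"].any():
        raise ValueError("no sample flagged is_reference")
    return meta.loc[list(matrix.columns)]


def filter_low_coverage(
    raw: pd.DataFrame, min_fraction: float = 0.5, report: CompileReport | None = None
) -> pd.DataFrame:
    """Drop features observed in fewer than ``min_fraction`` of samples.

    Removal is strictly-less-than: a feature observed in exactly half
    the samples is retained.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    coverage = raw.notna().mean(axis=1)
    keep = coverage >= min_fraction
    if not keep.any():
        raise ValueError(
            f"coverage filter removed all {len(raw)} features "
            f"(min_fraction={min_fraction})"
        )
    if report is not None:
        report.features_dropped.extend(raw.index[~keep].tolist())
    return raw.loc[keep]


def impute_missing_min(
    matrix: pd.DataFrame, report: CompileReport | None = None
) -> pd.DataFrame:
    """Replace missing cells with the global minimum observed value."""
    values = matrix.to_numpy(dtype=float)
    observed = np.isfinite(values)
    if not observed.any():
        raise ValueError("cannot impute: no observed values")
    global_min = float(values[observed].min())
    if report is not None:
        report.global_min = global_min
    return matrix.fillna(global_min)


def log_transform_ppm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Fractions -> log2(1e6 * fraction + 1)."""
    values = matrix.to_numpy(dtype=float)
    if np.nanmin(values) < 0:
        raise ValueError("fractions must be nonnegative")
    return pd.DataFrame(
        np.log2(1e6 * values + 1.0), index=matrix.index, columns=matrix.columns
    )


def _pairwise_r2(matrix: pd.DataFrame, a: str, b: str) -> float:
    r = np.corrcoef(matrix[a].to_numpy(), matrix[b].to_numpy())[0, 1]
    return float(r**2) if np.isfinite(r) else 0.0


def filter_replicates(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    r2_min: float = 0.9,
    drop_whole_group: bool = False,
    report: CompileReport | None = None,
):
    """Remove technically noisy replicates.

    For each condition, pairwise squared Pearson correlations between
    replicate columns are computed.  A two-member group below ``r2_min``
    is dropped whole.  In larger groups the group statistic is the
    minimum pairwise R2 and, unless ``drop_whole_group``, individual
    samples are removed greedily (worst mean-R2 first) until the minimum
    pairwise R2 of the survivors clears the threshold.

    Returns (matrix, metadata, dropped sample list).
    """
    meta = validate_metadata(matrix, metadata)
    dropped: list[str] = []
    notices: list[str] = []
    for condition, grp in meta.groupby("condition_id", sort=False):
        samples = [s for s in grp["sample_id"] if s in matrix.columns]
        if len(samples) < 2:
            notices.append(f"condition {condition}: singleton, not checked")
            continue
        current = list(samples)
        while len(current) >= 2:
            pairs = {
                (a, b): _pairwise_r2(matrix, a, b)
                for a, b in itertools.combinations(current, 2)
            }
            if min(pairs.values()) >= r2_min:
                break
            if len(current) == 2 or drop_whole_group:
                dropped.extend(current)
                notices.append(
                    f"condition {condition}: replicate group R2 "
                    f"{min(pairs.values()):.3f} < {r2_min}, group removed"
                )
                current = []
            else:
                mean_r2 = {
                    s: np.mean([v for k, v in pairs.items() if s in k])
                    for s in current
                }
                worst = min(mean_r2, key=mean_r2.get)
                dropped.append(worst)
                notices.append(
                    f"condition {condition}: sample {worst} removed "
                    f"(restores replicate R2)"
                )
                current.remove(worst)
    keep = [s for s in matrix.columns if s not in set(dropped)]
    if report is not None:
        report.samples_dropped.extend(dropped)
        report.notices.extend(notices)
    return matrix[keep], meta.loc[keep], dropped


def center_to_reference(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Subtract each batch's mean reference profile from its samples."""
    meta = validate_metadata(matrix, metadata)
    out = matrix.astype(float).copy()
    for batch, grp in meta.groupby("batch", sort=False):
        cols = [s for s in grp["sample_id"] if s in matrix.columns]
        ref_cols = [s for s in cols if bool(meta.loc[s, "is_reference"])]
        if not ref_cols:
            raise ValueError(f"batch {batch!r} has no reference-condition samples")
        ref_profile = matrix[ref_cols].mean(axis=1)
        out[cols] = matrix[cols].sub(ref_profile, axis=0)
    return out


def replicate_correlation_histogram(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    n_random_pairs: int = 1000,
    seed: int = 0,
):
    """Pearson correlations of replicate pairs vs random non-replicate pairs.

    Returns (replicate_correlations, random_correlations) as arrays;
    the two distributions are what the compendium-quality histogram
    plots.
    """
    meta = validate_metadata(matrix, metadata)
    rep_pairs = []
    for _, grp in meta.groupby("condition_id", sort=False):
        samples = [s for s in grp["sample_id"] if s in matrix.columns]
        rep_pairs.extend(itertools.combinations(samples, 2))
    if len(rep_pairs) < 1:
        raise ValueError("need at least one replicate pair")
    condition_of = meta["condition_id"].to_dict()
    rep_r = np.array(
        [np.corrcoef(matrix[a], matrix[b])[0, 1] for a, b in rep_pairs]
    )
    rng = np.random.default_rng(seed)
    cols = list(matrix.columns)
    rand_r = []
    attempts = 0
    while len(rand_r) < n_random_pairs and attempts < 50 * max(n_random_pairs, 1):
        a, b = rng.choice(len(cols), size=2, replace=False)
        attempts += 1
        if condition_of[cols[a]] == condition_of[cols[b]]:
            continue
        rand_r.append(np.corrcoef(matrix[cols[a]], matrix[cols[b]])[0, 1])
    return rep_r, np.array(rand_r)


def compile_compendium(
    raw: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    min_coverage: float = 0.5,
    r2_min: float = 0.9,
    already_fractions: bool = True,
    center: bool = True,
):
    """Run the full compilation pipeline on a raw abundance table.

    ``raw`` holds per-sample abundances or mass fractions (with
    missingness); the output is a complete, finite, log2(PPM+1),
    reference-centered matrix plus the filtered metadata and a report.
    """
    report = CompileReport()
    mat = filter_low_coverage(raw, min_coverage, report)
    mat = impute_missing_min(mat, report)
    if not already_fractions:
        mat = mat.div(mat.sum(axis=0), axis=1)
    else:
        # re-normalise: coverage filtering and imputation perturb the totals
        mat = mat.div(mat.sum(axis=0), axis=1)
    logged = log_transform_ppm(mat)
    logged, meta, _ = filter_replicates(logged, metadata, r2_min, report=report)
    if center:
        logged = center_to_reference(logged, meta)
    assert np.isfinite(logged.to_numpy()).all()
    return logged, meta, report
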