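"""Absolute protein quantification from top3 intensities.

Label-free top3 summaries (mean of the three highest peptide areas per
protein) are calibrated against a UPS2 spike-in standard of proteins at
known amounts.  Calibration is ordinary least squares in log10 space,

    log10(A) = a + b * log10(top3),

fit per sample because each sample carries its own spike.  Calibrated
amounts are converted to concentrations per gram dry weight by
normalising each sample to a fixed total protein budget

    C_i = gamma * A_i / sum_j A_j,      gamma = 13.94 umol/gDW,

so every sample's concentrations sum to gamma exactly.  Mass fractions
(A_i / sum_j A_j) are what downstream modules consume; the gamma-scaled
concentration is retained for reporting.

Missing values mean "not observed" and are never treated as zero here;
imputation happens later, after coverage filtering, in
:mod:`crossmodulon.compendium`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

#: Total protein budget per gram dry weight (umol/gDW).
GAMMA_UMOL_PER_GDW = 13.94


@dataclass(frozen=True)
class CalibrationModel:
    """OLS calibration of log10(amount) on log10(top3) for one sample."""

    intercept_a: float
    slope_b: float
    fit_r2: float
    n_points: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope_b) or self.slope_b == 0:
            raise ValueError("calibration slope must be finite and nonzero")
        if not (0.0 <= self.fit_r2 <= 1.0 + 1e-12):
            raise ValueError(f"fit_r2 must lie in [0, 1], got {self.fit_r2}")
        if self.n_points < 3:
            raise ValueError("calibration needs at least 3 standards")

    def predict_amount(self, top3: np.ndarray | float) -> np.ndarray | float:
        """Map top3 intensity to calibrated amount, 10**(a + b*log10(top3))."""
        return 10.0 ** (self.intercept_a + self.slope_b * np.log10(top3))

    def to_dict(self) -> dict:
        return {
            "a": self.intercept_a,
            "b": self.slope_b,
            "r2": self.fit_r2,
            "n": self.n_points,
        }


def fit_ups2_calibration(
    standard_amounts, standard_top3, standard_ids=None
) -> CalibrationModel:
    """Fit the UPS2 top3 calibration for one sample.

    Parameters
    ----------
    standard_amounts, standard_top3
        Spiked amounts and observed top3 intensities of the standards,
        strictly positive, same length >= 3.
    standard_ids
        Optional identifiers used in error messages.

    Returns
    -------
    CalibrationModel
    """
    amounts = np.asarray(standard_amounts, dtype=float)
    top3 = np.asarray(standard_top3, dtype=float)
    if amounts.shape != top3.shape:
        raise ValueError(
            f"length mismatch: {amounts.size} amounts vs {top3.size} top3 values"
        )
    if amounts.size < 3:
        raise ValueError("calibration needs at least 3 standards")
    ids = (
        list(standard_ids)
        if standard_ids is not None
        else [f"standard_{i}" for i in range(amounts.size)]
    )
    for name, values in (("amount", amounts), ("top3", top3)):
        bad = np.flatnonzero(~(values > 0) | ~np.isfinite(values))
        if bad.size:
            raise ValueError(
                f"nonpositive {name} for standard {ids[bad[0]]!r}: {values[bad[0]]}"
            )
    res = scipy.stats.linregress(np.log10(top3), np.log10(amounts))
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return CalibrationModel(
        intercept_a=float(res.intercept),
        slope_b=float(res.slope),
        fit_r2=min(r2, 1.0),
        n_points=int(amounts.size),
    )


@dataclass
class CalibrationSet:
    """Per-sample calibrations plus an optional pooled fallback.

    The default workflow fits one model per sample (each carries its own
    UPS2 spike); ``pooled`` concatenates all standards into a single fit
    for samples whose own calibration is poor or absent.
    """

    per_sample: dict[str, CalibrationModel] = field(default_factory=dict)
    pooled: CalibrationModel | None = None
    r2_warn: float = 0.9
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def fit(
        cls,
        ups2: pd.DataFrame,
        *,
        mode: str = "per_sample",
        r2_warn: float = 0.9,
    ) -> "CalibrationSet":
        """Fit calibrations from a long UPS2 table.

        ``ups2`` needs columns ``protein_id``, ``spiked_amount``, ``top3``
        and, for per-sample mode, ``sample_id``.
        """
        required = {"protein_id", "spiked_amount", "top3"}
        missing = required - set(ups2.columns)
        if missing:
            raise ValueError(f"UPS2 table missing columns: {sorted(missing)}")
        obj = cls(r2_warn=r2_warn)
        obj.pooled = fit_ups2_calibration(
            ups2["spiked_amount"], ups2["top3"], ups2["protein_id"]
        )
        if mode == "per_sample":
            if "sample_id" not in ups2.columns:
                raise ValueError("per-sample calibration needs a sample_id column")
            for sample, grp in ups2.groupby("sample_id"):
                model = fit_ups2_calibration(
                    grp["spiked_amount"], grp["top3"], grp["protein_id"]
                )
                if model.fit_r2 < r2_warn:
                    obj.warnings.append(
                        f"sample {sample}: calibration r2={model.fit_r2:.3f} "
                        f"below {r2_warn}"
                    )
                obj.per_sample[str(sample)] = model
        elif mode != "pooled":
            raise ValueError(f"unknown calibration mode {mode!r}")
        return obj

    def for_sample(self, sample_id: str) -> CalibrationModel:
        return self.per_sample.get(str(sample_id)) or self.pooled

    def report(self) -> dict:
        rep = {s: m.to_dict() for s, m in self.per_sample.items()}
        if self.pooled is not None:
            rep["__pooled__"] = self.pooled.to_dict()
        return rep

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=2)


def apply_calibration(
    top3_table: pd.DataFrame, model: CalibrationModel | CalibrationSet
) -> pd.DataFrame:
    """Convert a proteins x samples top3 table to calibrated amounts.

    Missing cells stay missing.  Observed zeros cannot be calibrated in
    log space and are flagged unquantifiable (left missing).
    """
    top3 = top3_table.astype(float)
    if (top3 < 0).any().any():
        raise ValueError("top3 intensities must be nonnegative where observed")
    quantifiable = top3 > 0
    amounts = pd.DataFrame(
        np.nan, index=top3.index, columns=top3.columns, dtype=float
    )
    for col in top3.columns:
        m = model.for_sample(col) if isinstance(model, CalibrationSet) else model
        mask = quantifiable[col]
        amounts.loc[mask, col] = m.predict_amount(top3.loc[mask, col].to_numpy())
    return amounts


def to_mass_concentration(
    amounts: pd.DataFrame, gamma: float = GAMMA_UMOL_PER_GDW
) -> pd.DataFrame:
    """Scale calibrated amounts to concentrations summing to gamma per sample."""
    return gamma * to_mass_fractions(amounts)


def to_mass_fractions(amounts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample normalisation A_i / sum_j A_j over observed proteins."""
    amounts = amounts.astype(float)
    totals = amounts.sum(axis=0, skipna=True)
    empty = totals[~(totals > 0)]
    if len(empty):
        raise ValueError(
            f"sample(s) with no positive amounts: {list(empty.index)}"
        )
    return amounts.div(totals, axis=1)


def top3_from_peptides(peptide_areas: pd.DataFrame) -> pd.DataFrame:
    """Roll peptide areas up to protein top3 metrics.

    ``peptide_areas`` is a long table with columns ``protein_id``,
    ``sample_id``, ``area``; the top3 metric is the mean of the three
    highest peptide areas per protein per sample (fewer peptides: mean
    of what is there).
    """
    required = {"protein_id", "sample_id", "area"}
    if not required <= set(peptide_areas.columns):
        raise ValueError(f"peptide table needs columns {sorted(required)}")
    top3 = (
        peptide_areas.groupby(["protein_id", "sample_id"])["area"]
        .apply(lambda v: float(np.sort(v.to_numpy())[::-1][:3].mean()))
        .unstack("sample_id")
    )
    top3.index.name = "protein_id"
    return top3
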