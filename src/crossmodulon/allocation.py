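"""Proteome-allocation regression on transcriptome module activities.

For each transcriptome module, the proteome mass fraction summed over
its member genes (replicate-averaged per condition) is regressed on
the module's activity.  Three regression families compete:

* linear            y = m x + c                       (2 parameters)
* exponential       y = c + a exp(b x)                (3 parameters)
* broken line       y = b0 + b1 x + b2 (x - t)+       (4 parameters,
                    continuous two-segment piecewise linear with
                    breakpoint t chosen by exhaustive interior search)

The family is selected by leave-one-out cross-validation: the one with
the lowest mean absolute error over held-out conditions wins (ties go
to the simpler family).  The winner is refit on all conditions and
labelled strong when its adjusted R^2 = 1 - (1-R^2)(n-1)/(n-p-1)
reaches 0.3, which corrects for the differing parameter counts.

``AllocationModel(x, y).fit()`` returns an :class:`AllocationFit`
results object; ``holdout_sweep`` probes robustness with 10-30% random
holdouts on top of the LOOCV selection.  ``summarize_allocation``
assigns genes to strong / weak / invariant / other groups sequentially
(each gene counted once, best models first) for the proteome-allocation
treemap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

FAMILIES = ("linear", "exponential", "broken_line")
FAMILY_N_PARAMS = {"linear": 2, "exponential": 3, "broken_line": 4}
MIN_POINTS = {"linear": 6, "exponential": 6, "broken_line": 8}
STRONG_ADJ_R2 = 0.3


class FitError(RuntimeError):
    """A regression family could not be fit on the given data."""


# ---------------------------------------------------------------- families


def _fit_linear(x: np.ndarray, y: np.ndarray) -> dict:
    slope, intercept = np.polyfit(x, y, 1)
    return {"slope": float(slope), "intercept": float(intercept)}


def _predict_linear(params: dict, x: np.ndarray) -> np.ndarray:
    return params["slope"] * x + params["intercept"]


def _exp_profile_sse(b: float, x: np.ndarray, y: np.ndarray):
    """SSE of y ~ c + a exp(b x) with (c, a) solved by least squares."""
    e = np.exp(np.clip(b * x, -700.0, 700.0))
    design = np.column_stack([np.ones_like(x), e])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = design @ coef - y
    return float(resid @ resid), coef


def _fit_exponential(x: np.ndarray, y: np.ndarray) -> dict:
    """y = c + a exp(b x) by separable (profiled) least squares.

    For fixed rate b the model is linear in (c, a), so the fit reduces
    to a 1-D search over b: a coarse grid seeded with the log-linear
    rate estimate, refined by bounded scalar minimisation around the
    best bracket.  Rates are bounded so exp stays finite over the
    observed activity range.
    """
    span = np.ptp(x)
    if span == 0:
        raise FitError("constant activity series")
    b_max = 50.0 / span
    grid = list(np.linspace(-b_max, b_max, 81))
    # log-linear initial estimates (both orientations) join the grid
    eps = 1e-9 + 1e-3 * (np.ptp(y) if np.ptp(y) > 0 else 1.0)
    for sign in (+1.0, -1.0):
        z = sign * (y - (y.min() if sign > 0 else y.max())) + eps
        with np.errstate(all="ignore"):
            try:
                b0 = float(np.polyfit(x, np.log(z), 1)[0])
            except Exception:
                continue
        if np.isfinite(b0):
            grid.append(float(np.clip(b0, -b_max, b_max)))
    grid = sorted(set(b for b in grid if abs(b) > 1e-12 / max(span, 1.0)))
    sses = [_exp_profile_sse(b, x, y)[0] for b in grid]
    i = int(np.argmin(sses))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = scipy.optimize.minimize_scalar(
        lambda b: _exp_profile_sse(b, x, y)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10 * max(1.0, b_max)},
    )
    b = float(res.x) if res.fun <= sses[i] else grid[i]
    sse, (c, a) = _exp_profile_sse(b, x, y)
    if not np.isfinite(sse):
        raise FitError("exponential fit did not converge")
    return {"offset": float(c), "scale": float(a), "rate": b}


def _predict_exponential(params: dict, x: np.ndarray) -> np.ndarray:
    return params["offset"] + params["scale"] * np.exp(
        np.clip(params["rate"] * x, -700, 700)
    )


def _breakpoint_candidates(x: np.ndarray, min_side: int = 2) -> np.ndarray:
    """Interior observed x values with >= min_side points strictly on
    each side."""
    xs = np.unique(x)
    out = []
    for t in xs:
        if (x < t).sum() >= min_side and (x > t).sum() >= min_side:
            out.append(t)
    return np.asarray(out)


def _fit_broken_line(x: np.ndarray, y: np.ndarray) -> dict:
    """Continuous two-segment piecewise linear fit.

    For each candidate breakpoint t (exhaustive over interior observed
    x), the model is linear in (1, x, (x-t)+) and solved by least
    squares; the breakpoint with minimal SSE wins.
    """
    cands = _breakpoint_candidates(x)
    if cands.size == 0:
        raise FitError("no interior breakpoint candidates")
    best = None
    ones = np.ones_like(x)
    for t in cands:
        design = np.column_stack([ones, x, np.maximum(x - t, 0.0)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(((design @ coef - y) ** 2).sum())
        if best is None or sse < best[0] - 1e-15:
            best = (sse, t, coef)
    _, t, (b0, b1, b2) = best
    return {
        "breakpoint": float(t),
        "intercept": float(b0),
        "left_slope": float(b1),
        "right_slope": float(b1 + b2),
    }


def _predict_broken_line(params: dict, x: np.ndarray) -> np.ndarray:
    t = params["breakpoint"]
    b2 = params["right_slope"] - params["left_slope"]
    return (
        params["intercept"]
        + params["left_slope"] * x
        + b2 * np.maximum(x - t, 0.0)
    )


_FIT = {
    "linear": _fit_linear,
    "exponential": _fit_exponential,
    "broken_line": _fit_broken_line,
}
_PREDICT = {
    "linear": _predict_linear,
    "exponential": _predict_exponential,
    "broken_line": _predict_broken_line,
}


def fit_family(x, y, family: str):
    """Fit one regression family; returns (params, in-sample R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < MIN_POINTS[family]:
        raise ValueError(
            f"{family} needs >= {MIN_POINTS[family]} conditions, got {x.size}"
        )
    params = _FIT[family](x, y)
    return params, _r2(y, predict_family(params, x, family))


def predict_family(params: dict, x, family: str) -> np.ndarray:
    return _PREDICT[family](params, np.asarray(x, dtype=float))


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if np.allclose(pred, y) else 0.0
    return 1.0 - float(((y - pred) ** 2).sum()) / ss_tot


def adjusted_r2(r2: float, n: int, n_params: int) -> float:
    denom = n - n_params - 1
    if denom <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / denom


def normalized_cv_error(y_pred, y_test, y_avg: float) -> np.ndarray:
    """|y_pred - y_test| / y_avg, elementwise."""
    if not y_avg > 0:
        raise ValueError("y_avg must be positive")
    return np.abs(np.asarray(y_pred, float) - np.asarray(y_test, float)) / y_avg


# ----------------------------------------------------------- model/results


@dataclass
class AllocationFit:
    """Results of LOOCV family selection for one module."""

    ti_index: str
    family: str
    parameters: dict
    loocv_mae: float
    loocv_predictions: np.ndarray
    normalized_errors: np.ndarray
    r2: float
    adjusted_r2: float
    n: int
    family_maes: dict = field(default_factory=dict)
    notices: list = field(default_factory=list)

    @property
    def strength(self) -> str:
        return "strong" if self.adjusted_r2 >= STRONG_ADJ_R2 else "weak"

    def predict(self, x) -> np.ndarray:
        return predict_family(self.parameters, x, self.family)

    def summary(self) -> str:
        lines = [
            f"Allocation regression: {self.ti_index}",
            f"  family          {self.family}",
            f"  n conditions    {self.n}",
            f"  LOOCV MAE       {self.loocv_mae:.6g}",
            f"  R^2 / adj R^2   {self.r2:.4f} / {self.adjusted_r2:.4f}",
            f"  strength        {self.strength}",
            "  parameters      "
            + ", ".join(f"{k}={v:.6g}" for k, v in self.parameters.items()),
            "  LOOCV MAE by family  "
            + ", ".join(f"{f}={m:.6g}" for f, m in self.family_maes.items()),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "ti": self.ti_index,
            "family": self.family,
            "parameters": self.parameters,
            "loocv_mae": self.loocv_mae,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "strength": self.strength,
            "n": self.n,
        }


class AllocationModel:
    """Activity -> mass-fraction regression model for one module.

    Parameters
    ----------
    x, y
        Replicate-averaged module activity and summed member mass
        fraction per condition, same length.
    name
        Module identifier carried into the results.
    families
        Families to compete (default all three).
    """

    def __init__(
        self, x, y, name: str = "module", families=FAMILIES, se_margin: float = 1.0
    ):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.size != self.y.size:
            raise ValueError("x and y must have the same length")
        self.name = str(name)
        self.families = tuple(families)
        self.se_margin = float(se_margin)

    def fit(self) -> AllocationFit:
        """LOOCV family selection, refit on all conditions.

        The lowest-MAE family wins, except that a simpler family whose
        held-out errors are within ``se_margin`` standard errors of the
        best family's (the one-standard-error parsimony rule; the
        exponential and broken-line families nest the linear one, so
        plain argmin over-selects them on truly linear data) is
        preferred.  ``se_margin=0`` gives plain argmin with exact ties
        going to the simpler family.
        """
        n = self.x.size
        notices = []
        maes: dict[str, float] = {}
        preds: dict[str, np.ndarray] = {}
        for family in self.families:
            if n < MIN_POINTS[family]:
                notices.append(f"{family}: needs >= {MIN_POINTS[family]} points")
                continue
            try:
                pred = self._loocv_predict(family)
            except FitError as exc:
                notices.append(f"{family}: {exc}")
                continue
            preds[family] = pred
            maes[family] = float(np.abs(pred - self.y).mean())
        if not maes:
            raise FitError(f"{self.name}: no family could be fit ({notices})")
        best = min(maes, key=maes.get)
        family = best
        for f in FAMILIES:  # simplest first: linear < exponential < broken_line
            if f not in maes:
                continue
            if f == best:
                break
            d = np.abs(preds[f] - self.y) - np.abs(preds[best] - self.y)
            se = float(d.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
            if d.mean() <= self.se_margin * se + 1e-12 * maes[best]:
                family = f
                break
        params, r2 = fit_family(self.x, self.y, family)
        y_avg = float(self.y.mean())
        norm_err = (
            normalized_cv_error(preds[family], self.y, y_avg)
            if y_avg > 0
            else np.full(n, np.nan)
        )
        return AllocationFit(
            ti_index=self.name,
            family=family,
            parameters=params,
            loocv_mae=maes[family],
            loocv_predictions=preds[family],
            normalized_errors=norm_err,
            r2=r2,
            adjusted_r2=adjusted_r2(r2, n, FAMILY_N_PARAMS[family]),
            n=n,
            family_maes=maes,
            notices=notices,
        )

    def _loocv_predict(self, family: str) -> np.ndarray:
        n = self.x.size
        pred = np.empty(n)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            params = _FIT[family](self.x[mask], self.y[mask])
            pred[i] = predict_family(params, self.x[i : i + 1], family)[0]
            mask[i] = True
        return pred


def select_model_loocv(x, y, name: str = "module") -> AllocationFit:
    """Functional wrapper: LOOCV family selection on one series pair."""
    return AllocationModel(x, y, name).fit()


def module_mass_fraction(
    ti_members,
    proteome_fractions: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-condition proteome mass fraction summed over a module's genes.

    ``proteome_fractions`` is proteins x samples on the raw fraction
    scale; with ``metadata`` supplied, columns are replicate-averaged
    per condition first.
    """
    covered = [g for g in ti_members if g in proteome_fractions.index]
    if not covered:
        raise ValueError("module has no genes covered by the proteome")
    frac = proteome_fractions
    if metadata is not None:
        meta = (
            metadata.set_index("sample_id")
            if "sample_id" in metadata.columns
            else metadata
        )
        cond = meta.loc[[c for c in frac.columns if c in meta.index], "condition_id"]
        frac = frac[cond.index].T.groupby(cond).mean().T
    return frac.loc[covered].sum(axis=0)


def holdout_sweep(
    x,
    y,
    fractions=(0.10, 0.15, 0.20, 0.25, 0.30),
    n_repeats: int = 10,
    seed: int = 0,
    name: str = "module",
) -> pd.DataFrame:
    """Robustness sweep: random holdouts on top of LOOCV selection.

    For each holdout fraction and repeat, a random test set of size
    round-half-up(n * fraction) is held out, LOOCV family selection runs
    on the training set, and the refit model is scored on the test set.
    Per-(fraction, repeat) seeds derive deterministically from ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rows = []
    for fi, frac in enumerate(sorted(fractions)):
        if not 0 < frac < 1:
            raise ValueError("holdout fractions must lie in (0, 1)")
        n_test = int(math.floor(n * frac + 0.5))
        n_train = n - n_test
        if n_train < MIN_POINTS["broken_line"]:
            raise ValueError(
                f"fraction {frac}: training set of {n_train} too small"
            )
        for rep in range(n_repeats):
            rng = np.random.default_rng((seed * 1000 + fi * 100 + rep) % 2**31)
            for _ in range(20):
                test_idx = rng.choice(n, size=n_test, replace=False)
                train_mask = np.ones(n, dtype=bool)
                train_mask[test_idx] = False
                if np.unique(x[train_mask]).size >= 3:
                    break
            else:
                raise RuntimeError("could not draw a non-degenerate split")
            fit = AllocationModel(x[train_mask], y[train_mask], name).fit()
            pred = fit.predict(x[test_idx])
            test_mae = float(np.abs(pred - y[test_idx]).mean())
            test_r2 = _r2(y[test_idx], pred)
            rows.append(
                {
                    "fraction": frac,
                    "repeat": rep,
                    "family": fit.family,
                    "test_mae": test_mae,
                    "test_adjusted_r2": adjusted_r2(
                        test_r2, n_test, FAMILY_N_PARAMS[fit.family]
                    ),
                    "train_adjusted_r2": fit.adjusted_r2,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------- sequential grouping


@dataclass
class AllocationSummary:
    group: str
    gene_count: int
    mean_mass_share: float
    cv_of_share: float
    genes: frozenset = frozenset()

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "gene_count": self.gene_count,
            "mean_mass_share": self.mean_mass_share,
            "cv_of_share": self.cv_of_share,
        }


def summarize_allocation(
    fits: dict,
    ti_member_sets: dict,
    proteome_fractions: pd.DataFrame,
    cv_cutoff: float = 1.0,
) -> list[AllocationSummary]:
    """Sequential proteome-allocation grouping for the treemap.

    Strong modules (descending adjusted R^2, ties to the larger gene
    count) claim their covered genes first, then weak modules; each gene
    is counted exactly once.  Unclaimed genes with mass-fraction CV at
    or below ``cv_cutoff`` are "invariant", the rest "other".  Each
    group reports its gene count and the mean and CV (across
    conditions) of its summed mass fraction.
    """
    covered = set(proteome_fractions.index)
    remaining = set(covered)
    group_genes = {"strong": set(), "weak": set()}
    for label in ("strong", "weak"):
        ranked = sorted(
            (f for f in fits.values() if f.strength == label),
            key=lambda f: (
                -f.adjusted_r2,
                -len(set(ti_member_sets.get(f.ti_index, ())) & covered),
            ),
        )
        for fit in ranked:
            genes = set(ti_member_sets.get(fit.ti_index, ())) & remaining
            group_genes[label] |= genes
            remaining -= genes
    means = proteome_fractions.mean(axis=1)
    sds = proteome_fractions.std(axis=1, ddof=1)
    rem = sorted(remaining)
    cv = pd.Series(np.inf, index=rem)
    nz = [g for g in rem if means[g] != 0]
    cv[nz] = sds[nz] / means[nz]
    group_genes["invariant"] = {g for g in rem if cv[g] <= cv_cutoff}
    group_genes["other"] = remaining - group_genes["invariant"]
    out = []
    for label in ("strong", "weak", "invariant", "other"):
        genes = sorted(group_genes[label])
        if genes:
            share = proteome_fractions.loc[genes].sum(axis=0)
            mean_share = float(share.mean())
            cv_share = (
                float(share.std(ddof=1) / share.mean()) if share.mean() else 0.0
            )
        else:
            mean_share, cv_share = 0.0, 0.0
        out.append(
            AllocationSummary(
                group=label,
                gene_count=len(genes),
                mean_mass_share=mean_share,
                cv_of_share=cv_share,
                genes=frozenset(genes),
            )
        )
    return out


def fit_report(fits: dict) -> pd.DataFrame:
    """Per-module fit table for export."""
    rows = []
    for fit in fits.values():
        d = fit.to_dict()
        d["parameters"] = ";".join(
            f"{k}={v:.6g}" for k, v in d["parameters"].items()
        )
        rows.append(d)
    return pd.DataFrame(rows).set_index("ti")
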