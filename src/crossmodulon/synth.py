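"""Matched transcriptome/proteome compendia with planted module structure.

Every stage of the analysis has a recoverable ground truth here:

* sparse transcriptome modules (1-3% of genes each, disjoint) with
  heavy-tailed Laplace condition activities (ICA's non-Gaussianity
  requirement),
* proteome modules that mirror single transcriptome modules or "lump"
  the union of two (the low-sample-count regime where proteome ICA
  merges signals),
* a transcript-to-protein mapping family per proteome module (linear,
  exponential or broken-line response of protein signal to module
  activity),
* post-transcriptional dominance scenarios: protein-only suppression at
  a module's most active conditions (transcriptome-dominant), a
  protein-only boost (proteome-dominant), or nothing (neutral),
* top-abundance coverage censoring — the proteome table only contains
  the most abundant ~1/3 of genes, as label-free proteomics would see,
* per-replicate Gaussian noise in log2 space and a designated common
  reference condition.

Defaults (2000 genes, 60 conditions x 2 replicates, k_t=12, k_p=8,
sigma_rep=0.02) are the study conditions used throughout the tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

FAMILY_CYCLE = ("linear", "exponential", "broken_line")


@dataclass
class SynthConfig:
    n_genes: int = 2000
    n_conditions: int = 60
    replicates: int = 2
    k_t: int = 12
    k_p: int = 8
    sigma_rep: float = 0.02
    module_frac_min: float = 0.01
    module_frac_max: float = 0.03
    n_lumped: int = 2
    coverage_frac: float = 1 / 3
    covered_member_frac: float = 0.9
    t_signal_scale: float = 2.0
    p_signal_scale: float = 2.0
    n_perturbed: int = 5
    suppress_factor: float = 0.1
    boost_sd: float = 4.0
    suppress_module: int = 0
    boost_module: int = 1
    families: tuple = FAMILY_CYCLE
    exp_rate: float = 0.1
    broken_left_slope: float = 0.5
    broken_right_slope: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0


@dataclass
class GroundTruth:
    """Planted structure behind one simulated compendium pair."""

    config: SynthConfig
    seed: int
    gene_ids: list
    condition_ids: list
    M0_t: pd.DataFrame  # genes x k_t, unit-norm sparse columns
    A0: pd.DataFrame  # k_t x conditions, row-centered Laplace
    ti_members: dict  # ti name -> frozenset of genes
    lumping_map: dict  # pi name -> list of ti names
    mapping_per_module: dict  # pi name -> {"family": ..., params}
    dominance_scenarios: dict  # pi name -> {"class", "conditions", ...}
    coverage_mask: list  # covered (proteome-detected) genes
    M0_p: pd.DataFrame  # covered genes x k_p
    S0_p: pd.DataFrame  # k_p x conditions planted proteome activities
    baseline_t: pd.Series
    baseline_p: pd.Series

    @property
    def planted_links(self) -> set:
        return {
            (pi, ti) for pi, tis in self.lumping_map.items() for ti in tis
        }

    def pi_members(self) -> dict:
        covered = set(self.coverage_mask)
        return {
            pi: frozenset().union(*(self.ti_members[ti] for ti in tis)) & covered
            for pi, tis in self.lumping_map.items()
        }

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "seed": self.seed,
            "ti_members": {k: sorted(v) for k, v in self.ti_members.items()},
            "lumping_map": {k: list(v) for k, v in self.lumping_map.items()},
            "mapping_per_module": self.mapping_per_module,
            "dominance_scenarios": {
                k: {
                    kk: (list(vv) if isinstance(vv, (set, frozenset, list)) else vv)
                    for kk, vv in v.items()
                }
                for k, v in self.dominance_scenarios.items()
            },
            "coverage_mask": list(self.coverage_mask),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _apply_family(u: np.ndarray, family: str, params: dict) -> np.ndarray:
    """Transcript-activity -> protein-signal mapping, centered."""
    if family == "linear":
        s = params["slope"] * u
    elif family == "exponential":
        s = np.exp(params["rate"] * u) - 1.0
    elif family == "broken_line":
        t = params["breakpoint"]
        s = np.where(
            u < t,
            params["left_slope"] * (u - t),
            params["right_slope"] * (u - t),
        )
    else:
        raise ValueError(f"unknown mapping family {family!r}")
    s = s - s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


def generate_ground_truth(
    n_genes: int | None = None,
    n_conditions: int | None = None,
    k_t: int | None = None,
    k_p: int | None = None,
    seed: int = 0,
    config: SynthConfig | None = None,
) -> GroundTruth:
    """Sample the planted module structure for one study."""
    cfg = config or SynthConfig()
    if n_genes is not None:
        cfg.n_genes = n_genes
    if n_conditions is not None:
        cfg.n_conditions = n_conditions
    if k_t is not None:
        cfg.k_t = k_t
    if k_p is not None:
        cfg.k_p = k_p
    if cfg.k_p > cfg.k_t:
        raise ValueError("k_p must not exceed k_t")
    if cfg.n_conditions < 20:
        raise ValueError("need at least 20 conditions")
    if cfg.k_p + cfg.n_lumped > cfg.k_t:
        raise ValueError(
            "lumping needs k_p + n_lumped <= k_t "
            f"({cfg.k_p} + {cfg.n_lumped} > {cfg.k_t})"
        )
    max_members = int(cfg.module_frac_max * cfg.n_genes)
    if cfg.k_t * max_members > cfg.n_genes:
        raise ValueError("infeasible sparsity: modules would exceed the gene count")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    conditions = [f"c{i:03d}" for i in range(cfg.n_conditions)]
    ti_names = [f"ti_{i}" for i in range(cfg.k_t)]
    pi_names = [f"pi_{i}" for i in range(cfg.k_p)]

    baseline_t = pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes), index=genes
    )
    baseline_p = pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes), index=genes
    )
    n_cov = int(round(cfg.coverage_frac * cfg.n_genes))
    coverage = list(baseline_p.sort_values(ascending=False).index[:n_cov])
    covered_set = set(coverage)

    # proteome modules: the first k_p - n_lumped mirror one ti module each,
    # the rest union two; backing ti modules draw most members from the
    # covered pool (proteomics only sees abundant proteins)
    lumping_map: dict[str, list[str]] = {}
    next_ti = 0
    for j, pi in enumerate(pi_names):
        width = 2 if j >= cfg.k_p - cfg.n_lumped else 1
        lumping_map[pi] = ti_names[next_ti : next_ti + width]
        next_ti += width
    backing = {ti for tis in lumping_map.values() for ti in tis}

    # iterate ordered lists, never sets: realisations must not depend on
    # the interpreter's string hashing
    unused_cov = list(coverage)
    unused_unc = [g for g in genes if g not in covered_set]
    rng.shuffle(unused_cov)
    rng.shuffle(unused_unc)
    ti_members: dict[str, frozenset] = {}
    lo = max(2, int(cfg.module_frac_min * cfg.n_genes))
    hi = max(lo + 1, max_members)
    for ti in ti_names:
        size = int(rng.integers(lo, hi + 1))
        if ti in backing:
            n_c = min(int(np.ceil(cfg.covered_member_frac * size)), len(unused_cov))
            members = [unused_cov.pop() for _ in range(n_c)]
            members += [unused_unc.pop() for _ in range(size - n_c)]
        else:
            pool_all = unused_unc if len(unused_unc) >= size else unused_cov
            members = [pool_all.pop() for _ in range(size)]
        ti_members[ti] = frozenset(members)

    M0 = np.zeros((cfg.n_genes, cfg.k_t))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for col, ti in enumerate(ti_names):
        idx = [gene_pos[g] for g in ti_members[ti]]
        w = rng.uniform(0.5, 1.0, len(idx)) * rng.choice([-1.0, 1.0], len(idx))
        M0[idx, col] = w
    M0 /= np.linalg.norm(M0, axis=0, keepdims=True)
    M0_t = pd.DataFrame(M0, index=genes, columns=ti_names)

    A0 = rng.laplace(0.0, 1.0, (cfg.k_t, cfg.n_conditions))
    A0 -= A0.mean(axis=1, keepdims=True)
    A0 = pd.DataFrame(A0, index=ti_names, columns=conditions)

    # mild curvature: matched module activities in real compendia remain
    # well correlated, so a planted "neutral" module must keep its
    # protein activity close in shape to its transcript activity
    family_params = {
        "linear": {"slope": 1.0},
        "exponential": {"rate": cfg.exp_rate},
        "broken_line": {
            "breakpoint": 0.0,
            "left_slope": cfg.broken_left_slope,
            "right_slope": cfg.broken_right_slope,
        },
    }
    mapping = {}
    for j, pi in enumerate(pi_names):
        fam = cfg.families[j % len(cfg.families)]
        mapping[pi] = {"family": fam, **family_params[fam]}

    # planted proteome activities: mapping family applied to the (scaled)
    # sum of constituent ti activities
    S0 = np.zeros((cfg.k_p, cfg.n_conditions))
    for j, pi in enumerate(pi_names):
        tis = lumping_map[pi]
        u = A0.loc[tis].sum(axis=0).to_numpy() / np.sqrt(len(tis))
        fam = mapping[pi]["family"]
        S0[j] = _apply_family(u, fam, mapping[pi])

    # dominance perturbations act on the protein layer only
    scenarios: dict[str, dict] = {}
    for j, pi in enumerate(pi_names):
        if j == cfg.suppress_module:
            order = np.argsort(-np.abs(S0[j]))[: cfg.n_perturbed]
            conds = [conditions[i] for i in order]
            S0[j, order] = S0[j, order] * cfg.suppress_factor
            scenarios[pi] = {
                "class": "transcriptome-dominant",
                "mechanism": "protein suppression",
                "conditions": conds,
                "factor": cfg.suppress_factor,
            }
        elif j == cfg.boost_module:
            order = np.argsort(np.abs(S0[j]))[: cfg.n_perturbed]
            conds = [conditions[i] for i in order]
            S0[j, order] = S0[j, order] + cfg.boost_sd * S0[j].std()
            scenarios[pi] = {
                "class": "proteome-dominant",
                "mechanism": "protein boost",
                "conditions": conds,
                "magnitude_sd": cfg.boost_sd,
            }
        else:
            scenarios[pi] = {"class": "neutral", "conditions": []}
    S0_p = pd.DataFrame(S0, index=pi_names, columns=conditions)

    Mp = np.zeros((len(coverage), cfg.k_p))
    cov_pos = {g: i for i, g in enumerate(coverage)}
    for j, pi in enumerate(pi_names):
        for ti in lumping_map[pi]:
            for g in ti_members[ti]:
                if g in cov_pos:
                    Mp[cov_pos[g], j] += M0_t.at[g, ti]
    norms = np.linalg.norm(Mp, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    Mp /= norms
    M0_p = pd.DataFrame(Mp, index=coverage, columns=pi_names)

    return GroundTruth(
        config=cfg,
        seed=seed,
        gene_ids=genes,
        condition_ids=conditions,
        M0_t=M0_t,
        A0=A0,
        ti_members=ti_members,
        lumping_map=lumping_map,
        mapping_per_module=mapping,
        dominance_scenarios=scenarios,
        coverage_mask=coverage,
        M0_p=M0_p,
        S0_p=S0_p,
        baseline_t=baseline_t,
        baseline_p=baseline_p,
    )


@dataclass
class SimulatedCompendia:
    transcriptome: pd.DataFrame  # genes x samples, log2 expression units
    proteome_abundance: pd.DataFrame  # covered genes x samples, raw scale
    metadata: pd.DataFrame
    ground_truth: GroundTruth = field(repr=False, default=None)


def generate_matched_compendia(
    gt: GroundTruth, replicates: int | None = None
) -> SimulatedCompendia:
    """Realise the two compendia from a ground truth.

    The transcriptome is emitted in log2 units (ready for reference
    centering); the proteome as raw abundances (ready for the mass-
    fraction / log2(PPM+1) compilation pipeline).  Condition c000 is the
    common reference.
    """
    cfg = gt.config
    reps = replicates if replicates is not None else cfg.replicates
    rng = np.random.default_rng(gt.seed + 1)
    samples = [f"{c}_r{r + 1}" for c in gt.condition_ids for r in range(reps)]
    cond_of = [c for c in gt.condition_ids for _ in range(reps)]
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "condition_id": cond_of,
            "replicate": [r + 1 for _ in gt.condition_ids for r in range(reps)],
            "batch": "batch0",
            "is_reference": [c == gt.condition_ids[0] for c in cond_of],
        }
    )
    A_samples = gt.A0[cond_of].to_numpy()
    signal_t = cfg.t_signal_scale * (gt.M0_t.to_numpy() @ A_samples)
    Xt = (
        gt.baseline_t.to_numpy()[:, None]
        + signal_t
        + rng.normal(0.0, cfg.sigma_rep, signal_t.shape)
    )
    transcriptome = pd.DataFrame(Xt, index=gt.gene_ids, columns=samples)

    S_samples = gt.S0_p[cond_of].to_numpy()
    signal_p = cfg.p_signal_scale * (gt.M0_p.to_numpy() @ S_samples)
    base_p = gt.baseline_p.loc[gt.coverage_mask].to_numpy()[:, None]
    Lp = base_p + signal_p + rng.normal(0.0, cfg.sigma_rep, signal_p.shape)
    proteome = pd.DataFrame(
        np.exp2(Lp), index=list(gt.coverage_mask), columns=samples
    )
    return SimulatedCompendia(
        transcriptome=transcriptome,
        proteome_abundance=proteome,
        metadata=meta,
        ground_truth=gt,
    )


def planted_activities(M0: pd.DataFrame, X: pd.DataFrame) -> pd.DataFrame:
    """Project a compendium onto planted weights (least squares), giving
    measured activities for the planted modules."""
    Xc = X.loc[M0.index].sub(X.loc[M0.index].mean(axis=1), axis=0)
    A = np.linalg.pinv(M0.to_numpy()) @ Xc.to_numpy()
    return pd.DataFrame(A, index=M0.columns, columns=X.columns)


def generate_allocation_data(
    family: str,
    n: int = 57,
    noise: float = 0.05,
    seed: int = 0,
    params: dict | None = None,
):
    """One module's (activity, mass-fraction) series from a known law.

    ``noise`` is the replicate-noise standard deviation as a fraction of
    the clean response range.  Returns (x, y, params used).
    """
    rng = np.random.default_rng(seed)
    x = rng.laplace(0.0, 1.0, n)
    x -= x.mean()
    defaults = {
        "linear": {"slope": 0.01, "intercept": 0.05},
        "exponential": {"offset": 0.01, "scale": 0.02, "rate": 0.5},
        "broken_line": {
            "breakpoint": 0.0,
            "intercept": 0.05,
            "left_slope": 0.002,
            "right_slope": 0.02,
        },
    }
    if family not in defaults:
        raise ValueError(f"unknown family {family!r}")
    p = {**defaults[family], **(params or {})}
    if family == "linear":
        y = p["slope"] * x + p["intercept"]
    elif family == "exponential":
        y = p["offset"] + p["scale"] * np.exp(p["rate"] * x)
    else:
        t = p["breakpoint"]
        y = p["intercept"] + np.where(
            x < t, p["left_slope"] * (x - t), p["right_slope"] * (x - t)
        )
    y = y + rng.normal(0.0, noise * np.ptp(y), n)
    return x, y, p


# ------------------------------------------------------------- scorecard


@dataclass
class RecoveryScorecard:
    per_ti: pd.DataFrame
    link_recall: float
    link_precision: float
    recovered_links: set
    planted_links: set
    family_recovery: dict = field(default_factory=dict)

    @property
    def min_abs_r(self) -> float:
        return float(self.per_ti["best_abs_r"].min())

    @property
    def median_jaccard(self) -> float:
        return float(self.per_ti["jaccard"].median())

    def to_dict(self) -> dict:
        return {
            "min_abs_r": self.min_abs_r,
            "median_jaccard": self.median_jaccard,
            "link_recall": self.link_recall,
            "link_precision": self.link_precision,
            "family_recovery": dict(self.family_recovery),
        }


def best_match_map(M_planted: pd.DataFrame, M_rec: pd.DataFrame) -> pd.DataFrame:
    """For each planted column: the recovered column with max |r| and that r."""
    shared = M_planted.index.intersection(M_rec.index)
    P = M_planted.loc[shared].to_numpy()
    R = M_rec.loc[shared].to_numpy()
    P = (P - P.mean(0)) / P.std(0)
    Rz = (R - R.mean(0)) / np.where(R.std(0) == 0, 1, R.std(0))
    corr = (P.T @ Rz) / len(shared)
    best = np.argmax(np.abs(corr), axis=1)
    return pd.DataFrame(
        {
            "recovered": [M_rec.columns[b] for b in best],
            "abs_r": [abs(corr[i, b]) for i, b in enumerate(best)],
        },
        index=M_planted.columns,
    )


def recovery_report(
    gt: GroundTruth,
    decomp_t,
    decomp_p,
    matches,
    fits: dict | None = None,
    members_t: dict | None = None,
) -> RecoveryScorecard:
    """Score a pipeline run against the planted ground truth.

    Per planted transcriptome module: best |r| to a recovered component
    and the Jaccard index between planted and recovered (thresholded)
    membership.  Planted pi-ti links are compared to the recovered match
    list after translating recovered component names to planted module
    names via best-|r| assignment; the scorecard is invariant to
    component permutation and sign.
    """
    from .imodulons import threshold_component

    map_t = best_match_map(gt.M0_t, decomp_t.M)
    map_p = best_match_map(gt.M0_p, decomp_p.M)
    rows = []
    for ti in gt.M0_t.columns:
        rec = map_t.loc[ti, "recovered"]
        if members_t is not None and rec in members_t:
            rec_members = frozenset(members_t[rec])
        else:
            _, rec_members = threshold_component(decomp_t.M[rec])
        planted = gt.ti_members[ti]
        union = planted | rec_members
        jac = len(planted & rec_members) / len(union) if union else 1.0
        rows.append(
            {
                "ti": ti,
                "recovered": rec,
                "best_abs_r": float(map_t.loc[ti, "abs_r"]),
                "jaccard": jac,
                "n_planted": len(planted),
                "n_recovered": len(rec_members),
            }
        )
    per_ti = pd.DataFrame(rows).set_index("ti")

    rec_to_ti = {}
    for ti, row in map_t.iterrows():
        rec = row["recovered"]
        if rec not in rec_to_ti or map_t.loc[rec_to_ti[rec], "abs_r"] < row["abs_r"]:
            rec_to_ti[rec] = ti
    rec_to_pi = {}
    for pi, row in map_p.iterrows():
        rec = row["recovered"]
        if rec not in rec_to_pi or map_p.loc[rec_to_pi[rec], "abs_r"] < row["abs_r"]:
            rec_to_pi[rec] = pi
    recovered_links = set()
    for pair in matches:
        pi = rec_to_pi.get(pair.pi_index)
        if pi is None:
            continue
        for rec_ti in pair.ti_indices:
            ti = rec_to_ti.get(rec_ti)
            if ti is not None:
                recovered_links.add((pi, ti))
    planted = gt.planted_links
    recall = len(recovered_links & planted) / len(planted) if planted else 1.0
    precision = (
        len(recovered_links & planted) / len(recovered_links)
        if recovered_links
        else 1.0
    )
    family_recovery = {}
    if fits:
        for pi, spec_map in gt.mapping_per_module.items():
            if pi in fits:
                family_recovery[pi] = fits[pi].family == spec_map["family"]
    return RecoveryScorecard(
        per_ti=per_ti,
        link_recall=recall,
        link_precision=precision,
        recovered_links=recovered_links,
        planted_links=planted,
        family_recovery=family_recovery,
    )
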