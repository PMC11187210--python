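"""iModulon characterization: membership thresholds, regulator
enrichment, categorization, and mass-fraction invariance statistics.

A component's members are the features whose weights are outliers of an
otherwise near-normal weight distribution.  The threshold is found by
iteratively stripping the largest-magnitude weight until the D'Agostino
K^2 normality statistic of the remainder drops below a cutoff; the
convention value 550 is used by default and exposed in every caller.

Regulator enrichment is a one-sided hypergeometric test of the overlap
between an iModulon's members and each known regulon (plus pairwise
regulon unions, to capture combined modules), Benjamini-Hochberg
adjusted across all tested gene sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

DAGOSTINO_CUTOFF = 550.0

CATEGORIES = (
    "regulatory",
    "biological",
    "technical/single-gene",
    "uncharacterized",
    "genomic",
)


@dataclass
class EnrichmentResult:
    regulator_name: str
    pvalue: float
    adjusted_pvalue: float
    precision: float
    recall: float
    overlap: frozenset

    def to_dict(self) -> dict:
        return {
            "regulator": self.regulator_name,
            "pvalue": self.pvalue,
            "adjusted_pvalue": self.adjusted_pvalue,
            "precision": self.precision,
            "recall": self.recall,
            "overlap": sorted(self.overlap),
        }


@dataclass
class IModulon:
    """One annotated component: weights, membership, category, enrichment."""

    component_index: str
    weights: pd.Series
    threshold: float
    members: frozenset
    category: str = "uncharacterized"
    name: str | None = None
    enrichment: EnrichmentResult | None = None
    all_enrichments: list = field(default_factory=list)
    explained_variance: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "component": self.component_index,
            "name": self.name or self.component_index,
            "threshold": self.threshold,
            "n_members": len(self.members),
            "members": sorted(self.members),
            "category": self.category,
            "explained_variance": self.explained_variance,
            "enrichment": self.enrichment.to_dict() if self.enrichment else None,
        }


def threshold_component(
    weights: pd.Series, cutoff: float | str = "auto"
) -> tuple[float, frozenset]:
    """Iterative-outlier membership threshold for one weight vector.

    Weights are removed largest magnitude first until the D'Agostino
    K^2 statistic of the remainder falls below ``cutoff``.  The
    threshold is placed midway between the smallest removed and largest
    kept magnitude, so members == {features with |weight| > threshold}
    exactly.  A distribution already below the cutoff yields an empty
    membership with threshold above the largest magnitude.

    The conventional cutoff value 550 presumes a genome-scale weight
    vector (~4000 features); the K^2 statistic grows roughly linearly
    in the feature count for a fixed outlier fraction, so ``"auto"``
    (the default) scales that anchor by n/4000 with a floor of 20
    (a clean near-normal vector scores below ~10 at any n).
    """
    w = weights.astype(float)
    if len(w) < 10:
        raise ValueError("need at least 10 features to threshold")
    if cutoff == "auto":
        cutoff = max(20.0, DAGOSTINO_CUTOFF * len(w) / 4000.0)
    order = np.argsort(-np.abs(w.to_numpy()), kind="stable")
    sorted_abs = np.abs(w.to_numpy())[order]
    n_removed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # normaltest warns for n < 20
        while len(w) - n_removed >= 10:
            remaining = w.to_numpy()[order[n_removed:]]
            if np.ptp(remaining) == 0:
                break
            stat, _ = scipy.stats.normaltest(remaining)
            if stat < cutoff:
                break
            n_removed += 1
    if n_removed == 0:
        threshold = float(sorted_abs[0]) * (1 + 1e-9) + 1e-300
        return threshold, frozenset()
    threshold = float((sorted_abs[n_removed - 1] + sorted_abs[n_removed]) / 2.0)
    members = frozenset(w.index[np.abs(w) > threshold])
    return threshold, members


def _hypergeom_tail(overlap: int, background: int, regulon: int, drawn: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(background, regulon, drawn)."""
    return float(scipy.stats.hypergeom.sf(overlap - 1, background, regulon, drawn))


def enrich_regulators(
    members,
    regulon_db: dict,
    background,
    *,
    include_unions: bool = True,
    max_union: int = 2,
) -> list[EnrichmentResult]:
    """Hypergeometric regulon enrichment for one member set.

    ``regulon_db`` maps regulator name -> gene collection.  Regulons are
    restricted to the background before testing; pairwise unions of
    regulons that each overlap the members are tested too, labelled
    "RegA/RegB".  P-values are BH-adjusted across everything tested and
    results are sorted by adjusted p.
    """
    members = frozenset(members)
    background = frozenset(background)
    if not members <= background:
        raise ValueError("members must be a subset of the background")
    if not members:
        return []
    candidates: dict[str, frozenset] = {}
    for reg, genes in regulon_db.items():
        in_bg = frozenset(genes) & background
        if in_bg:
            candidates[str(reg)] = in_bg
    if include_unions and max_union >= 2:
        overlapping = [r for r, g in candidates.items() if g & members]
        for a, b in itertools.combinations(sorted(overlapping), 2):
            candidates[f"{a}/{b}"] = candidates[a] | candidates[b]
    if not candidates:
        return []
    names = sorted(candidates)
    pvals, results = [], []
    N, n = len(background), len(members)
    for name in names:
        regulon = candidates[name]
        overlap = members & regulon
        p = _hypergeom_tail(len(overlap), N, len(regulon), n)
        pvals.append(p)
        results.append((name, p, overlap, regulon))
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = [
        EnrichmentResult(
            regulator_name=name,
            pvalue=p,
            adjusted_pvalue=float(q),
            precision=len(overlap) / n,
            recall=len(overlap) / len(regulon),
            overlap=frozenset(overlap),
        )
        for (name, p, overlap, regulon), q in zip(results, adj)
    ]
    out.sort(key=lambda e: (e.adjusted_pvalue, e.pvalue, e.regulator_name))
    return out


def characterize_components(
    M: pd.DataFrame,
    *,
    regulon_db: dict | None = None,
    curation: pd.DataFrame | None = None,
    component_ev=None,
    dagostino_cutoff: float | str = "auto",
    adj_p_cutoff: float = 1e-3,
) -> list[IModulon]:
    """Threshold, enrich and categorize every component of M."""
    background = frozenset(M.index)
    evs = (
        dict(zip(M.columns, component_ev))
        if component_ev is not None
        else {}
    )
    imodulons = []
    for col in M.columns:
        threshold, members = threshold_component(M[col], dagostino_cutoff)
        im = IModulon(
            component_index=str(col),
            weights=M[col],
            threshold=threshold,
            members=members,
            explained_variance=float(evs.get(col, float("nan"))),
        )
        if regulon_db and members:
            im.all_enrichments = enrich_regulators(members, regulon_db, background)
            if im.all_enrichments:
                im.enrichment = im.all_enrichments[0]
        imodulons.append(im)
    return categorize(imodulons, curation=curation, adj_p_cutoff=adj_p_cutoff)


def categorize(
    imodulons: list,
    *,
    curation: pd.DataFrame | None = None,
    adj_p_cutoff: float = 1e-3,
) -> list:
    """Assign categories: regulatory / technical / curated / uncharacterized.

    Regulatory requires a best adjusted p at or below the cutoff; one or
    zero members makes a component technical/single-gene; biological and
    genomic labels only come from the curation table (component, category,
    name columns), which also overrides names.
    """
    curated = {}
    if curation is not None:
        for _, row in curation.iterrows():
            curated[str(row["component"])] = (
                str(row["category"]),
                str(row.get("name", "")) or None,
            )
    for im in imodulons:
        if im.component_index in curated:
            cat, name = curated[im.component_index]
            if cat not in CATEGORIES:
                raise ValueError(f"unknown curated category {cat!r}")
            im.category, im.name = cat, name or im.name
            continue
        if len(im.members) <= 1:
            im.category = "technical/single-gene"
        elif im.enrichment and im.enrichment.adjusted_pvalue <= adj_p_cutoff:
            im.category = "regulatory"
            im.name = im.enrichment.regulator_name
        else:
            im.category = "uncharacterized"
    return imodulons


@dataclass
class InvarianceStats:
    """Mass-fraction variability split by iModulon membership."""

    in_count: int
    out_count: int
    in_invariant: int
    out_invariant: int
    in_mass_share: float
    out_mass_share: float
    in_median_mass: float
    out_median_mass: float
    in_median_cv: float
    out_median_cv: float
    excluded: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def invariance_stats(
    mass_fractions: pd.DataFrame,
    member_union,
    cv_cutoff: float = 1.0,
    strict: bool = True,
) -> InvarianceStats:
    """Per-protein CV and mean mass fraction, split by module membership.

    CVs are computed on raw mass fractions (not log).  ``strict``
    counts CV < cutoff as invariant (the compendium-statistics
    convention); inclusive CV <= cutoff is the allocation-treemap
    convention.
    """
    member_union = frozenset(member_union)
    means = mass_fractions.mean(axis=1)
    sds = mass_fractions.std(axis=1, ddof=1)
    excluded = means.index[means == 0].tolist()
    usable = means.index[means != 0]
    cv = (sds[usable] / means[usable]).astype(float)
    in_mask = usable.isin(member_union)
    is_invariant = (cv < cv_cutoff) if strict else (cv <= cv_cutoff)
    total_mass = float(means[usable].sum())

    def _side(mask):
        idx = usable[mask]
        return (
            int(len(idx)),
            int(is_invariant[idx].sum()),
            float(means[idx].sum() / total_mass) if total_mass else 0.0,
            float(means[idx].median()) if len(idx) else float("nan"),
            float(cv[idx].median()) if len(idx) else float("nan"),
        )

    n_in, inv_in, share_in, med_in, cv_in = _side(in_mask)
    n_out, inv_out, share_out, med_out, cv_out = _side(~in_mask)
    return InvarianceStats(
        in_count=n_in,
        out_count=n_out,
        in_invariant=inv_in,
        out_invariant=inv_out,
        in_mass_share=share_in,
        out_mass_share=share_out,
        in_median_mass=med_in,
        out_median_mass=med_out,
        in_median_cv=cv_in,
        out_median_cv=cv_out,
        excluded=excluded,
    )


def imodulon_table(imodulons: list) -> pd.DataFrame:
    """Flat export table (one row per iModulon)."""
    rows = []
    for im in imodulons:
        d = im.to_dict()
        d["members"] = ";".join(d["members"])
        enr = d.pop("enrichment")
        d["regulator"] = enr["regulator"] if enr else ""
        d["adjusted_pvalue"] = enr["adjusted_pvalue"] if enr else float("nan")
        rows.append(d)
    return pd.DataFrame(rows).set_index("component")
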