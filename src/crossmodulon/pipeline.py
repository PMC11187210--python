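"""End-to-end orchestration of the matched-omics analysis.

``run_pipeline`` sequences the stages — compile both compendia,
decompose each with robust ICA, characterize the components into
iModulons, match them across layers, compare activities (DiMA), and
regress proteome allocation on transcriptome module activities —
writing every intermediate artifact plus a manifest of parameters and
seeds so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import allocation as alloc
from . import compendium as comp
from . import imodulons as imod
from . import io as cio
from . import matching as match
from .ica import run_robust_ica
from .synth import (
    GroundTruth,
    SimulatedCompendia,
    generate_ground_truth,
    generate_matched_compendia,
    recovery_report,
)

__version__ = "0.1.0"


class PipelineConfig(BaseModel):
    """Validated configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "crossmodulon_out"
    # input tables (None -> synthetic mode)
    transcriptome_path: str | None = None
    proteome_path: str | None = None
    metadata_t_path: str | None = None
    metadata_p_path: str | None = None
    regulon_db_path: str | None = None
    # stage parameters
    min_coverage: float = 0.5
    r2_min: float = 0.9
    k_t: int | None = None
    k_p: int | None = None
    n_runs: int = 10
    dagostino_cutoff: float | str = "auto"
    adj_p_cutoff: float = 1e-3
    match_r_min: float = match.MATCH_R_MIN
    dima_band: float = match.DIMA_BAND_SD
    strong_r2: float = alloc.STRONG_ADJ_R2
    cv_cutoff: float = 1.0
    # synthetic mode
    synthetic: bool = True
    n_genes: int = 2000
    n_conditions: int = 60
    replicates: int = 2
    sigma_rep: float = 0.02
    n_lumped: int = 2


@dataclass
class PipelineResult:
    config: PipelineConfig
    transcriptome: pd.DataFrame
    proteome_fractions: pd.DataFrame
    decomp_t: object
    decomp_p: object
    imodulons_t: list
    imodulons_p: list
    matches: list
    dima_results: dict
    fits: dict
    allocation_summary: list
    scorecard: object = None
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute the full analysis per the configuration."""
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    gt: GroundTruth | None = None
    if config.synthetic:
        from .synth import SynthConfig

        scfg = SynthConfig(
            n_genes=config.n_genes,
            n_conditions=config.n_conditions,
            replicates=config.replicates,
            sigma_rep=config.sigma_rep,
            n_lumped=config.n_lumped,
        )
        if config.k_t:
            scfg.k_t = config.k_t
        if config.k_p:
            scfg.k_p = config.k_p
        gt = generate_ground_truth(seed=config.seed, config=scfg)
        sim = generate_matched_compendia(gt)
        Xt_raw, prot_raw = sim.transcriptome, sim.proteome_abundance
        meta_t = meta_p = sim.metadata
        regulon_db = {ti: set(m) for ti, m in gt.ti_members.items()}
    else:
        for attr in ("transcriptome_path", "proteome_path", "metadata_t_path", "metadata_p_path"):
            if getattr(config, attr) is None:
                raise ValueError(f"real-data mode needs {attr}")
        Xt_raw = cio.read_matrix(config.transcriptome_path)
        prot_raw = cio.read_matrix(config.proteome_path)
        meta_t = cio.read_metadata(config.metadata_t_path)
        meta_p = cio.read_metadata(config.metadata_p_path)
        regulon_db = (
            cio.read_regulon_db(config.regulon_db_path)
            if config.regulon_db_path
            else {}
        )

    # --- compile ---------------------------------------------------------
    compile_t = _stage("compile-transcriptome")(
        lambda: (comp.center_to_reference(Xt_raw, meta_t), comp.validate_metadata(Xt_raw, meta_t))
    )
    Xt, meta_t_v = compile_t()
    compile_p = _stage("compile-proteome")(comp.compile_compendium)
    Xp, meta_p_v, report_p = compile_p(
        prot_raw, meta_p, min_coverage=config.min_coverage, r2_min=config.r2_min
    )
    fractions = _stage("mass-fractions")(
        lambda: prot_raw.loc[Xp.index, Xp.columns].div(
            prot_raw.loc[Xp.index, Xp.columns].sum(axis=0), axis=1
        )
    )()

    # --- decompose -------------------------------------------------------
    k_t = config.k_t or (gt.config.k_t if gt else max(2, min(Xt.shape) // 5))
    k_p = config.k_p or (gt.config.k_p if gt else max(2, min(Xp.shape) // 5))
    decomp_t = _stage("decompose-transcriptome")(run_robust_ica)(
        Xt, k_t, config.n_runs, config.seed
    )
    decomp_p = _stage("decompose-proteome")(run_robust_ica)(
        Xp, k_p, config.n_runs, config.seed + 1
    )

    # --- characterize ----------------------------------------------------
    char = _stage("characterize")(imod.characterize_components)
    imods_t = char(
        decomp_t.M,
        regulon_db=regulon_db,
        component_ev=decomp_t.component_ev,
        dagostino_cutoff=config.dagostino_cutoff,
        adj_p_cutoff=config.adj_p_cutoff,
    )
    imods_p = char(
        decomp_p.M,
        regulon_db=regulon_db,
        component_ev=decomp_p.component_ev,
        dagostino_cutoff=config.dagostino_cutoff,
        adj_p_cutoff=config.adj_p_cutoff,
    )
    members_t = {im.component_index: im.members for im in imods_t}
    members_p = {im.component_index: im.members for im in imods_p}

    # --- match + DiMA ----------------------------------------------------
    matches = _stage("match")(match.match_components)(
        decomp_t.M,
        decomp_p.M,
        config.match_r_min,
        members_t=members_t,
        members_p=members_p,
    )
    dima_results = {}
    for pair in matches:
        try:
            dima_results[pair.pi_index] = match.dima(
                pair, decomp_t.A, decomp_p.A, meta_t_v, meta_p_v, config.dima_band
            )
        except ValueError:
            continue

    # --- allocation ------------------------------------------------------
    A_cond = match._replicate_average(decomp_t.A, meta_t_v)
    frac_cond = fractions.T.groupby(
        meta_p_v.loc[list(fractions.columns), "condition_id"]
    ).mean().T
    shared_conditions = [c for c in A_cond.columns if c in frac_cond.columns]
    fits = {}
    eligible = [
        im
        for im in imods_t
        if im.category not in ("uncharacterized", "genomic", "technical/single-gene")
    ]
    for im in eligible:
        covered = [g for g in im.members if g in frac_cond.index]
        if not covered:
            continue
        y = frac_cond.loc[covered, shared_conditions].sum(axis=0)
        x = A_cond.loc[im.component_index, shared_conditions]
        try:
            fits[im.component_index] = alloc.AllocationModel(
                x.to_numpy(), y.to_numpy(), im.component_index
            ).fit()
        except (alloc.FitError, ValueError):
            continue
    summary = _stage("allocate")(alloc.summarize_allocation)(
        fits, members_t, frac_cond[shared_conditions], config.cv_cutoff
    )

    scorecard = None
    if gt is not None:
        scorecard = recovery_report(
            gt, decomp_t, decomp_p, matches, fits=None, members_t=members_t
        )

    result = PipelineResult(
        config=config,
        transcriptome=Xt,
        proteome_fractions=fractions,
        decomp_t=decomp_t,
        decomp_p=decomp_p,
        imodulons_t=imods_t,
        imodulons_p=imods_p,
        matches=matches,
        dima_results=dima_results,
        fits=fits,
        allocation_summary=summary,
        scorecard=scorecard,
    )
    result.manifest = {
        "version": __version__,
        "config": config.model_dump(),
        "n_components_t": decomp_t.n_components,
        "n_components_p": decomp_p.n_components,
        "cumulative_ev_t": decomp_t.cumulative_ev,
        "cumulative_ev_p": decomp_p.cumulative_ev,
        "n_matches": len(matches),
        "compile_report_p": report_p.to_dict(),
    }
    if write:
        _write_artifacts(result, out, gt)
    return result


def _write_artifacts(result: PipelineResult, out: Path, gt) -> None:
    cio.write_matrix(result.decomp_t.M, out / "M_transcriptome.tsv")
    cio.write_matrix(result.decomp_t.A, out / "A_transcriptome.tsv")
    cio.write_matrix(result.decomp_p.M, out / "M_proteome.tsv")
    cio.write_matrix(result.decomp_p.A, out / "A_proteome.tsv")
    imod.imodulon_table(result.imodulons_t).to_csv(out / "imodulons_t.tsv", sep="\t")
    imod.imodulon_table(result.imodulons_p).to_csv(out / "imodulons_p.tsv", sep="\t")
    match.match_table(result.matches, result.dima_results).to_csv(
        out / "matches.tsv", sep="\t", index=False
    )
    if result.fits:
        alloc.fit_report(result.fits).to_csv(out / "allocation_fits.tsv", sep="\t")
    cio.write_json(
        [s.to_dict() for s in result.allocation_summary],
        out / "allocation_summary.json",
    )
    cio.write_json(result.manifest, out / "manifest.json")
    if gt is not None:
        gt.to_json(out / "ground_truth.json")
        if result.scorecard is not None:
            cio.write_json(result.scorecard.to_dict(), out / "recovery.json")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig(**json.load(fh))
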