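"""End-to-end analysis pipeline and report rendering.

Stages: locus QC -> (optional) parentage-based pedigree reconstruction ->
pedigree build -> additive relationship matrix -> fledging filter ->
univariate animal-model grid (traits x random-effect models) with DIC
selection -> bivariate fits per trait pair -> phenotype reports.  All
artifacts are written to the output directory together with a manifest
(inputs hash, seed, versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import pedqg
from pedqg import animal_model as am
from pedqg import msat, phenotypes
from pedqg.pedigree import (
    Pedigree,
    PedigreeRecord,
    additive_relationship_matrix,
    pedigree_summary,
    read_pedigree,
    write_pedigree,
)
from pedqg.simulate import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

#: the four univariate random-effect model candidates
MODEL_GRID: dict[str, tuple[str, ...]] = {
    "additive": ("additive",),
    "additive+maternal": ("additive", "maternal"),
    "additive+nest": ("additive", "nest"),
    "additive+nest+maternal": ("additive", "nest", "maternal"),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one pedigree source must be active."""

    output_dir: str = "pedqg_out"
    seed: int = 0
    preset: str = "fast"  # 'fast' or 'paper'
    pedigree_path: str | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    simulate: SimConfig | None = None
    reconstruct_pedigree: bool = False
    fledge_cutoff: float | None = phenotypes.DEFAULT_FLEDGE_CUTOFF
    traits: tuple[str, ...] = phenotypes.TRAITS
    #: optional (total, burn_in, thin) override of the preset schedules
    schedule: tuple[int, int, int] | None = None
    bivariate_schedule: tuple[int, int, int] | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulate is not None and self.pedigree_path is not None:
            raise ValueError("give either a simulation config or input files, not both")
        if self.simulate is None and self.phenotypes_path is None:
            raise ValueError("either 'simulate' or input file paths are required")
        if self.reconstruct_pedigree and self.pedigree_path is not None:
            raise ValueError("cannot both reconstruct the pedigree and read it from a file")
        if self.reconstruct_pedigree and self.genotypes_path is None and self.simulate is None:
            raise ValueError("pedigree reconstruction requires genotypes")
        if self.preset not in ("fast", "paper"):
            raise ValueError(f"unknown preset {self.preset!r}")

    def univariate_schedule(self) -> tuple[int, int, int]:
        if self.schedule is not None:
            return self.schedule
        return am.SCHEDULES["paper" if self.preset == "paper" else "fast"]

    def bivariate_schedule_(self) -> tuple[int, int, int]:
        if self.bivariate_schedule is not None:
            return self.bivariate_schedule
        return am.SCHEDULES["paper_bivariate" if self.preset == "paper" else "fast_bivariate"]


@dataclass
class ResultBundle:
    config: RunConfig
    pedigree: Pedigree
    locus_summaries: dict | None
    dic_table: pd.DataFrame
    ratio_table: pd.DataFrame
    bivariate_table: pd.DataFrame
    correlations: pd.DataFrame
    dimorphism: phenotypes.DimorphismResult | None
    assortative: pd.DataFrame | None
    manifest: dict


_SIM_MATRIX_FIELDS = ("G", "M", "N", "R")
_SIM_TUPLE_FIELDS = ("chamber_distribution", "clutch_range", "trait_names", "trait_means")


def _simconfig_to_jsonable(sc: SimConfig) -> dict:
    out = dataclasses.asdict(sc)
    for key in _SIM_MATRIX_FIELDS:
        out[key] = np.asarray(out[key]).tolist()
    if out.get("allele_freqs") is not None:
        out["allele_freqs"] = [list(map(float, f)) for f in out["allele_freqs"]]
    if not np.isscalar(out.get("null_freq")):
        out["null_freq"] = list(out["null_freq"])
    return out


def _simconfig_from_jsonable(d: dict) -> SimConfig:
    kwargs = dict(d)
    for key in _SIM_MATRIX_FIELDS:
        kwargs[key] = np.asarray(kwargs[key], dtype=float)
    for key in _SIM_TUPLE_FIELDS:
        if kwargs.get(key) is not None:
            val = kwargs[key]
            kwargs[key] = tuple(
                tuple(x) if isinstance(x, (list, tuple)) else x for x in val
            )
    if kwargs.get("allele_freqs") is not None:
        kwargs["allele_freqs"] = tuple(tuple(f) for f in kwargs["allele_freqs"])
    if isinstance(kwargs.get("null_freq"), list):
        kwargs["null_freq"] = tuple(kwargs["null_freq"])
    return SimConfig(**kwargs)


def run_config_to_jsonable(cfg: RunConfig) -> dict:
    out = {
        f.name: getattr(cfg, f.name)
        for f in dataclasses.fields(RunConfig)
        if f.name != "simulate"
    }
    out["traits"] = list(cfg.traits)
    for key in ("schedule", "bivariate_schedule"):
        if out[key] is not None:
            out[key] = list(out[key])
    out["simulate"] = None if cfg.simulate is None else _simconfig_to_jsonable(cfg.simulate)
    return out


def run_config_from_jsonable(d: dict) -> RunConfig:
    kwargs = dict(d)
    sim = kwargs.pop("simulate", None)
    if sim is not None:
        kwargs["simulate"] = _simconfig_from_jsonable(sim)
    kwargs["traits"] = tuple(kwargs.get("traits", phenotypes.TRAITS))
    for key in ("schedule", "bivariate_schedule"):
        if kwargs.get(key) is not None:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def reconstruct_pedigree(
    gt: msat.GenotypeTable,
    summaries: dict[str, msat.LocusSummary],
    candidate_dams: list[str],
    candidate_sires: list[str],
    offspring: list[str],
    *,
    threshold: float = 0.99,
    use_null: bool = True,
) -> Pedigree:
    """Likelihood parentage assignment of every offspring against the adult
    candidate lists; unassigned parents stay unknown."""
    records = [PedigreeRecord(a, None, None, "F") for a in candidate_dams]
    records += [PedigreeRecord(a, None, None, "M") for a in candidate_sires]
    for off in offspring:
        dam_res = msat.assign_parentage(
            off, None, candidate_dams, gt, summaries, threshold=threshold, use_null=use_null
        )
        sire_res = msat.assign_parentage(
            off, dam_res.assigned, candidate_sires, gt, summaries,
            threshold=threshold, use_null=use_null,
        )
        records.append(PedigreeRecord(off, dam_res.assigned, sire_res.assigned, "U"))
    return Pedigree(records, add_missing_parents=True)


def _load_genotypes(path: str) -> msat.GenotypeTable:
    if path.endswith((".gen", ".genepop", ".txt")):
        return msat.GenotypeTable.from_genepop(path)
    return msat.GenotypeTable.from_wide_csv(path)


def run_pipeline(cfg: RunConfig) -> ResultBundle:
    """Execute all stages; any failure aborts with the stage name and a
    partial manifest on disk."""
    cfg.validate()
    os.makedirs(cfg.output_dir, exist_ok=True)
    manifest: dict = {
        "package_version": pedqg.__version__,
        "seed": cfg.seed,
        "preset": cfg.preset,
        "run_config": run_config_to_jsonable(cfg),
        "inputs": {},
        "stages": [],
    }
    t_start = time.time()
    stage = "setup"

    def _done(name: str, t0: float) -> None:
        manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3)})

    def _write_manifest() -> None:
        with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        # ------------------------------------------------------------------ inputs
        t0 = time.time()
        stage = "load-inputs"
        if cfg.simulate is not None:
            sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
            ds = simulate_dataset(sim_cfg)
            gt = ds.genotypes
            traits = ds.traits
            true_ped: Pedigree | None = ds.colony.pedigree
            manifest["inputs"]["simulation"] = {
                k: str(v) for k, v in dataclasses.asdict(sim_cfg).items()
            }
        else:
            gt = _load_genotypes(cfg.genotypes_path) if cfg.genotypes_path else None
            traits = pd.read_csv(cfg.phenotypes_path)
            true_ped = None
            for key in ("pedigree_path", "genotypes_path", "phenotypes_path"):
                p = getattr(cfg, key)
                if p:
                    manifest["inputs"][key] = _hash_file(p)
        _done(stage, t0)

        # ------------------------------------------------------------------ locus QC
        t0 = time.time()
        stage = "locus-qc"
        summaries = None
        if gt is not None:
            summaries = msat.summarize_loci(gt, hwe_seed=cfg.seed)
            msat.write_locus_summaries(
                summaries, os.path.join(cfg.output_dir, "locus_summaries.csv")
            )
            manifest["combined_exclusion"] = {
                "q1": msat.combined_exclusion(s.q1 for s in summaries.values()),
                "q2": msat.combined_exclusion(s.q2 for s in summaries.values()),
            }
        _done(stage, t0)

        # ------------------------------------------------------------------ pedigree
        t0 = time.time()
        stage = "pedigree"
        if cfg.reconstruct_pedigree:
            if gt is None or summaries is None:
                raise PipelineError(stage, "genotypes required for reconstruction")
            adults = traits.loc[traits["age_class"] == "adult"]
            dams = adults.loc[adults["sex"] == "F", "id"].tolist()
            sires = adults.loc[adults["sex"] == "M", "id"].tolist()
            offspring = traits.loc[traits["age_class"] == "nestling", "id"].tolist()
            ped = reconstruct_pedigree(gt, summaries, dams, sires, offspring)
        elif cfg.pedigree_path is not None:
            ped = read_pedigree(cfg.pedigree_path)
        elif true_ped is not None:
            ped = true_ped
        else:
            raise PipelineError(stage, "no pedigree source")
        write_pedigree(ped, os.path.join(cfg.output_dir, "pedigree_used.csv"))
        manifest["pedigree_summary"] = dataclasses.asdict(pedigree_summary(ped))
        _done(stage, t0)

        t0 = time.time()
        stage = "relationship-matrix"
        A = additive_relationship_matrix(ped)
        A.to_triplet_csv(os.path.join(cfg.output_dir, "relationship_matrix.csv"))
        _done(stage, t0)

        # ------------------------------------------------------------------ filter
        t0 = time.time()
        stage = "fledge-filter"
        model_traits = traits
        if cfg.fledge_cutoff is not None and "weight" in traits.columns:
            model_traits = phenotypes.filter_fledged(traits, cfg.fledge_cutoff)
        _done(stage, t0)

        # ------------------------------------------------------------------ univariate
        t0 = time.time()
        stage = "univariate-models"
        total, burn, thin = cfg.univariate_schedule()
        dic_rows = []
        ratio_rows = []
        fit_index = 0
        for trait in cfg.traits:
            if trait not in model_traits.columns:
                continue
            dics = {}
            for label, terms in MODEL_GRID.items():
                spec = am.AnimalModelSpec(
                    traits=(trait,), random_terms=terms,
                    n_iter=total, burn_in=burn, thin=thin,
                    seed=cfg.seed + 1000 + fit_index,
                )
                fit_index += 1
                fit = am.fit_univariate(spec, model_traits, ped)
                dic = am.compute_dic(fit)
                dics[label] = dic
                vd = am.variance_ratios(fit)
                for ratio_name, summ in (("h2", vd.h2), ("me2", vd.me2), ("ne2", vd.ne2)):
                    ratio_rows.append(
                        dict(trait=trait, model=label, ratio=ratio_name,
                             mode=summ.mode, hpd_low=summ.hpd_low, hpd_high=summ.hpd_high)
                    )
            comparison = am.select_models(dics)
            for label in MODEL_GRID:
                dic_rows.append(
                    dict(trait=trait, model=label, dic=dics[label],
                         delta_dic=comparison.delta[label],
                         retained=label in comparison.retained)
                )
        dic_table = pd.DataFrame(dic_rows)
        ratio_table = pd.DataFrame(ratio_rows)
        dic_table.to_csv(os.path.join(cfg.output_dir, "univariate_dic.csv"), index=False)
        ratio_table.to_csv(os.path.join(cfg.output_dir, "variance_ratios.csv"), index=False)
        _done(stage, t0)

        # ------------------------------------------------------------------ bivariate
        t0 = time.time()
        stage = "bivariate-models"
        btotal, bburn, bthin = cfg.bivariate_schedule_()
        nestlings = model_traits
        if "age_class" in model_traits.columns:
            nestlings = model_traits.loc[model_traits["age_class"] == "nestling"]
        biv_rows = []
        avail = [t for t in cfg.traits if t in nestlings.columns]
        for i, tx in enumerate(avail):
            for ty in avail[i + 1 :]:
                spec = am.AnimalModelSpec(
                    traits=(tx, ty), random_terms=("additive",),
                    n_iter=btotal, burn_in=bburn, thin=bthin,
                    seed=cfg.seed + 5000 + fit_index,
                )
                fit_index += 1
                try:
                    fit = am.fit_bivariate(spec, nestlings, ped)
                except am.ModelError as exc:
                    logger.warning("bivariate %s/%s skipped: %s", tx, ty, exc)
                    continue
                cors = am.genetic_correlation(fit)
                row = dict(trait_x=tx, trait_y=ty)
                for kind, label in (("r_G", "genetic"), ("r_M", "maternal"), ("r_N", "nest")):
                    if kind in cors:
                        s = cors[kind]
                        row[label] = s.mode
                        row[f"{label}_low"] = s.hpd_low
                        row[f"{label}_high"] = s.hpd_high
                        row[f"{label}_significant"] = not (s.hpd_low <= 0.0 <= s.hpd_high)
                    else:
                        row[label] = ""
                        row[f"{label}_low"] = ""
                        row[f"{label}_high"] = ""
                        row[f"{label}_significant"] = ""
                biv_rows.append(row)
        bivariate_table = pd.DataFrame(biv_rows)
        bivariate_table.to_csv(
            os.path.join(cfg.output_dir, "bivariate_correlations.csv"), index=False
        )
        _done(stage, t0)

        # ------------------------------------------------------------------ phenotype stats
        t0 = time.time()
        stage = "phenotype-stats"
        avail_traits = tuple(t for t in cfg.traits if t in traits.columns)
        nest_tab = traits
        if "age_class" in traits.columns:
            nest_tab = traits.loc[traits["age_class"] == "nestling"]
        correlations = phenotypes.trait_correlations(nest_tab, avail_traits)
        correlations.to_csv(
            os.path.join(cfg.output_dir, "trait_correlations.csv"), index=False
        )
        dimorphism = None
        try:
            dimorphism = phenotypes.sex_dimorphism_tests(traits, avail_traits)
            dimorphism.anova.to_csv(
                os.path.join(cfg.output_dir, "dimorphism_anova.csv"), index=False
            )
        except phenotypes.StatsError as exc:
            logger.warning("dimorphism tests skipped: %s", exc)
        assort = None
        pairs = phenotypes.build_pair_table(ped, traits, avail_traits)
        if len(pairs) >= 3:
            arows = []
            for tr in avail_traits:
                try:
                    r, p, n = phenotypes.assortative_mating(pairs, tr)
                    arows.append(dict(trait=tr, r=r, p=p, n=n))
                except phenotypes.StatsError:
                    pass
            assort = pd.DataFrame(arows)
            assort.to_csv(os.path.join(cfg.output_dir, "assortative_mating.csv"), index=False)
        _done(stage, t0)

        manifest["total_seconds"] = round(time.time() - t_start, 3)
        _write_manifest()
    except PipelineError:
        _write_manifest()
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        _write_manifest()
        raise PipelineError(stage, str(exc)) from exc

    bundle = ResultBundle(
        config=cfg,
        pedigree=ped,
        locus_summaries=summaries,
        dic_table=dic_table,
        ratio_table=ratio_table,
        bivariate_table=bivariate_table,
        correlations=correlations,
        dimorphism=dimorphism,
        assortative=assort,
        manifest=manifest,
    )
    with open(os.path.join(cfg.output_dir, "report.md"), "w") as fh:
        fh.write(render_report(bundle))
    return bundle


def render_report(bundle: ResultBundle) -> str:
    """Human-readable summary; retained models (delta DIC < 7) are bolded and
    correlations carry significance stars."""
    lines = ["# Analysis report", ""]
    ped_sum = bundle.manifest.get("pedigree_summary")
    if ped_sum:
        lines.append(
            f"Pedigree: {ped_sum['n_individuals']} individuals, "
            f"{ped_sum['n_founders']} founders, "
            f"{ped_sum['n_full_sib_pairs']} full-sib pairs."
        )
        lines.append("")

    lines.append("## Model selection (DIC)")
    if bundle.dic_table.empty:
        lines.append("no univariate fits")
    else:
        lines.append("| trait | model | DIC | dDIC |")
        lines.append("|---|---|---|---|")
        for _, r in bundle.dic_table.iterrows():
            cell = f"{r.dic:.2f} | {r.delta_dic:.2f}"
            if r.retained:
                cell = f"**{r.dic:.2f}** | **{r.delta_dic:.2f}**"
            lines.append(f"| {r.trait} | {r.model} | {cell} |")
    lines.append("")

    lines.append("## Variance ratios (posterior mode [95% HPD])")
    if bundle.ratio_table.empty:
        lines.append("no ratio summaries")
    else:
        for trait, grp in bundle.ratio_table.groupby("trait", sort=False):
            lines.append(f"### {trait}")
            for _, r in grp.iterrows():
                bar_pos = int(round(20 * min(max(r["mode"], 0.0), 1.0)))
                bar = "-" * bar_pos + "o" + "-" * (20 - bar_pos)
                lines.append(
                    f"  {r['model']:<24s} {r['ratio']:>4s} "
                    f"{r['mode']:.3f} [{r['hpd_low']:.3f}, {r['hpd_high']:.3f}]  |{bar}|"
                )
    lines.append("")

    lines.append("## Bivariate correlations")
    if bundle.bivariate_table.empty:
        lines.append("no pairs fitted")
    else:
        for _, r in bundle.bivariate_table.iterrows():
            cells = []
            for kind in ("genetic", "maternal", "nest"):
                v = r.get(kind, "")
                if v == "" or pd.isna(v):
                    cells.append("-")
                else:
                    star = "*" if r.get(f"{kind}_significant") is True else ""
                    cells.append(f"{v:.3f}{star} ({r[f'{kind}_low']:.3f}..{r[f'{kind}_high']:.3f})")
            lines.append(f"| {r.trait_x}/{r.trait_y} | " + " | ".join(cells) + " |")
    lines.append("")

    lines.append("## Phenotypic correlations")
    if bundle.correlations.empty:
        lines.append("no correlations")
    else:
        for _, r in bundle.correlations.iterrows():
            lines.append(f"| {r.trait_x}/{r.trait_y} | {r.r:.3f} {r.stars} |")
    if bundle.dimorphism is not None:
        m = bundle.dimorphism.manova
        lines.append("")
        lines.append(
            f"MANOVA sex dimorphism: Wilks lambda = {m.wilks_lambda:.3f}, "
            f"df1 = {m.df1:.0f}, df2 = {m.df2:.0f}, p = {m.p:.3f}"
        )
    if bundle.assortative is not None and not bundle.assortative.empty:
        lines.append("")
        lines.append("## Assortative mating")
        for _, r in bundle.assortative.iterrows():
            note = " (low power)" if r.n < 10 else ""
            lines.append(f"| {r.trait} | r = {r.r:.3f}, p = {r.p:.4f}, n = {r.n}{note} |")
    return "\n".join(lines) + "\n"
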