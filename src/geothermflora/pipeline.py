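"""Orchestrate the full synthetic-data analysis from a single seeded config.

Stages: generate (or load) the dataset; taxon over/under-representation per
rank and thermophyte group; NRI phylogenetic clustering averaged over three
graft variants of the backbone tree (a fraction of species is pruned and
re-grafted by each placement method, mirroring the usual megatree
situation where not every pool species has a tip); pairwise zone-overlap
permutation tests; the edaphic importance screen with its thermophyte
Fisher aggregation; and soil indices plus zone comparisons.  Every stage's
randomness derives from the single run seed, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib
import shutil
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edaphic import importance_matrix, thermophyte_property_test
from .enrichment import enrich_table
from .exceptions import InvalidConfigError, PipelineError
from .nri import NriResult, nri_procedure
from .soil import group_samples, normalize_to_reference, silica_r2o3, sti, temp_gradient, zone_compare
from .synthetic import SyntheticConfig, SyntheticDataset, generate, write_dataset
from .trees import GraftMethod, graft_species, patristic_matrix

__all__ = ["RunConfig", "RunReport", "run_all", "demo"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("enrichment", "nri", "zones", "edaphic", "soil")
ENRICH_GROUPS = ("obligate", "facultative", "thermal", "non_thermal")
ENRICH_RANKS = ("family", "order", "class")


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    alpha_enrich: float = 0.05
    fdr_level: float = 0.15
    alpha_edaphic: float = 0.01
    nri_reps: int = 10
    nri_draws: int = 10_000
    nri_max_pairs: int = 100
    zone_draws: int = 1000
    edaphic_n_perm: int = 999
    graft_fraction: float = 0.23  # ~68 of 292 species pruned and re-grafted

    def __post_init__(self):
        for name, v in (
            ("alpha_enrich", self.alpha_enrich),
            ("fdr_level", self.fdr_level),
            ("alpha_edaphic", self.alpha_edaphic),
        ):
            if not 0 < v < 1:
                raise InvalidConfigError(f"{name} must be in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise InvalidConfigError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunReport:
    outdir: pathlib.Path
    dataset: SyntheticDataset
    enrichment: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    nri: dict[str, NriResult] = field(default_factory=dict)
    zone_overlap: dict[str, pd.DataFrame] = field(default_factory=dict)
    importance: pd.DataFrame | None = None
    fisher: pd.DataFrame | None = None
    soil_indices: pd.DataFrame | None = None
    gradient_angles: pd.DataFrame | None = None
    angle_compare: pd.DataFrame | None = None
    zone_profiles: pd.DataFrame | None = None


def _group_species(taxonomy: pd.DataFrame, group: str) -> set[str]:
    if group == "thermal":
        mask = taxonomy["status"].isin(("obligate", "facultative"))
    else:
        mask = taxonomy["status"] == group
    return set(taxonomy.loc[mask, "species"])


def _tsv(df: pd.DataFrame, path: pathlib.Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _stage_enrichment(cfg: RunConfig, report: RunReport, out: pathlib.Path) -> None:
    tax = report.dataset.taxonomy
    for group in ENRICH_GROUPS:
        species = _group_species(tax, group)
        for rank in ENRICH_RANKS:
            table = enrich_table(tax, species, rank, cfg.alpha_enrich, cfg.fdr_level)
            report.enrichment[(group, rank)] = table
            _tsv(table, out / "enrichment" / f"{group}_{rank}.tsv")


def _graft_variants(cfg: RunConfig, ds: SyntheticDataset, rng: np.random.Generator):
    """Three re-grafted trees: prune a fraction, re-attach by each method."""
    tax = ds.taxonomy
    fam_counts = tax["family"].value_counts().to_dict()
    n_drop = int(round(cfg.graft_fraction * len(tax)))
    order = rng.permutation(len(tax))
    drop: list[str] = []
    remaining = dict(fam_counts)
    for i in order:
        if len(drop) >= n_drop:
            break
        sp = tax["species"].iloc[i]
        fam = tax["family"].iloc[i]
        if remaining[fam] >= 2:  # keep every family represented
            drop.append(sp)
            remaining[fam] -= 1
    trees = []
    for method in GraftMethod:
        pruned = ds.tree.clone(depth=1)
        pruned.prune_taxa_with_labels(drop)
        trees.append(
            graft_species(pruned, tax, drop, method, seed=np.random.default_rng(rng.integers(2**31)))
        )
    return trees


def _stage_nri(cfg: RunConfig, report: RunReport, out: pathlib.Path,
               rng: np.random.Generator) -> None:
    ds = report.dataset
    trees = _graft_variants(cfg, ds, rng)
    pool = sorted(ds.taxonomy["species"])
    dists = [patristic_matrix(t, pool) for t in trees]
    rows = []
    for group in ("obligate", "facultative", "thermal"):
        species = sorted(_group_species(ds.taxonomy, group))
        if len(species) < 2:
            logger.info("NRI: group %s has <2 species, skipped", group)
            continue
        res = nri_procedure(
            dists, species, pool,
            reps=cfg.nri_reps, n_draws=cfg.nri_draws,
            max_pairs=cfg.nri_max_pairs, seed=rng,
        )
        report.nri[group] = res
        row = {
            "group": group, "n_species": len(species),
            "nri": res.nri, "p_value": res.p_value,
            "mpd_obs": res.mpd_obs, "null_mean": res.null_mean,
            "null_sd": res.null_sd, "n_pairs": res.n_pairs_used,
            "trees": res.trees_used,
        }
        for t, (m_nri, m_p) in enumerate(zip(res.per_tree_median_nri, res.per_tree_median_p)):
            row[f"tree{t + 1}_median_nri"] = m_nri
            row[f"tree{t + 1}_median_p"] = m_p
        rows.append(row)
    _tsv(pd.DataFrame(rows), out / "nri" / "nri_report.tsv")


def _stage_zones(cfg: RunConfig, report: RunReport, out: pathlib.Path,
                 rng: np.random.Generator) -> None:
    from .zones import all_pairs_matrix

    ds = report.dataset
    pool = sorted(set().union(*ds.zone_species.values()))
    mats = all_pairs_matrix(ds.zone_species, pool, cfg.zone_draws, rng)
    report.zone_overlap = mats
    for key, df in mats.items():
        _tsv(df, out / "zones" / f"overlap_{key}.tsv", index=True)


def _stage_edaphic(cfg: RunConfig, report: RunReport, out: pathlib.Path,
                   rng: np.random.Generator) -> None:
    ds = report.dataset
    imp = importance_matrix(
        ds.cover, ds.plot_soil, alpha=cfg.alpha_edaphic,
        n_perm=cfg.edaphic_n_perm, seed=rng,
    )
    statuses = dict(zip(ds.taxonomy["species"], ds.taxonomy["status"]))
    fisher = thermophyte_property_test(imp, statuses)
    report.importance = imp
    report.fisher = fisher
    _tsv(imp, out / "edaphic" / "importance.tsv")
    _tsv(fisher, out / "edaphic" / "thermophyte_fisher.tsv")


def _stage_soil(cfg: RunConfig, report: RunReport, out: pathlib.Path) -> None:
    ds = report.dataset
    soil = ds.soil.copy()
    soil["STI"] = [
        sti(r.SiO2, r.TiO2, r.Al2O3) for r in soil.itertuples()
    ]
    soil["silica_r2o3"] = [
        silica_r2o3(r.SiO2, r.Al2O3, r.Fe2O3, r.TiO2) for r in soil.itertuples()
    ]
    report.soil_indices = soil
    _tsv(soil, out / "soil" / "soil_indices.tsv")

    pits = soil.drop_duplicates("pit")
    angles = pd.DataFrame(
        {
            "pit": pits["pit"],
            "zone": pits["zone"],
            "k": [temp_gradient([(15.0, r.T15), (50.0, r.T50)])[0] for r in pits.itertuples()],
            "alpha_deg": [
                temp_gradient([(15.0, r.T15), (50.0, r.T50)])[1] for r in pits.itertuples()
            ],
        }
    )
    report.gradient_angles = angles
    _tsv(angles, out / "soil" / "gradient_angles.tsv")

    by_zone = {z: g["alpha_deg"].to_numpy() for z, g in angles.groupby("zone", sort=True)}
    if len(by_zone) >= 2:
        comp = zone_compare(by_zone, alternative="less")
        report.angle_compare = comp
        _tsv(comp, out / "soil" / "angle_zone_compare.tsv")

    topsoil = soil[soil["depth"] == soil["depth"].min()]
    comp_vars = [
        c for c in ("SiO2", "TiO2", "Al2O3", "Fe2O3", "kaolinite", "smectite",
                    "quartz", "sand", "silt", "clay", "SOC")
        if c in topsoil.columns
    ]
    profiles = normalize_to_reference(topsoil, comp_vars, reference="I")
    report.zone_profiles = profiles
    _tsv(profiles, out / "soil" / "topsoil_vs_zone_I.tsv", index=True)

    classed = group_samples(soil, "temperature_class")
    by_class = {
        c: g["pH"].to_numpy() for c, g in classed.groupby("group", sort=True) if len(g) >= 2
    }
    if len(by_class) >= 2:
        _tsv(zone_compare(by_class, alternative="two-sided"),
             out / "soil" / "pH_by_temperature_class.tsv")


_STAGE_FUNCS = {
    "enrichment": _stage_enrichment,
    "nri": _stage_nri,
    "zones": _stage_zones,
    "edaphic": _stage_edaphic,
    "soil": _stage_soil,
}


def run_all(config: RunConfig, outdir) -> RunReport:
    """Run the configured stages and write a reproducible report bundle.

    On stage failure the partially written output directory is removed and
    :class:`PipelineError` is raised naming the stage.
    """
    out = pathlib.Path(outdir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(len(ALL_STAGES))
    stage_rng = {name: np.random.default_rng(s) for name, s in zip(ALL_STAGES, seeds)}

    try:
        dataset = generate(config.synthetic)
        write_dataset(dataset, out / "data")
        report = RunReport(outdir=out, dataset=dataset)
        for stage in ALL_STAGES:
            if stage not in config.stages:
                logger.info("stage %s skipped (not in config.stages)", stage)
                continue
            try:
                func = _STAGE_FUNCS[stage]
                if stage == "enrichment":
                    func(config, report, out)
                elif stage == "soil":
                    func(config, report, out)
                else:
                    func(config, report, out, stage_rng[stage])
            except Exception as exc:
                raise PipelineError(stage, exc) from exc
        _write_manifest(config, report, out)
        return report
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise


def _write_manifest(config: RunConfig, report: RunReport, out: pathlib.Path) -> None:
    from .synthetic import _to_plain

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "thresholds": {
            "alpha_enrich": config.alpha_enrich,
            "fdr_level": config.fdr_level,
            "alpha_edaphic": config.alpha_edaphic,
        },
        "nri": {
            "reps": config.nri_reps,
            "draws": config.nri_draws,
            "max_pairs": config.nri_max_pairs,
            "graft_fraction": config.graft_fraction,
        },
        "zone_draws": config.zone_draws,
        "edaphic_n_perm": config.edaphic_n_perm,
        "synthetic": _to_plain(dataclasses.asdict(config.synthetic)),
        "planted": _to_plain(report.dataset.planted),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def demo(outdir, seed: int = 0) -> RunReport:
    """One-command all-synthetic demonstration run with planted signals."""
    cfg = RunConfig(synthetic=SyntheticConfig(seed=seed), seed=seed)
    return run_all(cfg, outdir)
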