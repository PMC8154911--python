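"""Synthetic geothermal flora and soil data with the structure the analysis assumes.

The generator emulates a volcanic-valley study system: a pool of roughly 292
vascular plant species in about 60 families on an ultrametric backbone
phylogeny; obligate and facultative thermophytes concentrated in small
clusters of related species; four thermal zones whose species richness
decreases toward the hot end while non-thermal species drop out first;
monotone soil-property gradients across the zones (temperature up, pH and
organic carbon down, clay and sesquioxides up, ...); and plot-level cover
values correlated with nominated soil properties through a Gaussian copula
so that a target Spearman correlation can be planted.

Everything is driven by a single integer seed: identical configuration and
seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .exceptions import InvalidConfigError
from .trees import read_newick_string

__all__ = [
    "GradientSpec",
    "CoverEffect",
    "SyntheticConfig",
    "SyntheticDataset",
    "gen_backbone_tree",
    "gen_thermal_status",
    "gen_zone_tables",
    "generate",
    "write_dataset",
    "load_dataset",
]

ZONES = ("I", "II", "III", "IV")
BIOMORPHS = ("herb", "graminoid", "shrub", "fern", "dwarf_shrub")


@dataclass(frozen=True)
class GradientSpec:
    """Per-property zone gradient: direction, per-zone means, noise, bounds."""

    direction: str  # up | down | flat
    zone_means: tuple[float, ...]
    noise_sd: float
    bounds: tuple[float, float] = (-math.inf, math.inf)

    def __post_init__(self):
        if self.direction not in ("up", "down", "flat"):
            raise InvalidConfigError(f"bad gradient direction {self.direction!r}")
        diffs = np.diff(self.zone_means)
        if self.direction == "up" and not (diffs >= 0).all():
            raise InvalidConfigError("direction 'up' requires non-decreasing means")
        if self.direction == "down" and not (diffs <= 0).all():
            raise InvalidConfigError("direction 'down' requires non-increasing means")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CoverEffect:
    """Planted cover-property dependence: species slot (index into the cover
    species list) or explicit name, target property, sign and Spearman-scale
    strength in (0, 1)."""

    property: str
    sign: int
    strength: float
    species: str | None = None
    species_slot: int = 0

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise InvalidConfigError("cover effect sign must be +1 or -1")
        if not 0 < self.strength < 1:
            raise InvalidConfigError("cover effect strength must be in (0, 1)")


def _default_gradients() -> dict[str, GradientSpec]:
    g = GradientSpec
    return {
        "pH": g("down", (6.2, 5.4, 4.4, 3.2), 0.25, (0.0, 14.0)),
        "EC": g("up", (0.10, 0.50, 1.50, 3.00), 0.10, (0.0, math.inf)),
        "Eh": g("down", (450.0, 350.0, 250.0, 150.0), 30.0),
        "SOC": g("down", (12.0, 8.0, 4.0, 1.5), 1.0, (0.0, 100.0)),
        "SiO2": g("down", (62.0, 58.0, 52.0, 45.0), 2.0, (0.1, 100.0)),
        "TiO2": g("up", (0.8, 1.0, 1.3, 1.6), 0.08, (0.01, 100.0)),
        "Al2O3": g("up", (14.0, 16.0, 19.0, 23.0), 1.0, (0.1, 100.0)),
        "Fe2O3": g("up", (5.0, 6.5, 8.0, 10.0), 0.5, (0.1, 100.0)),
        "kaolinite": g("up", (5.0, 15.0, 35.0, 60.0), 3.0, (0.0, 100.0)),
        "smectite": g("down", (25.0, 20.0, 12.0, 5.0), 2.0, (0.0, 100.0)),
        "quartz": g("down", (30.0, 25.0, 18.0, 10.0), 2.0, (0.0, 100.0)),
        "sand": g("down", (60.0, 45.0, 30.0, 15.0), 3.0, (0.0, 100.0)),
        "clay": g("up", (10.0, 20.0, 35.0, 55.0), 3.0, (0.0, 100.0)),
    }


def _default_cover_effects() -> tuple[CoverEffect, ...]:
    return (
        CoverEffect("EC", +1, 0.9, species_slot=0),
        CoverEffect("pH", -1, 0.85, species_slot=1),
        CoverEffect("SOC", +1, 0.8, species_slot=2),
    )


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 60 families / 292 species pool, 18 obligate and
    33 facultative thermophytes, four thermal zones of decreasing richness,
    12 cover plots along the gradient."""

    n_families: int = 60
    tips_per_family: tuple[int, int] = (1, 9)
    n_species: int = 292
    n_obligate: int = 18
    n_facultative: int = 33
    clustering_strength: float = 0.9
    n_zones: int = 4
    zone_richness: tuple[int, ...] = (24, 18, 12, 8)
    nested_zones: bool = True
    pits_per_zone: int = 3
    sample_depths: tuple[float, ...] = (10.0, 30.0, 50.0)
    t15_zone_means: tuple[float, ...] = (18.0, 38.0, 62.0, 90.0)
    t15_noise_sd: float = 2.0
    # temperature rise from 15 to 50 cm per zone; zone I ~3 C gives the
    # gentle 4.6-5.2 degree gradient angles of a non-heated profile
    t50_delta_means: tuple[float, ...] = (3.0, 9.5, 20.0, 2.0)
    t50_delta_sd: float = 0.1
    soil_gradient_spec: dict[str, GradientSpec] = field(default_factory=_default_gradients)
    n_plots: int = 12
    n_cover_species: int = 28
    n_cover_thermal: int = 9  # thermophytes among the cover species
    cover_effect_spec: tuple[CoverEffect, ...] = field(default_factory=_default_cover_effects)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.tips_per_family
        if self.n_families < 2 or lo < 1 or hi < lo:
            raise InvalidConfigError("need n_families >= 2 and 1 <= min <= max tips")
        if not self.n_families * lo <= self.n_species <= self.n_families * hi:
            raise InvalidConfigError(
                "n_species incompatible with n_families and tips_per_family bounds"
            )
        if self.n_obligate < 0 or self.n_facultative < 0:
            raise InvalidConfigError("thermophyte counts must be >= 0")
        if self.n_obligate + self.n_facultative > self.n_species:
            raise InvalidConfigError("more thermophytes requested than species")
        if not 0 <= self.clustering_strength <= 1:
            raise InvalidConfigError("clustering_strength must be in [0, 1]")
        if self.n_zones < 2 or self.n_zones > len(ZONES):
            raise InvalidConfigError("n_zones must be between 2 and 4")
        if len(self.zone_richness) != self.n_zones:
            raise InvalidConfigError("zone_richness length must equal n_zones")
        if any(r < 1 for r in self.zone_richness):
            raise InvalidConfigError("zone richness values must be >= 1")
        if any(np.diff(self.zone_richness) > 0):
            raise InvalidConfigError("zone_richness must be weakly decreasing")
        if max(self.zone_richness) > self.n_species:
            raise InvalidConfigError("zone richness exceeds pool size")
        if self.n_cover_species > self.n_species:
            raise InvalidConfigError("n_cover_species exceeds pool size")
        for spec in (self.t15_zone_means, self.t50_delta_means):
            if len(spec) < self.n_zones:
                raise InvalidConfigError("temperature means must cover every zone")
        for g in self.soil_gradient_spec.values():
            if len(g.zone_means) < self.n_zones:
                raise InvalidConfigError("gradient zone_means must cover every zone")

    @property
    def zones(self) -> tuple[str, ...]:
        return ZONES[: self.n_zones]


# ---------------------------------------------------------------------------
# backbone tree


def _family_sizes(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.tips_per_family
    sizes = rng.integers(lo, hi + 1, size=config.n_families)
    # repair to the exact requested pool size, staying within bounds
    while sizes.sum() != config.n_species:
        i = int(rng.integers(config.n_families))
        if sizes.sum() < config.n_species and sizes[i] < hi:
            sizes[i] += 1
        elif sizes.sum() > config.n_species and sizes[i] > lo:
            sizes[i] -= 1
    return sizes


def _coalesce(parts: list[tuple[str, float]], heights: np.ndarray, rng) -> tuple[str, float]:
    """Merge (newick, height) subtrees pairwise at increasing node heights."""
    parts = list(parts)
    for h in heights:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        (sa, ha), (sb, hb) = parts[i], parts[j]
        merged = f"({sa}:{h - ha:.10g},{sb}:{h - hb:.10g})"
        parts[j] = (merged, float(h))
        del parts[i]
    assert len(parts) == 1
    return parts[0]


def gen_backbone_tree(config: SyntheticConfig, rng: np.random.Generator | None = None):
    """Ultrametric depth-1 backbone tree plus a taxonomy table.

    Families are monophyletic clades; family crown ages fall below the
    shallowest between-family divergence, so the clade structure is clean.
    Returns ``(tree, taxonomy)`` where taxonomy has columns species, family,
    order, class, biomorph.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sizes = _family_sizes(config, rng)
    n_orders = max(2, config.n_families // 5)
    n_classes = 3 if n_orders >= 3 else 2

    records = []
    fam_parts = []
    sp = 0
    fam_order = rng.permutation(config.n_families)  # order/class assignment shuffle
    for f in range(config.n_families):
        fam = f"fam{f + 1:02d}"
        order = f"ord{(fam_order[f] % n_orders) + 1:02d}"
        klass = f"cls{(fam_order[f] % n_classes) + 1}"
        tips = []
        for _ in range(int(sizes[f])):
            sp += 1
            name = f"sp{sp:04d}"
            records.append(
                {
                    "species": name,
                    "family": fam,
                    "order": order,
                    "class": klass,
                    "biomorph": BIOMORPHS[int(rng.integers(len(BIOMORPHS)))],
                }
            )
            tips.append((name, 0.0))
        if len(tips) == 1:
            fam_parts.append(tips[0])
        else:
            crown = float(rng.uniform(0.15, 0.45))
            hs = np.sort(rng.uniform(0.02, 1.0, size=len(tips) - 1)) * crown
            hs[-1] = crown
            fam_parts.append(_coalesce(tips, hs, rng))

    bh = np.sort(rng.uniform(0.55, 1.0, size=config.n_families - 1))
    bh[-1] = 1.0
    newick, _ = _coalesce(fam_parts, bh, rng)
    tree = read_newick_string(newick + ";")
    taxonomy = pd.DataFrame(records)
    return tree, taxonomy


# ---------------------------------------------------------------------------
# thermal status


def gen_thermal_status(
    taxonomy: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign obligate / facultative / non_thermal statuses.

    Thermal species are drawn one at a time: with probability
    ``clustering_strength`` the next species comes from a family that
    already holds a thermal species (and still has unassigned members),
    otherwise uniformly from all unassigned species.  At strength 1 thermal
    species pack into as few families as the draw permits; at 0 the
    assignment is exchangeable, so per-family counts are hypergeometric.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if config.n_obligate + config.n_facultative > len(taxonomy):
        raise InvalidConfigError("requested thermophyte counts exceed the pool")
    fam_of = dict(zip(taxonomy["species"], taxonomy["family"]))
    remaining: dict[str, list[str]] = {}
    for sp_name, fam in fam_of.items():
        remaining.setdefault(fam, []).append(sp_name)
    thermal_families: list[str] = []
    status = {sp_name: "non_thermal" for sp_name in fam_of}

    def draw_one() -> str:
        slots = [f for f in thermal_families if remaining[f]]
        if slots and rng.random() < config.clustering_strength:
            fam = slots[int(rng.integers(len(slots)))]
        else:
            pool = [s for members in remaining.values() for s in members]
            pick = pool[int(rng.integers(len(pool)))]
            fam = fam_of[pick]
            if fam not in thermal_families:
                thermal_families.append(fam)
            remaining[fam].remove(pick)
            return pick
        members = remaining[fam]
        return members.pop(int(rng.integers(len(members))))

    for _ in range(config.n_obligate):
        status[draw_one()] = "obligate"
    for _ in range(config.n_facultative):
        status[draw_one()] = "facultative"

    out = taxonomy.copy()
    out["status"] = out["species"].map(status)
    return out


# ---------------------------------------------------------------------------
# zones, soil, cover


def _truncated_normal(rng, mean, sd, bounds, size=None):
    v = rng.normal(mean, sd, size=size)
    return np.clip(v, bounds[0], bounds[1])


_NT_WEIGHT = {1: 1.0, 2: 0.30, 3: 0.10, 4: 0.03}  # non-thermal weight by zone index
_OB_WEIGHT = {1: 0.05, 2: 1.0, 3: 1.0, 4: 1.0}  # obligate weight by zone index


def _weighted_subset(rng, candidates, weights, k):
    w = np.asarray(weights, dtype=float)
    p = w / w.sum()
    idx = rng.choice(len(candidates), size=k, replace=False, p=p)
    return [candidates[i] for i in sorted(idx)]


def _zone_species_sets(pool: pd.DataFrame, config: SyntheticConfig, rng):
    species = pool["species"].tolist()
    status = dict(zip(pool["species"], pool["status"]))
    zones = config.zones
    sets: dict[str, list[str]] = {}
    if not config.nested_zones:
        for z, r in zip(zones, config.zone_richness):
            sets[z] = _weighted_subset(rng, species, np.ones(len(species)), r)
        return sets

    def weight(sp, zi):
        st = status[sp]
        if st == "non_thermal":
            return _NT_WEIGHT[zi]
        if st == "obligate":
            return _OB_WEIGHT[zi]
        return 1.0

    # hot zones are nested: build the hottest first, grow toward zone II
    hot_zones = list(zones[1:])
    current: list[str] = []
    for z in reversed(hot_zones):
        zi = zones.index(z) + 1
        r = config.zone_richness[zones.index(z)]
        extra = r - len(current)
        candidates = [s for s in species if s not in current]
        w = [weight(s, zi) for s in candidates]
        current = current + _weighted_subset(rng, candidates, w, extra)
        sets[z] = sorted(current)
    # the non-heated zone is drawn independently, non-thermal species favored
    w = [weight(s, 1) for s in species]
    sets[zones[0]] = sorted(_weighted_subset(rng, species, w, config.zone_richness[0]))
    return {z: sets[z] for z in zones}


def _soil_row(config, rng, zone_idx, depth, t15, t50):
    k = (t50 - t15) / 35.0
    row = {"temperature": float(np.clip(t15 + k * (depth - 15.0), -20.0, 110.0))}
    for prop, g in config.soil_gradient_spec.items():
        row[prop] = float(
            _truncated_normal(rng, g.zone_means[zone_idx], g.noise_sd, g.bounds)
        )
    # particle-size closure: silt absorbs the remainder
    if "sand" in row and "clay" in row:
        sand, clay = row["sand"], row["clay"]
        total = sand + clay
        if total > 100.0:
            sand, clay = 100.0 * sand / total, 100.0 * clay / total
        row["sand"], row["clay"] = sand, clay
        row["silt"] = 100.0 - sand - clay
    return row


def _gen_soil_table(config: SyntheticConfig, rng) -> pd.DataFrame:
    rows = []
    pit = 0
    for zi, zone in enumerate(config.zones):
        for _ in range(config.pits_per_zone):
            pit += 1
            t15 = float(
                _truncated_normal(
                    rng, config.t15_zone_means[zi], config.t15_noise_sd, (-20.0, 108.0)
                )
            )
            delta = float(rng.normal(config.t50_delta_means[zi], config.t50_delta_sd))
            t50 = float(np.clip(t15 + delta, -20.0, 110.0))
            for depth in config.sample_depths:
                row = {"pit": f"pit{pit:02d}", "zone": zone, "depth": depth,
                       "T15": t15, "T50": t50}
                row.update(_soil_row(config, rng, zi, depth, t15, t50))
                rows.append(row)
    return pd.DataFrame(rows)


def _normal_scores(values: np.ndarray) -> np.ndarray:
    r = rankdata(values)
    return norm.ppf(r / (len(values) + 1.0))


def _gen_cover(config: SyntheticConfig, pool: pd.DataFrame, plot_soil: pd.DataFrame, rng):
    thermal = pool.loc[pool["status"] != "non_thermal", "species"].tolist()
    others = pool.loc[pool["status"] == "non_thermal", "species"].tolist()
    k = min(config.n_cover_thermal, len(thermal), config.n_cover_species)
    cover_species = (thermal[:k] + others)[: config.n_cover_species]

    effects = []
    for eff in config.cover_effect_spec:
        name = eff.species if eff.species is not None else cover_species[eff.species_slot]
        if name not in cover_species:
            raise InvalidConfigError(f"cover effect species {name!r} not in cover set")
        if eff.property not in plot_soil.columns:
            raise InvalidConfigError(f"cover effect property {eff.property!r} unknown")
        effects.append((name, eff))

    n = len(plot_soil)
    cover = {}
    planted = {name: eff for name, eff in effects}
    for sp_name in cover_species:
        if sp_name in planted:
            eff = planted[sp_name]
            zp = _normal_scores(plot_soil[eff.property].to_numpy())
            z = eff.sign * eff.strength * zp + math.sqrt(1 - eff.strength**2) * rng.normal(size=n)
        else:
            z = rng.normal(size=n)
        cover[sp_name] = 100.0 * norm.cdf(z)
    table = pd.DataFrame(cover, index=plot_soil.index)
    resolved = [
        {"species": name, "property": e.property, "sign": e.sign, "strength": e.strength}
        for name, e in effects
    ]
    return table, resolved


def _gen_plot_soil(config: SyntheticConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    zones = config.zones
    plot_rows = []
    soil_rows = []
    for i in range(config.n_plots):
        zi = i % len(zones)
        t15 = float(
            _truncated_normal(rng, config.t15_zone_means[zi], config.t15_noise_sd, (-20, 108))
        )
        delta = float(rng.normal(config.t50_delta_means[zi], config.t50_delta_sd))
        plot_rows.append({"plot": f"plot{i + 1:02d}", "zone": zones[zi]})
        soil_rows.append(_soil_row(config, rng, zi, 10.0, t15, t15 + delta))
    plots = pd.DataFrame(plot_rows).set_index("plot")
    plot_soil = pd.DataFrame(soil_rows, index=plots.index)
    plot_soil.insert(0, "temperature", plot_soil.pop("temperature"))
    return plots, plot_soil


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    tree: object  # dendropy.Tree
    taxonomy: pd.DataFrame  # species, family, order, class, biomorph, status
    zone_species: dict[str, list[str]]
    soil: pd.DataFrame
    plots: pd.DataFrame
    plot_soil: pd.DataFrame
    cover: pd.DataFrame
    planted: dict


def gen_zone_tables(
    pool: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator | None = None
):
    """Zone compositions, pit-level soil table, and plot cover matrix.

    ``pool`` must carry a ``status`` column (see :func:`gen_thermal_status`).
    Returns ``(zone_species, soil, plots, plot_soil, cover, planted_effects)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    zone_species = _zone_species_sets(pool, config, rng)
    soil = _gen_soil_table(config, rng)
    plots, plot_soil = _gen_plot_soil(config, rng)
    cover, planted = _gen_cover(config, pool, plot_soil, rng)
    return zone_species, soil, plots, plot_soil, cover, planted


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """End-to-end synthetic dataset from one config/seed."""
    config = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    tree, taxonomy = gen_backbone_tree(config, rng)
    pool = gen_thermal_status(taxonomy, config, rng)
    zone_species, soil, plots, plot_soil, cover, planted_effects = gen_zone_tables(
        pool, config, rng
    )
    thermal_families = sorted(
        pool.loc[pool["status"] != "non_thermal", "family"].unique()
    )
    return SyntheticDataset(
        config=config,
        tree=tree,
        taxonomy=pool,
        zone_species=zone_species,
        soil=soil,
        plots=plots,
        plot_soil=plot_soil,
        cover=cover,
        planted={
            "thermal_families": thermal_families,
            "cover_effects": planted_effects,
        },
    )


# ---------------------------------------------------------------------------
# I/O


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write tree (newick), tables (TSV) and the config (YAML) to a directory."""
    import pathlib

    import yaml

    from .trees import write_newick

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_newick(ds.tree, out / "tree.nwk")
    ds.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False, float_format="%.6g")
    zone_rows = [
        {"zone": z, "species": sp} for z, spp in ds.zone_species.items() for sp in spp
    ]
    pd.DataFrame(zone_rows).to_csv(out / "zones.tsv", sep="\t", index=False)
    ds.soil.to_csv(out / "soil.tsv", sep="\t", index=False, float_format="%.6g")
    ds.plots.to_csv(out / "plots.tsv", sep="\t", float_format="%.6g")
    ds.plot_soil.to_csv(out / "plot_soil.tsv", sep="\t", float_format="%.6g")
    ds.cover.to_csv(out / "cover.tsv", sep="\t", float_format="%.6g")
    cfg = _to_plain(dataclasses.asdict(ds.config))
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"synthetic": cfg, "planted": _to_plain(ds.planted)}, fh,
                       sort_keys=True)


def _to_plain(obj):
    """Recursively convert tuples and numpy scalars for YAML output."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_dataset(indir) -> SyntheticDataset:
    """Reload a dataset written by :func:`write_dataset`."""
    import pathlib

    import yaml

    from .trees import read_newick

    ind = pathlib.Path(indir)
    with open(ind / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    cfg_raw = raw["synthetic"]
    cfg_raw["soil_gradient_spec"] = {
        k: GradientSpec(
            direction=v["direction"],
            zone_means=tuple(v["zone_means"]),
            noise_sd=v["noise_sd"],
            bounds=tuple(v["bounds"]),
        )
        for k, v in cfg_raw["soil_gradient_spec"].items()
    }
    cfg_raw["cover_effect_spec"] = tuple(
        CoverEffect(**e) for e in cfg_raw["cover_effect_spec"]
    )
    for key in ("tips_per_family", "zone_richness", "sample_depths",
                "t15_zone_means", "t50_delta_means"):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = SyntheticConfig(**cfg_raw)
    zones_df = pd.read_csv(ind / "zones.tsv", sep="\t")
    zone_species = {
        z: sorted(sub["species"]) for z, sub in zones_df.groupby("zone", sort=False)
    }
    return SyntheticDataset(
        config=config,
        tree=read_newick(ind / "tree.nwk"),
        taxonomy=pd.read_csv(ind / "taxonomy.tsv", sep="\t"),
        zone_species=zone_species,
        soil=pd.read_csv(ind / "soil.tsv", sep="\t"),
        plots=pd.read_csv(ind / "plots.tsv", sep="\t", index_col="plot"),
        plot_soil=pd.read_csv(ind / "plot_soil.tsv", sep="\t", index_col="plot"),
        cover=pd.read_csv(ind / "cover.tsv", sep="\t", index_col="plot"),
        planted=raw["planted"],
    )
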