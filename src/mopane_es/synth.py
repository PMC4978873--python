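"""Synthetic study datasets for the Mopane-woodland trade-off pipeline.

The study's raw plot and survey microdata are not deposited, so every
downstream stage is exercised on generated data whose structure and
headline parameters mirror the published summaries: five woodland types
with the published stem densities, AGB, grass and coarse-woody-debris
levels as generator parameters; seven villages (A-G) in three
charcoal-chronosequence classes (post-boom, boom, pre-boom); a
species-service linkage table with the published cardinalities (6 charcoal
species, 5 firewood with 3 shared, 10 construction, 21 food, 39 medicine,
with "C. mopane" usable for all five tree services); and cut-stem
fractions that rise along the chronosequence.

Stem diameters are lognormal per woodland type, truncated at the 5 cm
inventory threshold, with the location parameter solved numerically so
that mean per-stem allometric biomass times stem density reproduces the
type's AGB.  Cut stems are generated by inflating a DBH down to stump
height with the same linear taper the inventory module inverts, so the
"no charcoal" scenario is an exact round trip in expectation.  All
generation is deterministic given the config seed.

Species names other than the five indicator taxa kept verbatim
("C. mopane", "A. johnsonii", "Combretum spp.", "B. albitrunca",
"Aloe spp.") are synthetic local names ("sp01", "sp02", ...).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .config import RunConfig, TREE_SERVICES
from .inventory import CwdPiece, Plot, Quadrat, StemRecord
from .production import ServiceDef, ServiceLinkTable

INDICATOR_SPECIES = ("C. mopane", "A. johnsonii", "Combretum spp.",
                     "B. albitrunca", "Aloe spp.")
SYNTH_SPECIES = tuple(f"sp{i:02d}" for i in range(1, 41))
SPECIES_POOL = INDICATOR_SPECIES + SYNTH_SPECIES

#: Measurement height used for generated stumps (m).
STUMP_POM = 0.3


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# woodland-type parameters


@dataclass
class TypeParams:
    """Generator parameters for one woodland type.

    The structural means are per-type study conditions (published plot-data
    characteristics); ``dbh_lognormal`` holds (mu, sigma) of the stem
    diameter distribution in cm, with mu solved so that per-stem biomass
    times density matches ``agb_mean``.
    """

    type_name: str
    stem_density_mean: float  # stems ha^-1
    agb_mean: float  # Mg C ha^-1
    grass_mean: float  # Mg ha^-1
    cwd_mean: float  # Mg C ha^-1
    species_pool: list[tuple[str, float]]
    dbh_lognormal: tuple[float, float]

    def __post_init__(self) -> None:
        for v in (self.stem_density_mean, self.agb_mean, self.grass_mean, self.cwd_mean):
            if v < 0:
                raise ConfigurationError("type means must be non-negative")
        w = sum(w for _, w in self.species_pool)
        if abs(w - 1.0) > 1e-6:
            raise ConfigurationError(f"species weights must sum to 1, got {w}")
        if self.dbh_lognormal[1] <= 0:
            raise ConfigurationError("dbh sigma must be positive")


def _trunc_lognormal_moment(mu: float, sigma: float, order: float,
                            lower: float) -> float:
    """E[X^order | X >= lower] for X ~ lognormal(mu, sigma), closed form."""
    z = (math.log(lower) - mu) / sigma
    tail = norm.sf(z)
    num = math.exp(order * mu + 0.5 * order**2 * sigma**2) * norm.sf(z - order * sigma)
    return num / tail


def solve_dbh_mu(target_stem_agb: float, sigma: float, a: float, b: float,
                 dmin: float = 5.0) -> float:
    """Solve the lognormal location so that mean truncated per-stem biomass
    ``a * E[D^b | D >= dmin]`` equals the target (Mg C per stem)."""

    def f(mu: float) -> float:
        return a * _trunc_lognormal_moment(mu, sigma, b, dmin) - target_stem_agb

    return brentq(f, math.log(0.5), math.log(80.0), xtol=1e-10)


def default_type_params(config: RunConfig | None = None) -> dict[str, TypeParams]:
    """The five woodland types with their published structural means."""
    config = config or RunConfig()
    a, b = config.allometry.a, config.allometry.b
    # Size-spread sigmas are generator assumptions (no per-species size
    # distributions are published): broad, comparable spreads for the
    # stem-rich types and a tight spread for the sparse shrub type keep
    # the five types' within-type compositional variances balanced, so no
    # single type dominates the clustering criterion.  The shrub pool is
    # dominated by C. mopane by AGB with Aloe as the compositional
    # indicator, consistent with the type's low published evenness.
    spec = [
        # name, density, agb, grass, cwd, sigma, pool
        ("Androstachys forest", 1764.0, 31.7, 0.06, 3.57, 0.50,
         [("A. johnsonii", 0.80), ("sp01", 0.06), ("sp02", 0.05),
          ("sp03", 0.04), ("C. mopane", 0.03), ("sp04", 0.02)]),
        ("Mopane woodland", 769.0, 11.8, 0.66, 0.90, 0.55,
         [("C. mopane", 0.78), ("Combretum spp.", 0.06), ("sp05", 0.05),
          ("sp06", 0.04), ("sp07", 0.04), ("sp01", 0.03)]),
        ("Combretum woodland", 639.0, 12.8, 1.06, 0.98, 0.55,
         [("Combretum spp.", 0.55), ("C. mopane", 0.10), ("sp08", 0.08),
          ("sp05", 0.07), ("sp09", 0.06), ("sp10", 0.05), ("sp02", 0.05),
          ("sp11", 0.04)]),
        ("Boscia woodland", 582.0, 5.4, 0.79, 0.72, 0.50,
         [("B. albitrunca", 0.60), ("C. mopane", 0.12), ("sp12", 0.10),
          ("sp08", 0.08), ("sp13", 0.06), ("sp06", 0.04)]),
        ("shrub Mopane", 103.0, 7.31, 0.34, 0.02, 0.20,
         [("Aloe spp.", 0.35), ("C. mopane", 0.65)]),
    ]
    out = {}
    for name, dens, agb, grass, cwd, sigma, pool in spec:
        mu = solve_dbh_mu(agb / dens, sigma, a, b)
        out[name] = TypeParams(name, dens, agb, grass, cwd, pool, (mu, sigma))
    return out


# ---------------------------------------------------------------------------
# study design


@dataclass
class VillageSpec:
    name: str
    chrono_class: str  # pre-boom | boom | post-boom
    landcover: dict[str, float]  # woodland type -> fraction of village area
    n_plots: int = 24
    households: int = 40
    cut_fraction: float | None = None  # overrides the class default

    def __post_init__(self) -> None:
        total = sum(self.landcover.values())
        if any(not 0 <= f <= 1 for f in self.landcover.values()) or total > 1 + 1e-9:
            raise ConfigurationError(
                f"village {self.name}: land-cover fractions must lie in [0,1] "
                f"and sum <= 1 (residual is 'other')")


def default_villages() -> list[VillageSpec]:
    """Seven villages in three chronosequence classes.

    Post-exclusion plot counts and household totals follow the published
    study design; land-cover mixes follow the published narrative (Mopane
    woodland dominating the southern post-boom villages, Combretum woodland
    and Androstachys forest the northern ones, Boscia and shrub Mopane
    woodland concentrated in village A).
    """
    return [
        VillageSpec("A", "post-boom",
                    {"Mopane woodland": 0.15, "Combretum woodland": 0.20,
                     "Boscia woodland": 0.35, "shrub Mopane": 0.12},
                    n_plots=23, households=38),
        VillageSpec("B", "post-boom",
                    {"Mopane woodland": 0.55, "Combretum woodland": 0.15},
                    n_plots=23, households=29),
        VillageSpec("C", "post-boom",
                    {"Mopane woodland": 0.40, "Combretum woodland": 0.30},
                    n_plots=20, households=63),
        VillageSpec("D", "boom",
                    {"Androstachys forest": 0.20, "Mopane woodland": 0.05,
                     "Combretum woodland": 0.50},
                    n_plots=19, households=42),
        VillageSpec("E", "boom",
                    {"Androstachys forest": 0.15, "Mopane woodland": 0.05,
                     "Combretum woodland": 0.60},
                    n_plots=23, households=58),
        VillageSpec("F", "pre-boom",
                    {"Androstachys forest": 0.20, "Mopane woodland": 0.40,
                     "Combretum woodland": 0.10},
                    n_plots=23, households=55),
        VillageSpec("G", "pre-boom",
                    {"Androstachys forest": 0.18, "Mopane woodland": 0.07,
                     "Combretum woodland": 0.50},
                    n_plots=23, households=27, cut_fraction=0.0),
    ]


@dataclass
class SynthConfig:
    """Full description of a synthetic study, deterministic given ``seed``."""

    villages: list[VillageSpec] = field(default_factory=default_villages)
    cut_fraction_by_class: dict[str, float] = field(
        default_factory=lambda: {"post-boom": 0.35, "boom": 0.15, "pre-boom": 0.05})
    burnt_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, f in self.cut_fraction_by_class.items():
            if not 0 <= f <= 1:
                raise ConfigurationError(f"cut fraction for {cls!r} not in [0,1]")

    def cut_fraction(self, village: VillageSpec) -> float:
        if village.cut_fraction is not None:
            return village.cut_fraction
        return self.cut_fraction_by_class[village.chrono_class]

    @property
    def class_map(self) -> dict[str, str]:
        return {v.name: v.chrono_class for v in self.villages}


# ---------------------------------------------------------------------------
# linkage table


def gen_linkage_table(seed: int, pool: tuple[str, ...] = SPECIES_POOL,
                      config: RunConfig | None = None) -> ServiceLinkTable:
    """Species-service linkage table with the study's cardinalities.

    Charcoal and firewood are highly selective (6 and 5 species, sharing
    exactly 3); construction uses 10 species; food and medicine are the
    least selective (21 and 39).  "C. mopane" appears in all five tree
    services.  The selective sets are fixed to species that occur in the
    woodland-type pools (so harvest scenarios bite); the diffuse food and
    medicine sets are filled from the remaining pool with the seeded RNG.
    """
    config = config or RunConfig()
    if len(set(pool)) < 39 or "C. mopane" not in pool:
        raise ConfigurationError("species pool must hold >= 39 names incl. 'C. mopane'")
    rng = np.random.default_rng(seed)
    charcoal = ["C. mopane", "Combretum spp.", "sp05", "sp06", "sp08", "sp12"]
    firewood = ["C. mopane", "Combretum spp.", "sp05",  # shared with charcoal
                "sp01", "sp09"]
    construction = ["C. mopane", "A. johnsonii", "B. albitrunca", "Combretum spp.",
                    "sp02", "sp06", "sp08", "sp10", "sp11", "sp13"]
    food_core = ["C. mopane", "B. albitrunca", "sp07", "sp09"]
    rest = [s for s in pool if s not in food_core]
    food = food_core + sorted(rng.choice(rest, size=21 - len(food_core), replace=False))
    med_pool = [s for s in pool if s != "C. mopane"]
    medicine = ["C. mopane"] + sorted(rng.choice(med_pool, size=38, replace=False))
    bands = config.dbh_bands
    defs = {
        svc: ServiceDef(frozenset(members), "biomass" if svc in
                        ("charcoal", "firewood", "construction") else "stem_density",
                        bands[svc])
        for svc, members in [("charcoal", charcoal), ("firewood", firewood),
                             ("construction", construction), ("food", food),
                             ("medicine", medicine)]
    }
    defs["grass"] = ServiceDef(frozenset(), "grass_potential", None)
    return ServiceLinkTable(defs)


# ---------------------------------------------------------------------------
# plot generation


def _sample_truncated_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                                lower: float, size: int) -> np.ndarray:
    """Exact inverse-CDF sampling of a lognormal truncated below at ``lower``."""
    z_lo = norm.cdf((math.log(lower) - mu) / sigma)
    u = rng.uniform(z_lo, 1.0, size=size)
    return np.exp(mu + sigma * norm.ppf(u))


def gen_plot(params: TypeParams, cut_fraction: float,
             seed: int | np.random.Generator, *,
             config: RunConfig | None = None,
             charcoal_species: frozenset[str] | None = None,
             charcoal_dmin: float = 10.0,
             plot_id: str = "P-01", village: str = "V", radius: float = 20.0,
             burnt: bool = False) -> Plot:
    """Generate one inventory plot of the given woodland type.

    The stem count is Poisson about density x plot area; diameters come
    from the type's truncated lognormal; a ``cut_fraction`` share of
    charcoal-suitable stems (charcoal-linked species at or above the
    charcoal diameter band) is flagged cut, with the stump diameter
    obtained by inflating the DBH down to stump height with the linear
    taper.  Four grass quadrats and four CWD transects are attached.
    """
    if not 0 <= cut_fraction <= 1:
        raise ConfigurationError("cut_fraction must be in [0, 1]")
    if params.stem_density_mean < 0:
        raise ConfigurationError("stem density must be non-negative")
    config = config or RunConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if charcoal_species is None:
        charcoal_species = frozenset(
        ["C. mopane", "Combretum spp.", "sp05", "sp06", "sp08", "sp12"])
    plot = Plot(plot_id=plot_id, village=village, radius=radius, burnt=burnt,
                stratum=params.type_name)
    area = plot.area_ha
    mu, sigma = params.dbh_lognormal
    names = [n for n, _ in params.species_pool]
    weights = np.array([w for _, w in params.species_pool])

    n = rng.poisson(params.stem_density_mean * area)
    if n > 0:
        species = rng.choice(names, p=weights, size=n)
        dbh = _sample_truncated_lognormal(rng, mu, sigma, 5.0, n)
        # ~10% of live stems measured below breast height (forks, swellings);
        # the recorded diameter is inflated with the same taper the
        # inventory correction removes, so correction is exact.
        pom = np.full(n, 1.3)
        odd = rng.random(n) < 0.10
        pom[odd] = rng.uniform(0.6, 1.1, size=odd.sum())
        suitable = np.array([sp in charcoal_species for sp in species]) & (dbh >= charcoal_dmin)
        cut = suitable & (rng.random(n) < cut_fraction)
        for i in range(n):
            if cut[i]:
                stump_h = float(rng.uniform(STUMP_POM, 0.6))
                d_stump = dbh[i] / (1.0 - config.taper * (1.3 - STUMP_POM))
                plot.stems.append(StemRecord(
                    plot_id=plot_id, species=str(species[i]), diameter=float(d_stump),
                    pom=STUMP_POM, alive=False, cut=True, stump_height=stump_h))
            else:
                d_rec = dbh[i] / (1.0 - config.taper * (1.3 - pom[i]))
                plot.stems.append(StemRecord(
                    plot_id=plot_id, species=str(species[i]), diameter=float(d_rec),
                    pom=float(pom[i]), alive=True, cut=False))

    # grass quadrats: plot-level dry grass around the type mean, split over
    # four quadrats with measurement noise; E[mean quadrat dry mass] equals
    # the type mean.
    plot_dry_g_m2 = params.grass_mean * 100.0 * rng.lognormal(-0.3**2 / 2, 0.3)
    for _ in range(4):
        dry = plot_dry_g_m2 * rng.lognormal(-0.2**2 / 2, 0.2)
        frac = rng.uniform(0.35, 0.55)
        plot.quadrats.append(Quadrat(fresh_g=dry / frac, dry_fraction=frac))

    # CWD: piece count Poisson with rate solved so the expected line-intersect
    # carbon equals the type mean.
    decay_p = np.array([0.15, 0.25, 0.25, 0.20, 0.15])
    classes = np.arange(1, 6)
    rho_bar = float((decay_p * np.array([config.decay_density[c] for c in classes])).sum())
    mu_c, sigma_c = math.log(0.07), 0.5
    e_d2 = _trunc_lognormal_moment(mu_c, sigma_c, 2.0, 0.03)
    L = plot.transect_length_m
    per_piece = math.pi**2 / (8 * L) * e_d2 * 1e4 * rho_bar * config.carbon_fraction
    lam = params.cwd_mean / per_piece if per_piece > 0 else 0.0
    for _ in range(rng.poisson(lam)):
        d_cm = float(_sample_truncated_lognormal(rng, mu_c, sigma_c, 0.03, 1)[0] * 100)
        plot.cwd_pieces.append(CwdPiece(
            diameter_cm=d_cm, length_m=float(rng.uniform(0.6, 4.0)),
            decay_class=int(rng.choice(classes, p=decay_p)),
            species=str(rng.choice(names, p=weights))))
    return plot


# ---------------------------------------------------------------------------
# full study dataset


@dataclass
class StudyDataset:
    """In-memory synthetic study: plots plus all delimited tables."""

    config: SynthConfig
    plots: list[Plot]
    links: ServiceLinkTable
    plots_df: pd.DataFrame
    stems_df: pd.DataFrame
    quadrats_df: pd.DataFrame
    cwd_df: pd.DataFrame
    landcover_df: pd.DataFrame
    survey_df: pd.DataFrame
    trends_df: pd.DataFrame
    truth: dict

    @property
    def class_map(self) -> dict[str, str]:
        return self.config.class_map

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.plots_df.to_csv(outdir / "plots.csv", index=False)
        self.stems_df.to_csv(outdir / "stems.csv", index=False)
        self.quadrats_df.to_csv(outdir / "quadrats.csv", index=False)
        self.cwd_df.to_csv(outdir / "cwd.csv", index=False)
        self.landcover_df.to_csv(outdir / "landcover.csv", index=False)
        self.links.to_csv(outdir / "links.csv")
        self.survey_df.to_csv(outdir / "survey.csv", index=False)
        self.trends_df.to_csv(outdir / "trends.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        (outdir / "synth_config.yaml").write_text(
            yaml.safe_dump(_synth_config_dict(self.config), sort_keys=True))


def _synth_config_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    return d


def _allocate_plots(landcover: dict[str, float], n_plots: int) -> dict[str, int]:
    """Largest-remainder allocation of plots to woodland types, proportional
    to the woodland share of the village landscape; every type with a
    nonzero fraction receives at least one plot so the class-level
    parameter table has no structural holes."""
    types = [t for t, f in landcover.items() if f > 0]
    fracs = np.array([landcover[t] for t in types])
    fracs = fracs / fracs.sum()
    raw = fracs * n_plots
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > n_plots:
        i = int(np.argmax(counts))
        counts[i] -= 1
    rem = raw - np.floor(raw)
    order = np.argsort(-rem)
    i = 0
    while counts.sum() < n_plots:
        counts[order[i % len(types)]] += 1
        i += 1
    return dict(zip(types, (int(c) for c in counts)))


# class-level service-use probabilities for the synthetic household survey;
# charcoal production is zeroed in villages with no cutting.
_SURVEY_P = {
    "charcoal": {"post-boom": 0.88, "boom": 0.57, "pre-boom": 0.60},
    "firewood": {"post-boom": 0.97, "boom": 0.95, "pre-boom": 1.0},
    "construction": {"post-boom": 0.58, "boom": 0.58, "pre-boom": 0.70},
    "grass": {"post-boom": 0.45, "boom": 0.30, "pre-boom": 0.25},
    "food": {"post-boom": 0.20, "boom": 0.19, "pre-boom": 0.18},
    "medicine": {"post-boom": 0.16, "boom": 0.15, "pre-boom": 0.15},
    "livestock": {"post-boom": 0.40, "boom": 0.40, "pre-boom": 0.60},
}


def _gen_survey(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for v in config.villages:
        n = int(round(v.households * rng.uniform(0.72, 0.90)))
        cut = config.cut_fraction(v)
        row = {"village": v.name, "class": v.chrono_class,
               "households_total": v.households, "households_sampled": n}
        for svc, p_by_class in _SURVEY_P.items():
            p = p_by_class[v.chrono_class]
            if svc == "charcoal" and cut == 0:
                p = 0.0
            row[svc] = int(rng.binomial(n, p))
        rows.append(row)
    return pd.DataFrame(rows)


def _gen_trends(config: SynthConfig) -> pd.DataFrame:
    """Perceived temporal trends implied by the generator's own cutting
    history: heavily cut villages perceive declines in the wood services,
    untouched villages report no change (charcoal 'n.a.' where production
    never started)."""
    rows = []
    for v in config.villages:
        cut = config.cut_fraction(v)
        rows.append({
            "village": v.name, "class": v.chrono_class,
            "charcoal": "not_applicable" if cut == 0
            else ("decline" if cut >= 0.15 else "no_change"),
            "firewood": "decline" if cut >= 0.35 else "no_change",
            "construction": "decline" if cut >= 0.15 else "no_change",
            "food": "no_change", "medicine": "no_change", "grass": "no_change",
        })
    return pd.DataFrame(rows)


def gen_dataset(config: SynthConfig | None = None,
                run_config: RunConfig | None = None) -> StudyDataset:
    """Generate the full synthetic study, deterministic given the seed."""
    config = config or SynthConfig()
    run_config = run_config or RunConfig()
    type_params = default_type_params(run_config)
    links = gen_linkage_table(config.seed, config=run_config)
    charcoal_species = links.species_for("charcoal")
    charcoal_dmin = run_config.dbh_bands["charcoal"][0]

    ss = np.random.SeedSequence(config.seed)
    rng_misc = np.random.default_rng(ss.spawn(1)[0])

    plots: list[Plot] = []
    truth_labels: dict[str, str] = {}
    landcover_rows = []
    for v_i, v in enumerate(config.villages):
        for t, f in v.landcover.items():
            if t not in type_params:
                raise ConfigurationError(f"unknown woodland type {t!r} in village {v.name}")
            landcover_rows.append({"village": v.name, "type": t, "fraction": f})
        landcover_rows.append({"village": v.name, "type": "other",
                               "fraction": round(1.0 - sum(v.landcover.values()), 10)})
        alloc = _allocate_plots(v.landcover, v.n_plots)
        cut = config.cut_fraction(v)
        plot_i = 0
        for t in v.landcover:  # insertion order keeps output deterministic
            for _ in range(alloc.get(t, 0)):
                plot_i += 1
                pid = f"{v.name}-{plot_i:02d}"
                child = np.random.default_rng(ss.spawn(1)[0])
                burnt = bool(child.random() < config.burnt_prob)
                plots.append(gen_plot(
                    type_params[t], cut, child, config=run_config,
                    charcoal_species=charcoal_species, charcoal_dmin=charcoal_dmin,
                    plot_id=pid, village=v.name, burnt=burnt))
                truth_labels[pid] = t

    plots_df = pd.DataFrame(
        [{"plot_id": p.plot_id, "village": p.village, "radius_m": p.radius,
          "burnt": p.burnt, "stratum": p.stratum} for p in plots])
    stems_df = pd.DataFrame(
        [{"plot_id": s.plot_id, "village": p.village, "species": s.species,
          "diameter_cm": s.diameter, "pom_m": s.pom, "alive": s.alive,
          "cut": s.cut, "stump_height_m": s.stump_height}
         for p in plots for s in p.stems])
    quadrats_df = pd.DataFrame(
        [{"plot_id": p.plot_id, "quadrat": i + 1, "fresh_g": q.fresh_g,
          "dry_fraction": q.dry_fraction}
         for p in plots for i, q in enumerate(p.quadrats)])
    cwd_df = pd.DataFrame(
        [{"plot_id": p.plot_id, "diameter_cm": c.diameter_cm, "length_m": c.length_m,
          "decay_class": c.decay_class, "species": c.species}
         for p in plots for c in p.cwd_pieces])
    landcover_df = pd.DataFrame(landcover_rows)
    survey_df = _gen_survey(config, rng_misc)
    trends_df = _gen_trends(config)

    truth = {
        "seed": config.seed,
        "type_params": {
            name: {"stem_density_mean": tp.stem_density_mean, "agb_mean": tp.agb_mean,
                   "grass_mean": tp.grass_mean, "cwd_mean": tp.cwd_mean,
                   "dbh_lognormal": list(tp.dbh_lognormal),
                   "species_pool": [list(x) for x in tp.species_pool]}
            for name, tp in type_params.items()},
        "labels": truth_labels,
        "cut_fraction_by_village": {v.name: config.cut_fraction(v)
                                    for v in config.villages},
        "assumptions": (
            "Diameter distributions are truncated lognormals with location "
            "solved from the type AGB; per-species size distributions, quadrat "
            "noise levels and CWD piece-size distributions are generator "
            "assumptions, not study observations."),
    }
    return StudyDataset(config, plots, links, plots_df, stems_df, quadrats_df,
                        cwd_df, landcover_df, survey_df, trends_df, truth)


# ---------------------------------------------------------------------------
# grass-envelope calibration data


def gen_envelope_data(n_plots: int = 150, intercept: float = 1.8,
                      slope: float = -9e-4, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """(density, grass) pairs from a known decreasing linear envelope.

    Maximum potential grass is ``max(intercept + slope*density, 0)``;
    realised grass multiplies the potential by a Beta(5, 1) utilisation
    draw (most plots near potential, a tail of heavily grazed/shaded ones),
    whose 0.9 quantile is 0.9^(1/5) ~ 0.979 — so a 0.9 quantile fit should
    recover the envelope slope almost exactly.  Returns the data and the
    ground truth for recovery tests.
    """
    rng = np.random.default_rng(seed)
    density = rng.uniform(50.0, 1800.0, size=n_plots)
    potential = np.maximum(intercept + slope * density, 0.0)
    grass = potential * rng.beta(5.0, 1.0, size=n_plots)
    df = pd.DataFrame({"density": density, "grass": grass})
    return df, {"intercept": intercept, "slope": slope,
                "utilisation": "Beta(5,1)", "seed": seed}
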