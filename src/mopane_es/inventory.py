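"""Plot-level woodland structure from raw inventory records.

A plot is a 20 m radius circle in which every live stem >= 5 cm DBH and
every remnant stump (any diameter) was recorded, together with four 1 m^2
grass quadrats and four 20 m line-intersect transects for coarse woody
debris.  This module turns those raw records into the structural metrics
the production functions consume: corrected DBH, above-ground woody biomass
(AGB, Mg C ha^-1), live stem density (stems ha^-1), species richness and
Pielou evenness, dry grass biomass (Mg ha^-1) and coarse-woody-debris
carbon (Mg C ha^-1), plus the stump-to-DBH reconstruction used by the
counterfactual scenarios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AllometryCoeffs, RunConfig

logger = logging.getLogger(__name__)

STANDARD_POM = 1.3  # breast height, m
MIN_LIVE_DBH = 5.0  # cm; inventory threshold for live intact stems
CWD_MIN_DIAMETER = 3.0  # cm at transect intersection
CWD_MIN_LENGTH = 0.5  # m


class SchemaError(ValueError):
    """An input table is missing required columns or violates invariants."""


@dataclass
class StemRecord:
    """One measured stem or stump."""

    plot_id: str
    species: str
    diameter: float  # cm, at the point of measurement
    pom: float = STANDARD_POM  # m, height of the diameter measurement
    alive: bool = True
    cut: bool = False
    stump_height: float | None = None  # m, total stump height (cut stems)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"stem diameter must be positive, got {self.diameter}")
        if self.pom <= 0:
            raise ValueError(f"point of measurement must be positive, got {self.pom}")


@dataclass
class Quadrat:
    """A 1 m^2 grass quadrat: fresh mass (g) and oven-dry mass fraction."""

    fresh_g: float
    dry_fraction: float

    def __post_init__(self) -> None:
        if self.fresh_g < 0:
            raise ValueError("fresh mass must be non-negative")
        if not 0 <= self.dry_fraction <= 1:
            raise ValueError("dry fraction must be in [0, 1]")


@dataclass
class CwdPiece:
    """A coarse-woody-debris piece intersected by a transect."""

    diameter_cm: float  # at the intersection
    length_m: float
    decay_class: int  # 1 (sound) .. 5 (rotten)
    species: str = ""


@dataclass
class Plot:
    """A circular inventory plot with its stems, quadrats and CWD pieces."""

    plot_id: str
    village: str
    radius: float = 20.0  # m
    stems: list[StemRecord] = field(default_factory=list)
    quadrats: list[Quadrat] = field(default_factory=list)
    cwd_pieces: list[CwdPiece] = field(default_factory=list)
    burnt: bool = False
    #: Land-cover stratum the plot was sampled from, if known.
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("plot radius must be positive")

    @property
    def area_ha(self) -> float:
        return math.pi * self.radius**2 / 1e4

    @property
    def transect_length_m(self) -> float:
        # Four centre-to-edge transects, one per cardinal direction.
        return 4.0 * self.radius


# ---------------------------------------------------------------------------
# stem-level operations


def correct_dbh(diameter: float, pom: float, taper: float = 0.02) -> float:
    """Estimate DBH at 1.3 m from a diameter measured at height ``pom``.

    Uses a linear taper, ``d(1.3) = d(pom) * (1 - taper*(1.3 - pom))``,
    clamped at zero.  The taper rate is per metre of height difference; the
    function is the identity at the standard 1.3 m measurement height and
    is inverted exactly by :func:`reconstruct_stump_dbh`.
    """
    if diameter <= 0 or pom <= 0:
        raise ValueError("diameter and pom must be positive")
    return diameter * max(0.0, 1.0 - taper * (STANDARD_POM - pom))


def stem_agb(dbh: float, coeffs: AllometryCoeffs) -> float:
    """Above-ground biomass (Mg C) of one stem from its DBH (cm)."""
    if dbh <= 0:
        raise ValueError("dbh must be positive")
    return coeffs.a * dbh**coeffs.b


def reconstruct_stump_dbh(stem: StemRecord, taper: float = 0.02) -> float | None:
    """Project a cut stem's stump diameter up to 1.3 m.

    The inverse problem of :func:`correct_dbh` under the same linear taper:
    the stump's diameter was measured at ``stem.pom`` (below 1.3 m), and we
    return the DBH the tree would have had when intact.  Returns ``None``
    (with a warning) when the stump's measurement height is missing, in
    which case the stem is excluded from scenario gains.
    """
    if not stem.cut:
        raise ValueError("reconstruction applies to cut stems only")
    if stem.stump_height is None or stem.pom is None or np.isnan(stem.pom):
        logger.warning("stump %s/%s lacks a measurement height; skipped",
                       stem.plot_id, stem.species)
        return None
    return correct_dbh(stem.diameter, stem.pom, taper)


# ---------------------------------------------------------------------------
# plot-level metrics


def live_stems(plot: Plot) -> list[StemRecord]:
    """Live, uncut stems — the ones that provide standing services."""
    return [s for s in plot.stems if s.alive and not s.cut]


def shannon_evenness(shares: np.ndarray) -> float:
    """Pielou's J on a vector of non-negative shares; 1.0 when <= 1 taxon."""
    shares = np.asarray(shares, dtype=float)
    shares = shares[shares > 0]
    if shares.size <= 1:
        return 1.0
    p = shares / shares.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(p.size))


def plot_structure(plot: Plot, coeffs: AllometryCoeffs,
                   taper: float = 0.02) -> dict[str, float]:
    """Density, AGB and diversity of one plot.

    Density counts live intact stems per hectare.  AGB sums the allometric
    biomass of live stems after DBH correction.  Richness is the number of
    distinct species among live stems; evenness is Pielou's J on species
    AGB shares (1.0 by convention when richness <= 1).
    """
    area = plot.area_ha
    alive = live_stems(plot)
    agb_by_species: dict[str, float] = {}
    for s in alive:
        dbh = correct_dbh(s.diameter, s.pom, taper)
        agb_by_species[s.species] = agb_by_species.get(s.species, 0.0) + stem_agb(dbh, coeffs)
    total_agb = sum(agb_by_species.values())
    richness = len(agb_by_species)
    return {
        "n_live": float(len(alive)),
        "stem_density": len(alive) / area,
        "agb": total_agb / area,
        "richness": float(richness),
        "evenness": shannon_evenness(np.array(list(agb_by_species.values()))),
    }


def grass_biomass(plot: Plot) -> float:
    """Mean dry grass biomass over the plot's quadrats, Mg ha^-1.

    Each quadrat contributes fresh mass x dry fraction (g m^-2); the mean
    is converted to Mg ha^-1 (x 0.01).  Recently burnt plots carry no
    usable grass signal and return NaN so that callers exclude them from
    grass means rather than crash.
    """
    if plot.burnt:
        return float("nan")
    if not plot.quadrats:
        return float("nan")
    dry_g_m2 = [q.fresh_g * q.dry_fraction for q in plot.quadrats]
    return float(np.mean(dry_g_m2)) * 0.01


def cwd_biomass(plot: Plot, density_by_decay: dict[int, float],
                carbon_fraction: float = 0.47) -> float:
    """Coarse-woody-debris carbon, Mg C ha^-1, by line-intersect sampling.

    Volume per hectare follows the standard line-intersect estimator,
    ``V = pi^2/(8 L) * sum(d_i^2) * 1e4`` with piece diameters d_i and total
    transect length L both in metres; each piece's volume is converted to
    carbon with its decay-class wood density and the carbon fraction.
    """
    L = plot.transect_length_m
    if L <= 0:
        raise ValueError("total transect length must be positive")
    total = 0.0
    for p in plot.cwd_pieces:
        d_m = p.diameter_cm / 100.0
        vol_ha = math.pi**2 / (8.0 * L) * d_m**2 * 1e4
        total += vol_ha * density_by_decay[p.decay_class] * carbon_fraction
    return total


def mean_se(values, min_n: int = 4) -> tuple[float, float]:
    """Mean and standard error of the mean, NaN-aware.

    The SE (sample SD / sqrt(n)) is suppressed (NaN) when fewer than
    ``min_n`` values are available, following the study's reporting rule
    for sparse cells.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    m = float(v.mean())
    if v.size < min_n:
        return m, float("nan")
    return m, float(v.std(ddof=1) / np.sqrt(v.size))


def structure_table(plots: list[Plot], config: RunConfig) -> pd.DataFrame:
    """Per-plot structural metrics for a list of plots."""
    rows = []
    for p in plots:
        rec = plot_structure(p, config.allometry, config.taper)
        rec.update(
            plot_id=p.plot_id,
            village=p.village,
            burnt=p.burnt,
            grass=grass_biomass(p),
            cwd=cwd_biomass(p, config.decay_density, config.carbon_fraction),
        )
        rows.append(rec)
    cols = ["plot_id", "village", "burnt", "n_live", "stem_density", "agb",
            "grass", "cwd", "richness", "evenness"]
    return pd.DataFrame(rows, columns=cols).set_index("plot_id")


# ---------------------------------------------------------------------------
# ingest


def _require(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing}")


def plots_from_frames(plots_df: pd.DataFrame, stems_df: pd.DataFrame,
                      quadrats_df: pd.DataFrame, cwd_df: pd.DataFrame) -> list[Plot]:
    """Assemble :class:`Plot` objects from the four delimited tables.

    CWD pieces below the 3 cm diameter / 0.5 m length thresholds are
    rejected at ingest (logged, not an error); live intact stems below the
    5 cm DBH inventory threshold raise a schema error.
    """
    _require(plots_df, ["plot_id", "village", "radius_m", "burnt"], "plots")
    _require(stems_df, ["plot_id", "species", "diameter_cm", "pom_m", "alive", "cut"],
             "stems")
    _require(quadrats_df, ["plot_id", "fresh_g", "dry_fraction"], "quadrats")
    _require(cwd_df, ["plot_id", "diameter_cm", "length_m", "decay_class"], "cwd")

    plots: dict[str, Plot] = {}
    for r in plots_df.itertuples():
        plots[str(r.plot_id)] = Plot(
            plot_id=str(r.plot_id), village=str(r.village), radius=float(r.radius_m),
            burnt=bool(r.burnt),
            stratum=str(r.stratum) if "stratum" in plots_df.columns else None,
        )
    for r in stems_df.itertuples():
        cut = bool(r.cut)
        stump_h = getattr(r, "stump_height_m", None)
        if stump_h is not None and (isinstance(stump_h, float) and np.isnan(stump_h)):
            stump_h = None
        stem = StemRecord(
            plot_id=str(r.plot_id), species=str(r.species),
            diameter=float(r.diameter_cm), pom=float(r.pom_m),
            alive=bool(r.alive), cut=cut,
            stump_height=float(stump_h) if (cut and stump_h is not None) else None,
        )
        if stem.alive and not stem.cut and stem.pom == STANDARD_POM \
                and stem.diameter < MIN_LIVE_DBH:
            raise SchemaError(
                f"stems: live intact stem below the {MIN_LIVE_DBH} cm inventory "
                f"threshold in plot {stem.plot_id}")
        plots[str(r.plot_id)].stems.append(stem)
    for r in quadrats_df.itertuples():
        plots[str(r.plot_id)].quadrats.append(
            Quadrat(fresh_g=float(r.fresh_g), dry_fraction=float(r.dry_fraction)))
    n_rejected = 0
    for r in cwd_df.itertuples():
        if float(r.diameter_cm) <= CWD_MIN_DIAMETER or float(r.length_m) <= CWD_MIN_LENGTH:
            n_rejected += 1
            continue
        plots[str(r.plot_id)].cwd_pieces.append(
            CwdPiece(diameter_cm=float(r.diameter_cm), length_m=float(r.length_m),
                     decay_class=int(r.decay_class),
                     species=str(getattr(r, "species", ""))))
    if n_rejected:
        logger.info("rejected %d CWD pieces below size thresholds", n_rejected)
    return list(plots.values())


def read_plots(indir: str | Path) -> list[Plot]:
    """Read plots.csv / stems.csv / quadrats.csv / cwd.csv from a directory."""
    indir = Path(indir)
    return plots_from_frames(
        pd.read_csv(indir / "plots.csv"),
        pd.read_csv(indir / "stems.csv"),
        pd.read_csv(indir / "quadrats.csv"),
        pd.read_csv(indir / "cwd.csv"),
    )


def as_intact(stem: StemRecord, dbh: float) -> StemRecord:
    """A copy of a cut stem restored as live and intact with the given DBH."""
    return replace(stem, diameter=dbh, pom=STANDARD_POM, alive=True, cut=False,
                   stump_height=None)
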