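"""Ecological production functions.

Service availability is modelled as a function of woodland structure: the
biomass services (charcoal, firewood, construction wood) sum allometric
AGB over live stems of the linked species within a diameter band; the
density services (wild food, medicinal plants) count such stems; grass is
handled through an upper-envelope relationship between measured grass
biomass and stem density, used as a maximum-potential proxy because grass
species composition could not be linked to use.  Per-hectare plot values
are amalgamated per (chronosequence class, woodland type) and upscaled to
each village's landscape with the village land-cover composition, with
standard errors propagated assuming independence between types.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from . import inventory
from .config import SERVICE_METRIC, SERVICES, TREE_SERVICES, RunConfig

logger = logging.getLogger(__name__)


class MissingParameterError(KeyError):
    """A village landscape needs a (class, type, service) parameter that no
    plot supports — the upscaling cannot proceed for that cell."""

    def __init__(self, gaps: list[tuple[str, str, str]]):
        self.gaps = gaps
        super().__init__(
            "missing production-function parameters for (class, type, service): "
            + ", ".join(map(str, gaps)))


# ---------------------------------------------------------------------------
# species-service linkage


@dataclass(frozen=True)
class ServiceDef:
    species: frozenset[str]
    metric: str
    dbh_band: tuple[float, float] | None  # cm; None for grass


class ServiceLinkTable:
    """Maps each provisioning service to the local species names, metric and
    diameter band that define its production function."""

    def __init__(self, defs: dict[str, ServiceDef]):
        for svc in TREE_SERVICES:
            if svc in defs and not defs[svc].species:
                raise ValueError(f"tree service {svc!r} has an empty species set")
        self._defs = dict(defs)

    @property
    def services(self) -> list[str]:
        return list(self._defs)

    def __getitem__(self, service: str) -> ServiceDef:
        if service not in self._defs:
            raise KeyError(f"unknown service {service!r}")
        return self._defs[service]

    def species_for(self, service: str) -> frozenset[str]:
        return self[service].species

    def counts(self) -> dict[str, int]:
        return {s: len(d.species) for s, d in self._defs.items()}

    # -- serialisation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for svc, d in self._defs.items():
            lo, hi = d.dbh_band if d.dbh_band else (np.nan, np.nan)
            hi = np.nan if (hi is not None and math.isinf(hi)) else hi
            if d.species:
                for sp in sorted(d.species):
                    rows.append((svc, sp, d.metric, lo, hi))
            else:
                rows.append((svc, "", d.metric, lo, hi))
        return pd.DataFrame(rows, columns=["service", "species", "metric",
                                           "dbh_min", "dbh_max"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ServiceLinkTable":
        defs = {}
        for svc, grp in df.groupby("service", sort=False):
            metric = grp["metric"].iloc[0]
            lo = grp["dbh_min"].iloc[0]
            if np.isnan(lo):
                band = None
            else:
                hi = grp["dbh_max"].iloc[0]
                band = (float(lo), math.inf if np.isnan(hi) else float(hi))
            species = frozenset(s for s in grp["species"] if isinstance(s, str) and s)
            defs[svc] = ServiceDef(species=species, metric=metric, dbh_band=band)
        return cls(defs)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ServiceLinkTable":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# per-plot production functions


def plot_service(plot: inventory.Plot, links: ServiceLinkTable, service: str,
                 config: RunConfig) -> float:
    """Per-hectare availability of a tree-based service on one plot.

    Biomass services return summed stem AGB (Mg C ha^-1) and density
    services a stem count (stems ha^-1), over live intact stems of the
    linked species whose corrected DBH falls in the service's band.  Cut
    stems provide no standing service.  Grass is not computed here; it
    goes through the envelope fit.
    """
    if service not in TREE_SERVICES:
        raise ValueError(f"plot_service handles tree services only, got {service!r}")
    d = links[service]
    lo, hi = d.dbh_band if d.dbh_band else (0.0, math.inf)
    total = 0.0
    for s in inventory.live_stems(plot):
        if s.species not in d.species:
            continue
        dbh = inventory.correct_dbh(s.diameter, s.pom, config.taper)
        if not (lo <= dbh <= hi):
            continue
        total += inventory.stem_agb(dbh, config.allometry) if d.metric == "biomass" else 1.0
    return total / plot.area_ha


# ---------------------------------------------------------------------------
# grass-potential envelope


@dataclass
class GrassEnvelope:
    """Upper-envelope model of maximum potential grass biomass vs stem density.

    ``form`` is "linear" (potential = intercept + slope * density) or
    "exponential" (potential = intercept * exp(slope * density)), fitted as
    a quantile regression at ``quantile``.  Predictions are clamped to be
    non-negative, and densities outside the fitted range are clamped to the
    range boundary (extrapolation guard).
    """

    form: str
    intercept: float
    slope: float
    quantile: float
    density_range: tuple[float, float]
    extrapolation_flagged: bool = field(default=False, compare=False)

    def predict(self, density) -> np.ndarray:
        d = np.asarray(density, dtype=float)
        lo, hi = self.density_range
        if np.any((d < lo) | (d > hi)):
            self.extrapolation_flagged = True
            logger.warning("grass envelope evaluated outside fitted density "
                           "range [%.1f, %.1f]; clamped", lo, hi)
        d = np.clip(d, lo, hi)
        if self.form == "linear":
            out = self.intercept + self.slope * d
        elif self.form == "exponential":
            out = self.intercept * np.exp(self.slope * d)
        else:  # pragma: no cover - guarded at fit time
            raise ValueError(f"unknown envelope form {self.form!r}")
        return np.maximum(out, 0.0)


def fit_grass_envelope(density, grass, quantile: float = 0.9,
                       form: str = "linear") -> GrassEnvelope:
    """Fit the grass-potential upper envelope by quantile regression.

    Requires at least 10 unburnt plots (NaN grass values are dropped).  A
    fitted positive slope is clamped to zero — the envelope is meant to be
    non-increasing in stem density (denser canopies shade out grass) — and
    an all-zero grass input yields a zero envelope with a warning.
    """
    if form not in ("linear", "exponential"):
        raise ValueError(f"unknown envelope form {form!r}")
    df = pd.DataFrame({"density": np.asarray(density, float),
                       "grass": np.asarray(grass, float)}).dropna()
    if len(df) < 10:
        raise ValueError(f"envelope fit needs >= 10 plots, got {len(df)}")
    rng = (float(df["density"].min()), float(df["density"].max()))
    if (df["grass"] == 0).all():
        warnings.warn("all grass observations are zero; envelope is identically zero")
        return GrassEnvelope(form, 0.0, 0.0, quantile, rng)
    y = df["grass"] if form == "linear" else np.log(df["grass"].clip(lower=1e-9))
    fit_df = pd.DataFrame({"y": y, "density": df["density"]})
    if np.ptp(fit_df["y"].to_numpy()) < 1e-12:
        # Degenerate (constant) response: QuantReg cannot iterate.
        const = float(df["grass"].quantile(quantile))
        return GrassEnvelope(form, const if form == "linear" else const, 0.0,
                             quantile, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QuantReg convergence chatter
        res = smf.quantreg("y ~ density", fit_df).fit(q=quantile)
    inter, slope = float(res.params["Intercept"]), float(res.params["density"])
    if form == "exponential":
        inter = math.exp(inter)
    if slope > 0:
        warnings.warn("grass envelope slope fitted positive; clamped to a flat "
                      "envelope at the grass quantile")
        return GrassEnvelope(form, float(df["grass"].quantile(quantile)), 0.0,
                             quantile, rng)
    return GrassEnvelope(form, inter, slope, quantile, rng)


# ---------------------------------------------------------------------------
# per-plot service table and village upscaling


def service_table(plots: list[inventory.Plot], links: ServiceLinkTable,
                  envelope: GrassEnvelope | None, config: RunConfig) -> pd.DataFrame:
    """Per-plot, per-hectare availability of every service.

    Grass is the envelope's maximum-potential prediction at the plot's live
    stem density (NaN when no envelope is supplied).
    """
    rows = []
    for p in plots:
        rec: dict[str, object] = {"plot_id": p.plot_id, "village": p.village}
        for svc in TREE_SERVICES:
            rec[svc] = plot_service(p, links, svc, config)
        if envelope is not None:
            dens = plot_structure_density(p, config)
            rec["grass"] = float(envelope.predict(dens))
        else:
            rec["grass"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("plot_id")


def plot_structure_density(plot: inventory.Plot, config: RunConfig) -> float:
    return len(inventory.live_stems(plot)) / plot.area_ha


def village_totals(landcover: pd.DataFrame, params: pd.DataFrame,
                   class_map: dict[str, str], area_ha: float,
                   services: tuple[str, ...] = SERVICES) -> pd.DataFrame:
    """Upscale per-ha (class, type, service) parameters to village landscapes.

    ``landcover`` is long format (village, type, fraction); fractions for
    the residual non-woodland class "other" are ignored.  ``params`` is long
    format (class, type, service, mean, se, n).  For each village and
    service the total is ``sum_type area*fraction*mean`` with SE
    ``sqrt(sum (area*fraction*se)^2)`` (independence between types); a
    suppressed SE (NaN, from an n < 4 cell) contributes zero and the
    estimate is marked ``se_complete = False``.  A nonzero land-cover
    fraction with no parameter at all raises :class:`MissingParameterError`
    listing the gaps.
    """
    p = params.set_index(["class", "type", "service"]).sort_index()
    rows = []
    gaps: list[tuple[str, str, str]] = []
    for village, grp in landcover.groupby("village", sort=False):
        cls = class_map[village]
        grp = grp[(grp["type"] != "other") & (grp["fraction"] > 0)]
        for svc in services:
            value, var, complete = 0.0, 0.0, True
            by_type: dict[str, float] = {}
            for r in grp.itertuples():
                key = (cls, r.type, svc)
                if key not in p.index:
                    gaps.append(key)
                    continue
                mean = float(p.loc[key, "mean"])
                se = float(p.loc[key, "se"])
                contrib = area_ha * float(r.fraction) * mean
                value += contrib
                by_type[r.type] = contrib
                if np.isnan(se):
                    complete = False
                else:
                    var += (area_ha * float(r.fraction) * se) ** 2
            se_total = math.sqrt(var)
            row = {
                "village": village, "class": cls, "service": svc,
                "value": value, "se": se_total,
                "ci_lo": value - 1.96 * se_total, "ci_hi": value + 1.96 * se_total,
                "se_complete": complete,
            }
            for t, c in by_type.items():
                row[f"by_{t}"] = c
            rows.append(row)
    if gaps:
        raise MissingParameterError(sorted(set(gaps)))
    return pd.DataFrame(rows).fillna({c: 0.0 for c in []})


def amalgamated_params(service_df: pd.DataFrame, labels: pd.Series,
                       class_map: dict[str, str], min_n: int = 4) -> pd.DataFrame:
    """Mean +- SE of per-ha service availability per (class, type, service).

    Plots are pooled within chronosequence classes to raise sample sizes,
    mirroring the study's amalgamation step; SEs are suppressed below
    ``min_n`` plots.
    """
    df = service_df.copy()
    df["type"] = labels.reindex(df.index)
    df["class"] = df["village"].map(class_map)
    svc_cols = [c for c in df.columns if c in SERVICES]
    rows = []
    for (cls, typ), grp in df.groupby(["class", "type"], sort=True):
        for svc in svc_cols:
            m, se = inventory.mean_se(grp[svc], min_n=min_n)
            n = int(grp[svc].notna().sum())
            rows.append({"class": cls, "type": typ, "service": svc,
                         "mean": m, "se": se, "n": n})
    return pd.DataFrame(rows)


def monte_carlo_total_se(fractions: np.ndarray, means: np.ndarray,
                         ses: np.ndarray, area_ha: float, draws: int,
                         rng: np.random.Generator) -> float:
    """Monte-Carlo check of the propagated SE of an area-weighted total:
    resample each type mean from Normal(mean, se) and take the SD of the
    resulting totals.  Used as an independent oracle for the closed form."""
    sims = rng.normal(means, ses, size=(draws, len(means)))
    totals = area_ha * (sims * fractions).sum(axis=1)
    return float(totals.std(ddof=1))
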