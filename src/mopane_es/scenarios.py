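"""Counterfactual charcoal-harvest scenarios.

Two counterfactuals bracket the charcoal history of each landscape.
"No charcoal" rebuilds the pre-extraction woodland: every observed cut
stem of a charcoal-linked species is modelled as intact, with its DBH
projected from the stump by the taper model.  "Total charcoal" models the
exhaustion of the resource: every live stem of a charcoal-linked species
within the charcoal diameter band is modelled as cut.  Both are selective
harvests — non-charcoal species are untouched.  Modified plots are pushed
back through the amalgamation and upscaling steps, and each service's
percent change from current is reported with a confidence interval from
first-order (delta-method) error propagation, treating the current and
counterfactual estimates as independent (a fidelity choice; a Monte-Carlo
alternative is available behind a config flag).
"""

from __future__ import annotations

import copy
import logging
import math

import numpy as np
import pandas as pd

from . import inventory, production
from .config import RunConfig, SERVICES

logger = logging.getLogger(__name__)

#: Stump measurement height assumed when modelling a live stem as cut (m).
CUT_POM = 0.3


def apply_no_charcoal(plot: inventory.Plot, links: production.ServiceLinkTable,
                      taper: float = 0.02) -> inventory.Plot:
    """Model all cut charcoal-species stems as intact (pre-extraction state).

    Cut stems of charcoal-linked species become live intact stems with DBH
    reconstructed from the stump via the taper model; everything else is
    untouched.  Stumps that cannot be reconstructed are skipped and
    counted in a log message.  The input plot is not modified.
    """
    charcoal = links.species_for("charcoal")
    out = copy.deepcopy(plot)
    new_stems = []
    skipped = 0
    for s in out.stems:
        if s.cut and s.species in charcoal:
            dbh = inventory.reconstruct_stump_dbh(s, taper)
            if dbh is None or dbh <= 0:
                skipped += 1
                continue
            new_stems.append(inventory.as_intact(s, dbh))
        else:
            new_stems.append(s)
    if skipped:
        logger.warning("plot %s: %d charcoal stumps could not be reconstructed",
                       plot.plot_id, skipped)
    out.stems = new_stems
    return out


def apply_total_charcoal(plot: inventory.Plot, links: production.ServiceLinkTable,
                         config: RunConfig | None = None) -> inventory.Plot:
    """Model all charcoal-suitable trees as cut (resource exhaustion).

    Live stems of charcoal-linked species whose corrected DBH falls within
    the charcoal band are flagged cut, leaving a stump whose diameter is
    the DBH inflated down to the stump measurement height with the same
    taper model — a selective harvest, not a clear-fell.  The input plot
    is not modified.
    """
    config = config or RunConfig()
    charcoal = links.species_for("charcoal")
    lo, hi = config.dbh_bands["charcoal"]
    out = copy.deepcopy(plot)
    for i, s in enumerate(out.stems):
        if not (s.alive and not s.cut and s.species in charcoal):
            continue
        dbh = inventory.correct_dbh(s.diameter, s.pom, config.taper)
        if not (lo <= dbh <= hi):
            continue
        d_stump = dbh / (1.0 - config.taper * (inventory.STANDARD_POM - CUT_POM))
        out.stems[i] = inventory.StemRecord(
            plot_id=s.plot_id, species=s.species, diameter=d_stump, pom=CUT_POM,
            alive=False, cut=True, stump_height=CUT_POM)
    return out


def scenario_change(value_cur: float, se_cur: float, value_cf: float,
                    se_cf: float, *, use_monte_carlo: bool = False,
                    draws: int = 100_000,
                    rng: np.random.Generator | None = None) -> dict[str, float]:
    """Percent change of a counterfactual estimate relative to current.

    ``pct = 100 * (cf - cur) / cur`` with the CI from the delta method on
    the ratio, treating the two estimates as independent:
    ``var(pct) = (100/cur)^2 var(cf) + (100*cf/cur^2)^2 var(cur)``.
    When current is zero the percent change is undefined and reported as
    NaN with the absolute change only.  The Monte-Carlo alternative
    resamples both estimates from normal distributions and takes
    percentile bounds.
    """
    absolute = value_cf - value_cur
    if value_cur == 0:
        return {"pct_change": float("nan"), "se_pct": float("nan"),
                "ci_lo": float("nan"), "ci_hi": float("nan"),
                "absolute_change": absolute}
    pct = 100.0 * absolute / value_cur
    if use_monte_carlo:
        rng = rng or np.random.default_rng(0)
        cur = rng.normal(value_cur, se_cur, size=draws)
        cf = rng.normal(value_cf, se_cf, size=draws)
        ok = cur != 0
        sims = 100.0 * (cf[ok] - cur[ok]) / cur[ok]
        lo, hi = np.percentile(sims, [2.5, 97.5])
        return {"pct_change": pct, "se_pct": float(np.std(sims, ddof=1)),
                "ci_lo": float(lo), "ci_hi": float(hi), "absolute_change": absolute}
    var = (100.0 / value_cur) ** 2 * se_cf**2 \
        + (100.0 * value_cf / value_cur**2) ** 2 * se_cur**2
    se = math.sqrt(var)
    return {"pct_change": pct, "se_pct": se, "ci_lo": pct - 1.96 * se,
            "ci_hi": pct + 1.96 * se, "absolute_change": absolute}


SCENARIOS = ("no_charcoal", "total_charcoal")


def _estimates(plots: list[inventory.Plot], labels: pd.Series,
               links: production.ServiceLinkTable,
               envelope: production.GrassEnvelope,
               landcover: pd.DataFrame, class_map: dict[str, str],
               config: RunConfig) -> pd.DataFrame:
    svc = production.service_table(plots, links, envelope, config)
    params = production.amalgamated_params(svc, labels, class_map,
                                           min_n=config.min_n_for_se)
    return production.village_totals(landcover, params, class_map,
                                     config.village_area_ha)


def run_scenarios(plots: list[inventory.Plot], labels: pd.Series,
                  links: production.ServiceLinkTable,
                  envelope: production.GrassEnvelope,
                  landcover: pd.DataFrame, class_map: dict[str, str],
                  config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Current estimates and scenario changes for every village x service.

    The scenario pipeline recomputes the class-amalgamated parameters from
    the modified plots (rather than adjusting totals directly) and keeps
    the current typology labels and grass envelope — cutting changes a
    plot's structure, not its type, and the envelope is an observed
    relationship, not a scenario output.
    """
    current = _estimates(plots, labels, links, envelope, landcover, class_map, config)
    transforms = {
        "no_charcoal": lambda p: apply_no_charcoal(p, links, config.taper),
        "total_charcoal": lambda p: apply_total_charcoal(p, links, config),
    }
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    cur_idx = current.set_index(["village", "service"])
    for name, fn in transforms.items():
        modified = [fn(p) for p in plots]
        est = _estimates(modified, labels, links, envelope, landcover,
                         class_map, config)
        for r in est.itertuples():
            cur = cur_idx.loc[(r.village, r.service)]
            ch = scenario_change(
                float(cur["value"]), float(cur["se"]), float(r.value), float(r.se),
                use_monte_carlo=config.use_monte_carlo_ci,
                draws=config.mc_draws, rng=rng)
            rows.append({"village": r.village, "service": r.service,
                         "scenario": name, **ch,
                         "value_current": float(cur["value"]),
                         "value_scenario": float(r.value)})
    return current, pd.DataFrame(rows)
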