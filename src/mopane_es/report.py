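"""Survey summaries, trend concordance, figures, and pipeline orchestration.

Ships loaders for the published field tables (household-survey counts,
perceived temporal trends, and the plot-count bookkeeping by village and
woodland type), which are printed data and serve as inputs; computes
service-use percentages from counts; checks whether perceived trends are
concordant with the modelled "no charcoal" gains; and chains the whole
pipeline (inventory -> typology -> production -> scenarios) behind one
deterministic, manifest-stamped entry point.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, inventory, production, scenarios, synth, typology
from .config import SERVICES, RunConfig

logger = logging.getLogger(__name__)

SURVEY_SERVICES = ("charcoal", "firewood", "construction", "grass", "food",
                   "medicine", "livestock")


# ---------------------------------------------------------------------------
# published field tables (printed data; inputs, not pipeline outputs)


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("mopane_es.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_field_survey() -> pd.DataFrame:
    """Household-survey counts per village: totals, sampled, per-service users."""
    return _load_packaged("mabalane_survey.csv")


def load_field_trends() -> pd.DataFrame:
    """Perceived temporal trend (decline / no_change / not_applicable) per
    village and service from the participatory trend analysis."""
    return _load_packaged("mabalane_trends.csv")


def load_field_plot_counts() -> pd.DataFrame:
    """Sample plots per village and woodland type (post hoc classification)."""
    return _load_packaged("mabalane_plot_counts.csv")


# ---------------------------------------------------------------------------
# survey percentages


def round_half_up(x) -> int:
    """Display rounding to the nearest integer, halves up."""
    return int(np.floor(x + 0.5))


def survey_percentages(survey: pd.DataFrame) -> pd.DataFrame:
    """Per-village and pooled service-use percentages from survey counts.

    Village percentages are 100*count/sampled; the pooled row divides
    summed counts by summed sampled households, and the sampled percentage
    refers to the village household total.  Unrounded values are returned;
    ``*_disp`` columns carry the half-up integer display form.
    """
    services = [s for s in SURVEY_SERVICES if s in survey.columns]
    for s in services:
        bad = survey[survey[s] > survey["households_sampled"]]
        if len(bad):
            raise inventory.SchemaError(
                f"survey: {s} count exceeds sampled households for "
                f"village(s) {sorted(bad['village'])}")
    if (survey["households_sampled"] > survey["households_total"]).any():
        raise inventory.SchemaError("survey: sampled households exceed totals")
    pooled = {"village": "pooled", "class": "(all)",
              "households_total": survey["households_total"].sum(),
              "households_sampled": survey["households_sampled"].sum()}
    for s in services:
        pooled[s] = survey[s].sum()
    out = pd.concat([survey, pd.DataFrame([pooled])], ignore_index=True)
    out["sampled_pct"] = 100.0 * out["households_sampled"] / out["households_total"]
    for s in services:
        out[f"{s}_pct"] = 100.0 * out[s] / out["households_sampled"]
    for c in ["sampled_pct"] + [f"{s}_pct" for s in services]:
        out[c.replace("_pct", "_disp")] = out[c].map(round_half_up)
    return out


# ---------------------------------------------------------------------------
# trend concordance


def trend_concordance(trends: pd.DataFrame, scenario_results: pd.DataFrame,
                      threshold: float = 10.0) -> tuple[pd.DataFrame, float]:
    """Do perceived declines line up with modelled 'no charcoal' gains?

    A perceived decline is concordant when the 'no charcoal' scenario shows
    a materially positive gain (percent change above ``threshold``) — i.e.
    the service really was more available before extraction.  A perceived
    'no change' is concordant when the modelled change is immaterial.
    'not_applicable' cells are excluded from the summary rate.
    """
    nc = scenario_results[scenario_results["scenario"] == "no_charcoal"] \
        .set_index(["village", "service"])
    rows = []
    for r in trends.itertuples():
        for svc in SERVICES:
            perceived = getattr(r, svc, None)
            if perceived is None:
                continue
            key = (r.village, svc)
            if perceived == "not_applicable" or key not in nc.index:
                rows.append({"village": r.village, "service": svc,
                             "perceived": perceived, "modelled_pct": np.nan,
                             "concordant": "not_applicable"})
                continue
            pct = float(nc.loc[key, "pct_change"])
            material_gain = pct > threshold
            if perceived == "decline":
                ok = material_gain
            else:  # no_change
                ok = abs(pct) <= threshold
            rows.append({"village": r.village, "service": svc,
                         "perceived": perceived, "modelled_pct": pct,
                         "concordant": "yes" if ok else "no"})
    table = pd.DataFrame(rows)
    judged = table[table["concordant"] != "not_applicable"]
    rate = float((judged["concordant"] == "yes").mean()) if len(judged) else float("nan")
    return table, rate


# ---------------------------------------------------------------------------
# figures


def plot_current_services(current: pd.DataFrame, path: str | Path) -> None:
    """Stacked bars of current availability per village, one panel per
    service, split by contributing woodland type."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_cols = [c for c in current.columns if c.startswith("by_")]
    services = list(current["service"].unique())
    fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharex=True)
    for ax, svc in zip(axes.ravel(), services):
        sub = current[current["service"] == svc].set_index("village")
        bottom = np.zeros(len(sub))
        for c in by_cols:
            vals = sub[c].fillna(0.0).to_numpy()
            ax.bar(sub.index, vals, bottom=bottom, label=c[3:])
            bottom += vals
        ax.errorbar(sub.index, sub["value"], yerr=1.96 * sub["se"], fmt="none",
                    ecolor="k", capsize=3)
        ax.set_title(svc)
    axes[0, 0].legend(fontsize=7)
    fig.suptitle("Current estimated service availability (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scenario_changes(results: pd.DataFrame, path: str | Path) -> None:
    """Percent change per village under each scenario, one panel per service."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    services = list(results["service"].unique())
    fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharex=True)
    width = 0.38
    for ax, svc in zip(axes.ravel(), services):
        sub = results[results["service"] == svc]
        villages = sorted(sub["village"].unique())
        x = np.arange(len(villages))
        for i, scen in enumerate(scenarios.SCENARIOS):
            s = sub[sub["scenario"] == scen].set_index("village").reindex(villages)
            err = np.vstack([(s["pct_change"] - s["ci_lo"]).to_numpy(),
                             (s["ci_hi"] - s["pct_change"]).to_numpy()])
            ax.bar(x + (i - 0.5) * width, s["pct_change"], width,
                   yerr=np.nan_to_num(err), label=scen, capsize=2)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xticks(x, villages)
        ax.set_title(svc)
    axes[0, 0].legend(fontsize=7)
    fig.suptitle("Modelled change in service availability vs current (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline


def _hash_inputs(paths: list[Path], config: RunConfig) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(config.to_dict(), sort_keys=True, default=str).encode())
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def run_pipeline(indir: str | Path, outdir: str | Path,
                 config: RunConfig | None = None,
                 figures: bool = False) -> dict:
    """Run inventory -> typology -> production -> scenarios on a dataset
    directory and write all outputs plus a JSON run manifest.

    Expects the delimited tables written by the synthetic generator (or
    equivalently structured field exports): plots/stems/quadrats/cwd,
    landcover, links, survey and trends.  Deterministic given the input
    bytes and the config (including its seed).
    """
    config = config or RunConfig()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    input_files = [indir / n for n in
                   ("plots.csv", "stems.csv", "quadrats.csv", "cwd.csv",
                    "landcover.csv", "links.csv", "survey.csv", "trends.csv")
                   if (indir / n).exists()]
    plots = inventory.read_plots(indir)
    links = production.ServiceLinkTable.from_csv(indir / "links.csv")
    landcover = pd.read_csv(indir / "landcover.csv")
    inventory._require(landcover, ["village", "type", "fraction"], "landcover")
    survey = pd.read_csv(indir / "survey.csv")
    trends = pd.read_csv(indir / "trends.csv")
    class_map = dict(zip(survey["village"], survey["class"]))

    logger.info("read %d plots from %s", len(plots), indir)
    structure = inventory.structure_table(plots, config)
    structure.to_csv(outdir / "plots_structure.csv")

    matrix = typology.abundance_matrix(plots, config)
    sel = typology.select_k(matrix, k_max=min(config.k_max, len(matrix) - 1),
                            seed=config.seed, k_min=config.k_min,
                            restarts=config.kmeans_restarts)
    labels = typology.assign_types(plots, matrix, config)
    (outdir / "typology.json").write_text(json.dumps({
        "k_selected_ch": sel.k,
        "ch_scores": {str(k): v for k, v in sel.ch_scores.items()},
        "indicator_species": {str(k): v for k, v in sel.indicator_species.items()},
        "labels": labels.to_dict(),
    }, indent=2, sort_keys=True))

    struct_params = typology.amalgamate(
        structure.drop(columns=["burnt"]), labels, class_map,
        min_n=config.min_n_for_se)
    struct_params.to_csv(outdir / "class_type_params.csv", index=False)

    unburnt = structure[~structure["burnt"]]
    envelope = production.fit_grass_envelope(
        unburnt["stem_density"], unburnt["grass"],
        quantile=config.grass_quantile, form=config.envelope_form)

    current, results = scenarios.run_scenarios(
        plots, labels, links, envelope, landcover, class_map, config)
    current.to_csv(outdir / "services_current.csv", index=False)
    results.to_csv(outdir / "services_scenarios.csv", index=False)

    pct = survey_percentages(survey)
    pct.to_csv(outdir / "survey_percentages.csv", index=False)
    concordance, rate = trend_concordance(trends, results,
                                          threshold=config.concordance_threshold)
    concordance.to_csv(outdir / "concordance.csv", index=False)

    if figures:
        plot_current_services(current, outdir / "services_current.png")
        plot_scenario_changes(results, outdir / "services_scenarios.png")

    manifest = {
        "package": "mopane-es",
        "version": __version__,
        "seed": config.seed,
        "n_plots": len(plots),
        "k_selected_ch": sel.k,
        "grass_envelope": {"form": envelope.form, "intercept": envelope.intercept,
                           "slope": envelope.slope, "quantile": envelope.quantile},
        "concordance_rate": rate,
        "input_hash": _hash_inputs(input_files, config),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
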