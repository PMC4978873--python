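"""Survey arithmetic, trend concordance, and the end-to-end pipeline."""

import hashlib
import json

import numpy as np
import pandas as pd
import pytest

from mopane_es.config import RunConfig
from mopane_es.inventory import SchemaError
from mopane_es.report import (
    load_field_plot_counts,
    load_field_survey,
    load_field_trends,
    round_half_up,
    run_pipeline,
    survey_percentages,
    trend_concordance,
)


class TestSurveyPercentages:
    def test_pooled_field_percentages(self):
        """Pooled service-use rates recomputed from the published counts:
        183/260 charcoal producers (70%), 260/312 households sampled (83%)."""
        out = survey_percentages(load_field_survey())
        pooled = out[out["village"] == "pooled"].iloc[0]
        assert pooled["charcoal"] == 183 and pooled["households_sampled"] == 260
        assert pooled["charcoal_pct"] == pytest.approx(100 * 183 / 260)
        assert pooled["charcoal_disp"] == 70
        assert pooled["sampled_pct"] == pytest.approx(100 * 260 / 312)
        assert pooled["sampled_disp"] == 83

    def test_village_level_spot_checks(self):
        out = survey_percentages(load_field_survey()).set_index("village")
        assert out.loc["A", "charcoal_disp"] == 85   # 29/34
        assert out.loc["G", "charcoal_disp"] == 0
        assert out.loc["E", "firewood_disp"] == 100  # 42/42
        assert out.loc["D", "food_disp"] == 28       # 10/36

    def test_zero_counts_give_zero_pct(self):
        df = pd.DataFrame([{"village": "V", "class": "boom",
                            "households_total": 10, "households_sampled": 8,
                            "charcoal": 0}])
        out = survey_percentages(df)
        assert (out["charcoal_pct"] == 0).all()

    def test_count_above_sampled_rejected(self):
        df = pd.DataFrame([{"village": "V", "class": "boom",
                            "households_total": 10, "households_sampled": 8,
                            "charcoal": 9}])
        with pytest.raises(SchemaError):
            survey_percentages(df)

    def test_half_up_rounding(self):
        assert round_half_up(70.5) == 71
        assert round_half_up(70.49) == 70


class TestTrendConcordance:
    def _scen(self, pct_by_village_service):
        rows = [{"village": v, "service": s, "scenario": "no_charcoal",
                 "pct_change": p} for (v, s), p in pct_by_village_service.items()]
        return pd.DataFrame(rows)

    def _trends(self, cells):
        rows = {}
        for (v, s), t in cells.items():
            rows.setdefault(v, {"village": v})[s] = t
        return pd.DataFrame(list(rows.values()))

    def test_all_no_change_and_flat_model_fully_concordant(self):
        trends = self._trends({("V", "charcoal"): "no_change",
                               ("V", "firewood"): "no_change"})
        scen = self._scen({("V", "charcoal"): 0.5, ("V", "firewood"): -2.0})
        _, rate = trend_concordance(trends, scen)
        assert rate == 1.0

    def test_decline_with_large_gain_concordant(self):
        trends = self._trends({("V", "charcoal"): "decline"})
        scen = self._scen({("V", "charcoal"): 95.0})
        table, rate = trend_concordance(trends, scen)
        assert rate == 1.0

    def test_decline_with_flat_model_discordant(self):
        trends = self._trends({("V", "charcoal"): "decline"})
        scen = self._scen({("V", "charcoal"): 1.0})
        table, rate = trend_concordance(trends, scen)
        assert rate == 0.0
        assert (table["concordant"] == "no").any()

    def test_not_applicable_excluded_from_rate(self):
        trends = self._trends({("V", "charcoal"): "not_applicable",
                               ("V", "firewood"): "no_change"})
        scen = self._scen({("V", "charcoal"): 50.0, ("V", "firewood"): 0.0})
        table, rate = trend_concordance(trends, scen)
        assert rate == 1.0
        assert (table["concordant"] == "not_applicable").sum() == 1


class TestFieldPlotCounts:
    def test_bookkeeping_margins(self):
        """The plot-count table's arithmetic: per-type totals match the
        published per-type sample sizes, villages sum to their plot totals,
        grand total 154."""
        tab = load_field_plot_counts()
        types = [c for c in tab.columns if c not in ("village", "class")]
        assert tab[types].sum().to_dict() == {
            "Androstachys forest": 24, "Mopane woodland": 51,
            "Combretum woodland": 63, "Boscia woodland": 13, "shrub Mopane": 3}
        assert tab[types].to_numpy().sum() == 154
        per_village = tab.set_index("village")[types].sum(axis=1).to_dict()
        assert per_village == {"A": 23, "B": 23, "C": 20, "D": 19, "E": 23,
                               "F": 23, "G": 23}

    def test_counts_table_reproduces_margins(self):
        """Feeding the published classification through the package's own
        bookkeeping reproduces the same margins."""
        from mopane_es.typology import counts_table
        tab = load_field_plot_counts()
        types = [c for c in tab.columns if c not in ("village", "class")]
        labels, villages = {}, {}
        i = 0
        for _, r in tab.iterrows():
            for t in types:
                for _ in range(int(r[t])):
                    labels[f"p{i}"] = t
                    villages[f"p{i}"] = r["village"]
                    i += 1
        class_map = dict(zip(tab["village"], tab["class"]))
        out = counts_table(pd.Series(labels), pd.Series(villages), class_map)
        grand = out.loc[("(all)", "(total)")]
        assert grand["total"] == 154
        for t in types:
            assert grand[t] == tab[t].sum()


@pytest.fixture(scope="module")
def run_dirs(dataset, tmp_path_factory):
    indir = tmp_path_factory.mktemp("data")
    outdir = tmp_path_factory.mktemp("out")
    dataset.write(indir)
    manifest = run_pipeline(indir, outdir, RunConfig())
    return indir, outdir, manifest


class TestPipeline:
    def test_outputs_exist(self, run_dirs):
        _, outdir, manifest = run_dirs
        for name in ("plots_structure.csv", "typology.json", "class_type_params.csv",
                     "services_current.csv", "services_scenarios.csv",
                     "survey_percentages.csv", "concordance.csv", "manifest.json"):
            assert (outdir / name).exists(), name
        assert manifest["n_plots"] == 154

    def test_total_charcoal_is_total_loss_everywhere(self, run_dirs):
        _, outdir, _ = run_dirs
        res = pd.read_csv(outdir / "services_scenarios.csv")
        tc = res[(res["scenario"] == "total_charcoal") & (res["service"] == "charcoal")]
        assert np.allclose(tc["pct_change"], -100.0)

    def test_rerun_is_deterministic(self, run_dirs, tmp_path):
        indir, outdir, _ = run_dirs
        outdir2 = tmp_path / "out2"
        run_pipeline(indir, outdir2, RunConfig())
        for name in ("services_current.csv", "services_scenarios.csv",
                     "class_type_params.csv", "typology.json", "manifest.json"):
            h1 = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            h2 = hashlib.sha256((outdir2 / name).read_bytes()).hexdigest()
            assert h1 == h2, name

    def test_manifest_hash_tracks_config(self, run_dirs, tmp_path):
        indir, _, manifest = run_dirs
        out3 = tmp_path / "out3"
        m2 = run_pipeline(indir, out3, RunConfig(concordance_threshold=12.0))
        assert m2["input_hash"] != manifest["input_hash"]

    def test_cli_simulate_then_run(self, tmp_path):
        from click.testing import CliRunner
        from mopane_es.cli import main
        runner = CliRunner()
        data = tmp_path / "data"
        out = tmp_path / "out"
        r1 = runner.invoke(main, ["simulate", "--seed", "2", "--out", str(data)])
        assert r1.exit_code == 0, r1.output
        assert (data / "stems.csv").exists()
        r2 = runner.invoke(main, ["run", "--in", str(data), "--out", str(out)])
        assert r2.exit_code == 0, r2.output
        assert (out / "services_scenarios.csv").exists()

    def test_missing_column_is_named_validation_error(self, dataset, tmp_path):
        indir = tmp_path / "broken"
        dataset.write(indir)
        stems = pd.read_csv(indir / "stems.csv").drop(columns=["diameter_cm"])
        stems.to_csv(indir / "stems.csv", index=False)
        with pytest.raises(SchemaError, match="diameter_cm"):
            run_pipeline(indir, tmp_path / "never", RunConfig())
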