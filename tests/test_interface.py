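"""CSV round trips, config handling, and end-to-end pipeline runs."""

import numpy as np
import pandas as pd
import pytest

from subcounty_le.bands import default_age_bands
from subcounty_le.config import load_config
from subcounty_le.errors import ConfigurationError, DataError, SubcountyLEError
from subcounty_le.io import (
    read_adjacency,
    read_counts,
    write_results,
    write_study,
)
from subcounty_le.pipeline import run, run_pipeline
from subcounty_le.reliability import AssessedEstimate, Reason


@pytest.fixture()
def study_dir(tmp_path, small_study):
    write_study(small_study, tmp_path)
    return tmp_path


def _count_rows(unit_ids, years, labels, value):
    rows = []
    for u in unit_ids:
        for y in years:
            for b in labels:
                rows.append((u, y, b, value))
    return pd.DataFrame(rows, columns=["unit_id", "year", "age_band", "count"])


class TestReadCounts:
    def test_complete_tables_shape(self, tmp_path, std_scheme):
        labels = std_scheme.labels
        pop = _count_rows(["a", "b"], [2010], labels, 100)
        deaths = _count_rows(["a", "b"], [2010], labels, 1)
        pop.to_csv(tmp_path / "pop.csv", index=False)
        deaths.to_csv(tmp_path / "d.csv", index=False)
        recs = read_counts(tmp_path / "d.csv", tmp_path / "pop.csv", std_scheme)
        assert len(recs) == 2
        assert all(r.person_years.sum() == 1_900 for r in recs)

    def test_unknown_band_label_names_row(self, tmp_path, std_scheme):
        labels = std_scheme.labels
        pop = _count_rows(["a"], [2010], labels, 100)
        deaths = _count_rows(["a"], [2010], labels, 1)
        deaths.loc[3, "age_band"] = "86+"
        pop.to_csv(tmp_path / "pop.csv", index=False)
        deaths.to_csv(tmp_path / "d.csv", index=False)
        with pytest.raises(DataError, match="row 5"):
            read_counts(tmp_path / "d.csv", tmp_path / "pop.csv", std_scheme)

    def test_absent_death_rows_default_to_zero(self, tmp_path, std_scheme):
        labels = std_scheme.labels
        pop = _count_rows(["a"], [2010], labels, 100)
        deaths = _count_rows(["a"], [2010], labels[:1], 2)  # only the infant band
        pop.to_csv(tmp_path / "pop.csv", index=False)
        deaths.to_csv(tmp_path / "d.csv", index=False)
        (rec,) = read_counts(tmp_path / "d.csv", tmp_path / "pop.csv", std_scheme)
        assert rec.deaths[0] == 2 and rec.deaths[1:].sum() == 0

    def test_missing_population_band_rejected(self, tmp_path, std_scheme):
        labels = std_scheme.labels
        pop = _count_rows(["a"], [2010], labels[:-1], 100)  # no 85+ row
        deaths = _count_rows(["a"], [2010], labels, 0)
        pop.to_csv(tmp_path / "pop.csv", index=False)
        deaths.to_csv(tmp_path / "d.csv", index=False)
        with pytest.raises(DataError):
            read_counts(tmp_path / "d.csv", tmp_path / "pop.csv", std_scheme)

    @pytest.mark.parametrize("bad", ["negative", "duplicate"])
    def test_bad_rows_rejected(self, tmp_path, std_scheme, bad):
        labels = std_scheme.labels
        pop = _count_rows(["a"], [2010], labels, 100)
        if bad == "negative":
            pop.loc[0, "count"] = -5
        else:
            pop = pd.concat([pop, pop.iloc[[0]]])
        deaths = _count_rows(["a"], [2010], labels, 0)
        pop.to_csv(tmp_path / "pop.csv", index=False)
        deaths.to_csv(tmp_path / "d.csv", index=False)
        with pytest.raises(DataError):
            read_counts(tmp_path / "d.csv", tmp_path / "pop.csv", std_scheme)


class TestAdjacency:
    def test_self_loop_rejected(self, tmp_path):
        pd.DataFrame([("a", "a")], columns=["unit_a", "unit_b"]).to_csv(
            tmp_path / "adj.csv", index=False)
        with pytest.raises(DataError):
            read_adjacency(tmp_path / "adj.csv")

    def test_unknown_unit_rejected(self, tmp_path):
        pd.DataFrame([("a", "z")], columns=["unit_a", "unit_b"]).to_csv(
            tmp_path / "adj.csv", index=False)
        with pytest.raises(DataError):
            read_adjacency(tmp_path / "adj.csv", known_units={"a", "b"})


class TestConfig:
    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("se_max: 2\nnot_a_key: 1\n")
        with pytest.raises(ConfigurationError):
            load_config(p)

    def test_overrides_beat_file_values(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("se_max: 2\nmin_pyar: 5000\n")
        cfg = load_config(p, se_max=3.0)
        assert cfg.se_max == 3.0 and cfg.min_pyar == 5000

    def test_none_overrides_ignored(self):
        cfg = load_config(None, se_max=None)
        assert cfg.se_max == 2.0


class TestWriteResults:
    def test_suppressed_rows_masked_but_flagged(self, tmp_path):
        class _R:
            e0, se, ci_low, ci_high = 70.0, 3.0, 64.1, 75.9

        est = AssessedEstimate(
            unit_id="x", result=_R(), flags={Reason.SE_GT_MAX},
            status="suppressed", total_pyar=3_000, total_deaths=40,
        )
        path = write_results([est], tmp_path)
        row = pd.read_csv(path, dtype=str).iloc[0]
        assert row["flags"] == "SE_GT_MAX" and row["status"] == "suppressed"
        assert pd.isna(row["e0"]) and pd.isna(row["ci_low"])
        path = write_results([est], tmp_path, show_suppressed=True)
        row = pd.read_csv(path).iloc[0]
        assert row["e0"] == pytest.approx(70.0)


class TestPipeline:
    def test_end_to_end_round_trip(self, study_dir, small_study, tmp_path):
        """Simulate -> compute: results cover all units, written values
        match in-memory results to 6 decimals, and no crosswalk is
        produced without aggregation."""
        out = tmp_path / "out"
        cfg = load_config(
            None,
            deaths=str(study_dir / "deaths.csv"),
            population=str(study_dir / "population.csv"),
            adjacency=str(study_dir / "adjacency.csv"),
            gq=str(study_dir / "gq.csv"),
            indicators=str(study_dir / "indicators.csv"),
            out=str(out),
        )
        result = run(cfg)
        df = pd.read_csv(out / "results.csv", dtype={"unit_or_region_id": str})
        assert len(df) == small_study.config.n_units
        by_id = {e.unit_id: e for e in result.estimates}
        for _, row in df[df.status == "reliable"].iterrows():
            assert row["e0"] == pytest.approx(
                by_id[row["unit_or_region_id"]].result.e0, abs=1e-6)
        assert not (out / "crosswalk.csv").exists()
        assert (out / "summary.txt").exists()
        n_excl = int((small_study.gq_fractions > 0.5).sum())
        assert (df.status == "excluded").sum() == n_excl

    def test_aggregated_run_writes_crosswalk(self, study_dir, tmp_path):
        out = tmp_path / "out"
        cfg = load_config(
            None,
            deaths=str(study_dir / "deaths.csv"),
            population=str(study_dir / "population.csv"),
            adjacency=str(study_dir / "adjacency.csv"),
            out=str(out),
            aggregate=True,
            min_deaths=400.0,
            aggregate_criteria=("min_deaths",),
        )
        result = run(cfg)
        xwalk = pd.read_csv(out / "crosswalk.csv", dtype=str)
        assert set(xwalk["unit_id"]) == set(result.crosswalk)
        assert any(len(r.members) > 1 for r in result.regions)

    def test_missing_file_names_read_stage(self, tmp_path):
        cfg = load_config(
            None, deaths=str(tmp_path / "none.csv"),
            population=str(tmp_path / "none2.csv"), out=str(tmp_path / "o"),
        )
        with pytest.raises(SubcountyLEError, match="read"):
            run(cfg)
        assert run_pipeline(cfg) == 1

    def test_byte_identical_reruns(self, study_dir, tmp_path):
        outs = []
        for name in ("o1", "o2"):
            out = tmp_path / name
            cfg = load_config(
                None,
                deaths=str(study_dir / "deaths.csv"),
                population=str(study_dir / "population.csv"),
                out=str(out),
            )
            run(cfg)
            outs.append((out / "results.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_single_year_population_threshold(self, study_dir, small_study, tmp_path):
        """With the single-year rule at 15,000 and one year of data,
        only units of at least 15,000 residents stay assessable."""
        out = tmp_path / "out"
        cfg = load_config(
            None,
            deaths=str(study_dir / "deaths.csv"),
            population=str(study_dir / "population.csv"),
            out=str(out),
            years=1,
            min_pyar=0.0,
            min_population_single_year=15_000.0,
        )
        result = run(cfg)
        pops = small_study.truth["population"]
        for est in result.estimates:
            if pops[est.unit_id] < 15_000:
                assert not est.reliable
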