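import json

import pytest
import yaml
from click.testing import CliRunner

from mirrorcoev.cli import main as cli_main
from mirrorcoev.errors import ConfigError
from mirrorcoev.report import AnalysisConfig, control_banding, run_panel
from mirrorcoev.sequence_io import write_fasta
from mirrorcoev.simulate import make_coevolving_pair
from tests.conftest import make_alignment


@pytest.fixture(scope="module")
def panel_dir(tmp_path_factory):
    """Simulated query + partner panel: partners at decreasing coevolution
    with the query, plus a positive (rho=1 twin) and negative (independent
    tree) control pair."""
    out = tmp_path_factory.mktemp("panel")
    n, length, sigma, seed = 16, 800, 0.5, 11
    strong = make_coevolving_pair(n, length, sigma, rho=0.9, seed=seed)
    weak = make_coevolving_pair(n, length, sigma, rho=0.1, seed=seed)
    write_fasta(strong.alignment_A.records, out / "query.fasta")
    write_fasta(strong.alignment_B.records, out / "partner_strong.fasta")
    write_fasta(weak.alignment_B.records, out / "partner_weak.fasta")
    # positive control: an exactly co-evolving pair
    pos = make_coevolving_pair(n, length, sigma, rho=1.0, seed=seed + 50)
    write_fasta(pos.alignment_A.records, out / "pos_a.fasta")
    write_fasta(pos.alignment_B.records, out / "pos_b.fasta")
    # negative control: same species labels, evolved on an independent tree
    neg = make_coevolving_pair(n, length, sigma, rho=0.0, seed=seed + 99)
    neg_b = make_alignment(
        {
            a: r.residues
            for a, r in zip(
                sorted(strong.alignment_A.species),
                neg.alignment_B.records,
            )
        }
    )
    write_fasta(strong.alignment_A.records, out / "neg_a.fasta")
    write_fasta(neg_b.records, out / "neg_b.fasta")
    return out


@pytest.fixture(scope="module")
def panel_config(panel_dir):
    return AnalysisConfig(
        query=str(panel_dir / "query.fasta"),
        panel={
            "strong": str(panel_dir / "partner_strong.fasta"),
            "weak": str(panel_dir / "partner_weak.fasta"),
        },
        positive_controls={"pos": (str(panel_dir / "pos_a.fasta"), str(panel_dir / "pos_b.fasta"))},
        negative_controls={"neg": (str(panel_dir / "neg_a.fasta"), str(panel_dir / "neg_b.fasta"))},
        out_dir=str(panel_dir / "out"),
    )


class TestControlBanding:
    def test_threshold_is_max_negative(self):
        band = control_banding(0.9639, [0.9172, 0.7915])
        assert band["threshold"] == pytest.approx(0.9172)
        assert band["source"] == "max negative control"
        assert not band["degenerate"]

    def test_fallback_without_negatives(self):
        band = control_banding(0.9639, [])
        assert band["threshold"] == pytest.approx(0.92)
        assert band["source"] == "fallback"

    def test_degenerate_band_flagged(self):
        band = control_banding(0.90, [0.95])
        assert band["degenerate"]


class TestAnalysisConfig:
    def test_empty_panel_rejected(self):
        with pytest.raises(ConfigError):
            AnalysisConfig(query="q.fasta", panel={})

    def test_yaml_round_trip(self, tmp_path, panel_config):
        raw = {
            "query": panel_config.query,
            "panel": dict(panel_config.panel),
            "controls": {
                "positive": {k: list(v) for k, v in panel_config.positive_controls.items()},
                "negative": {k: list(v) for k, v in panel_config.negative_controls.items()},
            },
            "out_dir": panel_config.out_dir,
        }
        p = tmp_path / "config.yaml"
        p.write_text(yaml.safe_dump(raw))
        cfg = AnalysisConfig.from_yaml(p)
        assert cfg == panel_config

    def test_bad_convention_rejected(self):
        with pytest.raises(ConfigError):
            AnalysisConfig(query="q", panel={"a": "a.fasta"}, sample_size="matrices")


class TestRunPanel:
    @pytest.fixture(scope="class")
    def report(self, panel_config):
        return run_panel(panel_config)

    def test_ranking_prefers_strong_coevolver(self, report):
        assert list(report.ranking["label"]) == ["strong", "weak"]

    def test_every_member_accounted_for(self, report, panel_config):
        assert len(report.ranking) + len(report.skipped) == len(panel_config.panel)

    def test_controls_band_the_panel(self, report):
        assert report.banding["source"] == "max negative control"
        assert report.controls["pos"]["kind"] == "positive"
        # the strongly coevolving partner clears the negative-control bar
        assert report.candidates["strong"]

    def test_outputs_written_and_deterministic(self, report, panel_config, tmp_path):
        from pathlib import Path

        out = json.loads((Path(panel_config.out_dir) / "report.json").read_text())
        assert set(out["results"]) == {"strong", "weak"}
        # byte-identical on re-run
        first = (Path(panel_config.out_dir) / "report.json").read_bytes()
        run_panel(panel_config)
        second = (Path(panel_config.out_dir) / "report.json").read_bytes()
        assert first == second

    def test_duplicate_paths_rejected(self, panel_config, panel_dir):
        bad = AnalysisConfig(
            query=panel_config.query,
            panel={"dup": panel_config.query},
        )
        with pytest.raises(ConfigError):
            run_panel(bad)


class TestCli:
    def test_mirror_subcommand(self, panel_dir, tmp_path):
        runner = CliRunner()
        out = tmp_path / "res.json"
        result = runner.invoke(
            cli_main,
            ["mirror", "--family-a", str(panel_dir / "query.fasta"),
             "--family-b", str(panel_dir / "partner_strong.fasta"),
             "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(out.read_text())
        assert payload["N"] == 16
        assert payload["n"] == 120
        assert 0.0 < payload["r_AB"] <= 1.0

    def test_distances_subcommand(self, panel_dir, tmp_path):
        from mirrorcoev.distance import read_matrix

        runner = CliRunner()
        out = tmp_path / "d.tsv"
        result = runner.invoke(
            cli_main,
            ["distances", "--in", str(panel_dir / "query.fasta"), "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        m = read_matrix(out)
        assert len(m) == 16

    def test_simulate_subcommand(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["simulate", "--n", "6", "--length", "100", "--rho", "1.0",
             "--seed", "3", "--out-dir", str(tmp_path / "sim")],
        )
        assert result.exit_code == 0, result.output
        truth = json.loads((tmp_path / "sim" / "truth.json").read_text())
        assert truth["rates_A"] == truth["rates_B"]
        assert (tmp_path / "sim" / "family_A.fasta").exists()

    def test_compare_subcommand(self, tmp_path):
        for label, r, n in [("alpha", 0.92, 820), ("beta", 0.13, 1035)]:
            (tmp_path / f"{label}.json").write_text(
                json.dumps({"r_AB": r, "N": 41, "n": n})
            )
        runner = CliRunner()
        out = tmp_path / "ranking.tsv"
        result = runner.invoke(
            cli_main,
            ["compare", "--results", str(tmp_path / "alpha.json"),
             "--results", str(tmp_path / "beta.json"), "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert out.read_text().splitlines()[1].startswith("alpha")
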