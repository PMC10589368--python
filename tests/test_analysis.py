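"""Bulge–read matrix, experiment runner and the command-line surface."""

from __future__ import annotations

import json

import numpy as np
import pytest
from click.testing import CliRunner

from crisprhw import (
    Dataset,
    ExperimentPlan,
    SynthConfig,
    bulge_read_heatmap,
    run_experiment,
    simulate_dataset,
    write_pairs_table,
)
from crisprhw.cli import main
from crisprhw.io_data import PAIR_LENGTH

from conftest import make_dataset, random_pair

TINY_SPEC = {
    "embedding_dim": 12,
    "feature_convs": [(4, 10), (6, 8)],
    "blstm_units": 6,
    "dense_units": [16, 8, 2],
}


class TestBulgeReadHeatmap:
    def test_no_bulges_gives_zero_matrix(self, rng):
        matrix = bulge_read_heatmap(make_dataset(rng, 20, 4))
        assert matrix.values.shape == (2, PAIR_LENGTH)
        assert matrix.total() == 0

    def test_single_rna_bulge_entry(self, rng):
        pair = random_pair(rng, label=1, bulge=(9, "rna"), reads=7)
        matrix = bulge_read_heatmap(Dataset("one", [pair]))
        assert matrix.values[0, 9] == 7
        assert matrix.total() == 7

    def test_matches_accumulation_oracle(self, rng):
        pairs = []
        expected = np.zeros((2, PAIR_LENGTH))
        for _ in range(50):
            pos = int(rng.integers(0, 23))
            kind = "rna" if rng.random() < 0.5 else "dna"
            reads = int(rng.integers(0, 40))
            pairs.append(random_pair(rng, label=1, bulge=(pos, kind), reads=reads))
            expected[0 if kind == "rna" else 1, pos] += reads
        matrix = bulge_read_heatmap(Dataset("fifty", pairs))
        np.testing.assert_array_equal(matrix.values, expected)

    def test_total_conserves_bulge_pair_reads(self):
        ds = simulate_dataset(SynthConfig(n_pairs=800, imbalance_ratio=5, seed=6))
        matrix = bulge_read_heatmap(ds)
        expected = sum(p.reads or 0 for p in ds if p.has_bulge)
        assert matrix.total() == expected

    def test_missing_reads_counted_as_zero(self, rng):
        pair = random_pair(rng, label=1, bulge=(5, "dna"), reads=None)
        assert bulge_read_heatmap(Dataset("nr", [pair])).total() == 0

    def test_csv_round_trip(self, rng, tmp_path):
        matrix = bulge_read_heatmap(
            Dataset("x", [random_pair(rng, 1, bulge=(4, "rna"), reads=3)])
        )
        path = matrix.to_csv(tmp_path / "matrix.csv")
        assert "RNA_bulge" in path.read_text()


class TestRunExperiment:
    def _pairs_file(self, tmp_path, n=250, n_pos=50, seed=0):
        ds = planted(seed, n, n_pos)
        return write_pairs_table(ds, tmp_path / f"pairs{seed}.csv")

    def test_crossval_plan_reports_five_folds(self, tmp_path, rng):
        ds = make_dataset(rng, 250, 50)
        path = write_pairs_table(ds, tmp_path / "pairs.csv")
        plan = ExperimentPlan(
            kind="crossval", datasets=[str(path)], spec=TINY_SPEC,
            train={"epochs": 1, "batch_size": 128}, seed=1,
        )
        report = run_experiment(plan, tmp_path / "out")
        assert len(report["result"]["folds"]) == 5
        assert (tmp_path / "out" / "report.json").exists()
        assert (tmp_path / "out" / "folds.csv").exists()

    def test_report_embeds_config_and_seed(self, tmp_path, rng):
        path = write_pairs_table(make_dataset(rng, 250, 50), tmp_path / "p.csv")
        plan = ExperimentPlan(
            kind="crossval", datasets=[str(path)], spec=TINY_SPEC,
            train={"epochs": 1, "batch_size": 128}, seed=7,
        )
        report = run_experiment(plan, tmp_path / "out")
        assert report["plan"]["seed"] == 7
        assert report["train_config"]["shuffle_seed"] == 7
        assert report["model_spec"]["embedding_dim"] == 12

    def test_rerun_same_seed_is_identical(self, tmp_path, rng):
        path = write_pairs_table(make_dataset(rng, 250, 50), tmp_path / "p.csv")
        plan = ExperimentPlan(
            kind="crossval", datasets=[str(path)], spec=TINY_SPEC,
            train={"epochs": 1, "batch_size": 128}, seed=3,
        )
        first = run_experiment(plan, tmp_path / "a")
        second = run_experiment(plan, tmp_path / "b")
        assert first["result"] == second["result"]

    def test_ablation_plan_one_report_per_variant(self, tmp_path, rng):
        path = write_pairs_table(make_dataset(rng, 250, 50), tmp_path / "p.csv")
        plan = ExperimentPlan(
            kind="ablation", datasets=[str(path)], spec=TINY_SPEC,
            variants=["full", "no_dense"],
            train={"epochs": 1, "batch_size": 128}, seed=1,
        )
        report = run_experiment(plan, tmp_path / "out")
        assert set(report["result"]) == {"full", "no_dense"}

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown experiment kind"):
            run_experiment(ExperimentPlan(kind="mystery"), tmp_path)


def planted(seed, n, n_pos):
    from crisprhw import planted_signal_separable

    ratio = n // n_pos - 1
    return planted_signal_separable(n_pairs=n, imbalance_ratio=ratio, seed=seed)


class TestCLI:
    def run(self, *args):
        result = CliRunner().invoke(main, list(args), catch_exceptions=False)
        assert result.exit_code == 0, result.output
        return result.stdout

    def test_simulate_then_stats(self, tmp_path):
        out = tmp_path / "sim.tsv"
        self.run("simulate", "-o", str(out), "--seed", "3", "--n-pairs", "400")
        stdout = self.run("stats", str(out))
        summary = json.loads(stdout)
        assert summary["total"] == 400
        assert summary["positives"] + summary["negatives"] == 400

    def test_encode_writes_token_rows(self, tmp_path):
        sim = tmp_path / "sim.tsv"
        self.run("simulate", "-o", str(sim), "--seed", "1", "--n-pairs", "200")
        tokens_file = tmp_path / "tokens.txt"
        table_file = tmp_path / "table.tsv"
        self.run("encode", str(sim), "-o", str(tokens_file), "--table-out", str(table_file))
        tokens = np.loadtxt(tokens_file, dtype=int)
        assert tokens.shape == (200, 23)
        assert len(table_file.read_text().splitlines()) == 25

    def test_heatmap_csv(self, tmp_path):
        sim = tmp_path / "sim.tsv"
        self.run("simulate", "-o", str(sim), "--seed", "2", "--n-pairs", "300")
        out = tmp_path / "hm.csv"
        self.run("heatmap", str(sim), "-o", str(out))
        assert out.exists()

    def test_crossval_subcommand(self, tmp_path):
        pairs = planted(5, 250, 50)
        path = write_pairs_table(pairs, tmp_path / "p.csv")
        config = tmp_path / "cfg.yaml"
        config.write_text(
            "model_spec:\n  embedding_dim: 12\n  feature_convs: [[4, 10], [6, 8]]\n"
            "  blstm_units: 6\n  dense_units: [16, 8, 2]\n"
            "train:\n  epochs: 1\n  batch_size: 128\n"
        )
        stdout = self.run(
            "crossval", str(path), "--config", str(config),
            "--seed", "1", "--out", str(tmp_path / "rep"),
        )
        mean = json.loads(stdout)
        assert set(mean) == {"pr_auc", "roc_auc", "recall", "precision"}
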