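import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from cernet.cerna_core import CeRNATriplet, SpongeTest
from cernet.cli import main as cli_main
from cernet.io_formats import load_association_table
from cernet.network_pipeline import (
    analyze_counts,
    build_network,
    run_pipeline,
    subnetwork_for_genes,
    summarize_nodes,
)
from cernet.synthetic_data import ScenarioConfig, generate_scenario, write_fixture


def make_triplet(ce="lnc1", mirna="mir1", mrna="gene1", ce_class="lncRNA"):
    sponge = SpongeTest(ce, mrna, 1, 1, 1, 30, 1 / 30)
    return CeRNATriplet(ce, ce_class, mirna, mrna, -0.9, -0.85, 0.95, sponge)


class TestBuildNetwork:
    def test_single_triplet_three_nodes_three_edges(self):
        net = build_network([make_triplet()])
        assert len(net.nodes) == 3
        assert len(net.edges) == 3
        kinds = sorted(kind for _, _, kind, _ in net.edges)
        assert kinds == [
            "cerna_coexpression", "mirna_represses", "mirna_represses",
        ]

    def test_two_triplets_sharing_mirna_and_mrna(self):
        triplets = [make_triplet(ce="lnc1"), make_triplet(ce="lnc2")]
        net = build_network(triplets)
        assert len(net.nodes) == 4
        assert len(net.edges) == 5

    def test_empty_input_empty_network(self):
        net = build_network([])
        assert net.nodes == [] and net.edges == []

    def test_edge_count_bounded_by_three_per_triplet(self, strong_scenario):
        _, _, _, triplets = analyze_counts(
            strong_scenario.counts, strong_scenario.sequences
        )
        net = build_network(triplets)
        assert len(net.edges) <= 3 * len(triplets)

    def test_de_direction_attached(self):
        net = build_network([make_triplet()], {"mir1": "up", "gene1": "down"})
        directions = {nid: d for nid, _, d in net.nodes}
        assert directions == {"mir1": "up", "gene1": "down", "lnc1": "ns"}


@pytest.fixture(scope="module")
def associations():
    return load_association_table()


class TestSubnetworkForGenes:
    def test_thbs1_mylk_published_counts(self, associations):
        net = subnetwork_for_genes(associations, ["THBS1", "MYLK"])
        assert summarize_nodes(net) == {
            "mRNA": 2, "miRNA": 5, "lncRNA": 18, "circRNA": 4,
        }
        assert len(net.nodes) == 29

    def test_comp_minimal_subnetwork(self, associations):
        net = subnetwork_for_genes(associations, ["COMP"])
        assert summarize_nodes(net) == {
            "mRNA": 1, "miRNA": 1, "lncRNA": 1, "circRNA": 0,
        }

    def test_empty_gene_list_empty_network(self, associations):
        net = subnetwork_for_genes(associations, [])
        assert net.nodes == [] and net.edges == []

    def test_unknown_gene_named_in_error(self, associations):
        with pytest.raises(KeyError, match="NOSUCH"):
            subnetwork_for_genes(associations, ["NOSUCH"])

    def test_gene_order_does_not_change_counts(self, associations):
        genes = [r.gene for r in associations]
        fwd = summarize_nodes(subnetwork_for_genes(associations, genes))
        rev = summarize_nodes(subnetwork_for_genes(associations, genes[::-1]))
        assert fwd == rev

    def test_summary_sums_to_total(self, associations):
        net = subnetwork_for_genes(associations, ["THBS1", "MYLK", "PDGFD"])
        assert sum(summarize_nodes(net).values()) == len(net.nodes)


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    directory = tmp_path_factory.mktemp("scenario")
    config = ScenarioConfig(
        n_replicates_per_group=20,
        n_mirna=40,
        n_mrna=130,
        n_lncrna=120,
        n_circrna=100,
        n_planted_triplets=30,
        n_planted_de_per_class=5,
        nb_dispersion=0.05,
        coupling_strength=2.0,
        seed=7,
    )
    write_fixture(generate_scenario(config), directory)
    return directory


class TestRunPipeline:
    def _config(self, fixture_dir, outdir, thresholds=None):
        config = {
            "counts": {
                c: f"counts_{c}.tsv" for c in ("mRNA", "miRNA", "lncRNA", "circRNA")
            },
            "condition_map": "condition_map.tsv",
            "sequences": "sequences.fasta",
            "output_dir": str(outdir),
        }
        if thresholds:
            config["thresholds"] = thresholds
        path = fixture_dir / f"config_{outdir.name}.yaml"
        path.write_text(yaml.safe_dump(config))
        return path

    def test_strong_scenario_yields_validating_triplets(self, fixture_dir, tmp_path):
        outdir = run_pipeline(self._config(fixture_dir, tmp_path / "out"))
        lines = (outdir / "triplets.tsv").read_text().strip().splitlines()
        assert len(lines) > 1
        for line in lines[1:]:
            fields = line.split("\t")
            scc_ce, scc_mrna, pcc, p = (
                float(fields[4]), float(fields[5]), float(fields[6]),
                float(fields[11]),
            )
            assert scc_ce < -0.7 and scc_mrna < -0.7
            assert pcc > 0.9 and p < 0.05

    def test_impossible_scc_threshold_gives_zero_triplets(self, fixture_dir, tmp_path):
        outdir = run_pipeline(
            self._config(
                fixture_dir, tmp_path / "none", thresholds={"scc_threshold": -1.01}
            )
        )
        lines = (outdir / "triplets.tsv").read_text().strip().splitlines()
        assert len(lines) == 1  # header only

    def test_two_runs_byte_identical(self, fixture_dir, tmp_path):
        out1 = run_pipeline(self._config(fixture_dir, tmp_path / "r1"))
        out2 = run_pipeline(self._config(fixture_dir, tmp_path / "r2"))
        assert (out1 / "triplets.tsv").read_bytes() == (
            out2 / "triplets.tsv"
        ).read_bytes()
        assert (out1 / "edges.tsv").read_bytes() == (out2 / "edges.tsv").read_bytes()

    def test_run_log_reports_stage_counts(self, fixture_dir, tmp_path):
        outdir = run_pipeline(self._config(fixture_dir, tmp_path / "log"))
        log = (outdir / "run_log.txt").read_text()
        for key in ("de_features", "target_pairs", "passing_edges", "triplets"):
            assert key in log


class TestRecovery:
    def test_planted_triplets_recovered_with_high_precision_and_recall(
        self, strong_scenario
    ):
        sc = strong_scenario
        _, _, _, triplets = analyze_counts(sc.counts, sc.sequences)
        found = {(t.ce_id, t.mirna_id, t.mrna_id) for t in triplets}
        truth = sc.truth.planted_triplets
        tp = len(found & truth)
        assert tp / len(truth) >= 0.8
        assert tp / len(found) >= 0.8


class TestCli:
    def test_network_subcommand_prints_published_counts(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["network", "THBS1", "MYLK"])
        assert result.exit_code == 0
        assert '"lncRNA": 18' in result.output

    def test_simulate_subcommand_writes_fixture(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["simulate", str(tmp_path / "sim"), "--seed", "4"]
        )
        assert result.exit_code == 0
        assert (tmp_path / "sim" / "truth.json").exists()
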