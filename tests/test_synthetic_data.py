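import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from chipintegrate.bivalency import build_state_matrix, call_bivalent_promoters
from chipintegrate.cli import main as cli_main
from chipintegrate.io_formats import CONDITIONS
from chipintegrate.synthetic_data import (
    TruthManifest,
    generate_annotation,
    generate_condition_peaks,
    generate_diff_and_expression,
    generate_motif_tables,
    simulate,
)


class TestGenerateAnnotation:
    def test_deterministic(self):
        a1 = generate_annotation(n_genes=50, seed=4)
        a2 = generate_annotation(n_genes=50, seed=4)
        assert a1.genes == a2.genes
        assert a1.chrom_sizes == a2.chrom_sizes

    def test_unique_ids_and_both_strands(self):
        anno = generate_annotation(n_genes=100, seed=1)
        ids = [g.gene_id for g in anno.genes]
        assert len(set(ids)) == 100
        assert {g.strand for g in anno.genes} == {"+", "-"}

    def test_spacing_keeps_tss_isolated(self):
        """With 12 kb minimum spacing every TSS is >5 kb from other genes."""
        anno = generate_annotation(n_genes=60, seed=2)
        for g in anno.genes:
            for other in anno.genes_on(g.chrom):
                if other.gene_id == g.gene_id:
                    continue
                gap = max(
                    other.interval.start - g.tss,
                    g.tss - (other.interval.end - 1),
                )
                assert gap > 5000

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            generate_annotation(
                n_genes=100, n_chroms=1, seed=0, chrom_size_limit=100_000
            )


class TestGenerateConditionPeaks:
    def test_planted_bivalency_recovered_exactly(self):
        anno = generate_annotation(n_genes=200, seed=8)
        peaks, truth = generate_condition_peaks(anno, jitter_sd=0.0, seed=8)
        recovered = {}
        for cond in CONDITIONS:
            calls = call_bivalent_promoters(
                peaks[("H3K4me3", cond)], peaks[("H3K27me3", cond)], anno
            )
            for call in calls:
                recovered.setdefault(call.gene_id, {})[cond] = call.bivalent
        for row in truth.itertuples(index=False):
            observed = "".join(
                "T" if recovered[row.gene_id][c] else "F" for c in CONDITIONS
            )
            assert observed == row.bivalency_pattern

    def test_planted_fraction_yields_expected_label_count(self):
        anno = generate_annotation(n_genes=100, seed=3)
        peaks, truth = generate_condition_peaks(
            anno, state_fractions={"TTFT": 0.1}, seed=3
        )
        calls = []
        for cond in CONDITIONS:
            calls.extend(
                call_bivalent_promoters(
                    peaks[("H3K4me3", cond)], peaks[("H3K27me3", cond)], anno
                )
            )
        matrices = build_state_matrix(calls)
        from chipintegrate.bivalency import classify_transition

        labels = [classify_transition(m) for m in matrices]
        assert labels.count("control_resolved_IUGR_repoised") == 10
        assert len(matrices) == 10

    def test_zero_planted_bivalency(self):
        anno = generate_annotation(n_genes=50, seed=5)
        peaks, _ = generate_condition_peaks(anno, state_fractions={}, seed=5)
        cond = CONDITIONS[0]
        calls = call_bivalent_promoters(
            peaks[("H3K4me3", cond)], peaks[("H3K27me3", cond)], anno
        )
        assert not any(c.bivalent for c in calls)

    def test_bad_fractions_rejected(self):
        anno = generate_annotation(n_genes=10, seed=0)
        with pytest.raises(ValueError):
            generate_condition_peaks(anno, state_fractions={"TTTT": 0.9,
                                                            "FFFT": 0.3})
        with pytest.raises(ValueError):
            generate_condition_peaks(anno, state_fractions={"TTX": 0.1})

    def test_jitter_degrades_recall_monotonically(self):
        """Mean planted-bivalency recall never increases with jitter."""
        anno = generate_annotation(n_genes=80, seed=10)
        cond = CONDITIONS[0]

        def recall(jitter_sd, seed):
            peaks, truth = generate_condition_peaks(
                anno, state_fractions={"TTTT": 0.5}, jitter_sd=jitter_sd,
                seed=seed,
            )
            planted = set(
                truth.loc[truth.bivalency_pattern == "TTTT", "gene_id"]
            )
            calls = call_bivalent_promoters(
                peaks[("H3K4me3", cond)], peaks[("H3K27me3", cond)], anno
            )
            found = {c.gene_id for c in calls if c.bivalent}
            return len(found & planted) / len(planted)

        seeds = range(20)
        means = [
            np.mean([recall(j, s) for s in seeds]) for j in (0.0, 40.0, 150.0)
        ]
        assert means[0] == 1.0
        assert means[0] >= means[1] >= means[2]
        assert means[2] >= 0.0


class TestGenerateDiffAndExpression:
    def test_planted_concordance_recovered(self):
        from chipintegrate.diff_integration import (
            assign_diff_sites,
            classify_concordance,
        )

        anno = generate_annotation(n_genes=150, seed=6)
        diff, expression, truth = generate_diff_and_expression(anno, seed=6)
        sites_10wk = [
            s for (mark, age), sl in diff.items() if age == "10wk" for s in sl
        ]
        calls = classify_concordance(
            assign_diff_sites(sites_10wk, anno), expression["10wk"]
        )
        all3 = {c.gene_id for c in calls if c.n_concordant_marks == 3}
        planted = set(
            truth.loc[
                truth.concordance_class.isin(["all3_up", "all3_down"]),
                "gene_id",
            ]
        )
        assert all3 == planted

    def test_discordant_class_excluded_from_all3(self):
        from chipintegrate.diff_integration import (
            assign_diff_sites,
            classify_concordance,
        )

        anno = generate_annotation(n_genes=100, seed=7)
        diff, expression, truth = generate_diff_and_expression(
            anno, class_fractions={"discordant_all3": 0.2}, seed=7
        )
        sites = [
            s for (mark, age), sl in diff.items() if age == "10wk" for s in sl
        ]
        calls = classify_concordance(
            assign_diff_sites(sites, anno), expression["10wk"]
        )
        assert not any(c.n_concordant_marks == 3 for c in calls)
        # the repressive mark is the discordant one by construction
        planted = set(
            truth.loc[truth.concordance_class == "discordant_all3", "gene_id"]
        )
        for c in calls:
            if c.gene_id in planted:
                assert c.statuses["H3K27me3"] == "discordant"

    def test_far_decoy_sites_never_assigned(self):
        from chipintegrate.diff_integration import assign_diff_sites

        anno = generate_annotation(n_genes=100, seed=9)
        diff, _, truth = generate_diff_and_expression(anno, seed=9)
        planted = set(
            truth.loc[truth.concordance_class != "background", "gene_id"]
        )
        for (mark, age), sites in diff.items():
            for a in assign_diff_sites(sites, anno):
                assert a.gene_id in planted


class TestGenerateMotifTables:
    def test_planted_persistence_recovered(self):
        from chipintegrate.io_formats import Condition
        from chipintegrate.motif_persistence import (
            classify_motif_change,
            persistent_motifs,
        )

        records, truth = generate_motif_tables(seed=2)
        calls = {}
        for mark in ("H3K4me3", "H3K27me3"):
            for age in ("2wk", "10wk"):
                iugr = records[(mark, Condition(age, "IUGR"))]
                control = {
                    r.motif_name: r
                    for r in records[(mark, Condition(age, "control"))]
                }
                calls[(mark, age)] = [
                    classify_motif_change(r, control[r.motif_name])
                    for r in iugr
                ]
        k4 = persistent_motifs(
            calls[("H3K4me3", "2wk")], calls[("H3K4me3", "10wk")], "H3K4me3"
        )
        gains = {c.motif_name for c in k4 if c.change == "gained_in_IUGR"}
        planted_gains = set(
            truth.loc[truth.planted_class == "persistent_gain", "motif_name"]
        )
        assert gains == planted_gains
        assert len(gains) == 9
        k27 = persistent_motifs(
            calls[("H3K27me3", "2wk")], calls[("H3K27me3", "10wk")],
            "H3K27me3",
        )
        assert {c.motif_name for c in k27} == set(
            truth.loc[truth.planted_class == "persistent_loss", "motif_name"]
        )

    def test_neither_class_yields_no_persistence(self):
        from chipintegrate.io_formats import Condition
        from chipintegrate.motif_persistence import (
            classify_motif_change,
            persistent_motifs,
        )

        specs = [("X1", "H3K4me3", "neither"), ("X2", "H3K4me3", "neither")]
        records, _ = generate_motif_tables(specs, seed=1)
        calls = {}
        for age in ("2wk", "10wk"):
            iugr = records[("H3K4me3", Condition(age, "IUGR"))]
            control = {
                r.motif_name: r
                for r in records[("H3K4me3", Condition(age, "control"))]
            }
            calls[age] = [
                classify_motif_change(r, control[r.motif_name]) for r in iugr
            ]
        assert persistent_motifs(calls["2wk"], calls["10wk"], "H3K4me3") == []


def _tree_digest(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def test_simulate_deterministic(tmp_path):
    simulate(tmp_path / "a", seed=13, n_genes=80)
    simulate(tmp_path / "b", seed=13, n_genes=80)
    assert _tree_digest(tmp_path / "a") == _tree_digest(tmp_path / "b")


def test_manifest_round_trip(tmp_path):
    manifest = simulate(tmp_path / "sim", seed=3, n_genes=60)
    back = TruthManifest.read(tmp_path / "sim" / "manifest")
    pd.testing.assert_frame_equal(manifest.genes, back.genes)
    pd.testing.assert_frame_equal(manifest.motifs, back.motifs)
    assert back.params == manifest.params


def test_cli_end_to_end(tmp_path):
    runner = CliRunner()
    bundle = tmp_path / "bundle"
    result = runner.invoke(
        cli_main, ["simulate", "--out", str(bundle), "--seed", "5",
                   "--n-genes", "60"]
    )
    assert result.exit_code == 0, result.output
    config = str(bundle / "config.yaml")
    for args in (
        ["integrate", "--config", config, "--out", str(tmp_path / "integ")],
        ["transitions", "--config", config, "--out", str(tmp_path / "trans")],
        ["motifs", "--config", config, "--out", str(tmp_path / "motifs")],
        ["annotate",
         "--peaks", str(bundle / "peaks" / "H3K4me3_2wk_control.bed"),
         "--annotation", str(bundle / "annotation.refflat.tsv"),
         "--chrom-sizes", str(bundle / "chrom.sizes"),
         "--out", str(tmp_path / "anno")],
    ):
        result = runner.invoke(cli_main, args)
        assert result.exit_code == 0, (args[0], result.output)
    counts = pd.read_csv(tmp_path / "integ" / "regulated_gene_counts.tsv",
                         sep="\t")
    assert set(counts["set"]) == {
        "H3K4me3", "H3K27me3", "H3K27Ac", "all_3_marks"
    }
    states = pd.read_csv(tmp_path / "trans" / "bivalency_states.tsv",
                         sep="\t")
    assert list(states.columns) == [
        "gene", "2wk_control", "2wk_IUGR", "10wk_control", "10wk_IUGR",
        "label",
    ]


def test_cli_profile(tmp_path):
    anno = generate_annotation(n_genes=4, n_chroms=1, seed=2)
    from chipintegrate.io_formats import write_refflat

    write_refflat(anno, tmp_path / "genes.tsv")
    size = anno.chrom_sizes["chr1"]
    (tmp_path / "chrom.sizes").write_text(f"chr1\t{size}\n")
    n_bins = -(-size // 100)
    rng = np.random.default_rng(0)
    with open(tmp_path / "sample.bedgraph", "w") as fh:
        for i in range(n_bins):
            fh.write(f"chr1\t{i*100}\t{min((i+1)*100, size)}"
                     f"\t{rng.uniform(0, 10):.3f}\n")
    with open(tmp_path / "input.bedgraph", "w") as fh:
        for i in range(n_bins):
            fh.write(f"chr1\t{i*100}\t{min((i+1)*100, size)}\t5.0\n")
    runner = CliRunner()
    result = runner.invoke(
        cli_main,
        ["profile", "--sample", str(tmp_path / "sample.bedgraph"),
         "--input", str(tmp_path / "input.bedgraph"),
         "--annotation", str(tmp_path / "genes.tsv"),
         "--chrom-sizes", str(tmp_path / "chrom.sizes"),
         "--out", str(tmp_path / "profile.tsv")],
    )
    assert result.exit_code == 0, result.output
    profile = pd.read_csv(tmp_path / "profile.tsv", sep="\t")
    assert len(profile) == 100  # 2 * 5000 / 100
    assert profile["mean_log2_ratio"].notna().all()
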