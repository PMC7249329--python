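import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ladomics.diffmeth import fit_moderated_f
from ladomics.enrichment import fold_enrichment
from ladomics.intervals import GenomicInterval, overlaps_any
from ladomics.simulate import (
    SimulationConfig,
    make_diff_peaks,
    make_expression,
    make_genome,
    make_methylation,
    simulate_all,
)
from conftest import small_config


def dir_digest(path: Path) -> dict[str, str]:
    return {
        str(p.relative_to(path)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.rglob("*"))
        if p.is_file()
    }


class TestConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_dict({"n_probes": 10, "bogus": 1})

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(lad_fraction=1.0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(lad_mean_length=10**9).validate()
        with pytest.raises(ValueError):
            SimulationConfig(n_gained=1, n_lost=1, n_diff_peaks=5).validate()


class TestGenome:
    def test_lad_fraction_law_of_large_numbers(self):
        cfg = small_config(n_chromosomes=4, chrom_length=20_000_000, n_probes=200)
        totals = []
        for seed in range(5):
            g = make_genome(cfg, seed)
            totals.append(g.lamin_a.total_bases() / (4 * 20_000_000))
        assert np.mean(totals) == pytest.approx(cfg.lad_fraction, abs=0.05)

    def test_zero_lad_fraction(self):
        cfg = small_config(lad_fraction=0.0, n_probes=100, n_affected_probes=0)
        g = make_genome(cfg, 1)
        assert len(g.lamin_a) == 0
        probes = [
            GenomicInterval(c, p - 1, p)
            for c, p in zip(g.probe_annot["chrom"], g.probe_annot["pos"])
        ]
        assert not overlaps_any(probes, g.lamin_a).any() if len(g.lamin_a) else True

    def test_probe_coordinates_unique_and_flags_complete(self, small_sim):
        annot = small_sim["genome"].probe_annot
        assert not annot[["chrom", "pos"]].duplicated().any()
        flags = annot[["sex_chromosome", "snp_affected", "cross_reactive",
                       "solo_wcgw", "in_pmd", "in_hmd"]]
        assert flags.notna().all().all()
        # pmd/hmd are exclusive strata
        assert not (annot["in_pmd"] & annot["in_hmd"]).any()

    def test_inter_lad_is_complement(self, small_sim):
        g = small_sim["genome"]
        cfg = small_sim["config"]
        for chrom in (f"chr{i+1}" for i in range(cfg.n_chromosomes)):
            covered = sum(len(iv) for iv in g.lamin_a if iv.chrom == chrom) + sum(
                len(iv) for iv in g.inter_lad if iv.chrom == chrom
            )
            assert covered == cfg.chrom_length


class TestMethylation:
    def test_affected_probes_are_lad_probes(self, small_sim):
        g, truth = small_sim["genome"], small_sim["truth"]
        annot = g.probe_annot.loc[truth["affected_probes"]]
        ivs = [GenomicInterval(c, p - 1, p) for c, p in zip(annot["chrom"], annot["pos"])]
        assert overlaps_any(ivs, g.lamin_a).all()

    def test_group_sizes_and_metadata(self, small_sim):
        sheet = small_sim["sheet"]
        cfg = small_sim["config"]
        assert (sheet["group"] == "control").sum() == cfg.n_control
        assert (sheet["subgroup"] == "sub1").sum() == cfg.n_case_sub1
        assert (sheet["subgroup"] == "sub2").sum() == cfg.n_case_sub2
        assert (sheet["passage"] >= cfg.passage_min).all()
        assert (sheet["harvested"] > sheet["seeded"]).all()

    def test_null_config_is_exchangeable(self):
        cfg = small_config(
            n_probes=4000, lad_delta_beta=0.0, n_affected_probes=0,
            subgroup_shift=0.0,
        )
        g = make_genome(cfg, 5)
        beta, det, sheet, _ = make_methylation(cfg, g, 5)
        tab = fit_moderated_f(beta, sheet)
        rej = (tab["p_value"] < 0.05).mean()
        assert 0.03 < rej < 0.07  # loose envelope at 4000 probes

    def test_infeasible_effect_errors(self):
        cfg = small_config(lad_delta_beta=0.95)
        g = make_genome(cfg, 1)
        with pytest.raises(ValueError, match="shift"):
            make_methylation(cfg, g, 1)


class TestPeaksAndExpression:
    def test_direction_bookkeeping_exact(self, small_sim):
        cfg, g = small_sim["config"], small_sim["genome"]
        peaks, truth = make_diff_peaks(cfg, g, 7)
        sig = peaks[peaks["significant"]]
        assert (sig["direction"] == "gained").sum() == cfg.n_gained
        assert (sig["direction"] == "lost").sum() == cfg.n_lost
        assert len(peaks) == cfg.n_diff_peaks + cfg.n_background_peaks

    def test_null_placement_gives_unit_fold(self):
        cfg = small_config(peak_lad_enrichment=1.0, n_diff_peaks=200,
                           n_gained=120, n_lost=80, n_background_peaks=2000)
        folds = []
        for seed in range(5):
            g = make_genome(cfg, seed)
            peaks, _ = make_diff_peaks(cfg, g, seed)
            r = fold_enrichment(
                peaks["significant"].to_numpy(), peaks["in_lamin_a"].to_numpy()
            )
            folds.append(r.signed_fold)
        assert np.mean(np.abs(folds)) == pytest.approx(1.0, abs=0.15)

    def test_expression_table_roundtrip_and_flags(self, tmp_path, small_sim):
        cfg, g = small_sim["config"], small_sim["genome"]
        expr, truth = make_expression(cfg, g, 7)
        assert (expr["significant"] == (expr["q_value"] < 0.05)).all()
        assert expr["significant"].sum() == cfg.n_de_genes
        p = tmp_path / "expr.tsv"
        expr.to_csv(p, sep="\t", index_label="gene_id", float_format="%.6g")
        back = pd.read_csv(p, sep="\t", index_col=0)
        assert back.index.equals(expr.index)
        np.testing.assert_allclose(
            back["log2_fold_change"], expr["log2_fold_change"], rtol=1e-5
        )

    def test_de_genes_enriched_near_lads(self, small_sim):
        truth = make_expression(small_sim["config"], small_sim["genome"], 7)[1]
        dists = np.array(list(truth["de_gene_lad_distances"].values()))
        frac_close = (dists <= small_sim["config"].proximal_max_distance).mean()
        assert frac_close >= small_sim["config"].de_lad_proximal_frac - 0.05


class TestDeterminism:
    def test_same_seed_byte_identical_directory(self, tmp_path):
        cfg = small_config()
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_all(cfg, a, seed=9)
        simulate_all(cfg, b, seed=9)
        assert dir_digest(a) == dir_digest(b)

    def test_different_seeds_differ(self, tmp_path):
        cfg = small_config()
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_all(cfg, a, seed=1)
        simulate_all(cfg, b, seed=2)
        assert dir_digest(a) != dir_digest(b)

    def test_truth_records_planted_effects(self, tmp_path):
        cfg = small_config()
        truth = simulate_all(cfg, tmp_path / "t", seed=3)
        assert len(truth["methylation"]["affected_probes"]) == cfg.n_affected_probes
        assert truth["peaks"]["n_gained"] == cfg.n_gained
        assert set(truth["clock"]["planted_dnam_age"]) == set(
            pd.read_csv(tmp_path / "t" / "sample_sheet.tsv", sep="\t",
                        index_col=0).index
        )
        on_disk = json.loads((tmp_path / "t" / "truth.json").read_text())
        assert on_disk["methylation"]["true_delta_beta"] == cfg.lad_delta_beta
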