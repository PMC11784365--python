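"""Synthetic community generator: determinism, planted structure, count model."""

import numpy as np
import pandas as pd
import pytest

from oracles import spearman_oracle

from darkfix.errors import ValidationError
from darkfix.synthetic import (
    DEFAULT_DESIGN,
    GroundTruth,
    SyntheticConfig,
    generate_all,
    generate_community,
    generate_samples,
    simulate_counts,
)
from darkfix.types import metadata_frame


class TestConfig:
    def test_bad_phylum_weights_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(phylum_weights={"A": 0.5, "B": 0.4})

    def test_unknown_pathway_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(pathway_assignment={"Krebs": {"complete": 0.1}})

    def test_empty_design_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(design=())

    def test_negative_overdispersion_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(overdispersion=-0.5)


class TestGenerateCommunity:
    def test_deterministic_under_seed(self, tmp_path):
        """Two runs with the same seed write byte-identical artifacts."""
        import filecmp

        from darkfix import io

        for sub in ("a", "b"):
            d = tmp_path / sub
            d.mkdir()
            data = generate_all(SyntheticConfig(seed=1))
            io.write_genomes(data["genomes"], d / "genomes.tsv")
            io.write_genes(data["genes"], d / "genes.tsv")
            io.write_annotations(data["annotations"], d / "annotations.tsv")
            io.write_counts(data["counts_metaG"], d / "counts_metaG.tsv")
            io.write_counts(data["counts_metaT"], d / "counts_metaT.tsv")
            io.write_metadata(data["samples"], d / "metadata.tsv")
            data["ground_truth"].to_json(d / "ground_truth.json")
        for name in ("genomes.tsv", "genes.tsv", "annotations.tsv",
                     "counts_metaG.tsv", "counts_metaT.tsv", "metadata.tsv",
                     "ground_truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_every_genome_has_each_marker_exactly_once(self, default_run):
        genes = default_run["genes"]
        markers = default_run["ground_truth"].marker_kos
        per_genome = {}
        for g in genes:
            if g.ko in markers:
                per_genome.setdefault(g.genome_id, []).append(g.ko)
        for genome in default_run["genomes"]:
            kos = per_genome[genome.genome_id]
            assert sorted(kos) == sorted(markers)

    def test_all_rtca_complete_carry_both_key_genes(self, registry):
        cfg = SyntheticConfig(seed=5, n_genomes=5,
                              pathway_assignment={"rTCA": {"complete": 1.0}})
        genomes, genes, _, truth = generate_community(cfg, registry)
        assert len(genomes) == 5
        for g in genomes:
            kos = {x.ko for x in genes if x.genome_id == g.genome_id}
            assert "K15230" in kos  # ATP-citrate lyase (EC 2.3.3.8)
            assert "K00174" in kos  # 2-oxoglutarate synthase (EC 1.2.7.3)
            assert truth.completeness[g.genome_id]["rTCA"] == "complete"

    def test_dc4hb_decoy_gets_only_shared_genes_and_truth_marks_it(self, registry):
        cfg = SyntheticConfig(seed=6, n_genomes=2,
                              pathway_assignment={"DC/4-HB": {"decoy": 0.5}})
        genomes, genes, _, truth = generate_community(cfg, registry)
        decoys = [g for g, m in truth.completeness.items() if m.get("DC/4-HB") == "decoy"]
        assert len(decoys) == 1
        kos = {x.ko for x in genes if x.genome_id == decoys[0] and x.symbol}
        # malate dehydrogenase (EC 1.1.1.37) + 4-hydroxybutyryl-CoA
        # dehydratase (EC 4.2.1.120), both shared, nothing exclusive
        assert kos == {"K00024", "K14534"}

    def test_taxonomy_has_seven_ranks(self, default_run):
        for g in default_run["genomes"]:
            assert len(g.taxonomy.split(";")) == 7
            assert g.rank("phylum")

    def test_overallocation_rejected(self):
        with pytest.raises(ValidationError):
            cfg = SyntheticConfig(n_genomes=4,
                                  pathway_assignment={"Calvin": {"complete": 2.0}})
            generate_community(cfg)


class TestGenerateSamples:
    def test_default_design_shape(self):
        samples = generate_samples(SyntheticConfig(seed=1))
        assert len(samples) == 18
        df = metadata_frame(samples)
        assert (df.groupby("site").size() == 6).all()
        assert (df.groupby(["site", "zone"]).size() == 2).all()

    def test_noiseless_limit_exactly_monotone(self):
        samples = generate_samples(SyntheticConfig(seed=2, covariate_noise=0.0))
        df = metadata_frame(samples)
        assert spearman_oracle(df.chloride, df.distance_to_sea) == pytest.approx(-1.0)
        assert spearman_oracle(df.sulfate, df.distance_to_sea) == pytest.approx(-1.0)
        assert spearman_oracle(df.organic_matter, df.soil_depth) == pytest.approx(-1.0)
        assert spearman_oracle(df.reduction_index, df.soil_depth) == pytest.approx(1.0)
        assert df.reduction_index.between(0, 1).all()

    def test_covariates_nonnegative_and_bounded(self):
        for seed in range(5):
            df = metadata_frame(generate_samples(SyntheticConfig(seed=seed)))
            assert (df[["chloride", "nitrate", "sulfate", "acetate", "pyruvate",
                        "isocitrate"]] >= 0).all().all()
            assert df.reduction_index.between(0, 1).all()
            assert df.organic_matter.between(0, 100).all()

    def test_reduction_depth_sign_positive_across_seeds(self):
        """The mean Spearman(reduction index, depth ordinal) over many seeds
        is positive: the planted depth gradient survives default noise."""
        rhos = []
        for seed in range(60):
            df = metadata_frame(generate_samples(SyntheticConfig(seed=seed)))
            rhos.append(spearman_oracle(df.reduction_index, df.soil_depth))
        assert np.mean(rhos) > 0.5


class TestSimulateCounts:
    def test_zero_abundance_genome_has_zero_counts(self, registry):
        cfg = SyntheticConfig(seed=9, n_genomes=6)
        genomes, genes, _, truth = generate_community(cfg, registry)
        samples = generate_samples(cfg)
        rng = np.random.default_rng(0)
        from darkfix.synthetic import draw_abundances

        ab = draw_abundances(cfg, genomes, samples, rng)
        dead = genomes[0].genome_id
        ab[dead] = 0.0
        ab = ab.div(ab.sum(axis=1), axis=0)
        truth.relative_abundance = ab
        metag, metat = simulate_counts((genomes, genes), samples, truth, cfg)
        dead_genes = [g.gene_id for g in genes if g.genome_id == dead]
        assert (metag.values[dead_genes].to_numpy() == 0).all()
        assert (metat.values[dead_genes].to_numpy() == 0).all()

    def test_counts_are_nonnegative_integers(self, default_run):
        for key in ("counts_metaG", "counts_metaT"):
            vals = default_run[key].values.to_numpy()
            assert (vals >= 0).all()
            assert np.allclose(vals, np.round(vals))

    def test_metag_expectation_tracks_abundance_times_length(self, registry):
        """Within a sample, expected metaG counts are proportional to genome
        abundance x gene length (checked on averaged draws)."""
        cfg = SyntheticConfig(seed=12, n_genomes=8, sequencing_depth=2e5)
        genomes, genes, _, truth = generate_community(cfg, registry)
        samples = generate_samples(cfg)
        metag, _ = simulate_counts((genomes, genes), samples, truth, cfg)
        ab = truth.relative_abundance
        s = metag.values.index[0]
        expected = np.array([ab.loc[s, g.genome_id] * g.length for g in genes])
        expected = expected / expected.sum() * metag.values.loc[s].sum()
        observed = metag.values.loc[s].to_numpy()
        # Poisson noise at this depth keeps relative error small in aggregate
        big = expected > 50
        assert np.corrcoef(expected[big], observed[big])[0, 1] > 0.99

    def test_overdispersion_increases_variance(self, registry):
        cfg_p = SyntheticConfig(seed=13, n_genomes=6)
        cfg_nb = SyntheticConfig(seed=13, n_genomes=6, overdispersion=1.5)
        out_p = generate_all(cfg_p)
        out_nb = generate_all(cfg_nb)
        vp = out_p["counts_metaG"].values.to_numpy().var()
        vnb = out_nb["counts_metaG"].values.to_numpy().var()
        assert vnb > vp

    def test_ground_truth_round_trips_json(self, default_run, tmp_path):
        truth = default_run["ground_truth"]
        truth.to_json(tmp_path / "gt.json")
        again = GroundTruth.from_json(tmp_path / "gt.json")
        assert again.completeness == truth.completeness
        assert again.effect_signs == truth.effect_signs
        pd.testing.assert_frame_equal(
            again.relative_abundance, truth.relative_abundance, check_like=True
        )

    def test_abundances_sum_to_one(self, default_run):
        ab = default_run["ground_truth"].relative_abundance
        assert np.allclose(ab.sum(axis=1), 1.0, atol=1e-9)


def test_default_design_is_full_crossing():
    assert len(DEFAULT_DESIGN) == 18
    assert len(set(DEFAULT_DESIGN)) == 18
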