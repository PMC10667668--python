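"""Generator behaviour: planted structure, determinism, round-trips."""

import numpy as np
import pandas as pd
import pytest

from secretomics import (
    ConfigError,
    GenomeSimConfig,
    SecretomeSimConfig,
    generate_ct_table,
    generate_genome_with_motifs,
    generate_growth_curve,
    generate_secretome_dataset,
    parse_pattern,
    scan,
)
from secretomics.simulate import write_secretome_dataset
from secretomics.matrix import SpectralCountMatrix


class TestSecretomeGenerator:
    def test_planted_secreted_count_is_exact(self):
        sim = generate_secretome_dataset(SecretomeSimConfig(n_proteins=200, secreted_fraction=0.165))
        assert sim.truth["secreted"].sum() == round(200 * 0.165) == 33

    def test_zero_secreted_fraction_gives_no_secreted_loci(self):
        sim = generate_secretome_dataset(SecretomeSimConfig(secreted_fraction=0.0))
        assert sim.truth["secreted"].sum() == 0

    def test_same_seed_bit_identical(self):
        a = generate_secretome_dataset(SecretomeSimConfig(seed=42))
        b = generate_secretome_dataset(SecretomeSimConfig(seed=42))
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.annotations, b.annotations)

    def test_different_seed_differs(self):
        a = generate_secretome_dataset(SecretomeSimConfig(seed=1))
        b = generate_secretome_dataset(SecretomeSimConfig(seed=2))
        assert not a.counts.counts.equals(b.counts.counts)

    def test_counts_are_nonnegative_integers(self, default_sim):
        counts = default_sim.counts.counts.to_numpy()
        assert (counts >= 0).all()
        assert np.issubdtype(counts.dtype, np.integer)

    def test_supernatant_cytosol_mean_ratio_matches_enrichment(self):
        # Monte-Carlo against the generator's own parameters: many replicate
        # loci, empirical mean ratio for secreted loci within 10% of planted.
        cfg = SecretomeSimConfig(
            n_proteins=10_000, secreted_fraction=1.0, enrichment=8.0, dropout=0.1, seed=3
        )
        sim = generate_secretome_dataset(cfg)
        sup = sim.counts.fraction_samples("supernatant")
        cyt = sim.counts.fraction_samples("cytosol")
        ratio = (
            sim.counts.counts[sup].to_numpy().mean()
            / sim.counts.counts[cyt].to_numpy().mean()
        )
        assert ratio == pytest.approx(8.0, rel=0.10)

    def test_default_design_follows_study_layout(self, default_sim):
        samples = default_sim.counts.samples
        assert len(samples) == 14  # 7 conditions x 2 fractions
        # mutant not assayed on pectin
        assert not (
            (samples["strain"] == "dtrmBL4") & (samples["sugar"] == "pectin")
        ).any()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_proteins", 0),
            ("secreted_fraction", 1.5),
            ("enrichment", 1.0),
            ("dispersion", 0.0),
            ("dropout", -0.1),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = SecretomeSimConfig(**{field: value})
        with pytest.raises(ConfigError, match=field):
            cfg.validate()

    def test_written_files_round_trip_with_readers(self, default_sim, tmp_path):
        paths = write_secretome_dataset(default_sim, tmp_path)
        matrix = SpectralCountMatrix.from_tsv(paths["counts"], paths["samples"])
        pd.testing.assert_frame_equal(
            matrix.counts.astype(int), default_sim.counts.counts
        )
        truth = pd.read_csv(paths["truth"], sep="\t", index_col=0)
        assert truth["secreted"].sum() == default_sim.truth["secreted"].sum()


class TestGenomeGenerator:
    def test_plus_strand_plant_readable_at_coordinates(self):
        cfg = GenomeSimConfig(
            length=2000, planted=[("TACTAAAAGTA", 501, "+", "g1")], seed=0
        )
        sim = generate_genome_with_motifs(cfg)
        seq = sim.sequences[cfg.contig]
        assert seq[500:511] == "TACTAAAAGTA"

    def test_minus_strand_plant_is_reverse_complement(self):
        cfg = GenomeSimConfig(
            length=3000, planted=[("TACTAAAAGTA", 1501, "-", "g1")], seed=0
        )
        sim = generate_genome_with_motifs(cfg)
        seq = sim.sequences[cfg.contig]
        # the forward slice must equal the reverse complement of the site
        from secretomics.simulate import REVCOMP

        site = sim.truth.iloc[0]["site_seq"]
        assert seq[1500:1511] == site.translate(REVCOMP)[::-1]

    def test_gene_placed_with_site_in_upstream_window(self):
        cfg = GenomeSimConfig(length=5000, planted=[("TATCACN5GTGATA", 1000, "+", "g1")])
        sim = generate_genome_with_motifs(cfg)
        gene = sim.genes.iloc[0]
        site = sim.truth.iloc[0]
        assert site["end"] < gene["start"] <= site["end"] + 300

    def test_overlapping_plants_rejected(self):
        cfg = GenomeSimConfig(
            length=2000,
            planted=[("TACTAAAAGTA", 501, "+", "g1"), ("TACTAAAAGTA", 505, "+", "g2")],
        )
        with pytest.raises(ConfigError, match="overlap"):
            cfg.validate()

    def test_scanner_round_trip_recovers_all_plants_exactly(self, rng):
        # 20 random non-overlapping plants; exact scan must equal truth.
        pattern = "TATCACN5GTGATA"
        span = parse_pattern(pattern).span
        positions = sorted(rng.choice(np.arange(1, 49_000, span + 1200), 20, replace=False))
        planted = [
            (pattern, int(p), "+" if i % 2 == 0 else "-", f"g{i}")
            for i, p in enumerate(positions)
        ]
        sim = generate_genome_with_motifs(GenomeSimConfig(length=60_000, planted=planted, seed=9))
        hits = scan(sim.sequences, pattern, max_mismatches=0)
        found = {(h.start, h.end, h.strand) for h in hits}
        expected = {
            (int(r.start), int(r.end), r.strand) for r in sim.truth.itertuples()
        }
        # every planted site is recovered on its strand; palindrome-like or
        # chance background matches may add hits, never remove planted ones
        assert expected <= found

    def test_fasta_gff_round_trip(self, tmp_path):
        from secretomics.motifs import read_gff_genes, _as_contigs

        cfg = GenomeSimConfig(length=4000, planted=[("TACTN3AGTA", 700, "+", "geneA")])
        sim = generate_genome_with_motifs(cfg)
        sim.write(tmp_path / "g.fasta", tmp_path / "g.gff3", tmp_path / "truth.tsv")
        contigs = _as_contigs(tmp_path / "g.fasta")
        assert contigs[cfg.contig] == sim.sequences[cfg.contig]
        genes = read_gff_genes(tmp_path / "g.gff3")
        assert list(genes["locus"]) == ["geneA"]
        assert genes.iloc[0]["start"] == sim.genes.iloc[0]["start"]


class TestCtGenerator:
    def test_unit_fold_no_noise_gives_flat_table(self):
        from secretomics import delta_delta_ct

        table = generate_ct_table({"t": 1.0}, sd=0.0)
        res = delta_delta_ct(table, "t", "treatment", "control")
        assert res.delta_delta_ct == 0.0
        assert res.fold_change == 1.0

    def test_planted_fold_recovered_exactly_without_noise(self):
        from secretomics import delta_delta_ct

        table = generate_ct_table({"t": 4.0}, sd=0.0)
        res = delta_delta_ct(table, "t", "treatment", "control")
        assert res.delta_delta_ct == pytest.approx(-2.0)
        assert res.fold_change == pytest.approx(4.0)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ConfigError, match="fold"):
            generate_ct_table({"t": 0.0})

    def test_references_condition_independent(self):
        table = generate_ct_table({"t": 4.0}, sd=0.0)
        refs = table[table["role"] == "reference"]
        assert refs.groupby("gene")["ct"].nunique().eq(1).all()


class TestGrowthGenerator:
    def test_zero_rate_constant_series(self):
        curve = generate_growth_curve(1e6, 0.0, 5.0)
        assert np.allclose(curve.density, 1e6)

    def test_noiseless_closed_form(self):
        curve = generate_growth_curve(1e6, 1.0, 3.0, dt=1.0)
        assert curve.density[-1] == pytest.approx(8e6)

    def test_negative_duration_rejected(self):
        with pytest.raises(ConfigError, match="duration"):
            generate_growth_curve(1e6, 1.0, -1.0)

    def test_noise_seed_determinism(self):
        a = generate_growth_curve(1e6, 0.8, 6.0, noise_cv=0.1, seed=5)
        b = generate_growth_curve(1e6, 0.8, 6.0, noise_cv=0.1, seed=5)
        assert np.array_equal(a.density, b.density)
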