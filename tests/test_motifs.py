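"""Motif grammar, comparison, genome scanning and upstream mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from secretomics import (
    GenomeSimConfig,
    compare_motifs,
    extract_upstream,
    generate_genome_with_motifs,
    parse_pattern,
    scan,
    screen_genome,
)

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


def brute_force_scan(seq, pattern, max_mismatches, strands="both"):
    """Position-by-position window enumeration, both strands."""
    L = len(seq)
    found = {}
    orientations = [("+", seq)] + ([("-", revcomp(seq))] if strands == "both" else [])
    for strand, oseq in orientations:
        for spacers in itertools.product(
            *[range(lo, hi + 1) for lo, hi in pattern.spacers]
        ):
            span = pattern.block_length + sum(spacers)
            for i in range(L - span + 1):
                off, mm = 0, 0
                for bi, block in enumerate(pattern.blocks):
                    for j, base in enumerate(block):
                        if oseq[i + off + j] != base:
                            mm += 1
                    off += len(block)
                    if bi < len(pattern.spacers):
                        off += spacers[bi]
                if mm <= max_mismatches:
                    if strand == "+":
                        key = (i + 1, i + span, "+")
                    else:
                        key = (L - (i + span) + 1, L - i, "-")
                    found[key] = min(found.get(key, mm), mm)
    return found


class TestPatternGrammar:
    @pytest.mark.parametrize(
        "text,blocks,spacers,span",
        [
            ("TACTN3AGTA", ("TACT", "AGTA"), ((3, 3),), 11),
            ("TACT", ("TACT",), (), 4),
            ("TATCACN5GTGATA", ("TATCAC", "GTGATA"), ((5, 5),), 17),
            ("TACTCN3CATA", ("TACTC", "CATA"), ((3, 3),), 12),
        ],
    )
    def test_parse_blocks_spacers_span(self, text, blocks, spacers, span):
        pat = parse_pattern(text)
        assert pat.blocks == blocks
        assert pat.spacers == spacers
        assert pat.span == span

    def test_spacer_range_syntax(self):
        pat = parse_pattern("TACTN3-6AGTA")
        assert pat.spacers == ((3, 6),)
        assert (pat.min_span, pat.max_span) == (11, 14)

    def test_illegal_character_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            parse_pattern("TAXT")


class TestCompareMotifs:
    def test_md_system_two_nucleotide_divergence(self):
        # The maltose/maltodextrin-system site in T. barophilus differs from
        # the P. furiosus TrmBL1 site at exactly two block positions.
        n, pos = compare_motifs(
            parse_pattern("TATCACN5GTGATA"), parse_pattern("AATCATN5GTGATA")
        )
        assert n == 2
        assert pos == [1, 6]

    def test_identical_patterns(self):
        p = parse_pattern("TACTN3AGTA")
        assert compare_motifs(p, p) == (0, [])

    def test_single_terminal_mismatch(self):
        assert compare_motifs(parse_pattern("TACT"), parse_pattern("TACA")) == (1, [4])

    def test_incompatible_structures_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            compare_motifs(parse_pattern("TACTN3AGTA"), parse_pattern("TACTN5AGTA"))


class TestScan:
    def test_single_exact_plant_found_at_coordinates(self):
        seq = "G" * 400 + "TATCACAAAAAGTGATA" + "G" * 300
        hits = scan({"c": seq}, "TATCACN5GTGATA")
        forward = [h for h in hits if h.strand == "+"]
        assert [(h.start, h.end) for h in forward] == [(401, 417)]
        assert forward[0].matched_seq == "TATCACAAAAAGTGATA"

    def test_minus_strand_reported_on_forward_coordinates(self):
        site = "TACTGGGAGTA"
        seq = "C" * 100 + revcomp(site) + "C" * 100
        hits = scan({"c": seq}, "TACTN3AGTA", strands="both")
        minus = [h for h in hits if h.strand == "-"]
        assert [(h.start, h.end) for h in minus] == [(101, 111)]
        assert minus[0].matched_seq == site

    def test_pattern_longer_than_sequence_is_empty_not_error(self):
        assert scan({"c": "ACGT"}, "TATCACN5GTGATA") == []

    def test_mismatch_positions_within_blocks(self):
        seq = "A" * 50 + "TACGTTTAGTA" + "A" * 50  # TACT -> TACG at block pos 4
        hits = [h for h in scan({"c": seq}, "TACTN3AGTA", max_mismatches=1)
                if h.strand == "+"]
        assert hits[0].mismatches == 1
        assert hits[0].mismatch_positions == [4]

    @pytest.mark.parametrize("pattern_text", ["TACTN3AGTA", "TATCACN5GTGATA", "TACT"])
    def test_equivalence_with_bruteforce_enumeration(self, rng, pattern_text):
        pattern = parse_pattern(pattern_text)
        for _ in range(40):
            L = int(rng.integers(60, 320))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            k = int(rng.integers(0, 3))
            ours = {
                (h.start, h.end, h.strand): h.mismatches
                for h in scan({"c": seq}, pattern, max_mismatches=k)
            }
            assert ours == brute_force_scan(seq, pattern, k)

    def test_strand_symmetry(self, rng):
        pattern = parse_pattern("TATCACN5GTGATA")
        seq = "".join(rng.choice(list("ACGT"), size=400))
        L = len(seq)
        fwd = scan({"c": seq}, pattern, max_mismatches=2)
        mirror = scan({"c": revcomp(seq)}, pattern, max_mismatches=2)
        flipped = {
            (L - h.end + 1, L - h.start + 1, "+" if h.strand == "-" else "-")
            for h in mirror
        }
        assert {(h.start, h.end, h.strand) for h in fwd} == flipped

    def test_hit_span_matches_realized_pattern_span(self, rng):
        pattern = parse_pattern("TACTN3-5AGTA")
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        for h in scan({"c": seq}, pattern, max_mismatches=1):
            assert pattern.min_span <= h.end - h.start + 1 <= pattern.max_span
            if h.strand == "+":
                assert seq[h.start - 1 : h.end] == h.matched_seq


class TestUpstream:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["locus", "contig", "start", "end", "strand"])

    def test_plus_strand_window_arithmetic(self):
        genes = self._genes([("g", "c", 1000, 2000, "+")])
        region = extract_upstream(genes, {"c": "A" * 3000}, window=300).iloc[0]
        assert (region["start"], region["end"]) == (700, 999)

    def test_minus_strand_window_arithmetic(self):
        genes = self._genes([("g", "c", 1000, 2000, "-")])
        region = extract_upstream(genes, {"c": "A" * 3000}, window=300).iloc[0]
        assert (region["start"], region["end"]) == (2001, 2300)

    def test_gene_at_contig_edge_clipped_empty(self):
        genes = self._genes([("g", "c", 1, 500, "+")])
        region = extract_upstream(genes, {"c": "A" * 1000}, window=300).iloc[0]
        assert region["end"] < region["start"]  # empty region, no failure

    def test_missing_contig_errors(self):
        genes = self._genes([("g", "nope", 10, 20, "+")])
        with pytest.raises(KeyError, match="nope"):
            extract_upstream(genes, {"c": "A" * 100}, window=300)


class TestScreenGenome:
    def test_round_trip_against_planted_truth(self):
        planted = [
            ("TATCACN5GTGATA", 2_000, "+", "geneA"),
            ("TACTN3AGTA", 6_000, "-", "geneB"),
            ("TATCACN5GTGATA", 11_000, "+", "geneC"),
        ]
        sim = generate_genome_with_motifs(GenomeSimConfig(length=15_000, planted=planted, seed=4))
        report = screen_genome(
            sim.sequences, sim.genes,
            ["TATCACN5GTGATA", "TACTN3AGTA"], window=300, max_mismatches=0,
        )
        assigned = {
            (h.assigned_gene, h.start, h.end)
            for h in report.hits if h.assigned_gene
        }
        expected = {
            (r.locus, int(r.start), int(r.end)) for r in sim.truth.itertuples()
        }
        assert expected <= assigned
        assert report.per_gene.loc["geneA", "TATCACN5GTGATA"]
        assert report.per_gene.loc["geneB", "TACTN3AGTA"]

    def test_no_patterns_empty_report(self):
        sim = generate_genome_with_motifs(
            GenomeSimConfig(length=3000, planted=[("TACT", 100, "+", "g")])
        )
        report = screen_genome(sim.sequences, sim.genes, [], window=300)
        assert report.hits == []
        assert report.per_gene.shape == (1, 0)
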