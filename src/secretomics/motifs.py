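"""Degenerate transcription-factor binding-motif scanning.

TrmB-family regulators of Thermococcales bind short, partly palindromic sites
such as TACT-N3-AGTA (trehalose/maltose system) and the Thermococcales
glycolytic motif (TGM) TATCAC-N5-GTGATA found upstream of sugar-metabolism
operons.  A pattern is written as consensus blocks of A/C/G/T separated by
fixed-length or ranged runs of N ("TACTN3AGTA", "TATCACN5GTGATA",
"TACTN3-6AGTA").  Spacer positions are unconstrained; mismatches are counted
at block positions only, and a hit is any genome window whose block positions
differ from the consensus at no more than ``max_mismatches`` sites, on either
strand.  Coordinates are 1-based inclusive on the forward strand; a minus
strand hit is the reverse complement of the forward-strand slice at the
reported coordinates.
"""

from __future__ import annotations

import dataclasses
import itertools
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_TOKEN = re.compile(r"([ACGT]+)|N(\d+)?(?:-(\d+))?")


@dataclasses.dataclass(frozen=True)
class MotifPattern:
    """Consensus blocks separated by free N spacers."""

    name: str
    blocks: tuple[str, ...]
    spacers: tuple[tuple[int, int], ...]  # (min, max) length between blocks

    def __post_init__(self):
        if not self.blocks or any(not b for b in self.blocks):
            raise ValueError("pattern blocks must be non-empty")
        if len(self.spacers) != len(self.blocks) - 1:
            raise ValueError("need exactly one spacer between consecutive blocks")
        for lo, hi in self.spacers:
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid spacer range ({lo}, {hi})")

    @property
    def block_length(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def min_span(self) -> int:
        return self.block_length + sum(lo for lo, _ in self.spacers)

    @property
    def max_span(self) -> int:
        return self.block_length + sum(hi for _, hi in self.spacers)

    @property
    def span(self) -> int:
        """Span for fixed-length spacers (errors if any spacer is ranged)."""
        if self.min_span != self.max_span:
            raise ValueError("pattern has ranged spacers; use min_span/max_span")
        return self.min_span

    def spacer_combos(self):
        yield from itertools.product(
            *[range(lo, hi + 1) for lo, hi in self.spacers]
        )


def parse_pattern(text: str, name: str | None = None) -> MotifPattern:
    """Parse a blocks-and-N-spacer pattern string.

    ``"TACTN3AGTA"`` -> blocks (TACT, AGTA), spacer 3.  ``"N3-6"`` denotes a
    spacer of 3 to 6 bases; a bare ``N`` is a single free base.  Illegal
    characters raise ``ValueError`` with the offending position.
    """
    text = text.strip().upper()
    blocks: list[str] = []
    spacers: list[tuple[int, int]] = []
    pos = 0
    pending_spacer: tuple[int, int] | None = None
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            raise ValueError(
                f"illegal character {text[pos]!r} at position {pos + 1} in pattern {text!r}"
            )
        if m.group(1):  # consensus block
            if pending_spacer is not None:
                spacers.append(pending_spacer)
                pending_spacer = None
            blocks.append(m.group(1))
        else:  # N run
            lo = int(m.group(2)) if m.group(2) else 1
            hi = int(m.group(3)) if m.group(3) else lo
            if not blocks:
                raise ValueError(f"pattern {text!r} cannot start with a spacer")
            if pending_spacer is not None:
                raise ValueError(f"consecutive spacers in pattern {text!r}")
            pending_spacer = (lo, hi)
        pos = m.end()
    if pending_spacer is not None:
        raise ValueError(f"pattern {text!r} cannot end with a spacer")
    return MotifPattern(name=name or text, blocks=tuple(blocks), spacers=tuple(spacers))


def compare_motifs(a: MotifPattern, b: MotifPattern) -> tuple[int, list[int]]:
    """Hamming distance between two patterns over block positions.

    Patterns must share block lengths and spacer ranges.  Returns the mismatch
    count and the 1-based mismatch positions within the concatenated blocks.
    """
    if tuple(len(x) for x in a.blocks) != tuple(len(x) for x in b.blocks) or (
        a.spacers != b.spacers
    ):
        raise ValueError(
            f"patterns {a.name} and {b.name} have incompatible structures"
        )
    cat_a = "".join(a.blocks)
    cat_b = "".join(b.blocks)
    positions = [i + 1 for i, (x, y) in enumerate(zip(cat_a, cat_b)) if x != y]
    return len(positions), positions


@dataclasses.dataclass
class MotifHit:
    contig: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str  # '+' or '-'
    matched_seq: str  # in pattern orientation
    mismatches: int
    mismatch_positions: list[int]  # 1-based within concatenated blocks
    pattern: str
    assigned_gene: str = ""


def _as_contigs(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return {str(k): str(v).upper() for k, v in genome.items()}
    if isinstance(genome, (str, Path)) and Path(str(genome)).exists():
        return {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(genome), "fasta")
        }
    if isinstance(genome, str):
        return {"seq": genome.upper()}
    raise TypeError(f"cannot interpret genome input of type {type(genome)!r}")


def _block_offsets(pattern: MotifPattern, spacer_lengths) -> list[tuple[str, int]]:
    offsets, off = [], 0
    for i, block in enumerate(pattern.blocks):
        offsets.append((block, off))
        off += len(block)
        if i < len(pattern.spacers):
            off += spacer_lengths[i]
    return offsets


def _scan_oriented(seq_arr: np.ndarray, pattern: MotifPattern, max_mismatches: int):
    """Yield (0-based start, span, mismatch count) on the given orientation."""
    n = seq_arr.size
    for spacer_lengths in pattern.spacer_combos():
        span = pattern.block_length + sum(spacer_lengths)
        n_pos = n - span + 1
        if n_pos <= 0:
            continue
        mm = np.zeros(n_pos, dtype=np.int32)
        for block, off in _block_offsets(pattern, spacer_lengths):
            for j, base in enumerate(block):
                mm += seq_arr[off + j : off + j + n_pos] != ord(base)
        for idx in np.flatnonzero(mm <= max_mismatches):
            yield int(idx), span, int(mm[idx])


def _mismatch_positions(window: str, pattern: MotifPattern, span: int) -> list[int]:
    # recover the spacer assignment realizing this span (first combo wins)
    for spacer_lengths in pattern.spacer_combos():
        if pattern.block_length + sum(spacer_lengths) == span:
            positions, block_pos = [], 0
            for block, off in _block_offsets(pattern, spacer_lengths):
                for j, base in enumerate(block):
                    block_pos += 1
                    if window[off + j] != base:
                        positions.append(block_pos)
            return positions
    raise AssertionError("span does not match any spacer combination")


def scan(
    genome,
    pattern: MotifPattern | str,
    max_mismatches: int = 0,
    strands: str = "both",
) -> list[MotifHit]:
    """Find all pattern matches in a genome.

    ``genome`` may be a FASTA path, a dict of contig id -> sequence, or a bare
    sequence string.  Hits are sorted by (contig, start, end, strand); minus
    strand hits are reported on forward coordinates, with ``matched_seq`` the
    reverse complement of the forward slice.  A pattern longer than the
    sequence yields an empty result.
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    contigs = _as_contigs(genome)
    if not contigs or all(not s for s in contigs.values()):
        raise ValueError("genome is empty")

    hits: dict[tuple, MotifHit] = {}
    for contig, seq in contigs.items():
        L = len(seq)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        orientations = [("+", seq, arr)]
        if strands == "both":
            rc = str(Seq(seq).reverse_complement())
            orientations.append(
                ("-", rc, np.frombuffer(rc.encode("ascii"), dtype=np.uint8))
            )
        for strand, oseq, oarr in orientations:
            for idx, span, mm in _scan_oriented(oarr, pattern, max_mismatches):
                window = oseq[idx : idx + span]
                if strand == "+":
                    start, end = idx + 1, idx + span
                else:
                    start, end = L - (idx + span) + 1, L - idx
                key = (contig, start, end, strand)
                if key in hits and hits[key].mismatches <= mm:
                    continue
                hits[key] = MotifHit(
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    matched_seq=window,
                    mismatches=mm,
                    mismatch_positions=_mismatch_positions(window, pattern, span),
                    pattern=pattern.name,
                )
    return sorted(
        hits.values(), key=lambda h: (h.contig, h.start, h.end, h.strand)
    )


# -- gene context ----------------------------------------------------------

def read_gff_genes(gff_path: str | Path) -> pd.DataFrame:
    """Gene records (locus, contig, start, end, strand) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        locus = gene.attributes.get("locus_tag", gene.attributes.get("ID", [gene.id]))[0]
        rows.append(
            {
                "locus": locus,
                "contig": gene.seqid,
                "start": gene.start,
                "end": gene.end,
                "strand": gene.strand,
            }
        )
    return pd.DataFrame(rows, columns=["locus", "contig", "start", "end", "strand"])


def extract_upstream(
    genes: pd.DataFrame, genome, window: int = 300
) -> pd.DataFrame:
    """Strand-aware upstream window immediately 5' of each gene start.

    Returns one row per gene (locus, contig, start, end); coordinates are
    1-based inclusive on the forward strand, clipped at contig bounds.  A gene
    flush against the contig edge gets an empty region (end < start).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    contigs = _as_contigs(genome)
    rows = []
    for rec in genes.itertuples(index=False):
        if rec.contig not in contigs:
            raise KeyError(f"gene {rec.locus}: contig {rec.contig!r} not in genome")
        L = len(contigs[rec.contig])
        if rec.strand == "-":
            start, end = rec.end + 1, min(L, rec.end + window)
        else:
            start, end = max(1, rec.start - window), rec.start - 1
        rows.append(
            {"locus": rec.locus, "contig": rec.contig, "start": start, "end": end}
        )
    return pd.DataFrame(rows, columns=["locus", "contig", "start", "end"])


@dataclasses.dataclass
class ScreenReport:
    hits: list[MotifHit]
    per_gene: pd.DataFrame  # loci x pattern presence flags

    def hits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [h.contig for h in self.hits],
                "start": [h.start for h in self.hits],
                "end": [h.end for h in self.hits],
                "strand": [h.strand for h in self.hits],
                "pattern": [h.pattern for h in self.hits],
                "matched_seq": [h.matched_seq for h in self.hits],
                "mismatches": [h.mismatches for h in self.hits],
                "assigned_gene": [h.assigned_gene for h in self.hits],
            }
        )


def screen_genome(
    genome,
    genes: pd.DataFrame,
    patterns,
    window: int = 300,
    max_mismatches: int = 2,
    strands: str = "both",
) -> ScreenReport:
    """Scan a genome for several patterns and map hits to gene upstream regions.

    Each hit is assigned to the gene whose upstream window fully contains it
    (nearest gene start when windows overlap; empty string when none).  The
    per-gene table flags, for every pattern, whether at least one hit lies in
    the gene's upstream window.
    """
    patterns = [
        parse_pattern(p) if isinstance(p, str) else p for p in patterns
    ]
    regions = extract_upstream(genes, genome, window=window) if len(genes) else None
    gene_starts = {
        rec.locus: (rec.start if rec.strand != "-" else rec.end)
        for rec in genes.itertuples(index=False)
    } if len(genes) else {}

    all_hits: list[MotifHit] = []
    for pat in patterns:
        for hit in scan(genome, pat, max_mismatches=max_mismatches, strands=strands):
            if regions is not None:
                containing = regions[
                    (regions["contig"] == hit.contig)
                    & (regions["start"] <= hit.start)
                    & (regions["end"] >= hit.end)
                ]
                if len(containing):
                    hit.assigned_gene = min(
                        containing["locus"],
                        key=lambda g: (abs(gene_starts[g] - hit.start), g),
                    )
            all_hits.append(hit)
    all_hits.sort(key=lambda h: (h.contig, h.start, h.end, h.strand, h.pattern))

    loci = list(genes["locus"]) if len(genes) else []
    presence = pd.DataFrame(
        False, index=pd.Index(loci, name="locus"), columns=[p.name for p in patterns]
    )
    for hit in all_hits:
        if hit.assigned_gene:
            presence.loc[hit.assigned_gene, hit.pattern] = True
    return ScreenReport(hits=all_hits, per_gene=presence)
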