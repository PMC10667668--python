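"""Synthetic data with the statistical structure the analysis assumes.

Every downstream stage can be exercised without any external download:

* :func:`generate_secretome_dataset` draws an overdispersed spectral-count
  matrix with a planted secreted subset enriched in supernatant fractions;
* :func:`generate_genome_with_motifs` builds a genome with binding sites
  planted at known coordinates and genes placed immediately downstream;
* :func:`generate_ct_table` produces qPCR Ct tables with known fold changes;
* :func:`generate_growth_curve` produces exponential growth curves.

The default secretome design mirrors a wild-type vs. regulator-deletion
study across sugar supplements: seven strain x sugar conditions (the mutant
is not assayed on pectin), each with one supernatant and one cytosol sample.
Counts are negative-binomial (mean m, variance m + dispersion * m^2) with an
independent post-draw dropout that zeroes a count with fixed probability,
mimicking detection limits.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .matrix import SpectralCountMatrix
from .motifs import MotifPattern, parse_pattern

REVCOMP = str.maketrans("ACGT", "TGCA")

DEFAULT_STRAINS = ("WT", "dtrmBL4")
DEFAULT_SUGARS = ("none", "maltose", "maltodextrin", "pectin")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def default_design(replicates: int = 1) -> list[tuple[str, str, str]]:
    """(strain, sugar, fraction) labels of the default study layout.

    Wild type is assayed on no sugar, maltose, maltodextrin and pectin; the
    deletion mutant on all but pectin.  Each condition has ``replicates``
    supernatant and cytosol samples (one by default, as in a single-run
    LC-MS/MS design).
    """
    design = []
    for strain in DEFAULT_STRAINS:
        for sugar in DEFAULT_SUGARS:
            if strain == "dtrmBL4" and sugar == "pectin":
                continue
            for fraction in ("supernatant", "cytosol"):
                design.extend([(strain, sugar, fraction)] * replicates)
    return design


@dataclasses.dataclass
class SecretomeSimConfig:
    """Study conditions for the synthetic secretome.

    ``dispersion`` is the negative-binomial overdispersion alpha with
    variance m + alpha * m^2 (alpha -> 0 approaches Poisson).
    """

    n_proteins: int = 200
    samples: list[tuple[str, str, str]] | None = None
    secreted_fraction: float = 0.165
    enrichment: float = 8.0
    baseline_mean: float = 20.0
    dispersion: float = 0.05
    dropout: float = 0.1
    signal_peptide_tpr: float = 0.9  # P(flag | secreted)
    signal_peptide_fpr: float = 0.05  # P(flag | not secreted)
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError(f"n_proteins must be >= 1, got {self.n_proteins}")
        if not 0.0 <= self.secreted_fraction <= 1.0:
            raise ConfigError(
                f"secreted_fraction must be in [0, 1], got {self.secreted_fraction}"
            )
        if self.enrichment <= 1.0:
            raise ConfigError(f"enrichment must be > 1, got {self.enrichment}")
        if self.dispersion <= 0.0:
            raise ConfigError(f"dispersion must be > 0, got {self.dispersion}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.baseline_mean <= 0.0:
            raise ConfigError(f"baseline_mean must be > 0, got {self.baseline_mean}")

    def design(self) -> list[tuple[str, str, str]]:
        return list(self.samples) if self.samples is not None else default_design()


@dataclasses.dataclass
class SimulatedSecretome:
    counts: SpectralCountMatrix
    truth: pd.DataFrame  # locus, secreted
    annotations: pd.DataFrame  # locus, signal_peptide

    @property
    def secreted_loci(self) -> list[str]:
        return sorted(self.truth.index[self.truth["secreted"]])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with mean m and variance m + alpha m^2."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_secretome_dataset(config: SecretomeSimConfig) -> SimulatedSecretome:
    """Draw a spectral-count matrix with planted secreted loci.

    Secreted loci have expected supernatant counts ``baseline_mean *
    enrichment`` and cytosol counts ``baseline_mean``; the remaining loci are
    the reverse (cytosol-enriched), so the cytosol control genuinely contains
    them.  Exactly ``round(n_proteins * secreted_fraction)`` loci are secreted.
    Identical config and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    width = max(4, len(str(n)))
    loci = [f"SYN_{i + 1:0{width}d}" for i in range(n)]

    n_secreted = round(n * config.secreted_fraction)
    secreted_idx = rng.choice(n, size=n_secreted, replace=False)
    secreted = np.zeros(n, dtype=bool)
    secreted[secreted_idx] = True

    design = config.design()
    sample_ids = []
    seen: dict[tuple, int] = {}
    for strain, sugar, fraction in design:
        key = (strain, sugar, fraction)
        seen[key] = seen.get(key, 0) + 1
        suffix = f"_r{seen[key]}" if design.count(key) > 1 else ""
        sample_ids.append(f"{strain}_{sugar}_{'sup' if fraction == 'supernatant' else 'cyt'}{suffix}")
    samples = pd.DataFrame(
        design, columns=["strain", "sugar", "fraction"], index=pd.Index(sample_ids, name="sample_id")
    )

    hi = config.baseline_mean * config.enrichment
    lo = config.baseline_mean
    counts = np.empty((n, len(design)), dtype=np.int64)
    for j, (_, _, fraction) in enumerate(design):
        if fraction == "supernatant":
            means = np.where(secreted, hi, lo)
        else:
            means = np.where(secreted, lo, hi)
        col = _nb_draw(rng, means, config.dispersion)
        col[rng.random(n) < config.dropout] = 0
        counts[:, j] = col

    truth = pd.DataFrame({"secreted": secreted}, index=pd.Index(loci, name="locus"))
    sp = np.where(
        secreted,
        rng.random(n) < config.signal_peptide_tpr,
        rng.random(n) < config.signal_peptide_fpr,
    )
    annotations = pd.DataFrame(
        {"signal_peptide": sp}, index=pd.Index(loci, name="locus")
    )
    matrix = SpectralCountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(loci, name="locus"), columns=samples.index),
        samples=samples,
    )
    return SimulatedSecretome(counts=matrix, truth=truth, annotations=annotations)


# -- genome with planted motifs -------------------------------------------

@dataclasses.dataclass
class GenomeSimConfig:
    length: int
    gc: float = 0.45
    planted: list[tuple[str, int, str, str]] = dataclasses.field(default_factory=list)
    #: each entry: (pattern string, 1-based start, strand, downstream locus tag)
    contig: str = "synthetic_contig_1"
    gene_gap: int = 50  # bp between site end and downstream gene start
    gene_length: int = 900
    seed: int = 0

    def validate(self) -> None:
        if self.length < 1:
            raise ConfigError(f"length must be >= 1, got {self.length}")
        if not 0.0 <= self.gc <= 1.0:
            raise ConfigError(f"gc must be in [0, 1], got {self.gc}")
        spans = []
        for pattern, pos, strand, locus in self.planted:
            pat = parse_pattern(pattern)
            span = pat.min_span
            if pat.min_span != pat.max_span:
                raise ConfigError(
                    f"planted pattern {pattern!r} has a ranged spacer; plant a fixed span"
                )
            if strand not in ("+", "-"):
                raise ConfigError(f"planted strand must be +/-, got {strand!r}")
            if not 1 <= pos <= self.length - span + 1:
                raise ConfigError(
                    f"planted position {pos} out of range for span {span} and length {self.length}"
                )
            spans.append((pos, pos + span - 1, pattern))
        spans.sort()
        for (s1, e1, p1), (s2, e2, p2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigError(
                    f"planted sites overlap: {p1} [{s1},{e1}] and {p2} [{s2},{e2}]"
                )


@dataclasses.dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    genes: pd.DataFrame  # locus, contig, start, end, strand
    truth: pd.DataFrame  # locus, pattern, start, end, strand, site_seq

    def write(self, fasta_path, gff_path, truth_path=None) -> None:
        write_fasta(self.sequences, fasta_path)
        write_gff(self.genes, self.sequences, gff_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def _realize_pattern(pat: MotifPattern, rng: np.random.Generator) -> str:
    parts = []
    for i, block in enumerate(pat.blocks):
        parts.append(block)
        if i < len(pat.spacers):
            lo, _ = pat.spacers[i]
            parts.append("".join(rng.choice(list("ACGT"), size=lo)))
    return "".join(parts)


def generate_genome_with_motifs(config: GenomeSimConfig) -> SimulatedGenome:
    """Random genome with motif instances planted at known coordinates.

    Reading the FASTA back at each planted 1-based position yields the planted
    site (its reverse complement for minus-strand plants).  One gene per site
    is placed downstream on the site's strand, ``gene_gap`` bp away, so the
    site falls in the gene's upstream window.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p_gc = config.gc / 2.0
    p_at = (1.0 - config.gc) / 2.0
    seq = rng.choice(list("ACGT"), size=config.length, p=[p_at, p_gc, p_gc, p_at])

    genes, truth = [], []
    for pattern_text, pos, strand, locus in config.planted:
        pat = parse_pattern(pattern_text)
        site = _realize_pattern(pat, rng)
        span = len(site)
        start, end = pos, pos + span - 1
        inserted = site if strand == "+" else site.translate(REVCOMP)[::-1]
        seq[start - 1 : end] = list(inserted)
        if strand == "+":
            g_start = end + config.gene_gap + 1
            g_end = g_start + config.gene_length - 1
        else:
            g_end = start - config.gene_gap - 1
            g_start = g_end - config.gene_length + 1
        if g_start < 1 or g_end > config.length:
            raise ConfigError(
                f"gene for planted site at {pos} ({strand}) falls outside the genome"
            )
        genes.append(
            {"locus": locus, "contig": config.contig, "start": g_start, "end": g_end, "strand": strand}
        )
        truth.append(
            {"locus": locus, "pattern": pat.name, "start": start, "end": end,
             "strand": strand, "site_seq": site}
        )
    return SimulatedGenome(
        sequences={config.contig: "".join(seq)},
        genes=pd.DataFrame(genes, columns=["locus", "contig", "start", "end", "strand"]),
        truth=pd.DataFrame(
            truth, columns=["locus", "pattern", "start", "end", "strand", "site_seq"]
        ),
    )


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff(genes: pd.DataFrame, sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, seq in sequences.items():
            fh.write(f"##sequence-region {contig} 1 {len(seq)}\n")
        for rec in genes.itertuples(index=False):
            fh.write(
                f"{rec.contig}\tsecretomics_sim\tgene\t{rec.start}\t{rec.end}\t.\t"
                f"{rec.strand}\t.\tID={rec.locus};locus_tag={rec.locus}\n"
            )


# -- qPCR Ct tables --------------------------------------------------------

def generate_ct_table(
    true_fold_changes: dict[str, float],
    references: tuple[str, ...] = ("pcna", "rps30"),
    sd: float = 0.0,
    replicates: int = 3,
    conditions: tuple[str, str] = ("control", "treatment"),
    target_base_ct: float = 24.0,
    reference_ct: float = 16.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format Ct table with known fold changes planted.

    The expected ddCt of each target equals -log2(fold); reference genes have
    condition-independent expected Ct.  Gaussian noise of standard deviation
    ``sd`` cycles is added per well.
    """
    for gene, fold in true_fold_changes.items():
        if fold <= 0:
            raise ConfigError(f"fold change for {gene!r} must be > 0, got {fold}")
    if replicates < 1:
        raise ConfigError(f"replicates must be >= 1, got {replicates}")
    if sd < 0:
        raise ConfigError(f"sd must be >= 0, got {sd}")
    rng = np.random.default_rng(seed)
    control, treatment = conditions
    rows = []
    for gene, fold in true_fold_changes.items():
        for condition in conditions:
            ct0 = target_base_ct - (math.log2(fold) if condition == treatment else 0.0)
            for rep in range(1, replicates + 1):
                rows.append(
                    {"gene": gene, "role": "target", "condition": condition,
                     "replicate": rep, "ct": ct0 + rng.normal(0.0, sd) if sd else ct0}
                )
    for ref in references:
        for condition in conditions:
            for rep in range(1, replicates + 1):
                rows.append(
                    {"gene": ref, "role": "reference", "condition": condition,
                     "replicate": rep, "ct": reference_ct + rng.normal(0.0, sd) if sd else reference_ct}
                )
    return pd.DataFrame(rows, columns=["gene", "role", "condition", "replicate", "ct"])


# -- growth curves ---------------------------------------------------------

def generate_growth_curve(
    n0: float,
    rate: float,
    hours: float,
    noise_cv: float = 0.0,
    dt: float = 0.5,
    seed: int = 0,
) -> GrowthCurve:
    """Exponential growth curve N(t) = n0 * 2^(rate * t) with optional
    multiplicative lognormal noise of coefficient of variation ``noise_cv``.
    """
    if n0 <= 0:
        raise ConfigError(f"n0 must be > 0, got {n0}")
    if rate < 0:
        raise ConfigError(f"rate must be >= 0, got {rate}")
    if hours < 0:
        raise ConfigError(f"duration must be >= 0, got {hours}")
    if noise_cv < 0:
        raise ConfigError(f"noise_cv must be >= 0, got {noise_cv}")
    times = np.arange(0.0, hours + dt / 2, dt)
    density = n0 * np.power(2.0, rate * times)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=times.size)
        density = density * noise
    return GrowthCurve(times=times, density=density)


# -- dataset export --------------------------------------------------------

def write_secretome_dataset(sim: SimulatedSecretome, outdir) -> dict[str, Path]:
    """Write counts/sample-sheet/annotations/truth TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.tsv",
    }
    sim.counts.to_tsv(paths["counts"], paths["samples"])
    sim.annotations.to_csv(paths["annotations"], sep="\t")
    sim.truth.to_csv(paths["truth"], sep="\t")
    return paths
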