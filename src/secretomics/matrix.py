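"""Spectral-count matrix container.

A label-free shotgun proteomics experiment yields, per protein (locus tag) and
per sample, the number of MS/MS spectra matched to that protein.  Samples carry
three pieces of metadata: strain (e.g. wild type vs. a regulator deletion),
sugar supplement of the culture medium, and fraction (culture supernatant vs.
cytosol of the lysed cells).  The cytosol fraction serves as a contamination
control when deciding whether a protein is genuinely secreted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

FRACTIONS = ("supernatant", "cytosol")

#: Default normalization total: spectra per sample are rescaled so that every
#: sample column sums to this value ("normalized spectra at 10,000/sample").
DEFAULT_TOTAL = 10_000.0


@dataclasses.dataclass
class SpectralCountMatrix:
    """Protein x sample spectral counts plus sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Nonnegative counts, rows indexed by locus tag, columns by sample id.
    samples : pandas.DataFrame
        Indexed by sample id; must carry ``strain``, ``sugar`` and
        ``fraction`` columns, with fraction in {"supernatant", "cytosol"}.
    normalized : bool
        Whether columns have been rescaled to a common total.
    total : float, optional
        The common column total when ``normalized`` is set.
    raw : pandas.DataFrame, optional
        The pre-normalization counts; retained because detection (presence /
        absence) is a raw-count notion while abundance ratios use normalized
        counts.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False
    total: float | None = None
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        counts, samples = self.counts, self.samples
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate locus tags: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("spectral counts must be nonnegative")
        missing = {"strain", "sugar", "fraction"} - set(samples.columns)
        if missing:
            raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
        if list(samples.index) != list(counts.columns):
            # allow same set, different order
            if set(samples.index) != set(counts.columns):
                raise ValueError("sample sheet does not match count columns")
            self.samples = samples = samples.loc[counts.columns]
        bad = set(samples["fraction"]) - set(FRACTIONS)
        if bad:
            raise ValueError(f"unknown fraction labels: {sorted(bad)}")
        if self.normalized and self.total is not None and len(counts):
            sums = counts.sum(axis=0).to_numpy(float)
            if not np.allclose(sums, self.total, rtol=1e-6):
                raise ValueError(
                    "normalized matrix whose columns do not sum to "
                    f"{self.total}: {dict(counts.sum(axis=0))}"
                )

    # -- convenience -------------------------------------------------------
    @property
    def loci(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def fraction_samples(self, fraction: str) -> list[str]:
        return list(self.samples.index[self.samples["fraction"] == fraction])

    def conditions(self) -> list[tuple[str, str]]:
        """Strain x sugar pairs that contain at least one supernatant sample."""
        sup = self.samples[self.samples["fraction"] == "supernatant"]
        seen: list[tuple[str, str]] = []
        for strain, sugar in zip(sup["strain"], sup["sugar"]):
            if (strain, sugar) not in seen:
                seen.append((strain, sugar))
        return seen

    def condition_samples(
        self, strain: str, sugar: str, fraction: str
    ) -> list[str]:
        s = self.samples
        mask = (
            (s["strain"] == strain)
            & (s["sugar"] == sugar)
            & (s["fraction"] == fraction)
        )
        return list(s.index[mask])

    def raw_counts(self) -> pd.DataFrame:
        """Raw counts for detection calls (falls back to ``counts``)."""
        return self.raw if self.raw is not None else self.counts

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, samples_path: str | Path
    ) -> "SpectralCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        counts.index.name = "locus"
        counts.columns.name = "sample_id"
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        samples.index.name = "sample_id"
        return cls(counts=counts, samples=samples)

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="locus")
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")
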