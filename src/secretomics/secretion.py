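"""Secretion scoring and secreted-protein classification.

A protein is called secreted when its abundance in the culture supernatant
cannot be explained by cytosolic contamination.  Evidence is evaluated per
condition (a strain x sugar pair with at least one supernatant sample): a
condition *supports* secretion when the normalized supernatant abundance
exceeds ``ratio_threshold`` times a cytosol reference level.  Detection
(presence/absence) is a raw-count notion: a locus is detected in a condition
when any supernatant sample of that condition has at least ``detection_floor``
raw spectra.

The cytosol reference for a condition is

* the condition's own mean normalized cytosol abundance, when the locus is
  detected in that condition's cytosol;
* otherwise the matrix-wide mean normalized cytosol abundance of the locus
  (a protein seen in the cytosol of other conditions is treated as present at
  its typical level, not as absent), floored at ``pseudocount``;
* the bare ``pseudocount`` for loci never detected in any cytosol sample
  ("found only in the supernatant" - maximal evidence).

The discrete secretion probability is then

* ``1``   - every detected condition supports secretion and detection spans at
  least ``min_conditions`` conditions;
* ``0.5`` - every detected condition supports secretion but detection spans
  fewer than ``min_conditions``, or the locus is supernatant-only with at
  least one supporting condition;
* ``0``   - otherwise (no support, or partial support combined with genuine
  cytosol presence, which is treated as contamination).

A locus is classified secreted iff its probability is >= 0.5.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import DEFAULT_TOTAL, SpectralCountMatrix
from .normalize import normalize_counts

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ConditionEvidence:
    """Per-condition support record kept for audit."""

    strain: str
    sugar: str
    detected: bool
    supernatant_mean: float  # normalized units
    cytosol_reference: float  # normalized units
    support: bool


@dataclasses.dataclass
class SecretionCall:
    locus: str
    supernatant_only: bool
    probability: float  # in {0, 0.5, 1}
    signal_peptide: bool
    secreted: bool
    evidence: list[ConditionEvidence]


def _ensure_normalized(matrix: SpectralCountMatrix) -> None:
    if not matrix.normalized:
        raise ValueError(
            "matrix is not normalized; call normalize_counts() first"
        )


def flag_supernatant_only(
    matrix: SpectralCountMatrix, locus: str, detection_floor: float = 1.0
) -> bool:
    """True iff the locus is detected in >=1 supernatant sample and in no
    cytosol sample (raw counts, detection floor inclusive)."""
    raw = matrix.raw_counts()
    if locus not in raw.index:
        raise KeyError(f"unknown locus: {locus}")
    sup = matrix.fraction_samples("supernatant")
    cyt = matrix.fraction_samples("cytosol")
    if not sup or not cyt:
        raise ValueError("matrix must contain both supernatant and cytosol samples")
    row = raw.loc[locus]
    return bool(
        (row[sup] >= detection_floor).any() and (row[cyt] < detection_floor).all()
    )


class SecretionClassifier(BaseEstimator):
    """Rule-based secreted/cytosolic classifier over a spectral-count matrix.

    Parameters
    ----------
    ratio_threshold : float, default 1.0
        A condition supports secretion when normalized supernatant abundance
        exceeds this multiple of the cytosol reference.
    min_conditions : int, default 2
        Number of detected conditions required for probability 1.
    pseudocount : float, default 0.5
        Cytosol reference (normalized units) for supernatant-only loci.
    detection_floor : float, default 1.0
        Minimum raw spectral count for a locus to count as detected.
    total : float, default 10000
        Normalization total applied when an unnormalized matrix is passed.

    Attributes
    ----------
    calls_ : list of SecretionCall, sorted by locus tag.
    probabilities_ : pandas.Series of probabilities indexed by locus.
    secreted_loci_ : list of loci classified secreted.
    matrix_ : the normalized matrix used for scoring.
    """

    def __init__(
        self,
        ratio_threshold: float = 1.0,
        min_conditions: int = 2,
        pseudocount: float = 0.5,
        detection_floor: float = 1.0,
        total: float = DEFAULT_TOTAL,
    ):
        self.ratio_threshold = ratio_threshold
        self.min_conditions = min_conditions
        self.pseudocount = pseudocount
        self.detection_floor = detection_floor
        self.total = total

    # -- scoring ----------------------------------------------------------
    def _score_locus(
        self, matrix: SpectralCountMatrix, locus: str
    ) -> tuple[float, bool, list[ConditionEvidence]]:
        raw = matrix.raw_counts().loc[locus]
        norm = matrix.counts.loc[locus]
        cyt_samples = matrix.fraction_samples("cytosol")
        cyt_detected_any = bool((raw[cyt_samples] >= self.detection_floor).any())
        global_cyt_mean = float(norm[cyt_samples].mean()) if cyt_samples else 0.0

        evidence: list[ConditionEvidence] = []
        n_detected = n_support = 0
        for strain, sugar in matrix.conditions():
            sup = matrix.condition_samples(strain, sugar, "supernatant")
            cyt = matrix.condition_samples(strain, sugar, "cytosol")
            detected = bool((raw[sup] >= self.detection_floor).any())
            sup_mean = float(norm[sup].mean())
            if cyt and bool((raw[cyt] >= self.detection_floor).any()):
                cyt_ref = float(norm[cyt].mean())
            elif cyt_detected_any:
                cyt_ref = max(self.pseudocount, global_cyt_mean)
            else:
                cyt_ref = self.pseudocount
            support = detected and sup_mean > self.ratio_threshold * cyt_ref
            n_detected += detected
            n_support += support
            evidence.append(
                ConditionEvidence(strain, sugar, detected, sup_mean, cyt_ref, support)
            )

        supernatant_only = bool(
            (raw[matrix.fraction_samples("supernatant")] >= self.detection_floor).any()
            and not cyt_detected_any
        )
        if n_support == 0:
            prob = 0.0
        elif n_support == n_detected:
            prob = 1.0 if n_detected >= self.min_conditions else 0.5
        elif supernatant_only:
            prob = 0.5
        else:
            prob = 0.0
        return prob, supernatant_only, evidence

    # -- estimator API -----------------------------------------------------
    def fit(self, X: SpectralCountMatrix, y=None, annotations: pd.DataFrame | None = None):
        """Score every locus of ``X``.

        ``annotations`` may carry a boolean ``signal_peptide`` column indexed
        by (or with a column of) locus tags; missing flags are treated as
        False.  The signal-peptide flag is an input annotation from an
        external predictor and does not enter the secretion rule.
        """
        if len(X.loci) == 0:
            matrix = X
        else:
            matrix = X if X.normalized else normalize_counts(X, total=self.total)
        sp = _signal_peptide_lookup(annotations)
        calls = []
        for locus in sorted(matrix.loci):
            prob, sup_only, evidence = self._score_locus(matrix, locus)
            calls.append(
                SecretionCall(
                    locus=locus,
                    supernatant_only=sup_only,
                    probability=prob,
                    signal_peptide=bool(sp.get(locus, False)),
                    secreted=prob >= 0.5,
                    evidence=evidence,
                )
            )
        self.matrix_ = matrix
        self.calls_ = calls
        self.probabilities_ = pd.Series(
            {c.locus: c.probability for c in calls}, name="probability"
        )
        self.secreted_loci_ = [c.locus for c in calls if c.secreted]
        self.n_secreted_ = len(self.secreted_loci_)
        logger.info("classified %d of %d loci as secreted", self.n_secreted_, len(calls))
        return self

    def predict(self, loci=None) -> pd.Series:
        """Boolean secreted verdict per locus (fitted loci by default)."""
        verdict = pd.Series(
            {c.locus: c.secreted for c in self.calls_}, name="secreted"
        )
        return verdict if loci is None else verdict.loc[list(loci)]

    def calls_frame(self) -> pd.DataFrame:
        """Tabular form of the calls (one row per locus)."""
        return pd.DataFrame(
            {
                "locus": [c.locus for c in self.calls_],
                "supernatant_only": [c.supernatant_only for c in self.calls_],
                "probability": [c.probability for c in self.calls_],
                "signal_peptide": [c.signal_peptide for c in self.calls_],
                "secreted": [c.secreted for c in self.calls_],
            }
        ).set_index("locus")


def _signal_peptide_lookup(annotations: pd.DataFrame | None) -> dict:
    if annotations is None or "signal_peptide" not in getattr(annotations, "columns", []):
        return {}
    ann = annotations
    if "locus" in ann.columns:
        ann = ann.set_index("locus")
    return ann["signal_peptide"].astype(bool).to_dict()


# -- functional wrappers ---------------------------------------------------

def secretion_probability(
    matrix: SpectralCountMatrix, locus: str, **params
) -> float:
    """Discrete secretion probability in {0, 0.5, 1} for one locus.

    Requires a normalized matrix (raises ``ValueError`` otherwise); detection
    uses the retained raw counts.
    """
    _ensure_normalized(matrix)
    clf = SecretionClassifier(**params)
    if locus not in matrix.counts.index:
        raise KeyError(f"unknown locus: {locus}")
    prob, _, _ = clf._score_locus(matrix, locus)
    return prob


def classify_secreted(
    matrix: SpectralCountMatrix,
    annotations: pd.DataFrame | None = None,
    **params,
) -> list[SecretionCall]:
    """Classify every locus; returns calls sorted by locus tag."""
    clf = SecretionClassifier(**params)
    clf.fit(matrix, annotations=annotations)
    return clf.calls_


def differential_table(
    calls: list[SecretionCall], matrix: SpectralCountMatrix
) -> pd.DataFrame:
    """Normalized counts restricted to secreted loci.

    The output (loci x samples, sorted by locus tag) is the direct input to
    the clustered-heatmap stage.  With zero secreted calls an empty table with
    the sample columns is returned.
    """
    _ensure_normalized(matrix)
    secreted = sorted(c.locus for c in calls if c.secreted)
    return matrix.counts.loc[secreted].copy()
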