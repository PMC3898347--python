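"""Weighted genetic risk score (GRS) for refractive error.

The score for a subject is the weighted sum of effect-allele dosages over the
SNP panel,

    GRS = Σ_i β_i · d_i,     d_i ∈ [0, 2],

with each β_i the per-allele effect in diopters, oriented so the effect
allele is the refraction-decreasing (myopia-risk) allele and β_i > 0.  An
optional normalization mode rescales by n_snps / Σβ so the score is on the
risk-allele-count scale.  Scores are binned into three genetic-load
categories at fixed diopter-weighted cut points (default 2.25 and 3.00).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DosageRangeError, FormatError

GRS_CATEGORIES = ("low", "medium", "high")

REQUIRED_PANEL_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta")


@dataclass
class SNPPanel:
    """The weight table: one row per variant with effect/other allele and a
    positive per-allele effect size (diopters).

    ``frame`` may additionally carry a ``freq`` column (effect-allele
    frequency) when the panel comes from the synthetic generator; it is
    ignored by scoring and not written to weight files.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_PANEL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"weight table missing column(s): {missing}")
        frame = self.frame.reset_index(drop=True)
        dup = frame["variant_id"][frame["variant_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate variant id(s): {sorted(set(dup))}")
        if (frame["effect_allele"] == frame["other_allele"]).any():
            bad = frame.loc[frame["effect_allele"] == frame["other_allele"], "variant_id"]
            raise FormatError(f"effect allele equals other allele for: {list(bad)}")
        betas = frame["beta"].to_numpy(dtype=float)
        if not np.all(np.isfinite(betas)) or np.any(betas <= 0):
            bad = frame.loc[~(np.isfinite(betas) & (betas > 0)), "variant_id"]
            raise FormatError(
                f"betas must be positive and finite after orientation; offending: {list(bad)}"
            )
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.frame["variant_id"].to_numpy(dtype=object)

    @property
    def betas(self) -> np.ndarray:
        return self.frame["beta"].to_numpy(dtype=float)

    @property
    def freqs(self) -> np.ndarray | None:
        if "freq" not in self.frame.columns:
            return None
        return self.frame["freq"].to_numpy(dtype=float)

    def subset(self, variant_ids) -> "SNPPanel":
        idx = self.frame["variant_id"].isin(list(variant_ids))
        return SNPPanel(self.frame.loc[idx].copy())


def _check_dosages(dosage: np.ndarray) -> np.ndarray:
    dosage = np.asarray(dosage, dtype=float)
    if not np.all(np.isfinite(dosage)):
        raise DosageRangeError("dosages must be finite")
    if np.any(dosage < 0) or np.any(dosage > 2):
        raise DosageRangeError("dosages must lie in [0, 2]")
    return dosage


@dataclass
class GenotypeMatrix:
    """Subjects × variants effect-allele dosage matrix (values in [0, 2],
    fractional permitted for imputed genotypes)."""

    subject_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self):
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.dosage = _check_dosages(self.dosage)
        if self.dosage.shape != (len(self.subject_ids), len(self.variant_ids)):
            raise AlignmentError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subject_ids)} subjects × {len(self.variant_ids)} variants"
            )

    def aligned_to(self, panel: SNPPanel) -> "GenotypeMatrix":
        """Reorder columns to the panel's variant order; every panel variant
        must be present."""
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        try:
            order = [pos[v] for v in panel.variant_ids]
        except KeyError:
            from .exceptions import MissingVariantError

            missing = [v for v in panel.variant_ids if v not in pos]
            raise MissingVariantError(missing) from None
        return GenotypeMatrix(self.subject_ids, list(panel.variant_ids), self.dosage[:, order])


def weighted_grs(dosage, panel: SNPPanel, *, normalize: bool = False):
    """Weighted genetic risk score Σ β_i · d_i.

    ``dosage`` is a length-n vector (one subject) or an m×n matrix aligned
    to the panel's variant order.  With ``normalize=True`` the score is
    rescaled by n_snps / Σβ (risk-allele-count convention).
    """
    dosage = _check_dosages(dosage)
    if dosage.shape[-1] != len(panel):
        raise AlignmentError(
            f"dosage has {dosage.shape[-1]} variants, panel has {len(panel)}"
        )
    score = dosage @ panel.betas
    if normalize:
        score = score * (len(panel) / panel.betas.sum())
    return score


def risk_allele_count(dosage):
    """Total effect-allele dosage Σ d_i (integer for hard calls)."""
    dosage = _check_dosages(dosage)
    return dosage.sum(axis=-1)


def categorize_grs(score, cut_points: tuple[float, float] = (2.25, 3.00)):
    """Three-level genetic load: low < cut_points[0] ≤ medium < cut_points[1] ≤ high.

    Intervals are half-open below with the top interval closed above, so
    every finite score lands in exactly one category.
    """
    lo, hi = cut_points
    if not lo < hi:
        raise ValueError("cut_points must be strictly increasing")
    arr = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    out = np.where(arr < lo, "low", np.where(arr < hi, "medium", "high"))
    if arr.ndim == 0:
        return str(out[()])
    return out.astype(object)
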