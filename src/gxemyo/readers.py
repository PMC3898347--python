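"""File readers for weight tables, genotypes and phenotype tables.

Formats
-------
* Weight TSV: tab-separated, header ``variant_id  effect_allele
  other_allele  beta``.  Rows with a negative beta are re-oriented at load
  time (alleles swapped, beta negated) so stored betas are positive.
* Genotypes: VCF 4.x (dosage from the ``DS`` FORMAT field, hard-call ``GT``
  fallback) or a dosage-matrix TSV (rows = subjects, header row of variant
  IDs, values already on the effect-allele scale).  For VCF, the record's
  ALT is matched against the panel's effect allele; when the effect allele
  is REF the dosage is flipped to 2 − d.  Variants are matched by ID and
  alleles only; an allele pair matching neither orientation is a hard error
  (no strand flipping is attempted).
* Phenotype CSV: header ``subject_id, age, sex, education, sphere_r, cyl_r,
  sphere_l, cyl_l, exclusion_flags`` with sex in {M, F}, education in
  {0, 1, 2} and semicolon-separated exclusion flags; an empty sphere cell
  marks that eye unavailable.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    AlleleMismatchError,
    DosageRangeError,
    FormatError,
    MissingVariantError,
)
from .grs import GenotypeMatrix, REQUIRED_PANEL_COLUMNS, SNPPanel
from .phenotype import EyeRefraction, apply_exclusions, classify_refraction, mean_se


def read_weights(path) -> SNPPanel:
    """Load and validate a weight TSV; negative betas are re-oriented."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    except Exception as exc:
        raise FormatError(f"cannot parse weight table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"weight table {path} missing column(s): {missing}")
    df = df[list(df.columns)].copy()
    betas = pd.to_numeric(df["beta"], errors="coerce")
    bad = df.loc[~np.isfinite(betas) | (betas == 0)]
    if len(bad):
        raise FormatError(
            f"weight table {path}: zero or non-numeric beta in row(s) "
            f"{[int(i) + 2 for i in bad.index]}"  # +2: header + 1-based
        )
    df["beta"] = betas
    flip = df["beta"] < 0
    if flip.any():
        ea = df.loc[flip, "effect_allele"].copy()
        df.loc[flip, "effect_allele"] = df.loc[flip, "other_allele"]
        df.loc[flip, "other_allele"] = ea
        df.loc[flip, "beta"] = -df.loc[flip, "beta"]
    return SNPPanel(df)


def read_genotypes(path, panel: SNPPanel, *, impute_mean: bool = False) -> GenotypeMatrix:
    """Read a dosage matrix aligned to the panel (VCF or TSV)."""
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        gm = _read_vcf(path, panel)
    else:
        gm = _read_dosage_tsv(path, panel, impute_mean=impute_mean)
    return gm.aligned_to(panel)


def _read_vcf(path, panel: SNPPanel) -> GenotypeMatrix:
    from cyvcf2 import VCF

    wanted = {v: i for i, v in enumerate(panel.variant_ids)}
    frame = panel.frame.set_index("variant_id")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    found: dict[str, np.ndarray] = {}
    for variant in vcf:
        vid = variant.ID
        if vid not in wanted or vid in found:
            continue
        ref = variant.REF
        alt = variant.ALT[0] if variant.ALT else None
        effect = frame.loc[vid, "effect_allele"]
        other = frame.loc[vid, "other_allele"]
        if alt == effect and ref == other:
            flip = False
        elif ref == effect and alt == other:
            flip = True
        else:
            raise AlleleMismatchError(
                f"{vid}: VCF alleles {ref}/{alt} match neither orientation of "
                f"panel alleles {effect}/{other}"
            )
        ds = variant.format("DS")
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gts = np.asarray(variant.genotypes, dtype=object)
            d = np.array(
                [float(int(g[0]) + int(g[1])) for g in gts], dtype=float
            )
        if flip:
            d = 2.0 - d
        if np.any(~np.isfinite(d)) or np.any(d < 0) or np.any(d > 2):
            raise DosageRangeError(f"{vid}: dosage outside [0, 2] in {path}")
        found[vid] = d
    missing = [v for v in panel.variant_ids if v not in found]
    if missing:
        raise MissingVariantError(missing)
    dosage = np.column_stack([found[v] for v in panel.variant_ids])
    return GenotypeMatrix(samples, list(panel.variant_ids), dosage)


def _read_dosage_tsv(path, panel: SNPPanel, *, impute_mean: bool) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [v for v in panel.variant_ids if v not in df.columns]
    if missing:
        raise MissingVariantError(missing)
    df = df[list(panel.variant_ids)].astype(float)
    if df.isna().any().any():
        if not impute_mean:
            raise FormatError(
                f"{path}: missing dosage cells; pass impute_mean=True to substitute "
                "twice the observed effect-allele frequency"
            )
        df = df.fillna(df.mean())
    dosage = df.to_numpy(dtype=float)
    if np.any(dosage < 0) or np.any(dosage > 2):
        raise DosageRangeError(f"{path}: dosage outside [0, 2]")
    return GenotypeMatrix([str(s) for s in df.index], list(panel.variant_ids), dosage)


_SEX_CODES = {"M": 1, "F": 0}

_PHENOTYPE_COLUMNS = (
    "subject_id", "age", "sex", "education",
    "sphere_r", "cyl_r", "sphere_l", "cyl_l", "exclusion_flags",
)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV into an analysis-ready cohort table.

    Derives per-eye and mean spherical equivalent, the refraction category,
    and exclusion status; sex is recoded to 1 = male / 0 = female and
    education kept ordinal (0/1/2).  ``se_mean`` is NaN when both eyes are
    unavailable or the subject is excluded from phenotyping upstream.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "exclusion_flags": str})
    missing = [c for c in _PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table {path} missing column(s): {missing}")

    rows = []
    for i, row in df.iterrows():
        line = i + 2  # header + 1-based
        sex = row["sex"]
        if sex not in _SEX_CODES:
            raise FormatError(f"{path}:{line}: unknown sex code {sex!r} (expected M or F)")
        edu = row["education"]
        try:
            edu = int(edu)
        except (TypeError, ValueError):
            raise FormatError(f"{path}:{line}: non-integer education code {edu!r}") from None
        if edu not in (0, 1, 2):
            raise FormatError(f"{path}:{line}: education code {edu} not in {{0, 1, 2}}")

        right = EyeRefraction.from_values(_cell(row["sphere_r"]), _cell(row["cyl_r"]))
        left = EyeRefraction.from_values(_cell(row["sphere_l"]), _cell(row["cyl_l"]))
        se = mean_se(right, left)

        flags_cell = row["exclusion_flags"]
        flags = []
        if isinstance(flags_cell, str) and flags_cell.strip():
            flags = [f.strip() for f in flags_cell.split(";") if f.strip()]
        try:
            excluded, reason = apply_exclusions(flags)
        except Exception as exc:
            raise FormatError(f"{path}:{line}: {exc}") from exc

        rows.append(
            {
                "subject_id": row["subject_id"],
                "age": float(row["age"]),
                "sex": _SEX_CODES[sex],
                "education": edu,
                "se_mean": se if se is not None else float("nan"),
                "category": classify_refraction(se) if se is not None else None,
                "excluded": excluded,
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def _cell(value):
    if value is None:
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
        return float(value)
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)
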