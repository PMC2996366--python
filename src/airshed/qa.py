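"""Measurement quality assurance for passive-sampler campaigns.

Two computations: subtraction of the laboratory-blank mean from every
measured concentration, and the relative precision of duplicate pairs.
All QA happens in whatever single concentration unit the records carry;
no unit conversion is attempted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .io import SamplingRecord


@dataclass
class QAReport:
    lab_blank_mean: float
    field_blank_mean: float | None
    n_duplicate_pairs: int
    relative_precision_pct: float | None
    overall_mean: float
    n_clamped: int = 0


def blank_correct(records: list[SamplingRecord]) -> tuple[list[SamplingRecord], dict]:
    """Subtract the lab-blank mean from every non-blank concentration.

    Blanks are removed from the returned analysis set. Corrected values
    that fall below zero are clamped to zero and counted. Raises if no
    laboratory blank is present (the correction is then impossible).
    """
    lab = [r.no2_ppb for r in records if r.role == "lab_blank"]
    if not lab:
        raise ValueError("no laboratory blanks present; cannot blank-correct")
    field = [r.no2_ppb for r in records if r.role == "field_blank"]
    lab_mean = float(np.mean(lab))
    corrected = []
    n_clamped = 0
    for r in records:
        if r.is_blank:
            continue
        value = r.no2_ppb - lab_mean
        if value < 0:
            value = 0.0
            n_clamped += 1
        corrected.append(dataclasses.replace(r, no2_ppb=value))
    fragment = {
        "lab_blank_mean": lab_mean,
        "field_blank_mean": float(np.mean(field)) if field else None,
        "n_clamped": n_clamped,
    }
    return corrected, fragment


def duplicate_pairs(records: list[SamplingRecord]) -> list[tuple[float, float]]:
    """Extract (primary, duplicate) concentration pairs by record id."""
    by_id = {r.record_id: r for r in records}
    pairs = []
    for r in records:
        parent = r.duplicate_parent
        if parent is not None:
            if parent not in by_id:
                raise ValueError(f"duplicate {r.record_id} references unknown record {parent}")
            pairs.append((by_id[parent].no2_ppb, r.no2_ppb))
    return pairs


def duplicate_relative_precision(pairs: list[tuple[float, float]], overall_mean: float) -> float:
    """Relative precision (%) of duplicate measurements.

    For each pair the two-observation standard deviation |a - b|/sqrt(2)
    is computed; the mean over pairs is divided by the overall mean
    concentration and expressed as a percentage.
    """
    if not pairs:
        raise ValueError("no duplicate pairs")
    if overall_mean <= 0:
        raise ValueError("overall mean must be positive")
    sds = [abs(a - b) / np.sqrt(2.0) for a, b in pairs]
    return float(np.mean(sds) / overall_mean * 100.0)


def qa_report(records: list[SamplingRecord]) -> tuple[list[SamplingRecord], QAReport]:
    """Full QA pass: blank correction, then duplicate relative precision.

    The duplicate records stay in the returned analysis set (they are
    genuine measurements); precision is computed on the corrected values.
    """
    corrected, frag = blank_correct(records)
    samples = [r.no2_ppb for r in corrected]
    overall_mean = float(np.mean(samples)) if samples else float("nan")
    pairs = duplicate_pairs(corrected)
    precision = duplicate_relative_precision(pairs, overall_mean) if pairs else None
    return corrected, QAReport(
        lab_blank_mean=frag["lab_blank_mean"],
        field_blank_mean=frag["field_blank_mean"],
        n_duplicate_pairs=len(pairs),
        relative_precision_pct=precision,
        overall_mean=overall_mean,
        n_clamped=frag["n_clamped"],
    )
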