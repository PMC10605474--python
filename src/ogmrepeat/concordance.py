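"""Cross-platform concordance: allele pairing, OLS regression, deviations.

Compares repeat sizes from optical genome mapping (OGM) against Southern
blot (SB) calls by rank-wise allele pairing and ordinary least squares of
OGM on SB, and against long-read (LR) medians by relative deviation
|LR - method| / method.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import EmptyInputError, InsufficientDataError, SingularDesignError, ValidationError

logger = logging.getLogger(__name__)

PAIRING_CONVENTIONS = ("rankwise", "drop-homozygous", "ogm-average")


@dataclass
class CohortRecord:
    """One patient/control row: SB calls, OGM component calls, optional LR reads."""

    patient_id: str
    sb_alleles: tuple[float, ...] = ()
    sb_homozygous: bool = False
    ogm_alleles: tuple[tuple[float, float], ...] = ()
    ogm_homozygous: bool = False
    lr_reads: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sb_alleles) > 2 or len(self.ogm_alleles) > 2:
            raise ValidationError(f"{self.patient_id}: at most 2 alleles per method")

    @property
    def ogm_means(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.ogm_alleles)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r_squared: float
    n_points: int


class MedianResult(NamedTuple):
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class DeviationRow:
    patient_id: str
    sb: float
    ogm: float
    lr: float
    dev_sb: float
    dev_ogm: float


def _expand_to_two(values: Sequence[float]) -> list[float]:
    vals = list(values)
    if len(vals) == 1:
        vals = vals * 2
    return sorted(vals)


def pair_alleles(record: CohortRecord, convention: str = "rankwise") -> list[tuple[float, float]]:
    """Pair SB against OGM allele sizes for one record.

    rankwise (default): expand homozygous singles to two identical values,
    sort both sides ascending, pair rank-wise -> exactly 2 points.
    drop-homozygous: one point per record when either side is a duplicated
    single (representative = mean of that side's values).
    ogm-average: always one point per record, mean SB vs mean OGM.
    Records missing a side are skipped (empty list) with a warning.
    """
    if convention not in PAIRING_CONVENTIONS:
        raise ValidationError(f"unknown pairing convention {convention!r}")
    sb = list(record.sb_alleles)
    ogm = list(record.ogm_means)
    if not sb or not ogm:
        logger.warning("record %s: missing SB or OGM side; skipped from pairing", record.patient_id)
        return []
    if convention == "ogm-average":
        return [(float(np.mean(sb)), float(np.mean(ogm)))]
    if convention == "drop-homozygous" and (len(sb) == 1 or len(ogm) == 1):
        return [(float(np.mean(sb)), float(np.mean(ogm)))]
    return list(zip(_expand_to_two(sb), _expand_to_two(ogm)))


def pair_cohort(
    records: Iterable[CohortRecord], convention: str = "rankwise"
) -> list[tuple[float, float]]:
    points: list[tuple[float, float]] = []
    for rec in records:
        points.extend(pair_alleles(rec, convention))
    return points


def ols_fit(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS of y on x with constant; 95% CIs from the t-distribution (n-2 df)."""
    if len(points) < 3:
        raise InsufficientDataError(f"need >= 3 points for OLS, got {len(points)}")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise SingularDesignError("all x values identical; design matrix is singular")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    # constant y: SStot == 0, statsmodels reports -inf; define r^2 = 0
    r_squared = float(model.rsquared) if np.ptp(y) > 0 else 0.0
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        r_squared=r_squared,
        n_points=len(points),
    )


def relative_deviation(reference_est: float, other_est: float) -> float:
    """|other - reference| / reference, e.g. deviation of LR from a method's
    estimate normalised by that method.  Returns a fraction."""
    if reference_est <= 0:
        raise ValidationError(f"reference estimate must be > 0, got {reference_est}")
    return abs(other_est - reference_est) / reference_est


def as_percent(fraction: float) -> int:
    """Nearest-integer percent, round-half-to-even."""
    return round(fraction * 100)


def lr_median(reads: Sequence[float]) -> MedianResult:
    """Median and quartiles (linear interpolation) of read-level repeat counts."""
    if len(reads) == 0:
        raise EmptyInputError("no long-read repeat counts supplied")
    arr = np.asarray(reads, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return MedianResult(median=float(med), q1=float(q1), q3=float(q3))


def deviation_table(
    records: Iterable[CohortRecord],
    lr_values: dict[str, float] | None = None,
) -> list[DeviationRow]:
    """Per-patient deviations of LR from SB and from OGM (largest allele).

    LR comes from the record's reads (median) or, failing that, from
    ``lr_values`` (e.g. published medians).  Records with no LR size are
    skipped.
    """
    rows = []
    for rec in records:
        if rec.lr_reads:
            lr = lr_median(rec.lr_reads).median
        elif lr_values and rec.patient_id in lr_values:
            lr = lr_values[rec.patient_id]
        else:
            continue
        if not rec.sb_alleles or not rec.ogm_alleles:
            logger.warning("record %s has LR but misses SB or OGM; skipped", rec.patient_id)
            continue
        sb = max(rec.sb_alleles)
        ogm = max(rec.ogm_means)
        rows.append(
            DeviationRow(
                patient_id=rec.patient_id,
                sb=sb,
                ogm=ogm,
                lr=lr,
                dev_sb=relative_deviation(sb, lr),
                dev_ogm=relative_deviation(ogm, lr),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "patient_id",
    "sb_allele1",
    "sb_allele2",
    "sb_homozygous",
    "ogm_mean1",
    "ogm_sd1",
    "ogm_mean2",
    "ogm_sd2",
    "ogm_homozygous",
]


def _opt_float(text: str) -> float | None:
    text = text.strip()
    return float(text) if text else None


def read_cohort(path) -> list[CohortRecord]:
    """Read a cohort CSV (see COHORT_COLUMNS) into CohortRecords."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path}: empty file")
        missing = set(COHORT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            sb = [v for v in (_opt_float(row["sb_allele1"]), _opt_float(row["sb_allele2"])) if v is not None]
            ogm = []
            for m_col, s_col in (("ogm_mean1", "ogm_sd1"), ("ogm_mean2", "ogm_sd2")):
                m, s = _opt_float(row[m_col]), _opt_float(row[s_col])
                if m is not None:
                    ogm.append((m, s if s is not None else math.nan))
            records.append(
                CohortRecord(
                    patient_id=row["patient_id"].strip(),
                    sb_alleles=tuple(sb),
                    sb_homozygous=row["sb_homozygous"].strip().lower() in {"1", "true", "yes"},
                    ogm_alleles=tuple(ogm),
                    ogm_homozygous=row["ogm_homozygous"].strip().lower() in {"1", "true", "yes"},
                )
            )
    if not records:
        raise EmptyInputError(f"{path}: no cohort records")
    return records


def write_cohort(records: Iterable[CohortRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for rec in records:
            sb = list(rec.sb_alleles) + ["", ""]
            ogm = list(rec.ogm_alleles) + [("", ""), ("", "")]
            writer.writerow(
                [
                    rec.patient_id,
                    sb[0],
                    sb[1],
                    int(rec.sb_homozygous),
                    ogm[0][0],
                    ogm[0][1],
                    ogm[1][0],
                    ogm[1][1],
                    int(rec.ogm_homozygous),
                ]
            )


def read_lr_reads(path) -> dict[str, list[float]]:
    """Read read-level repeat counts: CSV with patient_id, read_id, repeats."""
    reads: dict[str, list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"patient_id", "repeats"} <= set(reader.fieldnames):
            raise ValidationError(f"{path}: expected columns patient_id, read_id, repeats")
        for row in reader:
            reads.setdefault(row["patient_id"].strip(), []).append(float(row["repeats"]))
    if not reads:
        raise EmptyInputError(f"{path}: no reads")
    return reads


def _data_path(name: str):
    return resources.files("ogmrepeat.data").joinpath(name)


def load_builtin_cohort() -> list[CohortRecord]:
    """The published 17-patient + 2-control cohort shipped with the package."""
    with resources.as_file(_data_path("cohort_published.csv")) as p:
        return read_cohort(p)


def load_builtin_lr_reads() -> dict[str, list[float]]:
    """Published read-level long-read repeat counts (patient 7, PacBio)."""
    with resources.as_file(_data_path("lr_reads_published.csv")) as p:
        return read_lr_reads(p)


def load_builtin_lr_summary() -> dict[str, float]:
    """Published long-read median repeat sizes per patient."""
    out = {}
    with resources.as_file(_data_path("lr_summary_published.csv")) as p:
        with open(p, newline="") as fh:
            for row in csv.DictReader(fh):
                out[row["patient_id"].strip()] = float(row["lr_median"])
    return out
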