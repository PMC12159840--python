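"""Data model and I/O for *ex vivo* biodistribution studies.

A biodistribution study samples groups of tumor-bearing animals at fixed times
after injection of a radiotracer, measures the activity concentration of each
harvested tissue in a gamma counter, and expresses it as percent injected dose
per gram (%ID/g).  This module holds the per-animal records, converts counter
readings to decay-corrected %ID/g, summarises cells of the design
(group x tissue x timepoint) as mean +/- SEM, and integrates the resulting
time-activity curves by the trapezoid rule.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .dosimetry import NuclideData

#: Tissues harvested in the orthotopic liver-metastasis study design.  The
#: vocabulary is open: unknown tissue labels are accepted with a warning so
#: that SPECT/autoradiography ROI tables can reuse the same reader.
KNOWN_TISSUES = frozenset(
    {
        "tumor",
        "blood",
        "heart",
        "lungs",
        "normal liver",
        "spleen",
        "stomach",
        "small intestine",
        "large intestine",
        "kidneys",
        "muscle",
        "bone",
        "ovaries",
        "uterus",
    }
)

#: Sampling times (hours post radiohapten injection) of the default design.
DEFAULT_TIMEPOINTS_H = (2.0, 24.0, 48.0, 120.0)

REQUIRED_COLUMNS = ("animal_id", "group", "tissue", "time_h", "pct_id_g")


@dataclass(frozen=True)
class BiodistRecord:
    """One tissue measurement from one animal at one timepoint."""

    animal_id: str
    group: str
    tissue: str
    time_h: float
    pct_id_g: float
    mass_g: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.pct_id_g) or self.pct_id_g < 0:
            raise ValidationError(
                f"pct_id_g must be finite and >= 0, got {self.pct_id_g!r} "
                f"(animal {self.animal_id}, tissue {self.tissue})"
            )
        if not math.isfinite(self.time_h) or self.time_h <= 0:
            raise ValidationError(
                f"time_h must be > 0, got {self.time_h!r} (animal {self.animal_id})"
            )
        if self.mass_g is not None and self.mass_g <= 0:
            raise ValidationError(
                f"mass_g must be > 0, got {self.mass_g!r} (animal {self.animal_id})"
            )


@dataclass
class BiodistDataset:
    """A collection of biodistribution records plus study-design metadata.

    ``decay_corrected`` states the convention of the stored %ID/g values:
    True means values are corrected back to injection time, so the stored
    kinetics are purely biological and physical decay must be applied
    analytically downstream (the package default).
    """

    records: list[BiodistRecord]
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    n_per_timepoint: int = 5
    injected_activity_MBq: float = 3.7
    decay_corrected: bool = True
    warnings_log: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "animal_id": r.animal_id,
                    "group": r.group,
                    "tissue": r.tissue,
                    "time_h": r.time_h,
                    "pct_id_g": r.pct_id_g,
                    "mass_g": r.mass_g,
                }
                for r in self.records
            ]
        )

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group)
        return list(seen)

    def tissues(self, group: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if group is None or r.group == group:
                seen.setdefault(r.tissue)
        return list(seen)


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SEM of one (tissue, timepoint) cell; sem is None for n = 1."""

    tissue: str
    time_h: float
    n: int
    mean_pct_id_g: float
    sem_pct_id_g: float | None


def read_biodist(
    path: str | Path | io.TextIOBase,
    *,
    sep: str = ",",
    timepoints_h: Sequence[float] | None = None,
    injected_activity_MBq: float = 3.7,
    decay_corrected: bool = True,
) -> BiodistDataset:
    """Read a delimited biodistribution table into a validated dataset.

    The file must carry the header columns ``animal_id, group, tissue,
    time_h, pct_id_g`` (``mass_g`` optional), decimal point '.', row order
    preserved.  Unknown tissues are kept and noted on the dataset's warning
    log; structural problems raise :class:`SchemaError`, bad values raise
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, sep=sep, dtype={"animal_id": str, "group": str, "tissue": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")

    records: list[BiodistRecord] = []
    warn_log: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        tissue = str(row.tissue).strip().lower()
        if tissue not in KNOWN_TISSUES:
            msg = f"row {i}: unknown tissue {tissue!r} passed through"
            warn_log.append(msg)
            warnings.warn(msg, stacklevel=2)
        try:
            records.append(
                BiodistRecord(
                    animal_id=str(row.animal_id),
                    group=str(row.group),
                    tissue=tissue,
                    time_h=float(row.time_h),
                    pct_id_g=float(row.pct_id_g),
                    mass_g=float(row.mass_g)
                    if "mass_g" in df.columns and not pd.isna(row.mass_g)
                    else None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc

    observed_times = tuple(sorted({r.time_h for r in records}))
    return BiodistDataset(
        records=records,
        timepoints_h=tuple(timepoints_h) if timepoints_h is not None else (observed_times or DEFAULT_TIMEPOINTS_H),
        injected_activity_MBq=injected_activity_MBq,
        decay_corrected=decay_corrected,
        warnings_log=warn_log,
    )


def write_biodist(dataset: BiodistDataset, path: str | Path, *, sep: str = ",") -> None:
    """Write a dataset back to the delimited schema consumed by read_biodist."""
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def decay_correct(measured_counts: float, elapsed_h: float, nuclide: "NuclideData") -> float:
    """Correct a count rate measured ``elapsed_h`` hours after injection back
    to injection time: counts x 2^(elapsed / T_half,phys)."""
    if elapsed_h < 0:
        raise ValidationError(f"elapsed_h must be >= 0, got {elapsed_h}")
    return measured_counts * 2.0 ** (elapsed_h / nuclide.t_half_phys_h)


def pct_id_per_gram(
    sample_counts: float, standard_counts_per_injection: float, mass_g: float
) -> float:
    """%ID/g = 100 x (sample counts / whole-injection standard counts) / mass.

    Both count rates must be on the same decay-correction convention.
    """
    if standard_counts_per_injection <= 0:
        raise ValidationError("standard_counts_per_injection must be > 0")
    if mass_g <= 0:
        raise ValidationError("mass_g must be > 0")
    return 100.0 * (sample_counts / standard_counts_per_injection) / mass_g


def summarize(dataset: BiodistDataset, group: str, tissue: str) -> list[GroupSummary]:
    """Per-timepoint mean and SEM of one (group, tissue) cell, ascending time.

    SEM = sd / sqrt(n) with the n-1 (sample) standard deviation; for n = 1 the
    SEM is reported absent (None), never as a spurious zero.
    """
    tissue = tissue.strip().lower()
    by_time: dict[float, list[float]] = {}
    for r in dataset.records:
        if r.group == group and r.tissue == tissue:
            by_time.setdefault(r.time_h, []).append(r.pct_id_g)
    if not by_time:
        raise InsufficientDataError(
            f"no records for group {group!r}, tissue {tissue!r}"
        )
    out: list[GroupSummary] = []
    for t in sorted(by_time):
        vals = np.asarray(by_time[t], dtype=float)
        n = vals.size
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else None
        out.append(GroupSummary(tissue=tissue, time_h=t, n=n, mean_pct_id_g=mean, sem_pct_id_g=sem))
    return out


def summaries_to_frame(summaries: Iterable[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tissue": s.tissue,
                "time_h": s.time_h,
                "n": s.n,
                "mean_pct_id_g": s.mean_pct_id_g,
                "sem_pct_id_g": s.sem_pct_id_g,
            }
            for s in summaries
        ]
    )


def auc_trapezoid(
    summary: Sequence[GroupSummary], t_start: float, t_end: float
) -> float:
    """Trapezoidal area under the mean %ID/g curve over observed timepoints
    within [t_start, t_end]; no extrapolation beyond the data (%ID*h/g)."""
    pts = sorted(
        ((s.time_h, s.mean_pct_id_g) for s in summary if t_start <= s.time_h <= t_end),
        key=lambda p: p[0],
    )
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need >= 2 timepoints in [{t_start}, {t_end}], got {len(pts)}"
        )
    t = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    return float(np.trapezoid(y, t))
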