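"""Raw-to-analysis preprocessing: normalization and median-centering.

Each registered numeric parameter carries a normalization class:

``BRAIN_VOLUME_NORM``
    divided by the scan's raw total brain volume (which includes the
    ventricular volume),
``BODY_WEIGHT_NORM``
    divided by body weight (allometric control),
``HEAD_ANGLE_NORM``
    divided by head angle in degrees (positioning control),
``NONE``
    carried through unchanged,
``EXCLUDE``
    dropped from the numeric matrix (head angle, muzzle length),
``CATEGORIZE``
    removed from the numeric matrix and handled as a categorical
    descriptor instead (ventricle height -> septal integrity).

After normalization every parameter column is median-centered so that no
single high-magnitude parameter dominates the scan-to-scan correlations.
The default centering divides by the per-parameter cohort median (median
maps to 1, equalizing magnitudes); subtracting the median is available as
an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional

import numpy as np

from .cohort import CohortTable, ScanRecord
from .errors import InvalidMeasurementError, NormalizationError

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationClass",
    "MorphometricMatrix",
    "DEFAULT_REGISTRY",
    "normalize_cohort",
    "median_center",
    "residual_brain_volume",
]


class NormalizationClass(str, Enum):
    BRAIN_VOLUME_NORM = "BRAIN_VOLUME_NORM"
    BODY_WEIGHT_NORM = "BODY_WEIGHT_NORM"
    HEAD_ANGLE_NORM = "HEAD_ANGLE_NORM"
    NONE = "NONE"
    EXCLUDE = "EXCLUDE"
    CATEGORIZE = "CATEGORIZE"


#: Default parameter registry. The normalized total brain volume is retained
#: in the matrix; head angle and muzzle length are excluded (muzzle length
#: only feeds the craniofacial ratio); ventricle height is categorized.
DEFAULT_REGISTRY: dict[str, NormalizationClass] = {
    "brain_length": NormalizationClass.BRAIN_VOLUME_NORM,
    "cerebellar_volume": NormalizationClass.BRAIN_VOLUME_NORM,
    "cerebellar_diameter": NormalizationClass.BRAIN_VOLUME_NORM,
    "interthalamic_adhesion_height": NormalizationClass.BRAIN_VOLUME_NORM,
    "corpus_callosum_thickness": NormalizationClass.BRAIN_VOLUME_NORM,
    "ventricular_volume": NormalizationClass.BRAIN_VOLUME_NORM,
    "cranial_length": NormalizationClass.BODY_WEIGHT_NORM,
    "brain_width": NormalizationClass.BODY_WEIGHT_NORM,
    "total_brain_volume": NormalizationClass.BODY_WEIGHT_NORM,
    "sulcus_depth": NormalizationClass.BODY_WEIGHT_NORM,
    "cerebellar_compression_length": NormalizationClass.HEAD_ANGLE_NORM,
    "cerebellar_compression_index": NormalizationClass.HEAD_ANGLE_NORM,
    "obex_position": NormalizationClass.HEAD_ANGLE_NORM,
    "corpus_callosum_angle": NormalizationClass.NONE,
    "head_angle": NormalizationClass.EXCLUDE,
    "muzzle_length": NormalizationClass.EXCLUDE,
    "ventricle_height": NormalizationClass.CATEGORIZE,
}


def resolve_registry(
    cohort: CohortTable,
    registry: Optional[Mapping[str, object]] = None,
) -> dict[str, NormalizationClass]:
    """Merge the default registry, cohort registry and an explicit override.

    Unregistered ventricle-prefixed numeric parameters default to
    brain-volume normalization; any other unregistered measurement column
    raises, so that silently un-normalized parameters cannot enter the
    matrix.
    """
    merged: dict[str, NormalizationClass] = dict(DEFAULT_REGISTRY)
    for source in (cohort.parameter_registry, registry or {}):
        for name, cls in source.items():
            merged[name] = NormalizationClass(cls)
    seen = {name for record in cohort.records for name in record.measurements}
    for name in sorted(seen - set(merged)):
        if name.startswith(("ventricular_", "ventricle_")):
            merged[name] = NormalizationClass.BRAIN_VOLUME_NORM
        else:
            raise NormalizationError(
                f"parameter {name!r} has no registered normalization class"
            )
    return merged


@dataclass
class MorphometricMatrix:
    """Scans x parameters numeric matrix with a processing-stage marker."""

    scan_ids: list[str]
    parameter_names: list[str]
    values: np.ndarray  # shape (n_scans, n_parameters)
    stage: str  # raw / normalized / centered
    centering: Optional[str] = None  # ratio / difference (stage == centered)
    dropped_scans: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.scan_ids), len(self.parameter_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.scan_ids)} scans x {len(self.parameter_names)} parameters"
            )

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.parameter_names.index(name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=self.scan_ids, columns=self.parameter_names
        )

    def to_tsv(self, path) -> None:
        """Write as TSV with a stage marker in a leading comment line."""
        with open(path, "w") as fh:
            marker = f"# stage={self.stage}"
            if self.centering:
                marker += f" centering={self.centering}"
            fh.write(marker + "\n")
            fh.write("scan_id\t" + "\t".join(self.parameter_names) + "\n")
            for sid, row in zip(self.scan_ids, self.values):
                fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "MorphometricMatrix":
        with open(path) as fh:
            first = fh.readline().strip()
            stage, centering = "raw", None
            if first.startswith("#"):
                for token in first.lstrip("# ").split():
                    key, _, val = token.partition("=")
                    if key == "stage":
                        stage = val
                    elif key == "centering":
                        centering = val
                header = fh.readline()
            else:
                header = first
            names = header.strip().split("\t")[1:]
            scan_ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                scan_ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        values = np.array(rows, dtype=float) if rows else np.empty((0, len(names)))
        return cls(scan_ids, names, values, stage=stage, centering=centering)


def _normalizer(scan: ScanRecord, cls: NormalizationClass) -> Optional[float]:
    if cls is NormalizationClass.BRAIN_VOLUME_NORM:
        return scan.measurement("total_brain_volume")
    if cls is NormalizationClass.BODY_WEIGHT_NORM:
        return scan.body_weight
    if cls is NormalizationClass.HEAD_ANGLE_NORM:
        return scan.measurement("head_angle")
    return None


def normalize_cohort(
    cohort: CohortTable,
    registry: Optional[Mapping[str, object]] = None,
) -> MorphometricMatrix:
    """Build the normalized scans x parameters matrix from raw measurements.

    Scans missing any retained parameter (or a required denominator) are
    dropped with a warning rather than correlated pairwise-complete; the
    drop reasons are recorded on the returned matrix.
    """
    reg = resolve_registry(cohort, registry)
    retained = [
        name
        for name, cls in sorted(reg.items())
        if cls
        not in (NormalizationClass.EXCLUDE, NormalizationClass.CATEGORIZE)
    ]
    scan_ids: list[str] = []
    rows: list[list[float]] = []
    dropped: dict[str, str] = {}
    bad_denominators: list[str] = []
    for scan in cohort.records:
        row: list[float] = []
        reason = None
        for name in retained:
            value = scan.measurement(name)
            if value is None:
                reason = f"missing parameter {name!r}"
                break
            cls = reg[name]
            denom = _normalizer(scan, cls)
            if cls in (
                NormalizationClass.BRAIN_VOLUME_NORM,
                NormalizationClass.BODY_WEIGHT_NORM,
                NormalizationClass.HEAD_ANGLE_NORM,
            ):
                if denom is None:
                    reason = f"missing denominator for {name!r} ({cls.value})"
                    break
                if denom <= 0:
                    bad_denominators.append(
                        f"scan {scan.scan_id!r}: non-positive denominator "
                        f"{denom} for {name!r} ({cls.value})"
                    )
                    reason = "non-positive denominator"
                    break
                row.append(value / denom)
            else:
                row.append(value)
        if reason is None:
            scan_ids.append(scan.scan_id)
            rows.append(row)
        elif reason != "non-positive denominator":
            dropped[scan.scan_id] = reason
            logger.warning("dropping scan %s: %s", scan.scan_id, reason)
    if bad_denominators:
        raise NormalizationError("; ".join(bad_denominators))
    if dropped:
        warnings.warn(
            f"{len(dropped)} scan(s) dropped from the matrix: "
            + ", ".join(sorted(dropped)),
            stacklevel=2,
        )
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(retained)))
    return MorphometricMatrix(
        scan_ids, retained, values, stage="normalized", dropped_scans=dropped
    )


def median_center(matrix: MorphometricMatrix, mode: str = "ratio") -> MorphometricMatrix:
    """Center each parameter column on its cohort median.

    ``ratio`` (default) divides by the median so every column's median
    becomes 1; ``difference`` subtracts the median so it becomes 0.
    Re-centering an already centered matrix is permitted (and, by
    construction, a no-op up to the median statistic).
    """
    if matrix.stage not in ("normalized", "centered"):
        raise NormalizationError(
            f"median_center expects a normalized matrix, got stage={matrix.stage!r}"
        )
    if mode not in ("ratio", "difference"):
        raise ValueError(f"unknown centering mode {mode!r}")
    medians = np.median(matrix.values, axis=0) if len(matrix.scan_ids) else np.array([])
    if mode == "ratio":
        zero = [
            name
            for name, med in zip(matrix.parameter_names, medians)
            if med == 0
        ]
        if zero:
            raise NormalizationError(
                f"zero median in ratio centering for parameter(s): {zero}"
            )
        values = matrix.values / medians
    else:
        values = matrix.values - medians
    return replace(
        matrix,
        values=values,
        stage="centered",
        centering=mode,
        dropped_scans=dict(matrix.dropped_scans),
    )


def residual_brain_volume(
    total_brain_volume: float, ventricular_volume: float, body_weight: float
) -> float:
    """Brain tissue volume (total minus ventricles) per kilogram body weight."""
    if ventricular_volume < 0 or total_brain_volume < 0:
        raise InvalidMeasurementError("volumes must be non-negative")
    if ventricular_volume > total_brain_volume:
        raise InvalidMeasurementError(
            f"ventricular volume {ventricular_volume} exceeds total brain "
            f"volume {total_brain_volume}"
        )
    if not (body_weight > 0):
        raise InvalidMeasurementError(f"body weight must be > 0, got {body_weight}")
    return (total_brain_volume - ventricular_volume) / body_weight
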