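"""Domain types for scan cohorts and the categorization rules applied to them.

A cohort is a flat table of MRI scans (one row per scan, several scans may
share a patient). Raw measurements are held in physical units; this module
owns the rules that turn measurements and metadata into the categorical
descriptors consumed by the enrichment stage:

* craniofacial ratio (CFR) and the three craniofacial categories,
* age categories (five half-open bins),
* septal-integrity categories from measured ventricle height.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import CohortValidationError, InvalidMeasurementError

__all__ = [
    "ScanRecord",
    "CraniofacialCategory",
    "CohortTable",
    "compute_cfr",
    "assign_craniofacial_from_cfr",
    "resolve_craniofacial",
    "assign_age_category",
    "assign_septal_integrity",
    "AGE_LABELS",
    "SEPTAL_LABELS",
    "CRANIOFACIAL_LABELS",
]

CRANIOFACIAL_LABELS = ("brachycephalic", "mesocephalic", "dolichocephalic")
AGE_LABELS = ("Immature", "Young adult", "Middle-aged", "Mature", "Geriatric")
SEPTAL_LABELS = ("intact", "minor", "moderate", "severe", "absent")

#: metadata columns recognized in cohort TSV/CSV files; everything else is a
#: measurement column.
METADATA_COLUMNS = (
    "scan_id",
    "patient_id",
    "body_weight",
    "age",
    "sex",
    "neutered",
    "breed",
    "breed_group",
    "clade",
    "diagnostic_class",
    "purebred",
    "craniofacial_override",
)


@dataclass
class ScanRecord:
    """One MRI scan: raw measurements plus clinical metadata."""

    scan_id: str
    patient_id: str
    measurements: dict[str, float]
    body_weight: float
    age: float
    sex: str
    neutered: bool
    breed: str
    breed_group: str
    diagnostic_class: str
    purebred: bool
    clade: Optional[str] = None
    craniofacial_override: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.body_weight > 0):
            raise CohortValidationError(
                f"scan {self.scan_id!r}: body_weight must be > 0, got {self.body_weight}"
            )
        if not (self.age > 0):
            raise CohortValidationError(
                f"scan {self.scan_id!r}: age must be > 0, got {self.age}"
            )
        if self.sex not in ("female", "male"):
            raise CohortValidationError(
                f"scan {self.scan_id!r}: sex must be 'female' or 'male', got {self.sex!r}"
            )

    def measurement(self, name: str) -> Optional[float]:
        """Return a measurement value, or None when missing/NaN."""
        value = self.measurements.get(name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return value

    @property
    def sex_neuter(self) -> str:
        """Combined sex/neuter label: FE, FN, ME or MN."""
        first = "F" if self.sex == "female" else "M"
        second = "N" if self.neutered else "E"
        return first + second


@dataclass(frozen=True)
class CraniofacialCategory:
    """Craniofacial class with the provenance of the assignment."""

    value: Optional[str]  # brachycephalic / mesocephalic / dolichocephalic / None
    provenance: str  # individual_cfr / breed_average_cfr / metadata / unassigned

    def __post_init__(self) -> None:
        if self.value is not None and self.value not in CRANIOFACIAL_LABELS:
            raise CohortValidationError(f"unknown craniofacial label {self.value!r}")
        if self.provenance not in (
            "individual_cfr",
            "breed_average_cfr",
            "metadata",
            "unassigned",
        ):
            raise CohortValidationError(f"unknown provenance {self.provenance!r}")


def compute_cfr(muzzle_length: float, cranial_length: float) -> float:
    """Craniofacial ratio: muzzle length divided by cranial length (both mm)."""
    if not (muzzle_length > 0) or not (cranial_length > 0):
        raise InvalidMeasurementError(
            f"CFR requires positive lengths, got muzzle={muzzle_length}, "
            f"cranial={cranial_length}"
        )
    return muzzle_length / cranial_length


def assign_craniofacial_from_cfr(cfr: float) -> str:
    """Map a CFR to a craniofacial category.

    Cut-offs: <=0.52 brachycephalic, (0.52, 0.67) mesocephalic,
    >=0.67 dolichocephalic.
    """
    if not (cfr > 0):
        raise InvalidMeasurementError(f"CFR must be > 0, got {cfr}")
    if cfr <= 0.52:
        return "brachycephalic"
    if cfr < 0.67:
        return "mesocephalic"
    return "dolichocephalic"


def assign_age_category(age: float) -> str:
    """Five half-open age bins (years): [eps,2) [2,4) [4,8) [8,10) [10,inf)."""
    if not (age > 0):
        raise InvalidMeasurementError(f"age must be > 0, got {age}")
    if age < 2:
        return "Immature"
    if age < 4:
        return "Young adult"
    if age < 8:
        return "Middle-aged"
    if age < 10:
        return "Mature"
    return "Geriatric"


def assign_septal_integrity(ventricle_height: float) -> str:
    """Bin measured ventricle height (mm) into septal-integrity categories.

    0 is 'intact'; boundaries at exactly 3, 6 and 10 mm go to the more severe
    category: minor=(0,3), moderate=[3,6), severe=[6,10), absent=[10,inf).
    """
    if ventricle_height < 0:
        raise InvalidMeasurementError(
            f"ventricle height must be >= 0, got {ventricle_height}"
        )
    if ventricle_height == 0:
        return "intact"
    if ventricle_height < 3:
        return "minor"
    if ventricle_height < 6:
        return "moderate"
    if ventricle_height < 10:
        return "severe"
    return "absent"


@dataclass
class CohortTable:
    """A list of scan records plus the registry of numeric parameters.

    The registry maps parameter name -> normalization class name (see
    :mod:`morphnet.preprocess`); it defines which measurement columns enter
    the numeric matrix and how each is scaled.
    """

    records: list[ScanRecord]
    parameter_registry: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.scan_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate scan_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, scan_id: str) -> ScanRecord:
        for r in self.records:
            if r.scan_id == scan_id:
                return r
        raise KeyError(scan_id)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(
        cls,
        path,
        parameter_registry: Optional[Mapping[str, str]] = None,
        delimiter: str = "\t",
    ) -> "CohortTable":
        """Read a cohort table from delimited text (one row per scan).

        Metadata columns are recognized by name; all remaining columns are
        treated as numeric measurements. Empty fields are missing values.
        """
        records: list[ScanRecord] = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delimiter)
            if reader.fieldnames is None:
                raise CohortValidationError(f"{path}: empty file")
            missing = {"scan_id", "body_weight", "age", "sex"} - set(reader.fieldnames)
            if missing:
                raise CohortValidationError(f"{path}: missing columns {sorted(missing)}")
            meas_cols = [c for c in reader.fieldnames if c not in METADATA_COLUMNS]
            for row in reader:
                measurements = {}
                for col in meas_cols:
                    raw = (row.get(col) or "").strip()
                    if raw:
                        measurements[col] = float(raw)
                records.append(
                    ScanRecord(
                        scan_id=row["scan_id"],
                        patient_id=row.get("patient_id") or row["scan_id"],
                        measurements=measurements,
                        body_weight=float(row["body_weight"]),
                        age=float(row["age"]),
                        sex=row["sex"].strip().lower(),
                        neutered=_parse_bool(row.get("neutered", "")),
                        breed=row.get("breed") or "Unknown",
                        breed_group=row.get("breed_group") or "Unknown",
                        diagnostic_class=row.get("diagnostic_class") or "unknown",
                        purebred=_parse_bool(row.get("purebred", "")),
                        clade=(row.get("clade") or None),
                        craniofacial_override=(row.get("craniofacial_override") or None),
                    )
                )
        registry = dict(parameter_registry) if parameter_registry else {}
        return cls(records=records, parameter_registry=registry)

    def to_tsv(self, path, delimiter: str = "\t") -> None:
        meas_cols = sorted({m for r in self.records for m in r.measurements})
        header = list(METADATA_COLUMNS) + meas_cols
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
            writer.writerow(header)
            for r in self.records:
                row = [
                    r.scan_id,
                    r.patient_id,
                    repr(r.body_weight),
                    repr(r.age),
                    r.sex,
                    str(r.neutered),
                    r.breed,
                    r.breed_group,
                    r.clade or "",
                    r.diagnostic_class,
                    str(r.purebred),
                    r.craniofacial_override or "",
                ]
                for col in meas_cols:
                    v = r.measurements.get(col)
                    row.append("" if v is None else repr(v))
                writer.writerow(row)


def _parse_bool(raw: str) -> bool:
    return str(raw).strip().lower() in ("1", "true", "t", "yes", "y")


def _scan_cfr(scan: ScanRecord) -> Optional[float]:
    muzzle = scan.measurement("muzzle_length")
    cranial = scan.measurement("cranial_length")
    if muzzle is None or cranial is None:
        return None
    return compute_cfr(muzzle, cranial)


def resolve_craniofacial(scan: ScanRecord, cohort: CohortTable) -> CraniofacialCategory:
    """Assign the craniofacial category of one scan within its cohort.

    Precedence: (i) the scan's own CFR when muzzle length is measurable;
    (ii) the mean CFR of the scan's breed within the cohort, for purebred
    dogs with more than two breed-mates carrying measurable CFRs;
    (iii) an externally supplied metadata label; otherwise unassigned.
    """
    cfr = _scan_cfr(scan)
    if cfr is not None:
        return CraniofacialCategory(assign_craniofacial_from_cfr(cfr), "individual_cfr")
    if scan.purebred:
        breed_cfrs = [
            c
            for r in cohort.records
            if r.breed == scan.breed and (c := _scan_cfr(r)) is not None
        ]
        if len(breed_cfrs) > 2:
            mean_cfr = sum(breed_cfrs) / len(breed_cfrs)
            return CraniofacialCategory(
                assign_craniofacial_from_cfr(mean_cfr), "breed_average_cfr"
            )
    if scan.craniofacial_override:
        override = scan.craniofacial_override.strip().lower()
        if override not in CRANIOFACIAL_LABELS:
            raise CohortValidationError(
                f"scan {scan.scan_id!r}: unknown craniofacial override {override!r}"
            )
        return CraniofacialCategory(override, "metadata")
    return CraniofacialCategory(None, "unassigned")


def build_annotations(cohort: CohortTable) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate the categorical descriptors of every scan in a cohort.

    Returns a DataFrame indexed by scan_id with one column per descriptor
    category (breed, breed_group, craniofacial, age_category, sex_neuter,
    septal_integrity, diagnostic_class, clade). Missing annotations are NaN
    and are excluded from that category's enrichment tests downstream.
    """
    import pandas as pd

    rows = {}
    for scan in cohort.records:
        cf = resolve_craniofacial(scan, cohort)
        vh = scan.measurement("ventricle_height")
        rows[scan.scan_id] = {
            "breed": scan.breed,
            "breed_group": scan.breed_group,
            "craniofacial": cf.value,
            "age_category": assign_age_category(scan.age),
            "sex_neuter": scan.sex_neuter,
            "septal_integrity": None if vh is None else assign_septal_integrity(vh),
            "diagnostic_class": scan.diagnostic_class,
            "clade": scan.clade,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "scan_id"
    return frame
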