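"""Faecal-sample records, delimited-table I/O and sample-level QC filters.

A faecal record carries the identity of one scat (sample id, study area,
collection year), optional projected coordinates, the percentage of
inorganic matter (IOM) determined by ashing, the two hormone metabolite
concentrations (faecal glucocorticoid metabolites, fGCM, and faecal
triiodothyronine metabolites, fT3M; both ng/g dry faeces) and the set of
prey species identified from undigested remains.  High-IOM samples dilute
hormone measures and are excluded from physiology analyses; samples whose
prey remains could not be identified are excluded from diet analyses.
The two exclusions are independent, so the diet and hormone sample sets
differ.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

__all__ = [
    "AREAS",
    "FaecalSample",
    "PreyReference",
    "StudyGroup",
    "SampleValidationError",
    "read_samples",
    "write_samples",
    "read_prey_reference",
    "write_prey_reference",
    "filter_iom",
    "filter_prey_identified",
    "group_samples",
]

AREAS = ("East", "West")

#: default column layout of the sample CSV
DEFAULT_SCHEMA = {
    "sample_id": "sample_id",
    "area": "area",
    "year": "year",
    "x": "x",
    "y": "y",
    "iom_pct": "iom_pct",
    "fgcm": "fgcm",
    "ft3m": "ft3m",
    "prey": "prey",
}

#: separator for multi-prey cells (a minority of scats contain two prey)
PREY_SEP = ";"


class SampleValidationError(ValueError):
    """Raised when a sample table or record violates the domain contract.

    ``errors`` holds one human-readable message per offending row/field.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class FaecalSample:
    """One scat record: identity, group, QC fields, prey and hormone values."""

    sample_id: str
    area: str
    year: int
    x: float | None = None
    y: float | None = None
    iom_pct: float | None = None
    fgcm: float | None = None
    ft3m: float | None = None
    prey: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        errs = []
        if self.area not in AREAS:
            errs.append(f"sample {self.sample_id}: area {self.area!r} not in {AREAS}")
        if self.iom_pct is not None and not (0.0 <= self.iom_pct <= 100.0):
            errs.append(
                f"sample {self.sample_id}: iom_pct {self.iom_pct} outside [0, 100]"
            )
        for name in ("fgcm", "ft3m"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                errs.append(f"sample {self.sample_id}: {name} {v} not > 0")
        if errs:
            raise SampleValidationError(errs)
        object.__setattr__(self, "prey", frozenset(self.prey))

    @property
    def group_key(self) -> tuple[str, int]:
        return (self.area, self.year)


@dataclass(frozen=True)
class PreyReference:
    """Prey species table: mean body weight (kg) and body-size class.

    The mean body weight is the X of the digestibility correction
    Y = 1.980 + 0.035 X (kg of prey consumed per collectable faeces).
    """

    weights_kg: dict[str, float]
    size_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        from .diet import classify_prey_size

        for sp, w in self.weights_kg.items():
            if not w > 0:
                raise SampleValidationError(
                    f"prey {sp!r}: mean body weight {w} must be positive"
                )
        derived = {sp: classify_prey_size(w) for sp, w in self.weights_kg.items()}
        if self.size_classes:
            for sp, cls in self.size_classes.items():
                if sp in derived and cls != derived[sp]:
                    raise SampleValidationError(
                        f"prey {sp!r}: declared size class {cls!r} "
                        f"inconsistent with weight rule ({derived[sp]!r})"
                    )
        object.__setattr__(self, "size_classes", derived)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.weights_kg)

    def weight(self, species: str) -> float:
        try:
            return self.weights_kg[species]
        except KeyError:
            raise SampleValidationError(f"species {species!r} missing from prey reference")

    def size_class(self, species: str) -> str:
        if species not in self.size_classes:
            raise SampleValidationError(f"species {species!r} missing from prey reference")
        return self.size_classes[species]


@dataclass(frozen=True)
class StudyGroup:
    """All samples from one (area, year) cell of the study design."""

    label: str
    area: str
    year: int
    samples: tuple[FaecalSample, ...]

    def __post_init__(self):
        bad = [s.sample_id for s in self.samples if s.group_key != (self.area, self.year)]
        if bad:
            raise SampleValidationError(
                f"group {self.label}: samples {bad} do not belong to "
                f"({self.area}, {self.year})"
            )
        object.__setattr__(self, "samples", tuple(self.samples))

    def __len__(self) -> int:
        return len(self.samples)


def group_label(area: str, year: int) -> str:
    """Canonical group label, e.g. ('East', 2015) -> 'ERTR_2015'."""
    prefix = {"East": "ERTR", "West": "WRTR"}[area]
    return f"{prefix}_{year}"


# ---------------------------------------------------------------------------
# delimited-table readers / writers


def _parse_float(cell, row_no, col, errs, lo=None, hi=None, positive=False):
    cell = (cell or "").strip()
    if cell == "":
        return None
    try:
        v = float(cell)
    except ValueError:
        errs.append(f"row {row_no}: column {col!r}: unparseable numeric {cell!r}")
        return None
    if lo is not None and not (lo <= v <= hi):
        errs.append(f"row {row_no}: column {col!r}: value {v} outside [{lo}, {hi}]")
        return None
    if positive and not v > 0:
        errs.append(f"row {row_no}: column {col!r}: value {v} not > 0")
        return None
    return v


def read_samples(path, schema=None, skip_bad_rows: bool = False) -> list[FaecalSample]:
    """Read faecal samples from a CSV table.

    ``schema`` maps canonical field names to column headers (defaults to the
    canonical headers).  Blank prey cells yield empty prey sets.  Malformed
    rows are collected into a single :class:`SampleValidationError` naming
    each offending row, unless ``skip_bad_rows`` is set, in which case the
    offending rows are dropped.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    samples: list[FaecalSample] = []
    errs: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canon in ("sample_id", "area", "year"):
            if schema[canon] not in header:
                raise SampleValidationError(
                    f"mandatory column {schema[canon]!r} missing from {path}"
                )
        for row_no, row in enumerate(reader, start=2):
            row_errs: list[str] = []
            sid = (row.get(schema["sample_id"]) or "").strip()
            area = (row.get(schema["area"]) or "").strip()
            year_cell = (row.get(schema["year"]) or "").strip()
            try:
                year = int(year_cell)
            except ValueError:
                row_errs.append(f"row {row_no}: unparseable year {year_cell!r}")
                year = -1
            x = _parse_float(row.get(schema["x"]), row_no, "x", row_errs)
            y = _parse_float(row.get(schema["y"]), row_no, "y", row_errs)
            iom = _parse_float(
                row.get(schema["iom_pct"]), row_no, "iom_pct", row_errs, lo=0.0, hi=100.0
            )
            fgcm = _parse_float(row.get(schema["fgcm"]), row_no, "fgcm", row_errs, positive=True)
            ft3m = _parse_float(row.get(schema["ft3m"]), row_no, "ft3m", row_errs, positive=True)
            prey_cell = (row.get(schema["prey"]) or "").strip()
            prey = frozenset(p.strip() for p in prey_cell.split(PREY_SEP) if p.strip())
            if not row_errs:
                try:
                    samples.append(
                        FaecalSample(sid, area, year, x, y, iom, fgcm, ft3m, prey)
                    )
                except SampleValidationError as e:
                    row_errs.extend(f"row {row_no}: {m}" for m in e.errors)
            errs.extend(row_errs)
    if errs and not skip_bad_rows:
        raise SampleValidationError(errs)
    return samples


def write_samples(samples, path) -> None:
    """Write samples to CSV in the canonical column layout (round-trips)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(DEFAULT_SCHEMA))
        for s in samples:
            w.writerow(
                [
                    s.sample_id,
                    s.area,
                    s.year,
                    "" if s.x is None else repr(s.x),
                    "" if s.y is None else repr(s.y),
                    "" if s.iom_pct is None else repr(s.iom_pct),
                    "" if s.fgcm is None else repr(s.fgcm),
                    "" if s.ft3m is None else repr(s.ft3m),
                    PREY_SEP.join(sorted(s.prey)),
                ]
            )


def read_prey_reference(path) -> PreyReference:
    """Read a prey reference CSV with columns species, mean_body_weight_kg."""
    weights: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "species" not in reader.fieldnames:
            raise SampleValidationError(f"column 'species' missing from {path}")
        if "mean_body_weight_kg" not in reader.fieldnames:
            raise SampleValidationError(f"column 'mean_body_weight_kg' missing from {path}")
        for row_no, row in enumerate(reader, start=2):
            sp = row["species"].strip()
            if sp in weights:
                raise SampleValidationError(f"row {row_no}: duplicate species {sp!r}")
            weights[sp] = float(row["mean_body_weight_kg"])
    return PreyReference(weights)


def write_prey_reference(ref: PreyReference, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "mean_body_weight_kg", "size_class"])
        for sp in sorted(ref.weights_kg):
            w.writerow([sp, repr(ref.weights_kg[sp]), ref.size_classes[sp]])


# ---------------------------------------------------------------------------
# QC filters


def filter_iom(samples, threshold_pct: float = 80.0):
    """Partition samples by inorganic-matter content for hormone analyses.

    Samples with ``iom_pct`` strictly below the threshold are kept; samples
    at or above it, or with no IOM measurement, are discarded (missing IOM
    means the sample was never ashed, so it cannot enter hormone analyses).
    Returns ``(kept, discarded)``; the partition is exhaustive and disjoint.
    """
    if not (0.0 < threshold_pct <= 100.0):
        raise SampleValidationError(f"IOM threshold {threshold_pct} outside (0, 100]")
    kept, discarded = [], []
    for s in samples:
        if s.iom_pct is not None and s.iom_pct < threshold_pct:
            kept.append(s)
        else:
            discarded.append(s)
    return kept, discarded


def filter_prey_identified(samples):
    """Partition samples into (prey identified, unidentified).

    A sample with an empty prey set had remains too damaged to identify and
    is excluded from diet analyses.
    """
    identified = [s for s in samples if s.prey]
    unidentified = [s for s in samples if not s.prey]
    return identified, unidentified


def group_samples(samples, design) -> list[StudyGroup]:
    """Assign each sample to its (area, year) study group.

    ``design`` is an ordered list of (area, year) pairs; a sample whose
    (area, year) falls outside the design is an error listing the offenders.
    """
    design = list(design)
    if len(set(design)) != len(design):
        raise SampleValidationError("design contains duplicate (area, year) cells")
    cells = {tuple(c): [] for c in design}
    offenders = []
    for s in samples:
        if s.group_key in cells:
            cells[s.group_key].append(s)
        else:
            offenders.append(f"sample {s.sample_id}: ({s.area}, {s.year}) not in design")
    if offenders:
        raise SampleValidationError(offenders)
    return [
        StudyGroup(group_label(area, year), area, year, tuple(cells[(area, year)]))
        for (area, year) in design
    ]
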