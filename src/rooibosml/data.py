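"""Data model for labeled multi-assay rooibos samples and CSV I/O.

Each sample is one plant specimen measured with three assays (TPC, TEAC,
FRAP) in two extraction solvents (water, methanol), giving six numeric
features, plus a binary fermentation label: FR (fermented) or UFR
(unfermented, "green").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

#: The two fermentation classes. Exact, case-sensitive strings.
FR: str = "FR"
UFR: str = "UFR"
LABELS: tuple[str, str] = (FR, UFR)

#: Canonical assay order used everywhere a feature vector is assembled.
ASSAYS: tuple[str, str, str] = ("TPC", "TEAC", "FRAP")
SOLVENTS: tuple[str, str] = ("water", "methanol")

#: Fixed CSV schema (wide layout: one row per sample).
FEATURE_COLUMNS: tuple[str, ...] = (
    "tpc_water",
    "teac_water",
    "frap_water",
    "tpc_meoh",
    "teac_meoh",
    "frap_meoh",
)
CSV_COLUMNS: tuple[str, ...] = ("sample_id", "label") + FEATURE_COLUMNS

_SOLVENT_SUFFIX = {"water": "_water", "methanol": "_meoh"}


def measurement_column(assay: str, solvent: str) -> str:
    """Map an (assay, solvent) pair to its CSV column name."""
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    if solvent not in SOLVENTS:
        raise ValueError(f"unknown solvent {solvent!r}; expected one of {SOLVENTS}")
    return assay.lower() + _SOLVENT_SUFFIX[solvent]


class SchemaError(ValueError):
    """CSV file does not match the expected column schema."""


@dataclass(frozen=True)
class SampleMeasurements:
    """One plant sample: label plus six assay values.

    Units: TPC in mg gallic-acid equivalents per g, TEAC in µmol Trolox
    equivalents per g, FRAP in µmol ascorbic-acid equivalents per g; units
    are carried as opaque labels, never converted.
    """

    sample_id: str
    label: Literal["FR", "UFR"]
    tpc_water: float
    teac_water: float
    frap_water: float
    tpc_meoh: float
    teac_meoh: float
    frap_meoh: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(
                f"sample {self.sample_id!r}: label {self.label!r} not in {set(LABELS)}"
            )
        for col in FEATURE_COLUMNS:
            v = getattr(self, col)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"sample {self.sample_id!r}: {col} is not finite")
            if v < 0:
                raise ValueError(f"sample {self.sample_id!r}: {col} is negative ({v})")

    def values(self) -> np.ndarray:
        """Six measurements in canonical column order."""
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS], dtype=float)


@dataclass(frozen=True)
class AssayDataset:
    """Ordered collection of samples plus free-text provenance."""

    samples: tuple[SampleMeasurements, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=object)

    def label_counts(self) -> dict[str, int]:
        lab = [s.label for s in self.samples]
        return {l: lab.count(l) for l in LABELS}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s.sample_id, "label": s.label}
            | {c: getattr(s, c) for c in FEATURE_COLUMNS}
            for s in self.samples
        ]
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    def column(self, assay: str, solvent: str) -> np.ndarray:
        col = measurement_column(assay, solvent)
        return np.array([getattr(s, col) for s in self.samples], dtype=float)

    def subset(self, indices: Sequence[int], provenance: str | None = None) -> "AssayDataset":
        return AssayDataset(
            tuple(self.samples[i] for i in indices),
            provenance if provenance is not None else self.provenance,
        )


@dataclass(frozen=True)
class FeatureSetSpec:
    """One of the 21 classifier configurations.

    ``assays`` is a non-empty subset of {TPC, TEAC, FRAP}; ``solvent_scope``
    selects the water block, the methanol block, or both concatenated
    (water block first). Feature dimensionality is ``|assays|`` for a single
    solvent and ``2·|assays|`` for both.
    """

    assays: tuple[str, ...]
    solvent_scope: Literal["water", "methanol", "both"]

    def __post_init__(self) -> None:
        if not self.assays:
            raise ValueError("assays must be a non-empty subset of {TPC, TEAC, FRAP}")
        bad = [a for a in self.assays if a not in ASSAYS]
        if bad:
            raise ValueError(f"unknown assay(s) {bad}; expected subset of {ASSAYS}")
        if len(set(self.assays)) != len(self.assays):
            raise ValueError("assays contains duplicates")
        # normalise to canonical TPC, TEAC, FRAP order
        object.__setattr__(
            self, "assays", tuple(a for a in ASSAYS if a in self.assays)
        )
        if self.solvent_scope not in ("water", "methanol", "both"):
            raise ValueError(
                f"solvent_scope {self.solvent_scope!r} not in {{water, methanol, both}}"
            )

    @property
    def n_features(self) -> int:
        return len(self.assays) * (2 if self.solvent_scope == "both" else 1)

    def columns(self) -> tuple[str, ...]:
        """Feature column names: assays in canonical order, water before methanol."""
        if self.solvent_scope == "both":
            solvents: tuple[str, ...] = SOLVENTS
        else:
            solvents = (self.solvent_scope,)
        return tuple(
            measurement_column(a, sv) for sv in solvents for a in self.assays
        )

    def describe(self) -> str:
        return "+".join(self.assays) + "/" + self.solvent_scope


def enumerate_feature_sets() -> list[FeatureSetSpec]:
    """All 21 configurations: 7 non-empty assay subsets × 3 solvent scopes."""
    subsets = [
        combo
        for r in (1, 2, 3)
        for combo in combinations(ASSAYS, r)
    ]
    return [
        FeatureSetSpec(assays=sub, solvent_scope=scope)
        for scope in ("water", "methanol", "both")
        for sub in subsets
    ]


def extract_features(
    dataset: AssayDataset, spec: FeatureSetSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (rows follow dataset order) and per-row label array."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    cols = spec.columns()
    X = np.array(
        [[getattr(s, c) for c in cols] for s in dataset.samples], dtype=float
    )
    return X, dataset.labels()


def read_dataset(path: str | Path) -> AssayDataset:
    """Read a dataset from the wide CSV schema, preserving row order.

    Raises :class:`SchemaError` for missing/extra columns and ``ValueError``
    (naming the row) for non-numeric, negative, or unknown-label entries.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"sample_id": str, "label": str})
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    extra = [c for c in frame.columns if c not in CSV_COLUMNS]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")

    samples = []
    for idx, row in frame.iterrows():
        if row["label"] not in LABELS:
            raise ValueError(
                f"{path}: row {idx}: label {row['label']!r} not in {set(LABELS)}"
            )
        vals = {}
        for col in FEATURE_COLUMNS:
            try:
                v = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: row {idx}: non-numeric value in column {col!r}"
                ) from exc
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"{path}: row {idx}: column {col!r} must be finite and "
                    f"non-negative, got {row[col]!r}"
                )
            vals[col] = v
        samples.append(
            SampleMeasurements(sample_id=str(row["sample_id"]), label=row["label"], **vals)
        )
    return AssayDataset(tuple(samples), provenance=str(path))


def write_dataset(dataset: AssayDataset, path: str | Path) -> Path:
    """Write the dataset to CSV (UTF-8, ≥ 10 significant digits on floats)."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False, float_format="%.10g")
    return path
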