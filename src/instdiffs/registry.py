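"""Data model and I/O for school-level aggregate measures.

The unit of analysis throughout the package is the *institution* (a UK
medical school in the motivating study): each row of a
:class:`SchoolMeasureMatrix` is one school and each column one aggregate
measure (e.g. mean entry grades, hours of GP teaching, mean mark at a
postgraduate examination).  Measures belong to one of ten substantive
groups which are arranged in an approximate causal order -- institutional
history comes first, fitness-to-practise outcomes last -- and every
downstream stage (imputation, screening, path modelling) consumes that
ordering through the :class:`MeasureDefinition` registry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEASURE_GROUPS",
    "MeasureDefinition",
    "SchoolMeasureMatrix",
    "OccasionPanel",
    "load_registry",
    "study_registry",
    "causal_order",
    "load_matrix",
    "save_matrix",
    "subset_units",
]

#: The ten substantive measure groups, in causal order.
MEASURE_GROUPS: tuple[str, ...] = (
    "institutional history",
    "curricular influences",
    "selection",
    "teaching/learning/assessment",
    "student satisfaction",
    "Foundation entry scores",
    "F1 perceptions",
    "specialty training choice",
    "postgraduate examination performance",
    "fitness to practise",
)


@dataclass(frozen=True)
class MeasureDefinition:
    """One aggregate measure and its place in the causal ordering.

    Parameters
    ----------
    name
        Identifier used as the matrix column name.
    group
        One of :data:`MEASURE_GROUPS`.
    causal_rank
        Integer encoding group order x 100 + within-group position.
        Edges in the path model may only run from lower to higher rank.
    reliability
        Between-unit Cronbach alpha across occasions of measurement,
        in [0, 1], or ``None`` when no multi-occasion panel exists.
    higher_is_better
        Optional annotation; never used in computation.
    in_path_model
        Whether the measure belongs to the reduced set used for the
        causal path model (the study retains 29 of its 50 measures).
    """

    name: str
    group: str
    causal_rank: int
    reliability: float | None = None
    higher_is_better: bool | None = None
    in_path_model: bool = True

    def __post_init__(self) -> None:
        if self.group not in MEASURE_GROUPS:
            raise ValueError(
                f"unknown measure group {self.group!r}; expected one of {MEASURE_GROUPS}"
            )
        if self.reliability is not None and not (0.0 <= self.reliability <= 1.0):
            raise ValueError(f"reliability must be in [0, 1], got {self.reliability}")


def _default_rank(group: str, position_in_group: int) -> int:
    return (MEASURE_GROUPS.index(group) + 1) * 100 + position_in_group


def load_registry(path: str | Path) -> list[MeasureDefinition]:
    """Read a measure registry from JSON (array of objects) or CSV.

    Columns/keys: ``name`` and ``group`` are required; ``causal_rank``,
    ``reliability``, ``higher_is_better`` and ``in_path_model`` are
    optional.  When ``causal_rank`` is absent it defaults to the listing
    order within each group (group order x 100 + position), matching the
    convention that within-group ordering follows the registry file.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        frame = pd.read_csv(path)
        records = frame.to_dict(orient="records")
    return registry_from_records(records)


def registry_from_records(records: Iterable[dict]) -> list[MeasureDefinition]:
    defs: list[MeasureDefinition] = []
    per_group_count: dict[str, int] = {}
    seen: set[str] = set()
    for rec in records:
        name = str(rec["name"])
        if name in seen:
            raise ValueError(f"duplicate measure name {name!r} in registry")
        seen.add(name)
        group = str(rec["group"])
        per_group_count[group] = per_group_count.get(group, 0) + 1
        rank = rec.get("causal_rank")
        if rank is None or (isinstance(rank, float) and np.isnan(rank)):
            if group not in MEASURE_GROUPS:
                raise ValueError(f"unknown measure group {group!r}")
            rank = _default_rank(group, per_group_count[group])
        rel = rec.get("reliability")
        if rel is not None and isinstance(rel, float) and np.isnan(rel):
            rel = None
        ipm = rec.get("in_path_model", True)
        if isinstance(ipm, float) and np.isnan(ipm):
            ipm = True
        defs.append(
            MeasureDefinition(
                name=name,
                group=group,
                causal_rank=int(rank),
                reliability=None if rel is None else float(rel),
                higher_is_better=rec.get("higher_is_better"),
                in_path_model=bool(ipm),
            )
        )
    return defs


def study_registry(path_model_only: bool = False) -> list[MeasureDefinition]:
    """The packaged registry of the 50 UK medical-school measures.

    Ten groups in causal order, with the 32 published between-school
    reliabilities attached.  With ``path_model_only=True`` only the 29
    measures retained for the causal path model are returned.
    """
    with resources.as_file(
        resources.files("instdiffs.data") / "study_measures.csv"
    ) as p:
        defs = load_registry(p)
    if path_model_only:
        defs = [d for d in defs if d.in_path_model]
    return defs


def causal_order(registry: Sequence[MeasureDefinition]) -> list[str]:
    """Measure names sorted by causal rank, stable for ties.

    Raises on duplicate names; the output is a permutation of the
    registry names.
    """
    names = [d.name for d in registry]
    if len(set(names)) != len(names):
        raise ValueError("duplicate measure names in registry")
    order = sorted(range(len(registry)), key=lambda i: (registry[i].causal_rank, i))
    return [registry[i].name for i in order]


# ---------------------------------------------------------------------------
# Matrix container


OBSERVED = "observed"
IMPUTED = "imputed"


@dataclass
class SchoolMeasureMatrix:
    """Units x measures matrix of aggregate values with provenance.

    ``values`` holds floats with ``NaN`` marking missing cells;
    ``provenance`` holds ``"observed"`` or ``"imputed"`` per cell.  A cell
    that is still missing is never marked imputed.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                OBSERVED, index=self.values.index, columns=self.values.columns
            )
        if not self.values.index.equals(self.provenance.index) or not (
            self.values.columns.equals(self.provenance.columns)
        ):
            raise ValueError("values and provenance must share index and columns")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate unit ids")
        bad = self.values.isna() & (self.provenance == IMPUTED)
        if bad.any().any():
            raise ValueError("a cell cannot be both missing and imputed")

    # -- basic views --------------------------------------------------
    @property
    def unit_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def measure_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_measures(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    def copy(self) -> "SchoolMeasureMatrix":
        return SchoolMeasureMatrix(self.values.copy(), self.provenance.copy())

    def select_measures(self, names: Sequence[str]) -> "SchoolMeasureMatrix":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"unknown measures: {missing}")
        return SchoolMeasureMatrix(
            self.values.loc[:, list(names)].copy(),
            self.provenance.loc[:, list(names)].copy(),
        )


@dataclass
class OccasionPanel:
    """Repeated measurements of one measure: units x occasions.

    Reliability of between-unit differences is estimated from the
    consistency of unit values across the occasions (usually years).
    """

    measure_name: str
    values: pd.DataFrame  # units x occasions

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.shape[1] < 2:
            raise ValueError("an occasion panel needs at least 2 occasions")

    @property
    def occasion_labels(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Matrix I/O


_NA_VALUES = ["", "NA", "NaN", "nan"]


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        return "xlsx"
    if suffix == ".tsv":
        return "tsv"
    return "csv"


def load_matrix(
    path: str | Path,
    registry: Sequence[MeasureDefinition] | None = None,
    dialect: str | None = None,
) -> SchoolMeasureMatrix:
    """Read a units x measures matrix from CSV, TSV or XLSX.

    Layout: header row of measure names, first column of unit ids.
    Empty cells and ``NA`` mark missing values.  Measures not present in
    ``registry`` (when given) are dropped with a warning; duplicate unit
    ids or zero data rows are hard errors.  All loaded cells carry
    provenance ``"observed"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "xlsx":
        frame = pd.read_excel(path, index_col=0, na_values=_NA_VALUES)
    elif dialect in {"csv", "tsv"}:
        frame = pd.read_csv(
            path,
            sep="\t" if dialect == "tsv" else ",",
            index_col=0,
            na_values=_NA_VALUES,
            keep_default_na=False,
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if frame.shape[0] == 0:
        raise ValueError("no units: the file has a header but zero data rows")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate unit ids: {dups}")
    frame.index = frame.index.astype(str)
    if registry is not None:
        known = {d.name for d in registry}
        unknown = [c for c in frame.columns if c not in known]
        if unknown:
            warnings.warn(
                f"skipping measures not in the registry: {unknown}", stacklevel=2
            )
            frame = frame.drop(columns=unknown)
    return SchoolMeasureMatrix(frame)


def save_matrix(
    matrix: SchoolMeasureMatrix, path: str | Path, dialect: str | None = None
) -> None:
    """Write the matrix; missing cells are written as empty fields."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "xlsx":
        matrix.values.to_excel(path)
    elif dialect in {"csv", "tsv"}:
        matrix.values.to_csv(path, sep="\t" if dialect == "tsv" else ",", na_rep="")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def subset_units(
    matrix: SchoolMeasureMatrix, exclude: Sequence[str]
) -> SchoolMeasureMatrix:
    """Drop the named units (e.g. exclude Oxbridge from a sensitivity run)."""
    unknown = [u for u in exclude if u not in matrix.values.index]
    if unknown:
        raise KeyError(f"unknown unit ids: {unknown}")
    keep = [u for u in matrix.unit_ids if u not in set(exclude)]
    if not keep:
        raise ValueError("no units remain after exclusion")
    return SchoolMeasureMatrix(
        matrix.values.loc[keep].copy(), matrix.provenance.loc[keep].copy()
    )
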