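"""Study variable scheme, discretization rules, and observation datasets.

The behavioral-observation study records nine discrete variables per
observation: six worker attributes pulled from personnel records (age,
experience, marital status, previous accident, educational level, number of
safety training courses), two temporal covariates logged by the observer
(weekday, daytime), and the binary outcome — whether the observed act was a
high-risk unsafe behavior (HRUB), i.e. one capable of causing immediate
serious injury.

Raw values (years, course counts, clock hours, weekday indices) are
discretized into 2–3 ordered states per variable.  Bin edges follow a
half-open, lower-inclusive convention; the last bin of a bounded domain is
closed on the right (e.g. the working day ends at 18:00 inclusive).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from numbers import Real
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SchemeError",
    "DiscretizationError",
    "DatasetError",
    "Bin",
    "VariableSpec",
    "VariableScheme",
    "ObservationRecord",
    "ObservationDataset",
    "default_scheme",
    "discretize",
    "read_observations",
    "write_observations",
    "load_scheme",
    "save_scheme",
]

#: CSV cell values (after trimming, case-insensitive) treated as missing.
MISSING_TOKENS = frozenset({"", "na", "nan", "none"})


class SchemeError(ValueError):
    """An invalid variable scheme definition."""


class DiscretizationError(ValueError):
    """A raw value that cannot be mapped to any state."""


class DatasetError(ValueError):
    """A malformed observation dataset (bad column, label, or file)."""


def _canon(label: str) -> str:
    return " ".join(str(label).split()).lower()


@dataclass(frozen=True)
class Bin:
    """Numeric half-open interval [lo, hi) mapped to one state.

    ``closed_right=True`` makes the interval [lo, hi]; used for the last bin
    of a bounded domain.  ``hi`` may be ``inf`` for an unbounded top bin.
    """

    state: str
    lo: float
    hi: float
    closed_right: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise SchemeError(f"bin for state {self.state!r}: lo must be < hi")

    def contains(self, value: float) -> bool:
        if self.closed_right:
            return self.lo <= value <= self.hi
        return self.lo <= value < self.hi


@dataclass(frozen=True)
class VariableSpec:
    """One study variable: its ordered states and optional discretizer.

    ``bins`` discretizes numeric raw values; ``mapping`` translates raw
    categorical labels (e.g. "married") to state labels.  State labels are
    matched case-insensitively after whitespace normalization.
    """

    name: str
    states: tuple[str, ...]
    bins: tuple[Bin, ...] | None = None
    mapping: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise SchemeError(f"variable {self.name!r} needs at least 2 states")
        canon = [_canon(s) for s in self.states]
        if len(set(canon)) != len(canon):
            raise SchemeError(f"variable {self.name!r} has duplicate state labels")
        if self.bins is not None:
            valid = set(self.states)
            for b in self.bins:
                if b.state not in valid:
                    raise SchemeError(
                        f"bin of {self.name!r} maps to unknown state {b.state!r}"
                    )
            # bins must be ordered, non-overlapping and contiguous
            for prev, nxt in zip(self.bins, self.bins[1:]):
                if prev.closed_right:
                    raise SchemeError(
                        f"variable {self.name!r}: only the last bin may be closed"
                    )
                if not math.isclose(prev.hi, nxt.lo):
                    raise SchemeError(
                        f"variable {self.name!r}: bins must be contiguous and ordered"
                    )
        if self.mapping is not None:
            valid = set(self.states)
            for raw, state in self.mapping.items():
                if state not in valid:
                    raise SchemeError(
                        f"mapping of {self.name!r} targets unknown state {state!r}"
                    )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        """Index of a state label (case-insensitive, whitespace-trimmed)."""
        c = _canon(label)
        for i, s in enumerate(self.states):
            if _canon(s) == c:
                return i
        raise DiscretizationError(
            f"invalid state {label!r} for variable {self.name!r}; "
            f"expected one of {list(self.states)}"
        )

    def canonical_state(self, label: str) -> str:
        return self.states[self.state_index(label)]

    def discretize_value(self, value) -> str | None:
        """Map one raw value to a state label; ``None``/NaN stays missing."""
        if value is None:
            return None
        if isinstance(value, Real) and not isinstance(value, bool):
            if isinstance(value, float) and math.isnan(value):
                return None
            return self._bin_value(float(value))
        text = str(value).strip()
        if _canon(text) in MISSING_TOKENS:
            return None
        # already a valid state label?
        try:
            return self.canonical_state(text)
        except DiscretizationError:
            pass
        if self.mapping is not None:
            c = _canon(text)
            for raw, state in self.mapping.items():
                if _canon(raw) == c:
                    return state
        try:
            return self._bin_value(float(text))
        except (TypeError, ValueError):
            raise DiscretizationError(
                f"cannot discretize value {value!r} for variable {self.name!r}"
            ) from None

    def _bin_value(self, value: float) -> str:
        if self.bins is None:
            raise DiscretizationError(
                f"variable {self.name!r} has no numeric bins; got {value!r}"
            )
        for b in self.bins:
            if b.contains(value):
                return b.state
        raise DiscretizationError(
            f"value {value!r} outside all bins of variable {self.name!r}"
        )


@dataclass(frozen=True)
class VariableScheme:
    """Ordered collection of variables plus the designated outcome."""

    variables: tuple[VariableSpec, ...]
    target: str = "HRUB"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemeError("variable names must be unique")
        if self.target not in names:
            raise SchemeError(f"target {self.target!r} is not a scheme variable")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self.variables)

    def cardinalities(self) -> dict[str, int]:
        return {v.name: v.n_states for v in self.variables}

    def to_dict(self) -> dict:
        out: dict = {"target": self.target, "variables": []}
        for v in self.variables:
            d: dict = {"name": v.name, "states": list(v.states)}
            if v.bins is not None:
                d["bins"] = [
                    {
                        "state": b.state,
                        "lo": b.lo,
                        "hi": "inf" if math.isinf(b.hi) else b.hi,
                        "closed_right": b.closed_right,
                    }
                    for b in v.bins
                ]
            if v.mapping is not None:
                d["mapping"] = dict(v.mapping)
            out["variables"].append(d)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "VariableScheme":
        specs = []
        for d in data["variables"]:
            bins = None
            if "bins" in d:
                bins = tuple(
                    Bin(
                        state=b["state"],
                        lo=float(b["lo"]),
                        hi=math.inf if b["hi"] in ("inf", None) else float(b["hi"]),
                        closed_right=bool(b.get("closed_right", False)),
                    )
                    for b in d["bins"]
                )
            specs.append(
                VariableSpec(
                    name=d["name"],
                    states=tuple(d["states"]),
                    bins=bins,
                    mapping=d.get("mapping"),
                )
            )
        return cls(variables=tuple(specs), target=data.get("target", "HRUB"))


@dataclass(frozen=True)
class ObservationRecord:
    """State assignments of one behavioral observation; variables may be absent.

    Missingness is represented by absence from ``assignments`` — never by a
    sentinel state.
    """

    assignments: Mapping[str, str]

    def get(self, name: str) -> str | None:
        return self.assignments.get(name)

    def is_complete(self, scheme: VariableScheme) -> bool:
        return all(n in self.assignments for n in scheme.names)


@dataclass
class ObservationDataset:
    """A variable scheme plus an ordered collection of validated records."""

    scheme: VariableScheme
    records: list[ObservationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, rec in enumerate(self.records):
            for name, state in rec.assignments.items():
                if name not in self.scheme:
                    raise DatasetError(f"record {i}: unknown variable {name!r}")
                self.scheme[name].state_index(state)  # raises if invalid

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ObservationRecord]:
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {n: rec.get(n) for n in self.scheme.names} for rec in self.records
        ]
        return pd.DataFrame(rows, columns=list(self.scheme.names))

    def state_index_matrix(self) -> "pd.DataFrame":
        """Integer state indices with -1 for missing; one row per record."""
        cols = {}
        for name in self.scheme.names:
            spec = self.scheme[name]
            cols[name] = [
                spec.state_index(rec.get(name)) if rec.get(name) is not None else -1
                for rec in self.records
            ]
        return pd.DataFrame(cols, dtype=int)


# ---------------------------------------------------------------------------
# Default study scheme
# ---------------------------------------------------------------------------

def default_scheme() -> VariableScheme:
    """The nine-variable scheme of the behavioral-safety study.

    Seven variables have three ordered states, two (marital status and the
    HRUB outcome) are binary; 25 states in total.  Numeric discretizers use
    lower-inclusive half-open bins.
    """
    v = [
        VariableSpec(
            "Age",
            ("under 30 years", "from 30 to 40 years", "above 40 years"),
            bins=(
                Bin("under 30 years", 0.0, 30.0),
                Bin("from 30 to 40 years", 30.0, 40.0),
                Bin("above 40 years", 40.0, math.inf),
            ),
        ),
        VariableSpec(
            "Experience",
            ("under 1 year", "from 1 to 5 years", "above 5 years"),
            bins=(
                Bin("under 1 year", 0.0, 1.0),
                Bin("from 1 to 5 years", 1.0, 5.0),
                Bin("above 5 years", 5.0, math.inf),
            ),
        ),
        VariableSpec(
            "MaritalStatus",
            ("yes", "no"),
            mapping={"married": "yes", "single": "no", "unmarried": "no"},
        ),
        VariableSpec(
            "PreviousAccident",
            ("no accident", "minor accident", "major accident"),
            mapping={
                "no": "no accident",
                "none": "no accident",
                "minor": "minor accident",
                "major": "major accident",
            },
        ),
        VariableSpec(
            "EducationalLevel",
            ("primary", "high school", "academic"),
            mapping={"highschool": "high school"},
        ),
        VariableSpec(
            "Weekday",
            ("first days", "middle days", "last days"),
            # day-of-week index 0..6: two first days, three midweek, two last
            bins=(
                Bin("first days", 0.0, 2.0),
                Bin("middle days", 2.0, 5.0),
                Bin("last days", 5.0, 6.0, closed_right=True),
            ),
        ),
        VariableSpec(
            "Daytime",
            ("from 8am to 11am", "from 11am to 2pm", "from 2pm to 6pm"),
            # clock hours of the working day, 18:00 inclusive
            bins=(
                Bin("from 8am to 11am", 8.0, 11.0),
                Bin("from 11am to 2pm", 11.0, 14.0),
                Bin("from 2pm to 6pm", 14.0, 18.0, closed_right=True),
            ),
        ),
        VariableSpec(
            "Training",
            ("s1", "s2", "s3"),
            # s1: up to two safety courses, s2: three or four, s3: five or more
            bins=(
                Bin("s1", 0.0, 3.0),
                Bin("s2", 3.0, 5.0),
                Bin("s3", 5.0, math.inf),
            ),
        ),
        VariableSpec(
            "HRUB",
            ("no", "yes"),
            mapping={"safe": "no", "unsafe": "yes"},
        ),
    ]
    return VariableScheme(variables=tuple(v), target="HRUB")


def _parse_clock(value) -> float:
    """Accept 13, 13.5 or 'HH:MM' clock strings as fractional hours."""
    if isinstance(value, Real) and not isinstance(value, bool):
        return float(value)
    text = str(value).strip()
    if ":" in text:
        hh, mm = text.split(":", 1)
        return float(hh) + float(mm) / 60.0
    return float(text)


def discretize(raw: Mapping[str, object], scheme: VariableScheme) -> ObservationRecord:
    """Map a mapping of raw values to a validated observation record.

    Raw values may be numbers (years, course counts, clock hours, weekday
    indices), 'HH:MM' clock strings for daytime, raw categorical labels, or
    already-valid state labels.  Missing values propagate as missing.
    """
    assignments: dict[str, str] = {}
    for name, value in raw.items():
        if name not in scheme:
            raise DatasetError(f"unknown variable {name!r}")
        spec = scheme[name]
        if name == "Daytime" and value is not None and ":" in str(value):
            value = _parse_clock(value)
        state = spec.discretize_value(value)
        if state is not None:
            assignments[name] = state
    return ObservationRecord(assignments=assignments)


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

def read_observations(path, scheme: VariableScheme) -> ObservationDataset:
    """Read an observation CSV (header = variable names; empty/NA = missing).

    Errors are reported with the 1-based CSV line number (header is line 1).
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise DatasetError(f"malformed CSV {path}: {exc}") from exc
    for col in df.columns:
        if col not in scheme:
            raise DatasetError(f"unknown column {col!r} in {path}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        assignments = {}
        for col, cell in zip(df.columns, row):
            if _canon(cell) in MISSING_TOKENS:
                continue
            try:
                assignments[col] = scheme[col].canonical_state(cell)
            except DiscretizationError as exc:
                raise DatasetError(f"{path} line {i}: {exc}") from exc
        records.append(ObservationRecord(assignments=assignments))
    return ObservationDataset(scheme=scheme, records=records)


def write_observations(dataset: ObservationDataset, path) -> None:
    """Write a dataset as CSV; missing values become empty cells."""
    df = dataset.to_dataframe()
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Scheme serialization
# ---------------------------------------------------------------------------

def save_scheme(scheme: VariableScheme, path) -> None:
    path = Path(path)
    data = scheme.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_scheme(path) -> VariableScheme:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return VariableScheme.from_dict(data)
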