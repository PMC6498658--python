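"""Coded-statement data model and I/O.

A *statement* is the unit of coded discourse: one actor (an organisation,
or an individual acting as their own organisation-level actor) agreeing or
disagreeing with one concept in one article on one date.  Statement tables
are delimited long-format files, one statement per row, read through a
configurable column mapping so that exports from different coding tools can
be ingested without reshaping.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import EmptyInputError, ParameterError, RowValidationError, SchemaError

DEFAULT_SCHEMA = {
    "columns": {
        "person": "person",
        "organisation": "organisation",
        "org_type": "org_type",
        "concept": "concept",
        "agreement": "agreement",
        "date": "date",
        "article_id": "article_id",
    },
    "agreement": {
        "true_values": ["agree", "1", "true", "yes"],
        "false_values": ["disagree", "0", "false", "no"],
    },
}


@dataclass(frozen=True)
class Statement:
    """One coded attribution of (dis)agreement with a concept by an actor."""

    person: str
    organisation: str
    org_type: str
    concept: str
    agreement: bool
    date: dt.date
    article_id: str

    def __post_init__(self):
        if not self.organisation:
            raise ValueError("organisation must be non-empty")
        if not self.concept:
            raise ValueError("concept must be non-empty")


@dataclass(frozen=True)
class TimeWindow:
    """Half-open calendar interval [start, end)."""

    start: dt.date
    end: dt.date

    def __post_init__(self):
        if self.start >= self.end:
            raise ParameterError(f"empty window: start {self.start} >= end {self.end}")

    def __contains__(self, date: dt.date) -> bool:
        return self.start <= date < self.end


@dataclass
class StatementSet:
    """Ordered collection of statements with actor and concept registries.

    Statements are kept sorted by (date, article_id, input order) so that
    windowing and sliding-window analyses are deterministic even on tied
    dates.
    """

    statements: list = field(default_factory=list)
    actor_registry: dict = field(default_factory=dict)  # organisation -> org_type
    concept_registry: set = field(default_factory=set)

    def __post_init__(self):
        order = {id(s): i for i, s in enumerate(self.statements)}
        self.statements = sorted(
            self.statements, key=lambda s: (s.date, s.article_id, order[id(s)])
        )
        for s in self.statements:
            self.actor_registry.setdefault(s.organisation, s.org_type)
            self.concept_registry.add(s.concept)

    def __len__(self) -> int:
        return len(self.statements)

    def __iter__(self):
        return iter(self.statements)

    @property
    def actors(self) -> list:
        return sorted(self.actor_registry)

    @property
    def concepts(self) -> list:
        return sorted(self.concept_registry)

    @property
    def persons(self) -> list:
        return sorted({s.person for s in self.statements if s.person})

    def date_range(self) -> tuple:
        if not self.statements:
            raise EmptyInputError("no statements")
        dates = [s.date for s in self.statements]
        return min(dates), max(dates)

    def counts(self) -> dict:
        return {
            "statements": len(self.statements),
            "persons": len(self.persons),
            "organisations": len(self.actor_registry),
            "concepts": len(self.concept_registry),
        }

    def filter_window(self, window: TimeWindow) -> "StatementSet":
        """Statements with date in [start, end); registries restricted to
        actors/concepts with at least one retained statement."""
        kept = [s for s in self.statements if s.date in window]
        if not kept and self.statements:
            warnings.warn(
                f"window {window.start}..{window.end} retains no statements", stacklevel=2
            )
        return StatementSet(statements=kept)

    def to_frame(self) -> pd.DataFrame:
        cols = ["person", "organisation", "org_type", "concept", "agreement", "date", "article_id"]
        return pd.DataFrame(
            [
                {
                    "person": s.person,
                    "organisation": s.organisation,
                    "org_type": s.org_type,
                    "concept": s.concept,
                    "agreement": "agree" if s.agreement else "disagree",
                    "date": s.date.isoformat(),
                    "article_id": s.article_id,
                }
                for s in self.statements
            ],
            columns=cols,
        )


def filter_window(s: StatementSet, w: TimeWindow) -> StatementSet:
    return s.filter_window(w)


def _merge_schema(schema_config) -> dict:
    schema = {
        "columns": dict(DEFAULT_SCHEMA["columns"]),
        "agreement": {k: list(v) for k, v in DEFAULT_SCHEMA["agreement"].items()},
    }
    if schema_config:
        schema["columns"].update(schema_config.get("columns", {}))
        schema["agreement"].update(schema_config.get("agreement", {}))
    return schema


def read_statements(path, schema_config=None, study_window: TimeWindow | None = None) -> StatementSet:
    """Read a delimited long-format statement table.

    Parameters
    ----------
    path : str or Path
        CSV (or TSV, by extension) file with a header row.
    schema_config : dict, optional
        Overrides for ``columns.*`` (file column names) and
        ``agreement.true_values`` / ``agreement.false_values``.
    study_window : TimeWindow, optional
        When given, dates outside the window are row-level errors.

    Raises
    ------
    SchemaError, EmptyInputError, RowValidationError
    """
    schema = _merge_schema(schema_config)
    cols = schema["columns"]
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    if df.empty:
        raise EmptyInputError(f"{path}: header only, no statements")

    required = ["organisation", "concept", "agreement", "date"]
    for key in required + ["person", "org_type", "article_id"]:
        name = cols[key]
        if name not in df.columns:
            if key in required:
                raise SchemaError(f"missing required column {name!r} (maps to {key})")
            df[name] = ""

    true_vals = {str(v).strip().lower() for v in schema["agreement"]["true_values"]}
    false_vals = {str(v).strip().lower() for v in schema["agreement"]["false_values"]}

    statements, errors = [], []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        rec = dict(zip(df.columns, row))
        org = rec[cols["organisation"]].strip()
        concept = rec[cols["concept"]].strip()
        person = rec[cols["person"]].strip()
        if not org and person:
            # individuals without an affiliation stand as their own actor
            org = person
        if not org:
            errors.append((line, "empty organisation and person"))
            continue
        if not concept:
            errors.append((line, "empty concept"))
            continue
        raw_agree = rec[cols["agreement"]].strip().lower()
        if raw_agree in true_vals:
            agreement = True
        elif raw_agree in false_vals:
            agreement = False
        else:
            errors.append((line, f"agreement value {raw_agree!r} not in configured vocabulary"))
            continue
        try:
            date = dt.date.fromisoformat(rec[cols["date"]].strip())
        except ValueError:
            errors.append((line, f"unparseable date {rec[cols['date']]!r}"))
            continue
        if study_window is not None and date not in study_window:
            errors.append((line, f"date {date} outside study window"))
            continue
        statements.append(
            Statement(
                person=person,
                organisation=org,
                org_type=rec[cols["org_type"]].strip(),
                concept=concept,
                agreement=agreement,
                date=date,
                article_id=rec[cols["article_id"]].strip(),
            )
        )
    if errors:
        raise RowValidationError(errors)
    return StatementSet(statements=statements)


def write_statements(s: StatementSet, path) -> None:
    """Write the canonical long-format table (round-trips with
    :func:`read_statements` under the default schema)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    s.to_frame().to_csv(path, index=False, sep=sep)


def split_periods(s: StatementSet, boundary: dt.date) -> tuple[StatementSet, StatementSet]:
    """Split a debate into before/after periods at a boundary date
    (boundary itself falls in the second period, half-open convention)."""
    start, end = s.date_range()
    pre = s.filter_window(TimeWindow(start, boundary))
    post = s.filter_window(TimeWindow(boundary, end + dt.timedelta(days=1)))
    return pre, post
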