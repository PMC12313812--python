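"""Readers and writers for call annotations, metadata and interaction logs.

Two annotation dialects are supported — Audacity label tracks (headerless
TSV: start, end, label) and Raven Pro selection tables (TSV with header) —
and both normalise into a single canonical call table that every
downstream stage consumes.  Parsing is locale-independent (decimal point
only) and times are kept at full input precision.

Caller identity in Audacity files follows the field convention that the
observer announces the caller on the recording: the caller is passed
explicitly per file, and a label of the form ``id:NAME`` overrides it for
that call.  Quality flags (``unknown_caller``, ``overlapping``,
``incomplete_context``) are carried through ingest untouched; filtering on
them is the sequence builder's job.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

VALID_FLAGS = frozenset({"unknown_caller", "overlapping", "incomplete_context"})
VALID_SEXES = frozenset({"F", "M"})
VALID_SUBSPECIES = frozenset({"carrion", "hooded", "hybrid"})
AGONISTIC_BEHAVIORS = frozenset({"threat", "chase", "flight", "fight"})
AFFILIATIVE_BEHAVIORS = frozenset({"allopreen", "contact_sit"})

CALL_TABLE_COLUMNS = [
    "individual",
    "population",
    "group",
    "source_file",
    "onset_s",
    "offset_s",
    "flags",
]


class AnnotationParseError(ValueError):
    """A line of an annotation file could not be parsed."""


class AnnotationFormatError(ValueError):
    """An annotation file does not have the expected layout."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class CallRecord:
    """One annotated call: who called, when, and from which recording."""

    caller_id: str
    onset: float
    offset: float
    source_file: str = ""
    session_date: _dt.date | None = None
    label: str = ""
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValidationError(
                f"call offset must exceed onset: got onset={self.onset}, offset={self.offset}"
            )
        bad = set(self.flags) - VALID_FLAGS
        if bad:
            raise ValidationError(f"unknown call flags: {sorted(bad)}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def with_flags(self, *extra: str) -> "CallRecord":
        return replace(self, flags=frozenset(self.flags) | set(extra))


@dataclass(frozen=True)
class IndividualMeta:
    """Per-individual covariates: sex, hatch year, subspecies, housing history."""

    individual_id: str
    sex: str
    hatch_year: int | None
    subspecies: str
    population: str
    group_memberships: tuple[tuple[str, _dt.date, _dt.date], ...] = ()
    elo: float | None = None
    csi: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValidationError(f"sex must be F or M, got {self.sex!r}")
        if self.subspecies not in VALID_SUBSPECIES:
            raise ValidationError(
                f"subspecies must be one of {sorted(VALID_SUBSPECIES)}, got {self.subspecies!r}"
            )
        for gid, start, end in self.group_memberships:
            if end < start:
                raise ValidationError(
                    f"membership in {gid!r} has end {end} before start {start}"
                )

    def group_at(self, date: _dt.date) -> str | None:
        """Group the individual was housed in on ``date`` (None if unknown)."""
        for gid, start, end in self.group_memberships:
            if start <= date <= end:
                return gid
        return None


@dataclass(frozen=True)
class InteractionRecord:
    """One dyadic event from a focal observation (agonistic or affiliative)."""

    date: _dt.date
    category: str
    behavior: str
    initiator: str
    receiver: str
    winner: str | None = None

    def __post_init__(self) -> None:
        if self.initiator == self.receiver:
            raise ValidationError("initiator and receiver must differ")
        if self.category == "agonistic":
            if self.behavior not in AGONISTIC_BEHAVIORS:
                raise ValidationError(f"not an agonistic behavior: {self.behavior!r}")
            if self.winner not in (self.initiator, self.receiver):
                raise ValidationError(
                    "agonistic interaction winner must be initiator or receiver, "
                    f"got {self.winner!r}"
                )
        elif self.category == "affiliative":
            if self.behavior not in AFFILIATIVE_BEHAVIORS:
                raise ValidationError(f"not an affiliative behavior: {self.behavior!r}")
            if self.winner is not None:
                raise ValidationError("affiliative interactions have no winner")
        else:
            raise ValidationError(f"unknown interaction category: {self.category!r}")

    @property
    def dyad(self) -> tuple[str, str]:
        return tuple(sorted((self.initiator, self.receiver)))  # type: ignore[return-value]


def _sorted_by_onset(records: list[CallRecord]) -> list[CallRecord]:
    # stable sort: equal onsets keep input order
    return sorted(records, key=lambda r: r.onset)


def read_audacity_labels(path: str | Path, caller_id: str) -> list[CallRecord]:
    """Read an Audacity label track (TSV: start, end, label) as call records.

    ``caller_id`` is the default caller for every label; a label text of
    the form ``id:NAME`` (optionally followed by free text after a space)
    overrides it for that call.  A label of ``unknown`` or caller ``?``
    marks the call ``unknown_caller``.  Lines whose end does not exceed
    their start are rejected.
    """
    path = Path(path)
    records: list[CallRecord] = []
    text = path.read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise AnnotationParseError(
                f"{path.name}:{lineno}: expected at least 2 tab-separated fields"
            )
        try:
            start = float(parts[0])
            end = float(parts[1])
        except ValueError as exc:
            raise AnnotationParseError(
                f"{path.name}:{lineno}: non-numeric time field: {exc}"
            ) from None
        label = parts[2].strip() if len(parts) > 2 else ""
        if not end > start:
            raise ValidationError(
                f"{path.name}:{lineno}: call duration must be positive "
                f"(start={start}, end={end})"
            )
        caller = caller_id
        flags: set[str] = set()
        if label.startswith("id:"):
            caller = label[3:].split()[0] if label[3:].split() else caller_id
        if label.lower() == "unknown" or caller in ("?", "unknown", ""):
            flags.add("unknown_caller")
        records.append(
            CallRecord(
                caller_id=caller,
                onset=start,
                offset=end,
                source_file=path.name,
                label=label,
                flags=frozenset(flags),
            )
        )
    return _sorted_by_onset(records)


RAVEN_REQUIRED = ("Selection", "Begin Time (s)", "End Time (s)")


def read_raven_selection_table(
    path: str | Path,
    caller_column: str = "Caller",
    default_caller: str = "",
) -> list[CallRecord]:
    """Read a Raven Pro selection table as call records.

    Rows duplicated across "Waveform"/"Spectrogram" views are collapsed by
    Selection number.  The caller is read from ``caller_column`` when that
    column exists, else every record gets ``default_caller``; a caller of
    ``unknown``/``?``/empty flags the record ``unknown_caller``.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in RAVEN_REQUIRED if c not in table.columns]
    if missing:
        raise AnnotationFormatError(
            f"{path.name}: missing required Raven columns {missing}; "
            f"found {list(table.columns)}"
        )
    table = table.drop_duplicates(subset="Selection", keep="first")
    records: list[CallRecord] = []
    for _, row in table.iterrows():
        try:
            begin = float(row["Begin Time (s)"])
            end = float(row["End Time (s)"])
        except ValueError as exc:
            raise AnnotationParseError(f"{path.name}: bad time in selection "
                                       f"{row['Selection']}: {exc}") from None
        caller = default_caller
        if caller_column in table.columns:
            value = row[caller_column]
            caller = "" if pd.isna(value) else str(value).strip()
        flags: set[str] = set()
        if caller.lower() in ("", "?", "unknown"):
            flags.add("unknown_caller")
        records.append(
            CallRecord(
                caller_id=caller,
                onset=begin,
                offset=end,
                source_file=path.name,
                flags=frozenset(flags),
            )
        )
    return _sorted_by_onset(records)


# ---------------------------------------------------------------------------
# canonical tables


def calls_to_frame(
    records: Iterable[CallRecord],
    meta: dict[str, IndividualMeta] | None = None,
) -> pd.DataFrame:
    """Flatten call records into the canonical call table."""
    rows = []
    for r in records:
        population = group = ""
        if meta and r.caller_id in meta:
            m = meta[r.caller_id]
            population = m.population
            if r.session_date is not None:
                group = m.group_at(r.session_date) or ""
        rows.append(
            {
                "individual": r.caller_id,
                "population": population,
                "group": group,
                "source_file": r.source_file,
                "onset_s": r.onset,
                "offset_s": r.offset,
                "flags": ";".join(sorted(r.flags)),
            }
        )
    frame = pd.DataFrame(rows, columns=CALL_TABLE_COLUMNS)
    return frame.sort_values(
        ["source_file", "onset_s"], kind="stable"
    ).reset_index(drop=True)


def frame_to_calls(frame: pd.DataFrame) -> list[CallRecord]:
    records = []
    for _, row in frame.iterrows():
        flags = frozenset(f for f in str(row.get("flags", "") or "").split(";") if f)
        records.append(
            CallRecord(
                caller_id=str(row["individual"]),
                onset=float(row["onset_s"]),
                offset=float(row["offset_s"]),
                source_file=str(row.get("source_file", "") or ""),
                flags=flags,
            )
        )
    return records


def write_call_table(records: Iterable[CallRecord] | pd.DataFrame, path: str | Path) -> None:
    frame = records if isinstance(records, pd.DataFrame) else calls_to_frame(records)
    # %.17g guarantees binary round-trip of the times
    frame.to_csv(path, index=False, float_format="%.17g")


def read_call_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, dtype={"individual": str, "population": str, "group": str,
                     "source_file": str, "flags": str}, keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in CALL_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise AnnotationFormatError(f"call table missing columns {missing}")
    frame["onset_s"] = frame["onset_s"].astype(float)
    frame["offset_s"] = frame["offset_s"].astype(float)
    return frame.sort_values(["source_file", "onset_s"], kind="stable").reset_index(drop=True)


def _parse_date(value: str) -> _dt.date:
    return _dt.date.fromisoformat(str(value).strip())


def read_metadata(path: str | Path) -> list[IndividualMeta]:
    """Read the individual-metadata table.

    Columns: individual, hatch_year (empty for unknown), sex, subspecies,
    population, memberships (``group@start..end`` entries joined by ``|``).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["individual", "hatch_year", "sex", "subspecies", "population"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise AnnotationFormatError(f"metadata table missing columns {missing}")
    out = []
    for _, row in frame.iterrows():
        memberships = []
        for entry in str(row.get("memberships", "") or "").split("|"):
            entry = entry.strip()
            if not entry:
                continue
            gid, _, span = entry.partition("@")
            start_s, _, end_s = span.partition("..")
            memberships.append((gid, _parse_date(start_s), _parse_date(end_s)))
        year = str(row["hatch_year"]).strip()
        out.append(
            IndividualMeta(
                individual_id=str(row["individual"]),
                sex=str(row["sex"]).strip(),
                hatch_year=int(year) if year else None,
                subspecies=str(row["subspecies"]).strip(),
                population=str(row["population"]).strip(),
                group_memberships=tuple(memberships),
            )
        )
    return out


def write_metadata(meta: Iterable[IndividualMeta], path: str | Path) -> None:
    rows = []
    for m in meta:
        rows.append(
            {
                "individual": m.individual_id,
                "hatch_year": "" if m.hatch_year is None else m.hatch_year,
                "sex": m.sex,
                "subspecies": m.subspecies,
                "population": m.population,
                "memberships": "|".join(
                    f"{gid}@{start.isoformat()}..{end.isoformat()}"
                    for gid, start, end in m.group_memberships
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read the focal-observation interaction log.

    Columns: date (ISO), category, behavior, initiator, receiver, winner
    (empty for affiliative events).  Returned in chronological order; ties
    in date keep file order.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["date", "category", "behavior", "initiator", "receiver", "winner"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise AnnotationFormatError(f"interaction table missing columns {missing}")
    records = []
    for _, row in frame.iterrows():
        winner = str(row["winner"]).strip() or None
        records.append(
            InteractionRecord(
                date=_parse_date(row["date"]),
                category=str(row["category"]).strip(),
                behavior=str(row["behavior"]).strip(),
                initiator=str(row["initiator"]).strip(),
                receiver=str(row["receiver"]).strip(),
                winner=winner,
            )
        )
    return sorted(records, key=lambda r: r.date)


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    rows = [
        {
            "date": r.date.isoformat(),
            "category": r.category,
            "behavior": r.behavior,
            "initiator": r.initiator,
            "receiver": r.receiver,
            "winner": r.winner or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
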