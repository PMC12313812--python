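"""Partition calls into sequences with the inter-call-gap rule, then filter.

A sequence is a run of calls by one individual within one recording in
which every silent interval (next onset minus previous offset) is at most
the gap threshold; a gap of *more than* the threshold (default 1.0 s,
strict inequality) starts a new sequence.  Exclusion of unknown-caller,
overlapping, incomplete and single-call sequences is applied afterwards,
in a documented order, with an audit tally so the filter cascade is
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_annotations import CallRecord, IndividualMeta

DEFAULT_GAP_THRESHOLD = 1.0


@dataclass(frozen=True)
class CallSequence:
    """An ordered run of calls by one individual in one recording."""

    sequence_id: str
    individual_id: str
    calls: tuple[CallRecord, ...]
    incomplete: bool = False

    @property
    def length(self) -> int:
        """Number of calls — the construct size x of the Menzerath-Altmann law."""
        return len(self.calls)

    @property
    def durations(self) -> list[float]:
        """Per-call durations — the constituent sizes y."""
        return [c.duration for c in self.calls]

    @property
    def flags(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.calls:
            out |= c.flags
        if self.incomplete:
            out.add("incomplete_context")
        return frozenset(out)


def segment_sequences(
    calls: Iterable[CallRecord],
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> list[CallSequence]:
    """Partition calls into sequences by the strict >threshold silence rule.

    Calls are grouped per (individual, source_file) and sorted by onset; a
    new sequence starts whenever the silence before a call exceeds
    ``gap_threshold`` (a gap exactly equal to the threshold does NOT
    split).  Same-individual calls that overlap the preceding call are
    flagged ``overlapping`` rather than silently merged.  Sequence ids are
    deterministic: ``<source_file>:<individual>:<ordinal>``.
    """
    if not gap_threshold > 0:
        raise ValueError(f"gap_threshold must be positive, got {gap_threshold}")
    by_key: dict[tuple[str, str], list[CallRecord]] = {}
    for call in calls:
        by_key.setdefault((call.source_file, call.caller_id), []).append(call)

    sequences: list[CallSequence] = []
    for (source, individual) in sorted(by_key):
        group = sorted(by_key[(source, individual)], key=lambda c: c.onset)
        runs: list[list[CallRecord]] = [[group[0]]]
        for call in group[1:]:
            prev = runs[-1][-1]
            if call.onset < prev.offset:
                call = call.with_flags("overlapping")
                runs[-1].append(call)
            elif call.onset - prev.offset > gap_threshold:
                runs.append([call])
            else:
                runs[-1].append(call)
        for ordinal, run in enumerate(runs, start=1):
            sequences.append(
                CallSequence(
                    sequence_id=f"{source}:{individual}:{ordinal}",
                    individual_id=individual,
                    calls=tuple(run),
                )
            )
    return sequences


#: rule application order for ``apply_exclusions`` (audit counts depend on it)
EXCLUSION_ORDER = ("unknown_caller", "overlapping", "incomplete", "singleton")


def apply_exclusions(
    sequences: Iterable[CallSequence],
) -> tuple[list[CallSequence], dict[str, int]]:
    """Drop contaminated and single-call sequences; tally drops per rule.

    Rules in order: any unknown-caller call contaminates its whole
    sequence; likewise any overlapping call; sequences flagged incomplete;
    finally single-call sequences, which are known to depart from the
    Menzerath-Altmann law.  A sequence is counted against the first rule
    that removes it.
    """
    audit = {rule: 0 for rule in EXCLUSION_ORDER}
    audit["kept"] = 0
    kept: list[CallSequence] = []
    for seq in sequences:
        flags = seq.flags
        if "unknown_caller" in flags:
            audit["unknown_caller"] += 1
        elif "overlapping" in flags:
            audit["overlapping"] += 1
        elif "incomplete_context" in flags:
            audit["incomplete"] += 1
        elif seq.length < 2:
            audit["singleton"] += 1
        else:
            audit["kept"] += 1
            kept.append(seq)
    return kept, audit


def dataset_summary(
    sequences: Iterable[CallSequence],
    meta: Mapping[str, IndividualMeta] | None = None,
) -> pd.DataFrame:
    """Per-individual call and sequence counts, with grand totals.

    Individuals absent from ``meta`` are listed with subspecies/population
    ``unmatched`` rather than dropped.  The last row, ``TOTAL``, sums the
    counts.
    """
    rows: dict[str, dict] = {}
    for seq in sequences:
        row = rows.setdefault(
            seq.individual_id,
            {"individual": seq.individual_id, "n_calls": 0, "n_sequences": 0},
        )
        row["n_calls"] += seq.length
        row["n_sequences"] += 1
    for row in rows.values():
        if meta and row["individual"] in meta:
            m = meta[row["individual"]]
            row["subspecies"] = m.subspecies
            row["population"] = m.population
        else:
            row["subspecies"] = "unmatched" if meta else ""
            row["population"] = "unmatched" if meta else ""
    frame = pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["individual"]),
        columns=["individual", "subspecies", "population", "n_calls", "n_sequences"],
    )
    total = {
        "individual": "TOTAL",
        "subspecies": "",
        "population": "",
        "n_calls": int(frame["n_calls"].sum()) if len(frame) else 0,
        "n_sequences": int(frame["n_sequences"].sum()) if len(frame) else 0,
    }
    return pd.concat([frame, pd.DataFrame([total])], ignore_index=True)


def sequences_to_frame(sequences: Iterable[CallSequence]) -> pd.DataFrame:
    """Long-format sequence table: one row per call with its sequence context."""
    rows = []
    for seq in sequences:
        for idx, call in enumerate(seq.calls):
            rows.append(
                {
                    "sequence_id": seq.sequence_id,
                    "individual": seq.individual_id,
                    "length": seq.length,
                    "call_index": idx,
                    "onset_s": call.onset,
                    "offset_s": call.offset,
                    "duration_s": call.duration,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "individual",
            "length",
            "call_index",
            "onset_s",
            "offset_s",
            "duration_s",
        ],
    )
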