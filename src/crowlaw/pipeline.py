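"""End-to-end pipeline: ingest -> segment -> indices -> fit -> compare -> report.

Artifacts are plain CSV/JSON so every table is diffable and testable; the
run configuration is serialised next to the outputs and every stage logs
its in/out counts so the exclusion cascade is auditable.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .io_annotations import (
    CallRecord,
    IndividualMeta,
    frame_to_calls,
    read_audacity_labels,
    read_call_table,
    read_interactions,
    read_metadata,
)
from .menzerath import ModelFit, compare_models, fit_complex, fit_simple, predict_curves
from .sequence_builder import (
    apply_exclusions,
    dataset_summary,
    segment_sequences,
    sequences_to_frame,
)
from .social_indices import (
    FOCAL_MINUTES,
    csi,
    dyads_from_cohousing,
    effort_correct,
    elo_ratings,
)

logger = logging.getLogger("crowlaw")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One reproducible run of the full analysis."""

    calls: str = ""  # canonical call table (CSV)
    labels_dir: str = ""  # or: directory of Audacity label files
    metadata: str = ""
    interactions: str = ""
    out_dir: str = "crowlaw_run"
    gap_threshold: float = 1.0
    models: tuple[str, ...] = ("eq3", "eq4", "eq5", "eq6")
    estimation_method: str = "ML"
    standardize: bool = True
    seed: int = 0
    recording_date: str = ""  # ISO fallback when call table has no dates

    def validate(self) -> None:
        if not self.calls and not self.labels_dir:
            raise PipelineError("validate: need either a call table or a labels directory")
        for name in ("calls", "labels_dir", "metadata", "interactions"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise PipelineError(f"validate: {name} path does not exist: {value}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def ingest_calls(config: RunConfig) -> list[CallRecord]:
    if config.calls:
        return frame_to_calls(read_call_table(config.calls))
    records: list[CallRecord] = []
    for path in sorted(Path(config.labels_dir).glob("*.txt")):
        records.extend(read_audacity_labels(path, caller_id=path.stem))
    return records


def attach_covariates(
    frame: pd.DataFrame,
    meta: Mapping[str, IndividualMeta],
    indices: pd.DataFrame | None,
    recording_date: _dt.date,
) -> pd.DataFrame:
    """Join sex/age/subspecies/group covariates onto the per-call frame.

    Age at recording is recording year minus hatch year; unknown hatch
    years are imputed with the mean age of the known birds.  Group and
    group size come from the membership interval covering the recording
    date; effort-corrected Elo and CSI come from the indices table when
    given (zero otherwise).
    """
    out = frame.copy()
    known = {m.individual_id: m for m in meta.values()}

    def lookup(ind: str, attr: str):
        m = known.get(ind)
        return getattr(m, attr) if m is not None else None

    out["subspecies"] = out["individual"].map(lambda i: lookup(i, "subspecies") or "unmatched")
    out["population"] = out["individual"].map(lambda i: lookup(i, "population") or "unmatched")
    out["sex"] = out["individual"].map(lambda i: lookup(i, "sex") or "F")

    groups = {}
    group_rosters: dict[str, set[str]] = {}
    for m in known.values():
        gid = m.group_at(recording_date) or f"solo_{m.individual_id}"
        groups[m.individual_id] = gid
        group_rosters.setdefault(gid, set()).add(m.individual_id)
    out["group"] = out["individual"].map(lambda i: groups.get(i, "unmatched"))
    out["group_size"] = out["group"].map(lambda g: float(len(group_rosters.get(g, {0}))))

    ages = {
        m.individual_id: float(recording_date.year - m.hatch_year)
        for m in known.values()
        if m.hatch_year is not None
    }
    mean_age = float(np.mean(list(ages.values()))) if ages else 0.0
    out["age"] = out["individual"].map(lambda i: ages.get(i, mean_age))

    if indices is not None and len(indices):
        idx = indices.set_index("individual")
        out["elo"] = out["individual"].map(idx["elo_corrected"]).fillna(0.0)
        out["csi"] = out["individual"].map(idx["csi_corrected"]).fillna(0.0)
    else:
        out["elo"] = 0.0
        out["csi"] = 0.0
    return out


def compute_indices(
    interactions_path: str | Path,
    meta: Mapping[str, IndividualMeta],
) -> pd.DataFrame:
    """Elo and CSI (raw and effort-corrected) for every individual."""
    interactions = read_interactions(interactions_path)
    ids = sorted(meta)
    elo = elo_ratings(interactions, individuals=ids)
    dyads = dyads_from_cohousing(meta)
    if not dyads:  # no co-housing information: all pairs eligible
        dyads = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    n_obs = {i: 0 for i in ids}
    for event in interactions:
        for who in (event.initiator, event.receiver):
            if who in n_obs:
                n_obs[who] += 1
    observation_time = {i: max(n_obs[i], 1) * FOCAL_MINUTES for i in ids}
    try:
        csi_table = csi(interactions, dyads, observation_time=observation_time)
        csi_raw = {i: csi_table.mean_csi.get(i, 0.0) for i in ids}
    except ValueError:
        logger.warning("indices: no affiliative events at all; CSI set to 0")
        csi_raw = {i: 0.0 for i in ids}
    elo_corr = effort_correct(elo.ratings, n_obs)
    csi_corr = effort_correct(csi_raw, n_obs)
    return pd.DataFrame(
        {
            "individual": ids,
            "elo_raw": [elo.ratings[i] for i in ids],
            "elo_corrected": [elo_corr[i] for i in ids],
            "csi_raw": [csi_raw[i] for i in ids],
            "csi_corrected": [csi_corr[i] for i in ids],
            "n_observations": [n_obs[i] for i in ids],
        }
    )


def report_strong_effects(fit: ModelFit) -> pd.DataFrame:
    """Estimate table with the asterisk convention: CI excluding zero."""
    strong = fit.strong_effects()
    rows = [
        {
            "parameter": term,
            "estimate": point,
            "ci_lower": lo,
            "ci_upper": hi,
            "strong": strong[term],
        }
        for term, (point, se, lo, hi) in fit.estimates.items()
    ]
    return pd.DataFrame(rows)


def _fit_to_dict(fit: ModelFit) -> dict:
    return {
        "form": fit.spec.form,
        "estimates": {k: list(v) for k, v in fit.estimates.items()},
        "variance_components": fit.variance_components,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "n_params": fit.n_params,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
        "estimation_method": fit.estimation_method,
        "converged": fit.converged,
        "scaling": {k: list(v) for k, v in fit.scaling.items()},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written to disk).

    Stages: ingest, segment (+ exclusion audit + per-individual summary),
    social indices, per-subspecies simple fits, complex fits on carrion
    crows with AIC/LRT comparison, predicted curves for the winning model.
    A stage failure raises :class:`PipelineError` naming the stage; the
    artifacts written so far stay on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def persist() -> None:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))

    # --- ingest
    records = ingest_calls(config)
    if not records:
        persist()
        raise PipelineError("ingest: no calls read")
    report["stages"]["ingest"] = {"n_calls": len(records)}
    logger.info("ingest: %d calls", len(records))

    meta_list = read_metadata(config.metadata) if config.metadata else []
    meta = {m.individual_id: m for m in meta_list}

    # --- segment
    sequences = segment_sequences(records, gap_threshold=config.gap_threshold)
    kept, audit = apply_exclusions(sequences)
    summary = dataset_summary(kept, meta or None)
    summary.to_csv(out / "summary.csv", index=False)
    (out / "audit.json").write_text(json.dumps(audit, indent=2))
    n_calls_kept = int(sum(s.length for s in kept))
    report["stages"]["segment"] = {
        "n_sequences_pre_filter": len(sequences),
        "n_sequences_kept": len(kept),
        "n_calls_kept": n_calls_kept,
        "audit": audit,
    }
    logger.info("segment: %d sequences kept (%d calls)", len(kept), n_calls_kept)
    if not kept:
        persist()
        raise PipelineError("segment: no fittable sequences after exclusions")

    # --- indices
    indices = None
    if config.interactions:
        indices = compute_indices(config.interactions, meta)
        indices.to_csv(out / "indices.csv", index=False)
        report["stages"]["indices"] = {"n_individuals": len(indices)}

    # --- model frame
    frame = sequences_to_frame(kept)
    recording_date = (
        _dt.date.fromisoformat(config.recording_date)
        if config.recording_date
        else _dt.date(2012, 1, 1)
    )
    frame = attach_covariates(frame, meta, indices, recording_date)
    frame.to_csv(out / "model_frame.csv", index=False)

    # --- simple fits per subspecies
    simple_rows = []
    simple_fits: dict[str, ModelFit] = {}
    if "eq3" in config.models:
        for subspecies, chunk in frame.groupby("subspecies"):
            if chunk["sequence_id"].nunique() < 3:
                logger.warning("fit: skipping %s (too few sequences)", subspecies)
                continue
            fit = fit_simple(chunk)
            simple_fits[str(subspecies)] = fit
            for _, row in report_strong_effects(fit).iterrows():
                simple_rows.append({"subspecies": subspecies, **row.to_dict()})
        if simple_rows:
            pd.DataFrame(simple_rows).to_csv(out / "simple_fits.csv", index=False)
        report["stages"]["simple_fits"] = {
            sub: _fit_to_dict(fit) for sub, fit in simple_fits.items()
        }

    # --- complex fits on carrion crows
    complex_forms = [m for m in config.models if m in ("eq4", "eq5", "eq6")]
    winner = None
    if complex_forms:
        carrion = frame[frame["subspecies"] == "carrion"]
        if carrion.empty:
            persist()
            raise PipelineError("fit: no carrion-crow calls for the complex models")
        fits = []
        for form in complex_forms:
            fit = fit_complex(carrion, form=form, standardize=config.standardize)
            if not fit.converged:
                logger.warning("fit: %s did not converge", form)
            fits.append(fit)
        comparison = compare_models(fits)
        comparison.to_csv(out / "comparison.csv", index=False)
        winner = fits[int(np.argmin([f.aic for f in fits]))]
        report_strong_effects(winner).to_csv(out / "complex_fit.csv", index=False)
        report["stages"]["complex_fits"] = {
            "comparison": comparison.to_dict(orient="records"),
            "winner": _fit_to_dict(winner),
        }
        # --- predicted curves (plot data for the winning model)
        lengths = np.arange(2, int(frame["length"].max()) + 1)
        curve_rows = []
        for sex in ("F", "M"):
            curves = predict_curves(winner, {"sex": sex}, lengths=lengths)
            curves["profile"] = f"sex={sex}"
            curve_rows.append(curves)
        pd.concat(curve_rows).to_csv(out / "predicted_curves.csv", index=False)

    persist()
    return report
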