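"""End-to-end pipeline: simulate -> score -> analyze -> cluster.

A single configured run materializes the whole analysis: patient and event
tables (simulated or read from disk), the knowledge base, exclusion
filtering, per-patient risk profiles, prevalence tables (overall and
stratified, with rank tests), the summarized-risk-value medication ranking,
and k-modes clustering with descriptives.  Every artifact is written under
one output directory and listed, with SHA-256 checksums, in a run manifest
so that a re-run with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import cohort_builder as cb
from .clustering import describe_clusters, elbow_select, kmodes_fit
from .knowledge_base import KnowledgeBase, RiskCategory, load_kb, reference_fixture, write_kb
from .population_analysis import (
    kruskal_wallis,
    mann_whitney_u,
    prevalence_table,
    stratified_prevalence,
    summarized_risk_values,
    _age_groups_vector,
    AGE_GROUP_LABELS,
)
from .risk_engine import LevelThresholds, compute_profiles, profiles_to_frame
from .synthetic_data import SimulationParams, simulate_dataset

log = logging.getLogger("riskprofile")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    When ``simulate`` is true, patients/events are generated with
    ``sim_params`` and the reference knowledge base (unless ``kb_path`` is
    given); otherwise ``patients_path``/``events_path``/``kb_path`` must
    point at existing files.
    """

    outdir: Path
    simulate: bool = True
    sim_params: SimulationParams = field(default_factory=SimulationParams)
    kb_path: Path | None = None
    patients_path: Path | None = None
    events_path: Path | None = None
    cutoff_date: dt.date = dt.date(2020, 11, 5)
    window_days: int = 120
    source_mode: str = "combined"
    exclude_topical: bool = True
    thresholds: LevelThresholds = field(default_factory=LevelThresholds)
    k_clusters: int | None = None          # None -> elbow selection over k_range
    k_range: tuple[int, int] = (1, 8)
    n_init: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["outdir"] = str(self.outdir)
        doc["cutoff_date"] = self.cutoff_date.isoformat()
        doc["sim_params"]["cutoff_date"] = self.sim_params.cutoff_date.isoformat()
        for key in ("kb_path", "patients_path", "events_path"):
            if doc[key] is not None:
                doc[key] = str(doc[key])
        return doc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    window = cb.ExposureWindow(config.cutoff_date, config.window_days)

    # --- inputs ------------------------------------------------------------
    kb = _load_inputs_kb(config)
    patients, events = _load_inputs_data(config, kb, outdir)
    write_kb(kb, outdir / "kb.json")

    # --- cohort + scoring --------------------------------------------------
    ev, pt, report = _stage("exclusions")(cb.apply_exclusions)(events, patients, window)
    report.to_json(outdir / "exclusion_report.json")
    exposures = _stage("exposure")(cb.build_exposure_lists)(
        ev, window, source_mode=config.source_mode,
        exclude_topical=config.exclude_topical, patient_ids=pt["patient_id"],
    )
    profiles = _stage("scoring")(compute_profiles)(exposures, kb, config.thresholds)
    frame = profiles_to_frame(profiles)
    frame.to_csv(outdir / "profiles.csv", index=False, lineterminator="\n")

    # --- prevalence + tests ------------------------------------------------
    prev = _stage("prevalence")(prevalence_table)(frame)
    prev.to_csv(outdir / "prevalence.csv", lineterminator="\n")

    tests = _stage("tests")(_rank_tests)(frame, pt, config.cutoff_date)
    with open(outdir / "tests.json", "w", encoding="utf-8") as fh:
        json.dump(tests, fh, indent=1)
        fh.write("\n")

    srv_frames = []
    for c in RiskCategory:
        t = summarized_risk_values(frame, exposures, kb, c)
        t.insert(0, "category", c.key)
        t.insert(1, "rank", range(1, len(t) + 1))
        srv_frames.append(t)
    pd.concat(srv_frames, ignore_index=True).to_csv(
        outdir / "srv_top10.csv", index=False, lineterminator="\n"
    )

    # --- clustering ----------------------------------------------------------
    if config.k_clusters is None:
        import numpy as np

        lo, hi = config.k_range
        n_distinct = len(
            np.unique(frame[[f"{c.key}_level" for c in RiskCategory]].to_numpy(), axis=0)
        )
        hi = min(hi, n_distinct)
        chosen_k, costs = _stage("elbow")(elbow_select)(
            frame, range(lo, hi + 1), seed=config.seed, n_init=config.n_init
        )
        pd.DataFrame({"k": list(costs), "cost": list(costs.values())}).to_csv(
            outdir / "cost_curve.csv", index=False, lineterminator="\n"
        )
    else:
        chosen_k = config.k_clusters
    result = _stage("kmodes")(kmodes_fit)(
        frame, chosen_k, seed=config.seed, n_init=config.n_init
    )
    pd.DataFrame(
        {"patient_id": frame["patient_id"], "cluster": result.assignments}
    ).to_csv(outdir / "clusters.csv", index=False, lineterminator="\n")
    modes = pd.DataFrame(result.modes, columns=[c.key for c in RiskCategory])
    modes.insert(0, "cluster", range(result.k))
    modes.to_csv(outdir / "modes.csv", index=False, lineterminator="\n")
    summary = _stage("descriptives")(describe_clusters)(
        result, pt, exposures, frame, config.cutoff_date
    )
    summary.to_csv(outdir / "cluster_summary.csv", index=False, lineterminator="\n")

    # --- manifest ------------------------------------------------------------
    artifacts = sorted(
        p.name for p in outdir.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "chosen_k": int(chosen_k),
        "kmodes_cost": int(result.cost),
        "exclusions": report.__dict__,
        "artifacts": {name: _sha256(outdir / name) for name in artifacts},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest


def _load_inputs_kb(config: RunConfig) -> KnowledgeBase:
    if config.kb_path is not None:
        return load_kb(config.kb_path)
    return reference_fixture()


def _load_inputs_data(config: RunConfig, kb: KnowledgeBase, outdir: Path):
    if config.simulate:
        params = dataclasses.replace(
            config.sim_params, seed=config.seed,
            cutoff_date=config.cutoff_date, window_days=config.window_days,
        )
        patients, events, _ = simulate_dataset(params, kb, outdir=outdir)
        return patients, events
    if config.patients_path is None or config.events_path is None:
        raise PipelineError("stage 'inputs' failed: need patients_path and events_path")
    return (cb.read_patients(config.patients_path), cb.read_events(config.events_path))


def _rank_tests(frame: pd.DataFrame, patients: pd.DataFrame, cutoff_date) -> dict:
    merged = frame.merge(patients[["patient_id", "gender", "birth_date"]],
                         on="patient_id", how="left")
    merged["age_group"] = _age_groups_vector(merged["birth_date"], cutoff_date)
    out: dict[str, dict] = {}
    for c in RiskCategory:
        lv = f"{c.key}_level"
        f = merged.loc[merged["gender"] == "F", lv].to_numpy()
        m = merged.loc[merged["gender"] == "M", lv].to_numpy()
        groups = [merged.loc[merged["age_group"] == g, lv].to_numpy()
                  for g in AGE_GROUP_LABELS]
        entry: dict[str, dict] = {}
        if len(f) and len(m):
            mw = mann_whitney_u(f, m)
            entry["gender_mann_whitney"] = {
                "U": mw.statistic, "z": mw.z, "p": mw.p_value,
                "n": mw.group_sizes, "tie_factor": mw.tie_factor,
                "degenerate": mw.degenerate,
            }
        nonempty = [g for g in groups if len(g)]
        if len(nonempty) >= 2:
            kw = kruskal_wallis(nonempty)
            entry["age_kruskal_wallis"] = {
                "H": kw.statistic, "p": kw.p_value, "n": kw.group_sizes,
                "tie_factor": kw.tie_factor, "degenerate": kw.degenerate,
            }
        out[c.key] = entry
    return out
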