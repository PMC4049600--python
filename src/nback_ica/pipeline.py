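"""Pipeline driver: simulate -> decompose -> regress -> behavior -> stats.

Each stage reads its inputs from, and writes its artifacts to, the
configured output directory, so any contiguous subset of stages can be
re-run.  A MANIFEST.json records completion state; every table carries
the config hash and master seed in header comments.  Stages never
mutate their inputs, and the whole run is deterministic given the
config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import io as nio
from .config import PipelineConfig
from .hrf import basis_set, build_design
from .ica import GroupDataset, run_group_ica, select_components
from .regression import compute_activation_table
from .simulate import (build_schedule_for, generate_behavior,
                       generate_ground_truth, generate_subject_bold)
from .stats import analysis_report
from .task import CONDITIONS

logger = logging.getLogger(__name__)

STAGES = ("simulate", "decompose", "regress", "behavior", "stats")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _manifest_path(out: Path) -> Path:
    return out / "MANIFEST.json"


def _load_manifest(out: Path) -> dict:
    p = _manifest_path(out)
    if p.exists():
        return json.loads(p.read_text())
    return {"completed": []}


def _mark_done(out: Path, stage: str, manifest: dict) -> None:
    if stage not in manifest["completed"]:
        manifest["completed"].append(stage)
    _manifest_path(out).write_text(json.dumps(manifest, indent=2))


def run_pipeline(config: PipelineConfig,
                 stages: list[str] | None = None) -> Path:
    """Execute the requested stages; returns the output directory.

    Raises :class:`StageError` naming the failing stage; artifacts of
    completed stages are kept and recorded in MANIFEST.json.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    stages.sort(key=STAGES.index)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(out)
    cdict = config.to_dict()
    cdict.pop("out_dir", None)   # hash the scientific settings, not paths
    chash = nio.config_hash(cdict)
    seed = config.seed
    sim = dataclasses.replace(config.simulation, seed=seed)
    schedule = build_schedule_for(sim)
    meta = dict(config_hash=chash, seed=seed)

    for stage in stages:
        first = STAGES.index(stage)
        if first > 0 and STAGES[first - 1] not in manifest["completed"]:
            raise StageError(stage, f"requires completed stage "
                             f"{STAGES[first - 1]!r}; run it first")
        logger.info("stage %s starting (config=%s seed=%d)", stage, chash,
                    seed)
        try:
            _run_stage(stage, config, sim, schedule, out, meta)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        _mark_done(out, stage, manifest)
        logger.info("stage %s done", stage)
    return out


def _subject_paths(out: Path, n: int):
    return ([out / f"sub-{i:03d}_bold.nii" for i in range(n)],
            [out / f"sub-{i:03d}_motion.tsv" for i in range(n)])


def _run_stage(stage: str, config: PipelineConfig, sim, schedule, out: Path,
               meta: dict) -> None:
    n_sub = sim.n_subjects
    bold_paths, motion_paths = _subject_paths(out, n_sub)

    if stage == "simulate":
        truth = generate_ground_truth(sim)
        for i in range(n_sub):
            vol, motion = generate_subject_bold(truth, schedule, i, sim)
            nio.write_bold(bold_paths[i], vol, tr=sim.tr_seconds)
            nio.write_motion(motion_paths[i], motion)
        nio.write_table(out / "events.tsv", schedule.to_events_frame(),
                        **meta)
        trials = generate_behavior(sim, truth)
        nio.write_table(out / "behavior.tsv", trials, **meta)
        mask = np.ones(sim.grid_dims, dtype=bool)
        nio.write_mask(out / "mask.nii", mask)
        np.savetxt(out / "truth_source_maps.tsv", truth.source_maps.T,
                   delimiter="\t", fmt="%.8g")
        np.savetxt(out / "truth_amplitudes_2back.tsv",
                   truth.amplitudes[:, :, 2], delimiter="\t", fmt="%.8g")
        pd.DataFrame({"subject": [f"sub-{i:03d}" for i in range(n_sub)],
                      "group": list(sim.subject_groups)}).pipe(
            lambda df: nio.write_table(out / "participants.tsv", df, **meta))

    elif stage == "decompose":
        mask = nio.read_mask(out / "mask.nii")
        vols = []
        for p in bold_paths:
            data, _, _ = nio.read_bold(p, tr_override=sim.tr_seconds)
            vols.append(data)
        dataset = GroupDataset.from_volumes(vols, mask)
        ica_seed = (config.ica.seed if config.ica.seed is not None
                    else config.seed)
        decomp = run_group_ica(dataset, config.ica.n_components,
                               k_subject=config.ica.k_subject,
                               n_runs=config.ica.n_runs, seed=ica_seed,
                               max_sweeps=config.ica.max_sweeps,
                               tol=config.ica.tol)
        nio.write_component_maps(out / "group_maps.nii", decomp.maps, mask)
        np.save(out / "subject_timecourses.npy", decomp.subject_timecourses)
        nio.write_table(out / "stability.tsv", pd.DataFrame({
            "component": np.arange(decomp.n_components),
            "stability": decomp.stability
            if decomp.stability is not None
            else np.full(decomp.n_components, np.nan)}), **meta)
        tc = pd.DataFrame(decomp.timecourses.T,
                          columns=[f"ic{j:02d}" for j in
                                   range(decomp.n_components)])
        nio.write_table(out / "group_timecourses.tsv", tc, **meta)

        # template matching against ground-truth maps when available
        truth_path = out / "truth_source_maps.tsv"
        if truth_path.exists():
            tmpl = np.loadtxt(truth_path, delimiter="\t").T
            templates = {f"source{j}": tmpl[j][mask.ravel()]
                         if tmpl.shape[1] == mask.size else tmpl[j]
                         for j in range(tmpl.shape[0])}
            matches = select_components(decomp, templates, strict=False)
            nio.write_table(out / "component_matches.tsv", pd.DataFrame(
                [(k, v[0] if v[0] is not None else -1, v[1])
                 for k, v in matches.items()],
                columns=["template", "component", "correlation"]), **meta)

    elif stage == "regress":
        sub_tcs = np.load(out / "subject_timecourses.npy")
        basis = basis_set(config.hrf.step,
                          onset_shift=config.hrf.onset_shift,
                          dispersion_increment=config.hrf.dispersion_increment)
        designs = []
        for p in motion_paths:
            motion = nio.read_motion(p)
            designs.append(build_design(
                schedule, motion, basis,
                convolve_motion=config.hrf.convolve_motion))
        participants = nio.read_table(out / "participants.tsv")

        class _D:  # minimal decomposition view for the regression stage
            subject_timecourses = sub_tcs
            n_components = sub_tcs.shape[1]
            subject_ids = tuple(participants["subject"])

        table = compute_activation_table(_D(), designs, basis,
                                         groups=list(participants["group"]))
        nio.write_table(out / "activation.tsv", table.to_frame(), **meta)
        nio.write_table(out / "load_effects.tsv", table.load_effect_frame(),
                        **meta)

    elif stage == "behavior":
        trials = nio.read_behavior(out / "behavior.tsv")
        trials["subject"] = [f"sub-{int(s):03d}" if str(s).isdigit() else s
                             for s in trials["subject"]]
        summary, log = beh.analyze_behavior(
            trials, rule=config.behavior.exclusion_rule)
        nio.write_table(out / "behavior_per_condition.tsv",
                        summary.per_condition, **meta)
        nio.write_table(out / "behavior_per_subject.tsv",
                        summary.per_subject, **meta)
        nio.write_table(out / "exclusions.tsv", log, **meta)

    elif stage == "stats":
        from .regression import ActivationTable
        act = nio.read_table(out / "activation.tsv")
        per_subject = nio.read_table(out / "behavior_per_subject.tsv")
        per_condition = nio.read_table(out / "behavior_per_condition.tsv")
        subjects = list(dict.fromkeys(act["subject"]))
        comps = sorted(act["component"].unique())
        groups = [act[act["subject"] == s]["group"].iloc[0] for s in subjects]
        A = np.empty((len(subjects), len(comps), 3))
        for si, s in enumerate(subjects):
            for ci, comp in enumerate(comps):
                sel = act[(act["subject"] == s) & (act["component"] == comp)]
                for ki, cond in enumerate(CONDITIONS):
                    A[si, ci, ki] = float(
                        sel[sel["condition"] == cond]["activation"].iloc[0])
        table = ActivationTable(
            activation=A, load_effect=A[:, :, 2] - A[:, :, 0],
            residual_variance=np.zeros(A.shape[:2]),
            subject_ids=tuple(subjects), groups=tuple(groups),
            components=tuple(comps))
        summary = beh.BehaviorSummary(per_condition=per_condition,
                                      per_subject=per_subject)
        match_path = out / "component_matches.tsv"
        if match_path.exists():
            matches = nio.read_table(match_path)
            selected = {str(r["template"]): int(r["component"])
                        for _, r in matches.iterrows()
                        if int(r["component"]) >= 0}
        else:
            selected = {f"ic{j}": j for j in comps}
        report = analysis_report(table, summary, selected,
                                 alpha=config.stats.alpha,
                                 holm=config.stats.holm)
        (out / "report.txt").write_text(report.to_text() + "\n",
                                        encoding="utf-8")
        if report.correlations is not None:
            nio.write_table(out / "correlations.tsv", report.correlations,
                            **meta)
    else:  # pragma: no cover
        raise ValueError(stage)
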