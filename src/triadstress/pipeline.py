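"""End-to-end orchestration: simulate (or load) sessions, extract
beat-level physiology, build turns, aggregate status ranks, and run the
statistical layer, writing tidy report tables.

The report mirrors the study's result structure: a table of analyte
means by study, the three-level analyte models (competition, time,
status rank), the status-on-substrate models per study, the
hormone-change models, the ratio proportion summaries, power results,
and the data behind the rank-versus-ratio and lnAA-versus-rank figures.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mlm import DiagonalMLM
from .ppg import (ArtifactAnnotation, SegmentMap, apply_artifacts,
                  detect_beats, metrics_frame, normalize_session,
                  read_waveform)
from .stats import (paired_t_one_tailed, pearson_r, posthoc_power_f,
                    proportion_summary, transform_panel)
from .status import StatusComponents, aggregate_ranks, ranks_frame, tally_ties
from .synthetic import SessionBundle, SimulationConfig, simulate_study
from .turns import build_turns, read_label_track


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    outdir: str = "triadstress_out"
    seed: int = 0
    input_dir: Optional[str] = None  # files mode: directory of session files
    simulation: Dict = field(default_factory=dict)  # SimulationConfig overrides
    min_bpm: float = 40.0
    max_bpm: float = 180.0
    min_turn_s: float = 4.0
    merge_gap_s: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed)
        return SimulationConfig(**kwargs)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# input validation (files mode)
# ---------------------------------------------------------------------------

def validate_inputs(input_dir) -> List[dict]:
    """Schema/invariant checks over a session directory.

    Returns machine-readable findings: dicts with ``severity``
    ("error" | "warning"), ``file`` and ``message`` (plus ``row`` where
    applicable). Missing AA assays produce warnings, not errors — the
    models drop them listwise.
    """
    findings: List[dict] = []
    yamls = sorted(glob.glob(os.path.join(input_dir, "session_*.yaml")))
    if not yamls:
        findings.append({"severity": "error", "file": input_dir,
                         "message": "no session_*.yaml files found"})
        return findings
    for ypath in yamls:
        with open(ypath) as fh:
            meta = yaml.safe_load(fh)
        if len(meta.get("subjects", [])) != 3:
            findings.append({"severity": "error", "file": ypath,
                             "message": "session must list exactly 3 subjects"})
        for sid in meta.get("subjects", []):
            wpath = os.path.join(input_dir, f"waveform_{sid}.csv")
            if not os.path.exists(wpath):
                findings.append({"severity": "error", "file": wpath,
                                 "message": "missing waveform file"})
                continue
            try:
                tr = read_waveform(wpath, subject_id=sid)
                if tr.times[0] < 0:
                    findings.append({"severity": "error", "file": wpath,
                                     "row": 2,
                                     "message": "negative timestamps"})
            except ValueError as exc:
                msg = str(exc)
                row = None
                if " row " in msg:
                    row = int(msg.split(" row ")[1].split()[0])
                findings.append({"severity": "error", "file": wpath,
                                 "row": row, "message": msg})
        spath = os.path.join(input_dir, f"saliva_{meta['triad_id']}.csv")
        if os.path.exists(spath):
            sal = pd.read_csv(spath)
            for col in ("AA_prior", "AA_post"):
                if col in sal.columns and sal[col].isna().any():
                    findings.append({
                        "severity": "warning", "file": spath,
                        "message": f"{col} missing for "
                                   f"{int(sal[col].isna().sum())} subjects "
                                   "(assay not run); rows excluded listwise",
                    })
        else:
            findings.append({"severity": "error", "file": spath,
                             "message": "missing saliva file"})
    return findings


def load_sessions(input_dir) -> List[SessionBundle]:
    """Read back sessions written by :func:`triadstress.synthetic.write_session`."""
    from .turns import TurnTrack

    bundles: List[SessionBundle] = []
    for ypath in sorted(glob.glob(os.path.join(input_dir, "session_*.yaml"))):
        with open(ypath) as fh:
            meta = yaml.safe_load(fh)
        tid = meta["triad_id"]
        subjects = tuple(meta["subjects"])
        seg = SegmentMap(video=tuple(meta["segments"]["video"]),
                         conversation=tuple(meta["segments"]["conversation"]))
        traces = {
            sid: read_waveform(os.path.join(input_dir, f"waveform_{sid}.csv"),
                               subject_id=sid)
            for sid in subjects
        }
        utts = read_label_track(
            os.path.join(input_dir, f"utterances_{tid}.txt"),
            extent=seg.conversation, speakers=subjects)
        saliva = pd.read_csv(os.path.join(input_dir, f"saliva_{tid}.csv"))
        comp = pd.read_csv(os.path.join(input_dir, f"components_{tid}.csv"))
        comps = {
            name: tuple(
                comp[comp.component == name].set_index("member")
                .loc[list(subjects), "rank"]
            )
            for name in comp.component.unique()
        }
        gt = meta.get("ground_truth", {})
        arts = {
            sid: [ArtifactAnnotation(**a) for a in gt.get("artifacts", {}).get(sid, [])]
            for sid in subjects
        }
        bundles.append(SessionBundle(
            tid, int(meta["study"]), subjects, seg, traces, utts,
            TurnTrack([], seg.conversation, speakers=list(subjects)),
            saliva, StatusComponents(tid, subjects, comps), arts, gt))
    return bundles


# ---------------------------------------------------------------------------
# the run itself
# ---------------------------------------------------------------------------

def _analyte_long(panel: pd.DataFrame) -> pd.DataFrame:
    """Long (subject x time) frame for the three-level analyte models."""
    rows = []
    for _, r in panel.iterrows():
        for t, tc in (("prior", -0.5), ("post", 0.5)):
            rows.append({
                "subject": r["subject"], "triad": r["triad"],
                "member_pos": r["member_pos"], "study": r["study"],
                "competition": r["study"] - 1,  # 0 = no reward, 1 = reward
                "time": tc, "rank": r["final_rank"],
                "lnT": r[f"lnT_{t}"], "C": r[f"C_{t}"], "lnAA": r[f"lnAA_{t}"],
                "cell": f"m{int(r['member_pos'])}_{t}",
            })
    return pd.DataFrame(rows)


def _fit_or_none(fn, label, tables):
    from .mlm import ConvergenceError

    try:
        res = fn()
        tables[label] = res.summary().reset_index(names="term")
        return res
    except (ValueError, KeyError, ConvergenceError) as exc:
        tables[label] = pd.DataFrame([{"term": "error", "B": np.nan,
                                       "note": str(exc)}])
        return None


def analyze_sessions(bundles: Sequence[SessionBundle], cfg: RunConfig) -> dict:
    """Run signal -> turns -> status -> stats over loaded/simulated sessions.

    Returns a dict of tidy DataFrames plus scalar summaries.
    """
    metrics_rows = []
    rank_objs = []
    panels = []
    for bundle in bundles:
        turn_track = build_turns(bundle.utterances, min_turn_s=cfg.min_turn_s,
                                 merge_gap_s=cfg.merge_gap_s)
        ranks = aggregate_ranks(bundle.components)
        rank_objs.append(ranks)
        rank_map = ranks.as_dict()
        for pos, sid in enumerate(bundle.subjects, start=1):
            beats = detect_beats(bundle.traces[sid], cfg.min_bpm, cfg.max_bpm)
            beats = apply_artifacts(beats, bundle.artifacts.get(sid, []))
            m = normalize_session(beats, bundle.segments, turn_track, sid)
            row = m.to_dict()
            row.update(triad=bundle.triad_id, study=bundle.study,
                       member_pos=pos, final_rank=rank_map[sid])
            metrics_rows.append(row)
        sal = bundle.saliva.copy()
        sal["member_pos"] = np.arange(1, len(sal) + 1)
        sal["final_rank"] = [rank_map[s] for s in sal["subject"]]
        panels.append(sal)

    metrics = pd.DataFrame(metrics_rows)
    panel = transform_panel(pd.concat(panels, ignore_index=True))
    panel["lnT_mean_c"] = panel["lnT_mean"]
    status_table = ranks_frame(rank_objs)
    n_tie, n_pairs = tally_ties(rank_objs)

    tables: Dict[str, pd.DataFrame] = {
        "metrics": metrics,
        "status_ranks": status_table,
        "saliva_panel": panel,
    }
    scalars: Dict[str, float] = {
        "n_triads": len(bundles),
        "n_subjects": int(metrics.shape[0]),
        "tie_pairs": n_tie,
        "possible_pairs": n_pairs,
    }

    # --- real-time stress summaries -----------------------------------
    t, df, p = paired_t_one_tailed(metrics["bpm_conversation"],
                                   metrics["bpm_video"], "greater")
    scalars.update(bpm_video_mean=float(metrics["bpm_video"].mean()),
                   bpm_conversation_mean=float(metrics["bpm_conversation"].mean()),
                   bpm_conv_gt_video_t=t, bpm_conv_gt_video_p=p)
    t, df, p = paired_t_one_tailed(metrics["tbv_conv_video_ratio"],
                                   np.ones(len(metrics)), "less")
    scalars.update(tbv_conv_video_ratio_mean=float(
        metrics["tbv_conv_video_ratio"].mean()),
        tbv_conv_lt_video_p=p)
    sl = metrics["tbv_speak_listen_ratio"].dropna()
    pl = metrics["bpm_speak_listen_ratio"].dropna()
    scalars.update(
        tbv_speak_listen_ratio_mean=float(sl.mean()) if sl.size else np.nan,
        bpm_speak_listen_ratio_mean=float(pl.mean()) if pl.size else np.nan,
    )
    tables["proportions"] = proportion_summary(metrics)

    # --- analyte descriptives (study-by-analyte means) ----------------
    desc = (
        panel.groupby("study")[["lnT_prior", "lnT_post", "C_prior", "C_post",
                                "lnAA_prior", "lnAA_post"]]
        .agg(["mean", "count"])
    )
    tables["analyte_means"] = desc
    for var, col in (("lnT", "lnT"), ("C", "C"), ("lnAA", "lnAA")):
        try:
            scalars[f"{var}_prior_post_r"] = pearson_r(
                panel[f"{col}_prior"], panel[f"{col}_post"])
        except ValueError:
            scalars[f"{var}_prior_post_r"] = np.nan
    scalars["T_mean_pg_ml"] = float(
        pd.concat([panel["T_prior"], panel["T_post"]]).mean())

    # --- three-level analyte models -----------------------------------
    long = _analyte_long(panel)
    spec_predictors = ["competition", "time", "rank"]
    spec_inter = [("competition", "time"), ("competition", "rank"),
                  ("time", "rank"), ("time", "rank", "competition")]
    fits = {}
    for outcome in ("lnT", "C", "lnAA"):
        fits[outcome] = _fit_or_none(
            lambda o=outcome: DiagonalMLM.from_dataframe(
                long, o, spec_predictors, spec_inter,
                repeated="cell", groups="triad").fit(),
            f"analyte_model_{outcome}", tables)
    if fits.get("lnAA") is not None:
        scalars["status_rank_lnaa_B"] = float(
            fits["lnAA"].params["rank"])
        scalars["status_rank_lnaa_p"] = float(
            fits["lnAA"].pvalues["rank"])

    # --- status-on-substrate models per study -------------------------
    for study in sorted(panel["study"].unique()):
        sub = panel[panel.study == study]
        _fit_or_none(
            lambda s=sub: DiagonalMLM.from_dataframe(
                s, "final_rank", ["lnT_mean", "C_mean"],
                [("lnT_mean", "C_mean")],
                repeated="member_pos", groups="triad").fit(),
            f"status_model_TxC_study{study}", tables)
        _fit_or_none(
            lambda s=sub: DiagonalMLM.from_dataframe(
                s, "final_rank", ["lnT_mean", "lnAA_mean"],
                [("lnT_mean", "lnAA_mean")],
                repeated="member_pos", groups="triad").fit(),
            f"status_model_TxAA_study{study}", tables)
        for change in ("lnT_change", "C_change", "lnAA_change"):
            _fit_or_none(
                lambda s=sub, c=change: DiagonalMLM.from_dataframe(
                    s, "final_rank", [c],
                    repeated="member_pos", groups="triad").fit(),
                f"change_model_{change}_study{study}", tables)

    # --- power ---------------------------------------------------------
    power_rows = []
    for r2, n in ((0.22, 30), (0.51, 15), (0.09, 15), (0.34, 15)):
        pr = posthoc_power_f(r2, n, 3)
        power_rows.append(dataclasses.asdict(pr))
    tables["power"] = pd.DataFrame(power_rows)

    # --- figure data ----------------------------------------------------
    tables["fig_rank_vs_ratios"] = metrics[
        ["triad", "study", "subject_id", "final_rank",
         "tbv_speak_listen_ratio", "bpm_speak_listen_ratio"]
    ].copy()
    tables["fig_lnaa_vs_rank"] = panel[
        ["triad", "study", "subject", "final_rank", "lnAA_mean"]
    ].dropna().copy()

    return {"tables": tables, "scalars": scalars}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a full run and write the report bundle to ``cfg.outdir``.

    Any stage failure raises :class:`PipelineError` naming the stage;
    partial outputs already written are retained.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    try:
        if cfg.mode == "synthetic":
            bundles = simulate_study(cfg.simulation_config())
        elif cfg.mode == "files":
            if not cfg.input_dir:
                raise ValueError("files mode requires input_dir")
            findings = validate_inputs(cfg.input_dir)
            errs = [f for f in findings if f["severity"] == "error"]
            with open(os.path.join(cfg.outdir, "validation.json"), "w") as fh:
                json.dump(findings, fh, indent=1)
            if errs:
                raise ValueError(f"input validation failed: {errs[:3]}")
            bundles = load_sessions(cfg.input_dir)
        else:
            raise ValueError(f"unknown mode {cfg.mode!r}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    try:
        report = analyze_sessions(bundles, cfg)
    except Exception as exc:
        raise PipelineError("analysis", exc) from exc

    try:
        for name, tab in report["tables"].items():
            tab.to_csv(os.path.join(cfg.outdir, f"{name}.csv"),
                       float_format="%.6g")
        with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
            json.dump({k: (None if isinstance(v, float) and not np.isfinite(v)
                           else v)
                       for k, v in report["scalars"].items()}, fh, indent=1)
        log = {
            "package_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": cfg.seed,
            "config": dataclasses.asdict(cfg),
        }
        with open(os.path.join(cfg.outdir, "run_log.yaml"), "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=True)
    except Exception as exc:
        raise PipelineError("report", exc) from exc
    return report
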