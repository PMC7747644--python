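"""Trial-to-results orchestration and cohort summaries.

Per trial: markers -> segmental xCoM kinematics -> relative chain
variables -> phase segmentation -> per-phase, per-direction UCM
decomposition.  Results are tidy long-format tables; cohort summaries
average trials within subject first, then report group means with
standard errors across subjects.  Inferential statistics are deliberately
not implemented — the summary CSV is the hand-off point to statistics
software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .body_model import (
    BodyModel,
    FilterConfig,
    compute_kinematics,
    load_default_model,
    load_model,
)
from .chain_vars import decompose, reference_subtract
from .marker_io import MarkerTrial, read_trial
from .phase_events import PhaseSegmentation, segment_trial
from .ucm_synergy import UcmResult, analyze_deviations, build_jacobian, null_space_basis

logger = logging.getLogger("ucmbalance")

DIRECTIONS = ("AP", "ML")


@dataclass
class RunConfig:
    """One pipeline run: which trials, which model, which thresholds."""

    manifest: list[dict] = field(default_factory=list)
    body_model_path: str | None = None
    filter: FilterConfig = field(default_factory=lambda: FilterConfig(enabled=True))
    height_tol: float = 0.01       # m, foot-contact height window
    velocity_tol: float = 0.05     # m/s, foot-contact vertical-speed limit
    gravity: float = 9.81          # m/s^2
    directions: tuple[str, ...] = DIRECTIONS
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.manifest:
            raise ValueError("manifest must list at least one trial")
        for entry in self.manifest:
            if "path" not in entry:
                raise ValueError(f"manifest entry without 'path': {entry}")
        bad = set(self.directions) - set(DIRECTIONS)
        if bad:
            raise ValueError(f"unknown directions {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = raw.pop("filter", None)
        cfg = cls(**raw)
        if filt is not None:
            cfg.filter = FilterConfig(**filt)
        return cfg

    def log_values(self) -> dict[str, object]:
        """Every configurable value actually used, for the audit log."""
        return {
            "body_model_path": self.body_model_path or "<bundled female table>",
            "filter.enabled": self.filter.enabled,
            "filter.cutoff_hz": self.filter.cutoff_hz,
            "filter.order": self.filter.order,
            "height_tol": self.height_tol,
            "velocity_tol": self.velocity_tol,
            "gravity": self.gravity,
            "directions": ",".join(self.directions),
            "seed": self.seed,
            "n_trials": len(self.manifest),
        }


def run_trial(
    trial: MarkerTrial,
    model: BodyModel,
    filter_cfg: FilterConfig | None = None,
    height_tol: float = 0.01,
    velocity_tol: float = 0.05,
    gravity: float = 9.81,
    directions: tuple[str, ...] = DIRECTIONS,
    trial_id: str = "trial",
) -> tuple[PhaseSegmentation, dict[tuple[str, str], UcmResult], pd.DataFrame]:
    """Full UCM analysis of one trial.

    Returns the phase segmentation, the per-(phase, direction) results, and
    the tidy long-format table (one row per segment plus a TOTAL row whose
    ``imsd_*``/``isyn`` columns carry the whole-body MSDs and SYN).
    """
    kin = compute_kinematics(trial, model, filter_cfg, g=gravity)
    seg = segment_trial(
        trial, model, kin.xcom[:, 0],
        height_tol=height_tol, velocity_tol=velocity_tol,
    )
    jac = build_jacobian(model)
    basis = null_space_basis(jac)
    rel = decompose(kin.ixcom, model)

    results: dict[tuple[str, str], UcmResult] = {}
    rows: list[dict] = []
    windows = {"I": (seg.phase1, seg.onset), "II": (seg.phase2, seg.bos_crossing)}
    for phase, ((start, stop), ref) in windows.items():
        referenced = reference_subtract(rel, ref)
        for direction in directions:
            k = DIRECTIONS.index(direction)
            dev = referenced.irxcom[start:stop, :, k]
            res = analyze_deviations(dev, jac, basis=basis)
            results[(phase, direction)] = res
            base = {
                "subject": trial.subject_id,
                "group": trial.group_label,
                "trial": trial_id,
                "phase": phase,
                "direction": direction,
            }
            for i, segment in enumerate(model.segments):
                rows.append({
                    **base,
                    "segment": segment,
                    "imsd_tir": res.imsd_tir[i],
                    "imsd_tr": res.imsd_tr[i],
                    "isyn": res.isyn[i],
                })
            rows.append({
                **base,
                "segment": "TOTAL",
                "imsd_tir": res.msd_tir,
                "imsd_tr": res.msd_tr,
                "isyn": res.syn,
            })
    return seg, results, pd.DataFrame(rows)


def summarize_groups(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Group means and standard errors, averaging within subject first.

    One row per group x phase x direction x segment; the standard error is
    across subjects (NaN when a group has a single subject).
    """
    if per_trial.empty:
        raise ValueError("empty per-trial results table")
    keys = ["group", "phase", "direction", "segment"]
    values = ["imsd_tir", "imsd_tr", "isyn"]
    subject_means = (
        per_trial.groupby(keys + ["subject"], sort=True)[values].mean().reset_index()
    )
    grouped = subject_means.groupby(keys, sort=True)[values]
    mean = grouped.mean()
    n = grouped.size().rename("n_subjects")
    sem = grouped.sem(ddof=1)  # NaN for n = 1
    out = mean.join(sem, lsuffix="_mean", rsuffix="_se").join(n).reset_index()
    return out


def run_pipeline(config: RunConfig) -> int:
    """Run every manifest trial and write results, summary and audit log.

    Exit status: 0 if all trials succeeded, 2 on partial failures, 1 if
    every trial failed.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = (
        load_model(config.body_model_path)
        if config.body_model_path
        else load_default_model()
    )
    log_lines = [f"config.{k}={v}" for k, v in config.log_values().items()]

    frames: list[pd.DataFrame] = []
    failures = 0
    for i, entry in enumerate(config.manifest):
        path = entry["path"]
        trial_id = str(entry.get("trial", Path(path).stem))
        try:
            trial = read_trial(path, format=entry.get("format", "csv"))
            if "group" in entry:
                trial.group_label = str(entry["group"])
            if "subject" in entry:
                trial.subject_id = str(entry["subject"])
            seg, _, df = run_trial(
                trial, model,
                filter_cfg=config.filter,
                height_tol=config.height_tol,
                velocity_tol=config.velocity_tol,
                gravity=config.gravity,
                directions=tuple(config.directions),
                trial_id=trial_id,
            )
            frames.append(df)
            log_lines += [
                f"trial.{trial_id}.onset={seg.onset}",
                f"trial.{trial_id}.bos_crossing={seg.bos_crossing}",
                f"trial.{trial_id}.foot_contact={seg.foot_contact}",
                f"trial.{trial_id}.stepping_side={seg.stepping_side}",
                f"trial.{trial_id}.toe_tip_ap={seg.toe_tip_ap!r}",
            ]
        except Exception as exc:  # noqa: BLE001 - per-trial isolation
            failures += 1
            logger.error("trial %s failed: %s", path, exc)
            log_lines.append(f"trial.{trial_id}.error={exc}")

    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    if not frames:
        return 1
    per_trial = pd.concat(frames, ignore_index=True)
    per_trial.to_csv(out_dir / "results_per_trial.csv", index=False)
    summarize_groups(per_trial).to_csv(out_dir / "summary_by_group.csv", index=False)
    return 2 if failures else 0
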