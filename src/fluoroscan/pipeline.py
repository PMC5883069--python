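"""End-to-end orchestration: simulate -> segment -> indicators -> diagnose.

One run produces, per day, a plant mask, the three indicator maps (as
pseudo-color PNGs), tidy summary rows, and finally a diagnosis report.
Identical configuration and seed give byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import scene as sc
from .diagnosis import (
    NormalRanges,
    RuleConfig,
    StressDiagnosis,
    Trajectory,
    classify_stress,
    patchiness_score,
)
from .frame_io import FrameStack, read_stack
from .indicators import (
    compute_fvfm,
    compute_phipsii,
    compute_ratio_550_510,
    render_pseudocolor,
    summarize,
)
from .segmentation import (
    DEFAULT_MIN_COMPONENT_AREA,
    clean_mask,
    segment_fluorescence_threshold,
    segment_kmeans,
)

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "day", "position", "plant_id", "indicator",
    "mean", "std", "median", "q1", "q3", "min", "max", "n_pixels",
]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one monitoring run."""

    out_dir: str = "fluoroscan_run"
    input_dir: str | None = None  # read stacks here instead of simulating
    stress: str = "none"
    days: int = 9
    seed: int = 42
    method: str = "threshold"  # or "kmeans"
    min_component_area: int = DEFAULT_MIN_COMPONENT_AREA
    write_images: bool = True
    per_plant: bool = False  # additionally summarize each plant label
    ranges: NormalRanges = field(default_factory=NormalRanges)
    rules: RuleConfig = field(default_factory=RuleConfig)
    log_level: str = "INFO"

    _KNOWN = None  # populated below

    @classmethod
    def from_mapping(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(d)
        if "ranges" in kwargs and isinstance(kwargs["ranges"], dict):
            kwargs["ranges"] = NormalRanges(**kwargs["ranges"])
        if "rules" in kwargs and isinstance(kwargs["rules"], dict):
            kwargs["rules"] = RuleConfig(**kwargs["rules"])
        return cls(**kwargs)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _segment(stack: FrameStack, config: PipelineConfig):
    if config.method == "threshold":
        mask = segment_fluorescence_threshold(stack["Fm"])
    elif config.method == "kmeans":
        mask = segment_kmeans(stack["R510"], stack["R550"], seed=config.seed)
    else:
        raise ValueError(f"unknown segmentation method {config.method!r}")
    return clean_mask(mask, config.min_component_area)


def analyze_stack(
    stack: FrameStack, config: PipelineConfig, plant_labels: np.ndarray | None = None
):
    """Segment one acquisition and compute its three indicator maps.

    Returns (mask, {indicator: IndicatorMap}, patchiness, summary rows).
    """
    day = stack.metadata.day
    try:
        mask = _segment(stack, config)
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError("segment", f"day {day}: {e}") from e
    try:
        maps = {
            "fvfm": compute_fvfm(stack["Fo"], stack["Fm"], mask),
            "phipsii": compute_phipsii(stack["F"], stack["Fm_prime"], mask),
            "r550_510": compute_ratio_550_510(stack["R550"], stack["R510"], mask),
        }
        patch = patchiness_score(maps["fvfm"], config.rules.impairment_threshold)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("indicators", f"day {day}: {e}") from e

    rows = []
    pos = list(stack.metadata.position)
    for name, imap in maps.items():
        s = summarize(imap, day=day)
        rows.append([day, f"{pos[0]},{pos[1]}", "all", name,
                     s.mean, s.std, s.median, s.q1, s.q3, s.min, s.max, s.n_pixels])
        if config.per_plant and plant_labels is not None:
            for pid in np.unique(plant_labels[plant_labels > 0]):
                sub = imap.values.copy()
                sub[plant_labels != pid] = np.nan
                sel = np.isfinite(sub)
                if not sel.any():
                    continue
                vals = sub[sel]
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                rows.append([day, f"{pos[0]},{pos[1]}", str(int(pid)), name,
                             float(vals.mean()), float(vals.std()), float(med),
                             float(q1), float(q3), float(vals.min()),
                             float(vals.max()), int(vals.size)])
    return mask, maps, patch, rows


def analyze_series(
    stacks: list[FrameStack],
    config: PipelineConfig,
    truths: list | None = None,
) -> tuple[pd.DataFrame, list[float]]:
    """Segment + compute indicators for a day series of stacks.

    Returns the tidy summary table and the per-day patchiness scores.
    """
    if truths is None:
        truths = [None] * len(stacks)
    rows, patchiness = [], []
    for stack, truth in zip(stacks, truths):
        labels = truth.plant_id if (truth is not None and config.per_plant) else None
        _, _, patch, r = analyze_stack(stack, config, labels)
        rows.extend(r)
        patchiness.append(patch)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS), patchiness


def trajectory_from_summaries(df: pd.DataFrame) -> Trajectory:
    """Build a Trajectory from pooled ('all') rows of a tidy summary table."""
    from .indicators import IndicatorSummary

    pooled = df[df["plant_id"].astype(str) == "all"]
    days = sorted(pooled["day"].unique())
    summaries: dict[str, list] = {"fvfm": [], "phipsii": [], "r550_510": []}
    for day in days:
        sub = pooled[pooled["day"] == day]
        for name in summaries:
            row = sub[sub["indicator"] == name]
            if row.empty:
                raise ValueError(f"day {day} missing indicator {name}")
            r = row.iloc[0]
            summaries[name].append(
                IndicatorSummary(
                    indicator=name, mean=r["mean"], std=r["std"], median=r["median"],
                    q1=r["q1"], q3=r["q3"], min=r["min"], max=r["max"],
                    n_pixels=int(r["n_pixels"]), day=int(day),
                )
            )
    return Trajectory(days=[int(d) for d in days], summaries=summaries)


def run_pipeline(config: PipelineConfig) -> StressDiagnosis:
    """Run the full monitoring pipeline; returns the final diagnosis.

    Outputs under ``config.out_dir``: ``config.json`` (effective config
    echo), ``stacks/`` (when simulating), ``maps/`` (pseudo-color PNGs),
    ``summaries.csv``, ``diagnosis.json`` and ``run.log``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("fluoroscan")
    root.addHandler(handler)
    try:
        (out_dir / "config.json").write_text(
            json.dumps(config.echo(), indent=2, sort_keys=True, default=str) + "\n"
        )
        if config.input_dir is not None:
            stack_dir = Path(config.input_dir)
            paths = sorted(stack_dir.glob("day_*.tif"))
            if not paths:
                raise FileNotFoundError(f"no day_*.tif stacks under {stack_dir}")
            stacks = [read_stack(p) for p in paths]
            truths = [None] * len(stacks)
        else:
            spec = sc.SceneSpec()
            model = sc.StressModel(stress_type=config.stress, day_range=(1, config.days))
            pairs = sc.generate_dataset(
                spec, model, sc.ImagingModel(),
                days=list(range(1, config.days + 1)),
                seed=config.seed, out_dir=out_dir / "stacks",
            )
            stacks = [p[0] for p in pairs]
            truths = [p[1] for p in pairs]

        all_rows, patchiness = [], []
        maps_dir = out_dir / "maps"
        for stack, truth in zip(stacks, truths):
            labels = truth.plant_id if (truth is not None and config.per_plant) else None
            mask, maps, patch, rows = analyze_stack(stack, config, labels)
            logger.info(
                "day %d: %d plant pixels, patchiness %.3f",
                stack.metadata.day, mask.n_plant_pixels, patch,
            )
            patchiness.append(patch)
            all_rows.extend(rows)
            if config.write_images:
                maps_dir.mkdir(exist_ok=True)
                for name, imap in maps.items():
                    render_pseudocolor(
                        imap, maps_dir / f"day_{stack.metadata.day:02d}_{name}.png"
                    )

        df = pd.DataFrame(all_rows, columns=SUMMARY_COLUMNS)
        df.to_csv(out_dir / "summaries.csv", index=False, float_format="%.6f")

        traj = trajectory_from_summaries(df)
        diag = classify_stress(traj, patchiness, config.ranges, config.rules)
        report = {
            "label": diag.label,
            "confidence": diag.confidence,
            "evidence": diag.evidence,
            "thresholds": diag.thresholds,
            "per_day": [
                {
                    "day": int(d),
                    "patchiness": round(p, 6),
                    "means": {
                        name: round(traj.summaries[name][i].mean, 6)
                        for name in traj.summaries
                    },
                }
                for i, (d, p) in enumerate(zip(traj.days, patchiness))
            ],
        }
        (out_dir / "diagnosis.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        return diag
    finally:
        root.removeHandler(handler)
        handler.close()
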