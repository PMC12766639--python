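"""End-to-end experiment runner.

One :class:`RunConfig` drives simulate -> ingest/align -> feature extraction
-> grouped cross-validation -> sleep summaries -> agreement reports for every
(model family x HR-variant) cell, mirroring the device-agnostic evaluation
design. A single master seed fans out deterministically to every stage, and
the run directory carries a checksum manifest so reruns with an identical
config are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (bland_altman, confusion, discrepancy, ebe_metrics,
                        group_discrepancy, group_ebe)
from .exceptions import PipelineError
from .features import extract_cohort
from .metrics import derive_summary
from .models import ModelConfig, cross_validate
from .simulate import simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable description of one full experiment."""

    seed: int = 0
    n_subjects: int = 12
    night_len_epochs: int | tuple[int, int] = (900, 1020)
    device_profile: str = "garmin"
    task: str = "binary"
    families: tuple[str, ...] = ("logistic", "random_forest", "lstm")
    include_hr_variants: tuple[bool, ...] = (True, False)
    folds: int = 10
    out_dir: str = "runs"
    hyperparameters: dict = field(default_factory=dict)  # per-family overrides
    version: str = __version__

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        # the output location is not part of the experiment's identity:
        # keeping it out makes rerun manifests comparable across directories
        d.pop("out_dir")
        d["night_len_epochs"] = (
            list(self.night_len_epochs)
            if isinstance(self.night_len_epochs, tuple)
            else self.night_len_epochs
        )
        d["families"] = list(self.families)
        d["include_hr_variants"] = list(self.include_hr_variants)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if isinstance(d.get("night_len_epochs"), list):
            d["night_len_epochs"] = tuple(d["night_len_epochs"])
        for key in ("families", "include_hr_variants"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)


def _jsonable(obj):
    """Recursively convert to JSON-safe values (NaN -> null, numpy -> py)."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _cell_report(pred: pd.DataFrame, task: str) -> dict:
    """Agreement report of one (family x HR) cell from out-of-fold predictions."""
    classes = ("wake", "sleep") if task == "binary" else ("wake", "light", "deep", "rem")
    ebe_list, disc_list = [], []
    tst_dev, tst_psg = [], []
    for pid, g in pred.groupby("participant_id", sort=True):
        g = g.sort_values("epoch_index")
        cm = confusion(g["pred"].to_numpy(), g["true"].to_numpy(), classes,
                       participant_id=str(pid))
        ebe_list.append(ebe_metrics(cm))
        dev = derive_summary(g["pred"].to_numpy(), participant_id=str(pid))
        psg = derive_summary(g["true"].to_numpy(), participant_id=str(pid))
        disc_list.append(discrepancy(dev, psg))
        tst_dev.append(dev.TST)
        tst_psg.append(psg.TST)
    ebe_tab = group_ebe(ebe_list)
    disc_tab = group_discrepancy(disc_list)
    ba = bland_altman(tst_dev, tst_psg)
    return {
        "n_participants": int(pred["participant_id"].nunique()),
        "n_epochs_compared": int(len(pred)),
        "ebe": _jsonable(ebe_tab.to_dict(orient="index")),
        "discrepancy": _jsonable(disc_tab.to_dict(orient="index")),
        "bland_altman_tst": _jsonable(dataclasses.asdict(ba)),
    }


def run_experiment(config: RunConfig) -> Path:
    """Run the full pipeline; returns the run directory.

    Writes, per (family x include_hr) cell, out-of-fold predictions, per-night
    sleep summaries and an agreement report, plus a manifest of SHA-256
    checksums over every artifact. Any stage failure aborts with a
    stage-named error after writing the partial manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: list[dict] = []

    def log(stage: str, **kv):
        run_log.append({"stage": stage, **kv})

    try:
        cohort = simulate_cohort(
            n_subjects=config.n_subjects,
            night_len_epochs=config.night_len_epochs,
            device_profiles=(config.device_profile,),
            seed=config.seed,
        )
        log("simulate", n_subjects=config.n_subjects,
            profile=config.device_profile)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    try:
        feats, seqs = extract_cohort(cohort)
        n_total = sum(n.hypnogram.n_epochs for n in cohort.nights)
        n_valid = len(feats.df)
        log("extract", n_epochs=n_total, n_valid=n_valid,
            n_dropped=n_total - n_valid)
    except Exception as exc:
        raise PipelineError("extract", str(exc)) from exc

    config.to_yaml(out / "config.yaml")
    artifacts = [out / "config.yaml"]
    try:
        for family in config.families:
            for include_hr in config.include_hr_variants:
                cell = f"{family}_{'hr' if include_hr else 'nohr'}"
                hp = dict(config.hyperparameters.get(family, {}))
                mc = ModelConfig(family=family, task=config.task,
                                 include_hr=include_hr,
                                 hyperparameters=hp, seed=config.seed)
                data = seqs if family == "lstm" else feats
                cv = cross_validate(data, mc, k=config.folds, seed=config.seed)
                pred_path = out / f"predictions_{cell}.csv"
                cv.predictions.to_csv(pred_path, index=False)
                artifacts.append(pred_path)

                summaries = []
                for pid, g in cv.predictions.groupby("participant_id", sort=True):
                    g = g.sort_values("epoch_index")
                    for source, col in (("device", "pred"), ("psg", "true")):
                        s = derive_summary(g[col].to_numpy(), participant_id=str(pid))
                        row = {"participant": str(pid), "source": source,
                               "TST": s.TST, "SE": s.SE, "SOL": s.SOL,
                               "WASO": s.WASO, "light": s.light,
                               "deep": s.deep, "rem": s.rem}
                        summaries.append(row)
                sum_path = out / f"summaries_{cell}.csv"
                pd.DataFrame(summaries).to_csv(sum_path, index=False)
                artifacts.append(sum_path)

                report = _cell_report(cv.predictions, config.task)
                report["cell"] = cell
                report["chosen_params"] = _jsonable(cv.chosen_params)
                rep_path = out / f"agreement_{cell}.json"
                rep_path.write_text(json.dumps(report, sort_keys=True, indent=1))
                artifacts.append(rep_path)
                log("evaluate", cell=cell,
                    accuracy=round(cv.accuracy(), 6))
    except PipelineError:
        raise
    except Exception as exc:
        _write_manifest(out, artifacts, run_log)
        raise PipelineError("model", str(exc)) from exc

    _write_manifest(out, artifacts, run_log)
    return out


def _write_manifest(out: Path, artifacts: list[Path], run_log: list[dict]) -> None:
    log_path = out / "run.log"
    with open(log_path, "w") as fh:
        for rec in run_log:
            fh.write(json.dumps(_jsonable(rec), sort_keys=True) + "\n")
    manifest = {}
    for p in artifacts + [log_path]:
        if p.exists():
            manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
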