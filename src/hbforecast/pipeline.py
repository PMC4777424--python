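"""End-to-end pipeline: simulate -> build records -> train -> evaluate.

One global seed deterministically derives the per-stage seeds, so a config
plus seed pins every artifact bit-for-bit (cohort CSVs, records CSV, model
JSON, report JSON).  Each stage is also runnable standalone through the
library or CLI with identical results.  On a stage failure the partial
artifacts are moved into a ``failed-<stage>`` subdirectory and the error is
re-raised with the failing stage named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .evaluation import evaluate, save_report
from .model import Hyperparams, SplitSpec, predict, train
from .records import apply_inclusion_criteria, build_records, save_records
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("hbforecast")


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    hyper: Hyperparams = field(default_factory=Hyperparams)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.sim.validate()
        self.split.validate()
        self.hyper.validate()

    def stage_seeds(self) -> dict:
        """Derive all stage seeds (< 2**31) from the one global seed."""
        state = np.random.SeedSequence(self.seed).generate_state(3)
        return {
            "sim": int(state[0] % (2 ** 31)),
            "split": int(state[1] % (2 ** 31)),
            "train": int(state[2] % (2 ** 31)),
        }

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("target_band", "modality_fracs", "access_fracs", "quarterly_analytes"):
            d["sim"][key] = list(d["sim"][key])
        d["hyper"]["hidden"] = list(d["hyper"]["hidden"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        sim = SimulationConfig.from_json(json.dumps(d.get("sim", {})))
        split = SplitSpec(**d.get("split", {}))
        hyper_d = dict(d.get("hyper", {}))
        if "hidden" in hyper_d:
            hyper_d["hidden"] = tuple(hyper_d["hidden"])
        hyper = Hyperparams(**hyper_d)
        return cls(sim=sim, split=split, hyper=hyper,
                   seed=d.get("seed", 0), log_level=d.get("log_level", "INFO"))


def _quarantine(out_dir: Path, produced: list, stage: str) -> None:
    failed = out_dir / f"failed-{stage}"
    failed.mkdir(parents=True, exist_ok=True)
    for path in produced:
        path = Path(path)
        if path.exists():
            shutil.move(str(path), str(failed / path.name))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full chain into ``out_dir``; returns the artifact paths.

    Raises the underlying exception on any stage failure after quarantining
    the partial outputs under ``failed-<stage>/``.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    cfg_text = config.to_json()
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    log.info("hbforecast %s | config sha256:%s | seed %d", __version__, cfg_hash, config.seed)
    (out_dir / "pipeline_config.json").write_text(cfg_text + "\n")

    seeds = config.stage_seeds()
    produced: list[Path] = [out_dir / "pipeline_config.json"]
    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(config.sim, seed=seeds["sim"])
        cohort = simulate_cohort(sim_cfg)
        cohort.save(out_dir / "cohort")
        produced.append(out_dir / "cohort")
        log.info("simulate: %d patients, %d dose rows, %d lab rows",
                 len(cohort.profiles), len(cohort.doses), len(cohort.labs))

        stage = "build-records"
        kept, inc_report = apply_inclusion_criteria(cohort.profiles, cohort.doses)
        records = build_records(cohort, kept)
        save_records(records, out_dir / "records.csv")
        (out_dir / "inclusion_report.json").write_text(inc_report.to_json() + "\n")
        produced += [out_dir / "records.csv", out_dir / "inclusion_report.json"]
        n_valid = int(records["valid"].sum())
        log.info("build-records: %d kept patients, %d records (%d valid)",
                 len(kept), len(records), n_valid)

        stage = "train"
        split = dataclasses.replace(config.split, seed=seeds["split"])
        model = train(records, split, config.hyper, seed=seeds["train"])
        model.save(out_dir / "model.json")
        produced.append(out_dir / "model.json")
        log.info("train: %d/%d records, %d epochs, train MSE %.4f",
                 model.metadata["n_train"], model.metadata["n_test"],
                 model.metadata["epochs_run"], model.metadata["final_train_loss"])

        stage = "predict"
        valid = records[records["valid"].astype(bool)]
        preds = predict(model, valid)
        preds.to_csv(out_dir / "predictions.csv", index=False)
        produced.append(out_dir / "predictions.csv")

        stage = "evaluate"
        report = evaluate(model, records, cohort.events)
        save_report(report, out_dir / "report.json")
        produced.append(out_dir / "report.json")
        log.info("evaluate: test MAE %.3f g/dL, %.0f%% within +/-1.5",
                 report["test"]["metrics"]["mae"],
                 100 * report["test"]["metrics"]["frac_within_1p5"])

        stage = "plots"
        from .plots import plot_bland_altman, plot_error_histogram
        plots_dir = out_dir / "plots"
        plots_dir.mkdir(exist_ok=True)
        sub = valid.merge(preds[["record_id", "hb_pred"]], on="record_id")
        obs = sub["hb_t"].to_numpy(float) + sub["delta_hb"].to_numpy(float)
        pred_hb = sub["hb_pred"].to_numpy(float)
        plot_error_histogram(obs - pred_hb, plots_dir / "error_histogram.png")
        plot_bland_altman(obs, pred_hb, plots_dir / "bland_altman.png")
        produced.append(plots_dir)
    except Exception:
        log.exception("pipeline failed in stage %r; quarantining partial outputs", stage)
        _quarantine(out_dir, produced, stage)
        raise

    return {
        "cohort": out_dir / "cohort",
        "records": out_dir / "records.csv",
        "inclusion_report": out_dir / "inclusion_report.json",
        "model": out_dir / "model.json",
        "predictions": out_dir / "predictions.csv",
        "report": out_dir / "report.json",
        "plots": out_dir / "plots",
    }
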