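"""End-to-end orchestration: simulate -> screen -> ic50 -> kinetics -> selectivity -> pls.

The pipeline mirrors the order of a formulation-screening campaign: a
single-dose panel screen, dose-response follow-up of the hits, kinetic mode
calls and selectivity profiling for the top samples, and a PLS attribution
of panel activity to constituent crude drugs.  Each stage reads and writes
plain CSV/JSON under a stage-named subfolder of the working directory, and a
single ``summary.json`` collects the machine-readable outcomes.  Outputs are
pure functions of inputs + config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import assay, doseresponse, kinetics, selectivity, synthetic
from .exceptions import PTPScreenError
from .pls import PLS1
from .units import UnitDose

logger = logging.getLogger("ptpscreen")

ALL_STAGES = ("simulate", "screen", "ic50", "kinetics", "selectivity", "pls")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML/JSON."""

    workdir: str = "ptpscreen_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    complete_threshold: float = 90.0
    ic50_band: tuple = (5.0, 95.0)
    alpha_band: float = 1.5
    dose_scale: str = "uU"
    response_is_ic50: bool = True
    pls_a_max: Optional[int] = None
    # synthetic-panel shape
    n_samples: int = 147
    n_hits: int = 22
    n_formulations: int = 40
    n_drugs: int = 11
    noise_cv: float = 0.03
    # optional pre-existing inputs (CSV paths); when unset the simulate stage provides them
    inputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["ic50_band"] = list(self.ic50_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "ic50_band" in d:
            d["ic50_band"] = tuple(d["ic50_band"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        return cls.from_dict(d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _stage_dir(workdir: Path, stage: str) -> Path:
    d = workdir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _simulate_stage(cfg: RunConfig, workdir: Path, summary: dict) -> None:
    out = _stage_dir(workdir, "simulate")
    rng = np.random.default_rng(cfg.seed)
    noise = synthetic.NoiseModel(cv=cfg.noise_cv)

    # screening panel: absorbance triples at the common screening dose
    rates = synthetic.screen_rates(cfg.n_samples, cfg.n_hits, rng=rng)
    dose = UnitDose(0.1, "mU")
    rows = []
    for sample_id, rate in rates.items():
        t = assay.triple_from_rate(float(rate), dose=dose)
        rows.append(
            (sample_id, t.dA_sample, t.dA_blank, t.dA_control, dose.value, dose.scale)
        )
    plate = pd.DataFrame(
        rows,
        columns=["sample_id", "dA_sample", "dA_blank", "dA_control", "dose_value", "dose_scale"],
    )
    plate.to_csv(out / "plate.csv", index=False)

    # dose-response curves for five follow-up samples (half-log dilutions)
    true_ic50s = {f"hit_{i + 1}": v for i, v in enumerate((4.1, 4.3, 4.9, 6.3, 6.6))}
    dr_frames = []
    for sample_id, ic50 in true_ic50s.items():
        curve = synthetic.simulate_dose_response(
            ic50,
            synthetic.half_log_dilutions(ic50, 8),
            noise=noise,
            rng=rng,
            sample_id=sample_id,
            dose_scale=cfg.dose_scale,
        )
        df = curve.to_frame()
        df["conc_scale"] = cfg.dose_scale
        dr_frames.append(df)
    pd.concat(dr_frames).to_csv(out / "dose_response.csv", index=False)

    # kinetics grids for three samples with distinct true modes
    kin_params = {
        "kin_mixed_a": synthetic.KineticParameters.mixed(1.0, 4.0, Ki=2.0, Ki_prime=6.0),
        "kin_mixed_b": synthetic.KineticParameters.mixed(1.0, 4.0, Ki=2.0, Ki_prime=8.0),
        "kin_competitive": synthetic.KineticParameters.competitive(1.0, 4.0, Ki=2.0),
    }
    kin_frames = []
    for sample_id, params in kin_params.items():
        grid = synthetic.simulate_kinetics_grid(params, noise=noise, rng=rng)
        df = grid.to_long()
        df.insert(0, "sample_id", sample_id)
        kin_frames.append(df)
    pd.concat(kin_frames).to_csv(out / "kinetics.csv", index=False)

    # selectivity panel at a matched dose for the three kinetics samples
    enzymes = ("PTP1B", "TCPTP", "VHR", "SHP-1", "SHP-2")
    base = {"PTP1B": 97.0, "VHR": 78.0, "TCPTP": 60.0, "SHP-1": 21.0, "SHP-2": 9.0}
    sel_rows = []
    for sample_id in kin_params:
        for enz in enzymes:
            rate = float(np.clip(base[enz] * (1.0 + cfg.noise_cv * rng.standard_normal()), 0, 100))
            sel_rows.append((sample_id, enz, 25.0, "uU", rate))
    pd.DataFrame(
        sel_rows, columns=["sample_id", "enzyme", "dose_value", "dose_scale", "inhibition_pct"]
    ).to_csv(out / "selectivity.csv", index=False)

    # formulation panel for PLS attribution
    truth = synthetic.random_formulation_truth(
        n_formulations=cfg.n_formulations, n_drugs=cfg.n_drugs, rng=rng
    )
    X, y = synthetic.simulate_formulation_panel(truth, noise=noise, rng=rng)
    X.to_csv(out / "composition.csv", index_label="formulation")
    y.rename_axis("formulation").to_csv(out / "response.csv")
    sidecar = {
        "seed": cfg.seed,
        "noise_cv": cfg.noise_cv,
        "true_ic50s": true_ic50s,
        "kinetic_modes": {k: p.mode_label for k, p in kin_params.items()},
        "dominant_drug": truth.drug_names[0],
        "potency": dict(zip(truth.drug_names, truth.potency.tolist())),
        "ic50_scale": truth.ic50_scale,
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    summary["simulate"] = {"seed": cfg.seed, "files": sorted(p.name for p in out.iterdir())}


def _input_path(cfg: RunConfig, workdir: Path, stage: str, name: str) -> Path:
    if name in cfg.inputs:
        p = Path(cfg.inputs[name])
    else:
        p = workdir / "simulate" / f"{name}.csv"
    if not p.exists():
        raise PTPScreenError(
            f"stage {stage!r} needs input {p}; run the simulate stage or set inputs[{name!r}]"
        )
    return p


def _screen_stage(cfg: RunConfig, workdir: Path, summary: dict) -> None:
    out = _stage_dir(workdir, "screen")
    triples = assay.read_plate_csv(_input_path(cfg, workdir, "screen", "plate"))
    res = assay.screen_panel(triples, threshold=cfg.complete_threshold)
    res.table.to_csv(out / "screen.csv", index=False)
    summary["screen"] = {
        "n_samples": len(res.table),
        "n_complete": res.n_complete,
        "threshold": res.threshold,
        "top_samples": res.table.head(5)["sample_id"].tolist(),
    }


def _ic50_stage(cfg: RunConfig, workdir: Path, summary: dict) -> None:
    out = _stage_dir(workdir, "ic50")
    df = pd.read_csv(_input_path(cfg, workdir, "ic50", "dose_response"))
    table = doseresponse.fit_ic50_table(df, band=tuple(cfg.ic50_band))
    table.to_csv(out / "ic50.csv", index=False)
    summary["ic50"] = {
        "table": table.to_dict(orient="records"),
        "warnings": table.loc[~table["bracketed"], "sample_id"].tolist(),
    }


def _kinetics_stage(cfg: RunConfig, workdir: Path, summary: dict) -> None:
    out = _stage_dir(workdir, "kinetics")
    df = pd.read_csv(_input_path(cfg, workdir, "kinetics", "kinetics"))
    results = {}
    for sample_id, grp in df.groupby("sample_id", sort=False):
        model = kinetics.LineweaverBurk.from_dataframe(
            grp, sample_id=str(sample_id), alpha_band=cfg.alpha_band
        )
        results[str(sample_id)] = model.fit().to_dict()
    (out / "kinetics.json").write_text(json.dumps(results, indent=2))
    summary["kinetics"] = {
        k: {"mode": v["mode"], "tendency": v["tendency"], "alpha": v["alpha"]}
        for k, v in results.items()
    }


def _selectivity_stage(cfg: RunConfig, workdir: Path, summary: dict) -> None:
    out = _stage_dir(workdir, "selectivity")
    panels = selectivity.read_panel_csv(_input_path(cfg, workdir, "selectivity", "selectivity"))
    tables = []
    summ = {}
    for panel in panels:
        prof = selectivity.selectivity_profile(panel, complete_threshold=cfg.complete_threshold)
        t = prof.table.copy()
        t.insert(0, "sample_id", panel.sample_id)
        tables.append(t)
        summ[panel.sample_id] = {
            "reference_rate": prof.reference_rate,
            "reference_complete": prof.reference_complete,
            "order": prof.table["enzyme"].tolist(),
        }
    pd.concat(tables).to_csv(out / "selectivity.csv", index=False)
    summary["selectivity"] = summ


def _pls_stage(cfg: RunConfig, workdir: Path, summary: dict) -> None:
    out = _stage_dir(workdir, "pls")
    X = pd.read_csv(_input_path(cfg, workdir, "pls", "composition"), index_col=0)
    y = pd.read_csv(_input_path(cfg, workdir, "pls", "response"), index_col=0).iloc[:, 0]
    model = PLS1.from_dataframes(X, y)
    results = model.fit_press(a_max=cfg.pls_a_max)
    (out / "model.json").write_text(json.dumps(results.to_dict(), indent=2))
    ranking = results.ranking(response_is_ic50=cfg.response_is_ic50)
    ranking.to_csv(out / "ranking.csv", index=False)
    summary["pls"] = {
        "ncomp": results.ncomp,
        "press": results.press_profile.press.tolist(),
        "rsquared": results.rsquared,
        "top_contributor": ranking["crude_drug"].iloc[0],
        "ranking": ranking["crude_drug"].tolist(),
        "dropped_columns": model.constant_cols,
    }


_STAGE_FUNCS = {
    "simulate": _simulate_stage,
    "screen": _screen_stage,
    "ic50": _ic50_stage,
    "kinetics": _kinetics_stage,
    "selectivity": _selectivity_stage,
    "pls": _pls_stage,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in order and write ``summary.json``.

    Returns the summary dict.  Stage errors are logged with the stage name
    and re-raised.
    """
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    config.save(workdir / "config.yaml")
    summary: dict = {"config": config.to_dict()}
    unknown = [s for s in config.stages if s not in _STAGE_FUNCS]
    if unknown:
        raise PTPScreenError(f"unknown stage(s): {unknown}")
    for stage in ALL_STAGES:  # canonical order regardless of config order
        if stage not in config.stages:
            continue
        logger.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](config, workdir, summary)
        except Exception:
            logger.exception("stage %s failed", stage)
            raise
        logger.info("stage %s: done", stage)
    (workdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
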