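"""Run orchestration: configuration, stage sequencing and the run report.

The canonical stage order mirrors the experimental workflow: simulate (or
ingest) a gel set, normalize it against a reference gel, quantify the
per-spot abundance/S-NO folds and RoR, select differential spots, model
the groups with MARS, and (independently of data) verify the packaged
spot-table fixture.  Every stage writes its artifacts as TSV/JSON under
``out_dir`` and contributes a summary block to the :class:`RunReport`.

Configuration is a flat key-value file (YAML mapping); unknown keys are
rejected.  Synthetic-generator parameters carry a ``sim_`` prefix.  All
randomness funnels through the single ``seed`` key, which is recorded in
the report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffstats import DifferentialModel
from .errors import StageError, ValidationError
from .gelset import GelSet, read_gelset
from .mars import MARS, validate
from .normalize import normalize_gelset
from .ror import load_table_fixture, ror_table, verify_table_fixture
from .simulate import SyntheticConfig, simulate_gelset

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

STAGES = ("simulate", "normalize", "quantify", "select", "mars", "verify_table")


@dataclass
class RunConfig:
    """Flat pipeline configuration."""

    stages: tuple[str, ...] = STAGES[:-1]  # verify_table is opt-in
    out_dir: str = "snoquant_run"
    seed: int = 0
    volumes: str | None = None  # input TSVs when not simulating
    meta: str | None = None
    # selection thresholds
    preset: str = "discovery"
    fold_threshold: float | None = None
    alpha: float | None = None
    use_adjusted: bool | None = None
    trim: float = 0.0
    # MARS stage
    mars_preset: str = "mars_input"
    mars_schemes: tuple[str, ...] = ("cv10", "split80_20")
    mars_max_interaction: int = 1
    mars_penalty: float = 2.0
    # synthetic generator (sim_ prefix in files)
    sim: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages and any(
            s in self.stages for s in ("normalize", "quantify", "select", "mars")
        ):
            if not (self.volumes and self.meta):
                raise ValidationError(
                    "volumes and meta paths are required when not simulating"
                )

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config file must be a flat key-value mapping")
        raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim_kwargs = {}
        for key in list(raw):
            if key.startswith("sim_"):
                sim_kwargs[key[4:]] = raw.pop(key)
        known = {f.name for f in fields(cls)} - {"sim"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            stages = raw["stages"]
            if isinstance(stages, str):
                stages = [s.strip() for s in stages.split(",") if s.strip()]
            raw["stages"] = tuple(stages)
        if "mars_schemes" in raw and isinstance(raw["mars_schemes"], str):
            raw["mars_schemes"] = tuple(
                s.strip() for s in raw["mars_schemes"].split(",") if s.strip()
            )
        seed = raw.get("seed", 0)
        sim_kwargs.setdefault("seed", seed)
        raw["sim"] = SyntheticConfig(**sim_kwargs)
        return cls(**raw)


@dataclass
class RunReport:
    """Per-stage summaries of one pipeline run."""

    version: str
    seed: int
    stages_run: list[str]
    stages: dict
    timestamp: str

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def subject_features(gelset: GelSet, spot_ids: list[str], channel: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-subject log2 feature matrix for one channel and spot panel.

    Rows are subjects, columns spot ids; labels are 0 for NH and 1 for
    HF.  Zero volumes are imputed with half the spot's smallest positive
    volume before the log transform.
    """
    gels = gelset.gels(channel=channel)
    sub = gelset.volumes.loc[spot_ids, gels]
    floor = sub[sub > 0].min(axis=1) / 2.0
    sub = sub.where(sub > 0, floor, axis=0)
    logv = np.log2(sub)
    meta = gelset.gel_meta.loc[gels]
    X = logv.T
    X.index = meta["subject"].to_numpy()
    y = (meta["group"] == "HF").astype(int).to_numpy()
    return X, y


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the requested stages in canonical order.

    Identical config + seed gives an identical report (timestamp aside).
    Raises :class:`StageError` naming the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    requested = [s for s in STAGES if s in config.stages]

    gelset = None
    truth = None
    results = None

    for stage in requested:
        try:
            if stage == "simulate":
                sim_cfg = config.sim.with_seed(config.seed)
                gelset, truth = simulate_gelset(sim_cfg)
                gelset.to_tsv(out / "volumes.tsv", out / "gel_meta.tsv")
                truth.to_tsv(out / "truth.tsv")
                report["simulate"] = {
                    "n_gels": len(gelset.gel_ids),
                    "n_spots": len(gelset.spot_ids),
                    "n_abundance_affected": len(truth.abundance_spots),
                    "n_sno_affected": len(truth.sno_spots),
                    "config": {
                        k: v for k, v in asdict(sim_cfg).items() if v is not None
                    },
                }
            elif stage == "normalize":
                if gelset is None:
                    gelset = read_gelset(config.volumes, config.meta)
                gelset = normalize_gelset(gelset, trim=config.trim)
                gelset.to_tsv(out / "normalized_volumes.tsv", out / "gel_meta.tsv")
                gains = gelset.gain_factors.rename_axis("gel_id").reset_index()
                gains.to_csv(out / "gain_factors.tsv", sep="\t", index=False)
                report["normalize"] = {
                    "reference_gel": gelset.reference_gel,
                    "gain_min": float(gelset.gain_factors.min()),
                    "gain_max": float(gelset.gain_factors.max()),
                }
            elif stage == "quantify":
                if gelset is None or not gelset.normalized:
                    raise ValidationError("quantify requires the normalize stage")
                rors = ror_table(gelset)
                rors.to_csv(out / "ror.tsv", sep="\t", index=False)
                finite = rors["ror"].dropna()
                report["quantify"] = {
                    "n_spots": len(rors),
                    "n_undefined": int(rors["ror"].isna().sum()),
                    "ror_min": float(finite.min()),
                    "ror_max": float(finite.max()),
                }
            elif stage == "select":
                if gelset is None or not gelset.normalized:
                    raise ValidationError("select requires the normalize stage")
                model = DifferentialModel(
                    gelset,
                    preset=config.preset,
                    fold_threshold=config.fold_threshold,
                    alpha=config.alpha,
                    use_adjusted=config.use_adjusted,
                )
                results = model.fit()
                results.to_tsv(out / "differential.tsv")
                t = results.table
                report["select"] = {
                    "preset": config.preset,
                    "n_tested": int(t["p_abundance"].notna().sum()),
                    "n_abundance": len(results.abundance_selected),
                    "n_sno": len(results.sno_selected),
                    "venn": results.venn,
                }
            elif stage == "mars":
                if results is None:
                    raise ValidationError("mars requires the select stage")
                sel_model = DifferentialModel(gelset, preset=config.mars_preset)
                sel = sel_model.fit()
                panels = {
                    "abundance": (sorted(sel.abundance_selected), "Asc+"),
                    "sno": (sorted(sel.sno_selected), "Asc-"),
                }
                block = {}
                for panel, (spots, channel) in panels.items():
                    if len(spots) < 1:
                        block[panel] = {"skipped": "no spots selected"}
                        continue
                    X, y = subject_features(gelset, spots, channel)
                    entry = {"n_features": len(spots), "features": spots}
                    for scheme in config.mars_schemes:
                        v = validate(
                            X, y, scheme, seed=config.seed,
                            max_interaction=config.mars_max_interaction,
                            penalty=config.mars_penalty,
                        )
                        v.roc_test.to_csv(
                            out / f"roc_{panel}_{scheme}.tsv", sep="\t", index=False
                        )
                        entry[scheme] = v.to_dict()
                    full = MARS(
                        X, y,
                        max_interaction=config.mars_max_interaction,
                        penalty=config.mars_penalty,
                    ).fit()
                    full.to_json(out / f"mars_{panel}.json")
                    block[panel] = entry
                report["mars"] = block
            elif stage == "verify_table":
                fixture = load_table_fixture()
                rep = verify_table_fixture(fixture)
                rep.to_csv(out / "table_verification.tsv", sep="\t", index=False)
                report["verify_table"] = {
                    "n_rows": len(rep),
                    "n_passed": int(rep["passed"].sum()),
                    "pass_rate_pct": float(100.0 * rep["passed"].mean()),
                    "abundance_fold_max": float(fixture["abundance_HF_vs_NH"].max()),
                    "abundance_fold_min": float(fixture["abundance_HF_vs_NH"].min()),
                    "ror_max": float(fixture["ror_HF_vs_NH"].max()),
                    "ror_min": float(fixture["ror_HF_vs_NH"].min()),
                }
        except ValidationError:
            raise
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage isolation boundary
            raise StageError(stage, str(exc)) from exc

    run_report = RunReport(
        version=__version__,
        seed=config.seed,
        stages_run=requested,
        stages=report,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    run_report.to_json(out / "run_report.json")
    return run_report
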