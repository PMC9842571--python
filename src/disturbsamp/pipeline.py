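"""End-to-end orchestration: configuration, logging, report bundles.

A run takes either three survey CSVs or a simulation block, and produces a
directory of publication-shaped tables: the per-passage descriptive summary,
posterior summaries and pairwise contrasts for the encounter-rate and
group-size models, the selected detection functions and per-passage
densities, the corrected density, and the heard-distance chi-squared tests.
Every stochastic stage derives its seed deterministically from the top-level
seed, so a repeated run with the same configuration is byte-identical.

Report tables are written twice: rounded to 4 significant digits for reading
(``<name>.csv``) and at full precision for machines (``<name>_full.csv``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import EncounterRateModel, GroupSizeModel, passage_contrasts
from .category import far_proportion, heard_distance_table, pearson_chi2
from .density import corrected_density, passage_density
from .detection import KeyFunctionSpec
from .simulate import SimulationConfig, simulate_survey
from .survey import SurveyDataset, read_survey, summarize_by_passage, write_survey

logger = logging.getLogger("disturbsamp")

_KNOWN_KEYS = {
    "schema_version", "input_dir", "simulation", "truncation_rule", "truncation_q",
    "candidates", "chains", "iterations", "warmup", "nwalkers", "contrast_level",
    "size_kind", "test_pairs", "p_method", "mc_batches", "seed", "out_dir",
}


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Configuration of one end-to-end run (schema version 1)."""

    out_dir: str = "disturbsamp_run"
    input_dir: str | None = None
    simulation: SimulationConfig | None = None
    truncation_rule: str = "quantile"
    truncation_q: float = 0.95
    candidates: Sequence[KeyFunctionSpec] | None = None
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    nwalkers: int = 8
    contrast_level: float = 0.95
    size_kind: str = "estimated"
    test_pairs: tuple = ((2, 3), (2, 4))
    p_method: str = "asymptotic"
    mc_batches: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dir is None and self.simulation is None:
            self.simulation = SimulationConfig()
        if self.input_dir is not None and self.simulation is not None:
            raise ConfigError("give either input_dir or a simulation block, not both")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ConfigError(f"input_dir does not exist: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        if raw.pop("schema_version", 1) != 1:
            raise ConfigError("unsupported schema_version")
        sim = raw.pop("simulation", None)
        if sim is not None:
            known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
            unknown = set(sim) - known_sim
            if unknown:
                raise ConfigError(f"unknown simulation key(s): {sorted(unknown)}")
            for key in ("availability", "visibility", "vocal_category_probs",
                        "species_labels", "species_weights", "morning_prob"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        cand = raw.pop("candidates", None)
        if cand is not None:
            cand = [KeyFunctionSpec(**c) for c in cand]
        if "test_pairs" in raw:
            raw["test_pairs"] = tuple(tuple(p) for p in raw["test_pairs"])
        return cls(simulation=sim, candidates=cand, **raw)


def _round_sig(x, digits: int = 4):
    if isinstance(x, (int, np.integer)) or not isinstance(x, (float, np.floating)):
        return x
    if not np.isfinite(x) or x == 0:
        return x
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + digits - 1)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path.with_name(path.stem + "_full.csv"), index=False)
    df.map(_round_sig).to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns {table name: DataFrame} and writes
    the report bundle (CSVs, JSON manifest, log) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    stage = "load"
    results: dict[str, pd.DataFrame] = {}
    try:
        if config.simulation is not None:
            ds = simulate_survey(config.simulation, seed=int(seeds[0]))
            write_survey(ds, out / "data")
        else:
            p = Path(config.input_dir)
            ds = read_survey(p / "transects.csv", p / "observations.csv", p / "heard.csv")
        logger.info("dataset: %d walks, %d observation rows, %d heard-only records",
                    ds.n_walks(), len(ds.observations), len(ds.heard))

        stage = "summary"
        summary = summarize_by_passage(ds)
        results["summary"] = summary
        _write_table(summary, out / "summary.csv")

        stage = "passage_models"
        sampler = dict(chains=config.chains, iterations=config.iterations,
                       warmup=config.warmup, nwalkers=config.nwalkers)
        er_model = EncounterRateModel(seed=int(seeds[1]), **sampler).fit(ds)
        results["encounter_rate_posteriors"] = er_model.summary_
        _write_table(er_model.summary_, out / "encounter_rate_posteriors.csv")
        er_contrasts = passage_contrasts(er_model).summary
        results["encounter_rate_contrasts"] = er_contrasts
        _write_table(er_contrasts, out / "encounter_rate_contrasts.csv")

        gs_model = GroupSizeModel(seed=int(seeds[2]), size_kind="observed", **sampler).fit(ds)
        results["group_size_posteriors"] = gs_model.summary_
        _write_table(gs_model.summary_, out / "group_size_posteriors.csv")
        gs_contrasts = passage_contrasts(gs_model).summary
        results["group_size_contrasts"] = gs_contrasts
        _write_table(gs_contrasts, out / "group_size_contrasts.csv")

        stage = "densities"
        rows = []
        for r in (2, 3, 4):
            for size_kind in ("observed", "estimated"):
                try:
                    est = passage_density(ds, [r], size_kind=size_kind,
                                          truncation=config.truncation_rule,
                                          q=config.truncation_q,
                                          candidates=config.candidates)
                except Exception as exc:  # too few sightings to fit
                    logger.warning("passage %d (%s sizes): no density (%s)", r, size_kind, exc)
                    continue
                row = est.as_row()
                row["size_kind"] = size_kind
                rows.append(row)
        densities = pd.DataFrame(rows)
        results["densities"] = densities
        _write_table(densities, out / "densities.csv")

        stage = "corrected_density"
        corrected = corrected_density(
            ds, rate_model=er_model, contrast_level=config.contrast_level,
            truncation=config.truncation_rule, q=config.truncation_q,
            candidates=config.candidates)
        corrected_df = pd.DataFrame([corrected.as_row()])
        results["corrected_density"] = corrected_df
        _write_table(corrected_df, out / "corrected_density.csv")

        stage = "category_tests"
        table = heard_distance_table(ds, (1, 2, 3, 4))
        rows = []
        for (a, b) in config.test_pairs:
            pair = heard_distance_table(ds, (a, b))
            try:
                res_a = pearson_chi2(pair, "asymptotic")
                res_m = pearson_chi2(pair, "monte_carlo", B=config.mc_batches, seed=int(seeds[3]))
                rows.append({"pair": f"P{a}:P{b}", "statistic": res_a.statistic, "df": res_a.df,
                             "p_asymptotic": res_a.p_value, "p_monte_carlo": res_m.p_value})
            except ValueError as exc:  # degenerate table (e.g. no heard records)
                logger.warning("chi-squared P%d:P%d not computable: %s", a, b, exc)
                rows.append({"pair": f"P{a}:P{b}", "statistic": np.nan, "df": 0,
                             "p_asymptotic": np.nan, "p_monte_carlo": np.nan})
        tests = pd.DataFrame(rows)
        far = pd.DataFrame({"passage": [f"P{p}" for p in (1, 2, 3, 4)],
                            "far_pct": [far_proportion(ds, p) for p in (1, 2, 3, 4)]})
        results["heard_table"] = table
        results["heard_tests"] = tests
        results["far_proportions"] = far
        _write_table(table.reset_index(names="passage"), out / "heard_table.csv")
        _write_table(tests, out / "heard_tests.csv")
        _write_table(far, out / "far_proportions.csv")

        stage = "manifest"
        manifest = {
            "disturbsamp_version": __version__,
            "python_version": platform.python_version(),
            "numpy_version": np.__version__,
            "seed": config.seed,
            "stage_seeds": [int(s) for s in seeds],
            "truncation": {"rule": config.truncation_rule, "q": config.truncation_q},
            "sampler": sampler,
            "contrast_level": config.contrast_level,
            "config": {
                k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                for k, v in dataclasses.asdict(config).items()
                if k not in ("candidates", "out_dir")
            },
            "selected_detection_models": {
                "corrected": corrected_df.detection_model.iloc[0] if len(corrected_df) else None,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results
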