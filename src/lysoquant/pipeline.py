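"""End-to-end experiment runners: simulate, measure, compare, report.

Ties the stages together for the two assay designs:

* distribution experiment — two simulated conditions, each a population of
  cells; per cell the organelle image is segmented, background-subtracted
  and reduced to a cumulative distribution profile; populations are
  aggregated (mean ± SEM) and compared with the extra sum-of-squares
  F-test;
* motility experiment — two groups of movies reduced to PCC decay curves
  and compared with the decay-model F-test.

Runs are reproducible: every source of randomness derives from the config
seed, outputs carry a hash of the serialized config, and no timestamps are
written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__ as _version
from .curvestats import aggregate_profiles, compare_curves
from .images import CellMask, ValidationError, segment_cell, subtract_background
from .motility import compare_decay, fit_decay, pcc_decay_curve
from .radial import CumulativeProfile, cumulative_profile, decile_masks
from .synthetic import (
    MotilitySpec,
    SyntheticCellSpec,
    generate_population,
    generate_timeseries,
    population_seeds,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cell."""


def _condition_seed(master_seed: int, spec) -> int:
    """Per-condition seed derived from the master seed and the spec content.

    Identical conditions therefore reproduce identical cells (so comparing a
    condition against a copy of itself gives F = 0, p = 1), while conditions
    that differ in any parameter get independent populations.
    """
    digest = hashlib.sha256(
        (str(master_seed) + "|" + repr(spec)).encode()
    ).digest()
    return int.from_bytes(digest[:4], "little") % 2**31


@dataclass
class RunConfig:
    """Configuration of a two-condition experiment.

    ``experiment`` is ``distribution`` or ``motility``.  Conditions are two
    :class:`SyntheticCellSpec` instances (the per-cell seeds are derived
    from ``seed`` and override the specs' own); motility experiments add a
    :class:`MotilitySpec` per condition.
    """

    experiment: str = "distribution"
    seed: int = 0
    n_cells: int = 30
    name_a: str = "condition_a"
    name_b: str = "condition_b"
    spec_a: SyntheticCellSpec = field(default_factory=SyntheticCellSpec)
    spec_b: SyntheticCellSpec = field(default_factory=SyntheticCellSpec)
    motility_a: MotilitySpec = field(default_factory=MotilitySpec)
    motility_b: MotilitySpec = field(default_factory=MotilitySpec)
    saturation_quantile: float = 0.99
    use_ground_truth_masks: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in ("distribution", "motility"):
            raise ValidationError(
                f"experiment must be 'distribution' or 'motility', "
                f"got {self.experiment!r}"
            )
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")

    # -- flat key-value serialization ------------------------------------

    def to_text(self) -> str:
        lines = []
        for key, val in sorted(_flatten(self).items()):
            lines.append(f"{key} = {_fmt(val)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        flat: dict[str, str] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"config line {lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            flat[key.strip()] = val.strip()
        return _unflatten(cls, flat)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def _fmt(val: Any) -> str:
    if val is None:
        return "none"
    if isinstance(val, bool):
        return "true" if val else "false"
    return repr(val) if isinstance(val, float) else str(val)


def _flatten(cfg: RunConfig) -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for f in dataclasses.fields(cfg):
        val = getattr(cfg, f.name)
        if dataclasses.is_dataclass(val):
            for sub in dataclasses.fields(val):
                flat[f"{f.name}.{sub.name}"] = getattr(val, sub.name)
        else:
            flat[f.name] = val
    return flat


def _parse_scalar(text: str, pytype: Any) -> Any:
    if text.lower() == "none":
        return None
    if pytype is bool or text.lower() in ("true", "false"):
        return text.lower() == "true"
    try:
        return pytype(text)
    except (TypeError, ValueError):
        return text


def _unflatten(cls: type, flat: dict[str, str]) -> "RunConfig":
    top: dict[str, Any] = {}
    nested: dict[str, dict[str, str]] = {}
    for key, val in flat.items():
        if "." in key:
            head, _, tail = key.partition(".")
            nested.setdefault(head, {})[tail] = val
        else:
            top[key] = val
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name in nested:
            sub_cls = SyntheticCellSpec if f.name.startswith("spec") else MotilitySpec
            sub_kwargs = {}
            sub_fields = {sf.name: sf for sf in dataclasses.fields(sub_cls)}
            for k, v in nested[f.name].items():
                if k not in sub_fields:
                    raise ValidationError(f"unknown config key {f.name}.{k}")
                hint = sub_fields[k].type
                pytype = float if "float" in str(hint) else (
                    bool if "bool" in str(hint) else (
                        int if "int" in str(hint) else str))
                sub_kwargs[k] = _parse_scalar(v, pytype)
            kwargs[f.name] = sub_cls(**sub_kwargs)
        elif f.name in top:
            hint = str(f.type)
            pytype = float if "float" in hint else (
                bool if "bool" in hint else (int if "int" in hint else str))
            kwargs[f.name] = _parse_scalar(top[f.name], pytype)
    unknown = set(top) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# distribution experiment


def _profiles_for_condition(
    name: str,
    spec: SyntheticCellSpec,
    n_cells: int,
    seed: int,
    saturation_quantile: float,
    use_ground_truth_masks: bool,
) -> list[CumulativeProfile]:
    cells = generate_population(n_cells, spec, seed)
    profiles = []
    for i, (stack, truth) in enumerate(cells):
        cell_id = f"{name}/cell{i}"
        try:
            frame = stack.frame("LAMP1", 0)
            if use_ground_truth_masks:
                mask = truth.cell_mask
            else:
                mask = segment_cell(frame, saturation_quantile)
            corrected = subtract_background(frame, mask)
            deciles = decile_masks(mask)
            profiles.append(cumulative_profile(corrected, deciles, cell_id=cell_id))
        except Exception as exc:
            raise PipelineError(f"stage failed for {cell_id}: {exc}") from exc
    return profiles


def run_distribution_experiment(
    config: RunConfig, out_dir: str | Path | None = None
) -> dict:
    """Simulate two conditions, profile every cell and compare the groups."""
    groups: dict[str, list[CumulativeProfile]] = {}
    for name, spec, s in (
        (config.name_a, config.spec_a, _condition_seed(config.seed, config.spec_a)),
        (config.name_b, config.spec_b, _condition_seed(config.seed, config.spec_b)),
    ):
        groups[name] = _profiles_for_condition(
            name,
            spec,
            config.n_cells,
            s,
            config.saturation_quantile,
            config.use_ground_truth_masks,
        )
    prof_a = groups[config.name_a]
    prof_b = groups[config.name_b]
    comparison = compare_curves(prof_a, prof_b)
    report = {
        "experiment": "distribution",
        "lysoquant_version": _version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_cells": config.n_cells,
        "conditions": [config.name_a, config.name_b],
        "comparison": {
            "f_stat": comparison.f_stat,
            "p_value": comparison.p_value,
            "ssr_shared": comparison.ssr_shared,
            "ssr_separate": comparison.ssr_separate,
            "df_shared": comparison.df_shared,
            "df_separate": comparison.df_separate,
        },
        "population_curves": {},
    }
    for name, profs in groups.items():
        pop = aggregate_profiles(profs)
        report["population_curves"][name] = {
            "x": pop.x.tolist(),
            "mean_y": pop.mean_y.tolist(),
            "sem_y": pop.sem_y.tolist(),
            "n_cells": pop.n_cells,
        }
    if out_dir is not None:
        _write_distribution_outputs(config, groups, report, Path(out_dir))
    return report


def _write_distribution_outputs(
    config: RunConfig,
    groups: dict[str, list[CumulativeProfile]],
    report: dict,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, profs in groups.items():
        for p in profs:
            for x, y in zip(p.x, p.y):
                rows.append(
                    {"cell_id": p.cell_id, "condition": name, "x": x, "y": y}
                )
    pd.DataFrame(rows).to_csv(out_dir / "profiles.csv", index=False)
    pop_rows = []
    for name, pop in report["population_curves"].items():
        for x, m, s in zip(pop["x"], pop["mean_y"], pop["sem_y"]):
            pop_rows.append(
                {"condition": name, "x": x, "mean_y": m, "sem_y": s,
                 "n_cells": pop["n_cells"]}
            )
    pd.DataFrame(pop_rows).to_csv(out_dir / "population_curves.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    config.save(out_dir / "config.txt")


# ---------------------------------------------------------------------------
# motility experiment


def _decay_for_condition(
    name: str,
    spec: SyntheticCellSpec,
    motility: MotilitySpec,
    n_movies: int,
    seed: int,
    saturation_quantile: float,
    use_ground_truth_masks: bool,
):
    curves = []
    for i, s in enumerate(population_seeds(n_movies, seed)):
        cell_id = f"{name}/movie{i}"
        try:
            movie, truth = generate_timeseries(
                dataclasses.replace(spec, seed=s),
                dataclasses.replace(motility, seed=s + 1),
            )
            if use_ground_truth_masks:
                mask = truth.cell_mask
            else:
                mask = segment_cell(movie.frame(0, 0), saturation_quantile)
            curves.append(pcc_decay_curve(movie, mask, cell_id=cell_id))
        except Exception as exc:
            raise PipelineError(f"stage failed for {cell_id}: {exc}") from exc
    return curves


def run_motility_experiment(
    config: RunConfig, out_dir: str | Path | None = None
) -> dict:
    """Simulate two groups of movies, reduce to PCC decay and compare."""
    groups = {}
    for name, spec, mot, s in (
        (config.name_a, config.spec_a, config.motility_a,
         _condition_seed(config.seed, (config.spec_a, config.motility_a))),
        (config.name_b, config.spec_b, config.motility_b,
         _condition_seed(config.seed, (config.spec_b, config.motility_b))),
    ):
        groups[name] = _decay_for_condition(
            name,
            spec,
            mot,
            config.n_cells,
            s,
            config.saturation_quantile,
            config.use_ground_truth_masks,
        )
    curves_a = groups[config.name_a]
    curves_b = groups[config.name_b]
    comparison = compare_decay(curves_a, curves_b)
    report = {
        "experiment": "motility",
        "lysoquant_version": _version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_movies": config.n_cells,
        "conditions": [config.name_a, config.name_b],
        "comparison": {
            "f_stat": comparison.f_stat,
            "p_value": comparison.p_value,
            "ssr_shared": comparison.ssr_shared,
            "ssr_separate": comparison.ssr_separate,
            "df_shared": comparison.df_shared,
            "df_separate": comparison.df_separate,
        },
        "fits": {},
    }
    for name, curves in groups.items():
        fits = [fit_decay(c) for c in curves]
        report["fits"][name] = {
            "plateau_mean": float(np.mean([f.plateau for f in fits])),
            "rate_per_s_mean": float(np.mean([f.rate_per_s for f in fits])),
            "n_curves": len(fits),
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for name, curves in groups.items():
            for c in curves:
                for t, v in zip(c.times_s, c.pcc):
                    rows.append(
                        {"cell_id": c.cell_id, "condition": name,
                         "time_s": t, "pcc": v}
                    )
        pd.DataFrame(rows).to_csv(out / "decay_curves.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        config.save(out / "config.txt")
    return report
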