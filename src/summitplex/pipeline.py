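"""End-to-end pipeline: cohort in, one CSV table per analysis stage out.

The configuration (a plain mapping, loadable from YAML or JSON) names
either input CSV paths or a synthetic-generation block, an output
directory, the tau range, experience bins, and the minimum expedition size
for the feature analysis. Outputs are deterministic for a fixed
config+seed: rows are sorted, floats printed with a fixed format, and a
JSON manifest records the config, the seed, and SHA-256 hashes of the
input tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .complexes import cohort_complexes, influence_table, co_influence_table, serialize_complex
from .features import (
    MIN_EXPEDITION_MEMBERS,
    centrality_comparison,
    expedition_feature_centralities,
    factor_correlations,
)
from .influence import DEFAULT_EXPERIENCE_BINS, influence_by_outcome
from .partners import failure_ratio_analysis, repeated_partner_flags
from .records import expedition_success_rates, read_records, write_records
from .style import style_curves
from .synthetic import GeneratorConfig, generate_cohort


class ConfigError(ValueError):
    """Conflicting or incomplete pipeline configuration."""


STAGES = (
    "simulate",
    "complexes",
    "partners",
    "influence",
    "style",
    "features",
    "factors",
)

_FLOAT_FORMAT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohort(config: Mapping[str, Any], out_dir: Path):
    has_inputs = "inputs" in config
    has_synth = "synthetic" in config
    if has_inputs == has_synth:
        raise ConfigError(
            "config must name exactly one of 'inputs' (CSV paths) or "
            "'synthetic' (generator block)"
        )
    if has_inputs:
        paths = config["inputs"]
        climbers = Path(paths["climbers"])
        exps = Path(paths["expeditions"])
        records, expeditions = read_records(climbers, exps)
    else:
        block = dict(config["synthetic"])
        for tup_key in (
            "expedition_size_range",
            "seed_block_size_range",
            "failure_cause_weights",
            "feature_prevalences",
            "feature_effects",
        ):
            if tup_key in block:
                block[tup_key] = tuple(block[tup_key])
        gen = GeneratorConfig(**block)
        records, expeditions = generate_cohort(gen)
        climbers = out_dir / "cohort" / "climbers.csv"
        exps = out_dir / "cohort" / "expeditions.csv"
        climbers.parent.mkdir(parents=True, exist_ok=True)
        write_records(records, expeditions, climbers, exps)
    return records, expeditions, climbers, exps


def run_pipeline(
    config: Mapping[str, Any],
    out_dir: str | Path | None = None,
    stages: tuple[str, ...] | list[str] | None = None,
) -> dict[str, Any]:
    """Run the analysis stages and write their tables under ``out_dir``.

    Returns the manifest (also written as ``manifest.json``). ``stages``
    restricts execution; the cohort is always materialized.
    """
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)
    run_stages = STAGES if stages is None else tuple(stages)
    unknown = set(run_stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")

    tau_values = tuple(config.get("tau_values", (1, 2, 3, 4)))
    bins = tuple(tuple(b) for b in config.get("experience_bins", DEFAULT_EXPERIENCE_BINS))
    min_members = int(config.get("min_expedition_size", MIN_EXPEDITION_MEMBERS))
    min_total_climbs = int(config.get("min_total_climbs", 15))

    records, expeditions, climbers_path, exps_path = _load_cohort(config, out)
    tables = out / "tables"
    written: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        _write_csv(df, tables / name)
        written.append(f"tables/{name}")

    rates = expedition_success_rates(records, expeditions)
    emit(
        pd.DataFrame(
            [
                {"expedition_id": s.expedition_id, "success_rate": s.success_rate}
                for s in rates
            ]
        ),
        "success_rates.csv",
    )

    inf_df = None
    if {"complexes", "influence"} & set(run_stages):
        inf_df = influence_table(expeditions, tau_values)

    if "complexes" in run_stages:
        emit(inf_df, "influence.csv")
        emit(co_influence_table(inf_df), "co_influence.csv")
        for tau in tau_values:
            cxs = cohort_complexes(expeditions, tau)
            frames = [serialize_complex(cx) for _, cx in sorted(cxs.items())]
            emit(pd.concat(frames, ignore_index=True), f"complexes_tau{tau}.csv")

    if "partners" in run_stages:
        flags = repeated_partner_flags(records, expeditions)
        emit(
            failure_ratio_analysis(
                records, expeditions, flags, min_total_climbs=min_total_climbs
            ),
            "partner_failure_ratios.csv",
        )

    if "influence" in run_stages:
        for tau in tau_values:
            summ = influence_by_outcome(
                inf_df[inf_df["tau"] == tau], records, expeditions, bins
            )
            emit(summ.tests, f"influence_tests_tau{tau}.csv")
            emit(summ.summary, f"influence_summary_tau{tau}.csv")
            emit(summ.histograms, f"influence_histograms_tau{tau}.csv")

    if "style" in run_stages:
        res = style_curves(expeditions, records, tau_values)
        emit(res.per_expedition, "style_per_expedition.csv")
        emit(res.per_tau, "style_per_tau.csv")
        emit(res.dimension_bins, "style_dimension_bins.csv")

    if "features" in run_stages:
        cents = expedition_feature_centralities(records, expeditions, min_members)
        if cents:
            emit(centrality_comparison(cents), "feature_centrality.csv")

    if "factors" in run_stages:
        rate_map = {s.expedition_id: s.success_rate for s in rates}
        emit(factor_correlations(expeditions, rate_map), "factor_correlations.csv")

    from . import __version__ as version

    manifest = {
        "package_version": version,
        "config": _jsonable(config),
        "seed": config.get("synthetic", {}).get("rng_seed"),
        "stages": list(run_stages),
        "inputs": {
            "climbers": {"path": str(climbers_path), "sha256": _sha256(climbers_path)},
            "expeditions": {"path": str(exps_path), "sha256": _sha256(exps_path)},
        },
        "outputs": sorted(written),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
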