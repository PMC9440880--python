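#!/usr/bin/env python
"""Polarized or cooperative? Style classification from simplex structure.

Generates one cohort per regime and traces the three style diagnostics:
outsider success rate against maximal simplex dimension, mean maximal
dimension against tau, and the per-tau correlation between expedition
success rate and mean maximal-simplex dimension.
"""
from pathlib import Path

from summitplex.style import outsider_dimension_slope, style_curves
from summitplex.synthetic import GeneratorConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "tables"
TAUS = (1, 2, 3, 4)


def cohort(regime: str):
    cfg = GeneratorConfig(
        n_climbers=120,
        n_expeditions=300,
        expedition_size_range=(6, 10),
        group_persistence=0.6,
        seed_block_size_range=(2, 5),
        base_success_logit=-0.5,
        influence_effect=0.3,
        regime=regime,
        cooperative_spillover=0.5 if regime == "cooperative" else 0.0,
        polarized_penalty=0.0 if regime == "cooperative" else 1.0,
        rng_seed=42,
    )
    return generate_cohort(cfg)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for regime in ("cooperative", "polarized"):
        records, expeditions = cohort(regime)
        res = style_curves(expeditions, records, TAUS)
        res.per_expedition.to_csv(OUT / f"style_per_expedition_{regime}.csv", index=False)
        res.per_tau.to_csv(OUT / f"style_per_tau_{regime}.csv", index=False)
        res.dimension_bins.to_csv(OUT / f"style_dimension_bins_{regime}.csv", index=False)
        slope = outsider_dimension_slope(res.per_expedition, 1)
        print(f"{regime}: outsider-success slope vs max dimension = {slope:+.3f}")
        print(res.per_tau[["tau", "n_expeditions", "mean_max_dimension", "pcc_r"]]
              .to_string(index=False))
    print(
        "cooperative expeditions reward outsiders of large simplices and "
        "lose predictive power as tau prunes weak relationships; polarized "
        "ones stay flat"
    )


if __name__ == "__main__":
    main()
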