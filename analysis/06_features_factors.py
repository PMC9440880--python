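#!/usr/bin/env python
"""Which personal features and expedition-wide factors drive success?

Large-expedition cohort (rosters of 13-16) with a planted oxygen-ascent
effect: the bipartite feature projection and its eigenvector centralities
should place oxygen_ascent among the biggest success/no-success
differences. Expedition-wide factors are correlated with success rate.
"""
from pathlib import Path

from summitplex.features import (
    centrality_comparison,
    expedition_feature_centralities,
    factor_correlations,
)
from summitplex.records import expedition_success_rates
from summitplex.synthetic import GeneratorConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "tables"


def main() -> None:
    cfg = GeneratorConfig(
        n_climbers=200,
        n_expeditions=40,
        expedition_size_range=(13, 16),
        group_persistence=0.3,
        influence_effect=0.2,
        cooperative_spillover=0.0,
        polarized_penalty=0.0,
        base_success_logit=-0.6,
        feature_effects=(0.0, 0.0, 0.0, 0.0, 1.5, 0.0),
        rng_seed=42,
    )
    records, expeditions = generate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)

    cents = expedition_feature_centralities(records, expeditions)
    table = centrality_comparison(cents)
    table.to_csv(OUT / "feature_centrality.csv", index=False)
    print("feature centralities ordered by increasing success difference:")
    print(
        table[["feature", "mean_success", "mean_failure", "difference"]]
        .to_string(index=False)
    )

    rates = {
        s.expedition_id: s.success_rate
        for s in expedition_success_rates(records, expeditions)
    }
    factors = factor_correlations(expeditions, rates)
    factors.to_csv(OUT / "factor_correlations.csv", index=False)
    print("\nexpedition-wide factor correlations with success rate:")
    print(factors.to_string(index=False))
    print(
        "\nthe planted oxygen effect surfaces at the top of the centrality "
        "differences; among factors only expedition size picks up a real "
        "signal, inherited through the influence channel (bigger rosters "
        "intersect more history), while the rest hover near zero"
    )


if __name__ == "__main__":
    main()
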