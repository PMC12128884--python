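"""Why sigma-weighting matters when data quality varies.

A three-group study where 30% of the data sets carry threefold sigma
inflation on half their observations is clustered twice: once with the
sigma-weighted pairwise correlations (the default) and once unweighted.
The weighted run should match or beat the unweighted one.
"""

import dataclasses

from isoclust import PipelineOptions, ScenarioConfig, analyze_study, generate_study

cfg = ScenarioConfig(
    group_sizes=(12, 12, 12),
    n_unique=2500,
    coverage=0.7,
    delta=0.3,
    perturbed_fraction=0.05,
    noise_scale=0.15,
    hetero_fraction=0.3,
    multiplicity_mean=3.0,
    seed=1,
)
tables, meta, truth = generate_study(cfg)

for mode in ("sigma", "unweighted"):
    report = analyze_study(
        tables, meta, PipelineOptions(seed=1, weighting=mode), truth=truth
    )
    v = report.metrics["optics"]["v_measure"]
    k = report.optics_result.cluster_count
    print(f"{mode:>10} weighting: {k} clusters, V-Measure = {v:.3f}")
# V-Measure = 1.0 is a perfect recovery of the three planted species groups.
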