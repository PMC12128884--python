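"""Reading an OPTICS reachability profile.

On an unbalanced study (83/85/28 data sets per group plus 19 aberrant
ones) the OPTICS ordering visits each dense group in turn: cluster
members show low reachability (valleys), boundaries show spikes, and the
aberrant data sets never enter a valley and are labeled -1.
"""

import dataclasses

from isoclust import (
    PipelineOptions,
    analyze_study,
    generate_study,
    preset_scenarios,
    reachability_report,
)

cfg = dataclasses.replace(
    preset_scenarios()["three_group_unbalanced_outliers"], seed=1
)
tables, meta, truth = generate_study(cfg)
report = analyze_study(tables, meta, PipelineOptions(seed=1), truth=truth)

rows = reachability_report(report.optics_result, report.dataset_ids)
print("pos  dataset      reachability  label")
for pos, name, reach, label in rows[:10]:
    print(f"{pos:>3}  {name}  {reach:12.4f}  {label:>5}")
print("...")
print(f"clusters found : {report.optics_result.cluster_count}")
print(f"outliers (-1)  : {int((report.labels['optics'] == -1).sum())}")
print(f"V-Measure      : {report.metrics['optics']['v_measure']:.3f}")
# Low reachability = deep inside a dense cluster; the first point of each
# run and boundary points carry large values (infinity for seeds).
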