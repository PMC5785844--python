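"""Run the whole workflow on one dataset and render the report.

EFA with scree and parallel analysis, a one-factor confirmatory fit,
bootstrap EGA, a confirmatory fit of the structure the bootstrap proposes,
and the nested model comparison, in one call.
"""

from netdim import PipelineConfig, render_report, run_pipeline

cfg = PipelineConfig(preset="online_4dim", n=1000, seed=1, bootstrap_B=100)
report = run_pipeline(cfg)

print(render_report(report, "markdown"))
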