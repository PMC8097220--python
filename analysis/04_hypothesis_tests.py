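"""Locate the observed trade-off slope between two simulated hypotheses:
no evolutionary correlation (slope 0) and a strong trade-off (slope -1)."""

from common import load_json, study_config
from ovarevo.pipeline import run_pipeline

run_pipeline(study_config(["hypothesis"]))

s = load_json("hypothesis_summary.json")
null, strong = s["null_slope_0"], s["strong_slope_-1"]
print(f"observed residual-PGLS slope {null['observed_slope']:.3f}")
print(
    f"against the no-correlation simulations: quantile {null['observed_quantile']:.3f}, "
    f"inside central 95%: {null['inside_central_95']} (a false positive would sit inside)"
)
print(
    f"against the slope -1 simulations: quantile {strong['observed_quantile']:.3f}, "
    f"inside central 95%: {strong['inside_central_95']}"
)
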