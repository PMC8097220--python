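"""Shared run configuration for the numbered analysis scripts.

The scripts rerun the full study on a synthetic 128-tip dataset at a
desk-scale replication level (200 posterior regressions, 200 hypothesis
simulations, 25 ancestral-state replicates) and write every stage's output
under ``results/run/``.  Stage order matters: 01 must run before the rest.
"""

import json
import os

from ovarevo.pipeline import RunConfig

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results", "run")


def study_config(stages) -> RunConfig:
    return RunConfig.from_dict(
        {
            "stages": list(stages),
            "outdir": RESULTS,
            "seed": 404,
            "R": 200,
            "S": 200,
            "asr_replicates": 25,
            "adequacy_sims": 200,
            "generator": {"n_tips": 128, "n_posterior": 20},
        }
    )


def load_json(name: str) -> dict:
    with open(os.path.join(RESULTS, name)) as fh:
        return json.load(fh)
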