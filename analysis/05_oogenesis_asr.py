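"""Reconstruct the ancestral mode of oogenesis (nurse-cell arrangement)
and count evolutionary transitions between modes on the MAP painting."""

import os

import pandas as pd

from common import RESULTS, load_json, study_config
from ovarevo.pipeline import run_pipeline

run_pipeline(study_config(["asr"]))

s = load_json("asr_summary.json")
print(f"root MAP state: {s['root_map_state']} (marginals: " +
      ", ".join(f"{k} {v:.2f}" for k, v in s["root_marginal"].items()) + ")")
print("MAP transitions between modes:", s["map_transitions"])

support = pd.read_csv(os.path.join(RESULTS, "asr_clade_support.tsv"), sep="\t")
root = support[support["is_root"]]
if len(root):
    print(
        f"root MAP-state frequency across {int(root.iloc[0]['n_replicates'])} "
        f"posterior replicates: {root.iloc[0]['map_frequency']:.2f}"
    )
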