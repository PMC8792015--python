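"""Compare nucleosome occupancy between two reconstitution conditions.

Runs the full pipeline driver on two simulated conditions (with and
without a stabilizing factor, i.e. low vs high mean occupancy), fits a
Poisson rate per condition with a 10,000-resample bootstrap CI, and
compares rates with the exact conditional test.
"""

import json

from nucbubble.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    seed=11,
    conditions=[
        {"label": "octamer alone", "simulate": {"n_molecules": 150, "lambda_true": 0.3}},
        {"label": "octamer + factor", "simulate": {"n_molecules": 150, "lambda_true": 1.3}},
    ],
)
report = run_pipeline(cfg)

for label, cond in report["conditions"].items():
    print(
        f"{label}: lambda = {cond['lambda_hat']:.2f} "
        f"[{cond['ci_low']:.2f}, {cond['ci_high']:.2f}] (n = {cond['n_molecules']})"
    )
for pair, p in report["comparisons"].items():
    print(f"exact-Poisson test, {pair}: p = {p:.2e}")
print(f"report hash (determinism stamp): {report['report_hash']}")
# lambda is the average number of nucleosome-sized bubbles per DNA
# molecule; a small p-value says the two conditions' rates differ.
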