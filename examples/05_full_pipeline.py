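"""Run the whole evaluation end to end and write a report bundle.

One config drives synthesis, model fitting, adaptive-test simulation,
classification, predictive values and the fairness audit; everything is
written under the output directory (response table, fitted bank, fit
summary, per-patient results, metrics JSON, fairness report, markdown
report and summary figures).
"""

import json
import warnings
from pathlib import Path

from epdscat import PipelineConfig, run_pipeline

warnings.filterwarnings("ignore")

out = Path("pipeline_out")
config = PipelineConfig(
    output_dir=out,
    synth_n=2000,
    dimension=1,
    seed=42,
    reference_group="White",
    termination_delta=0.05,
)
report = run_pipeline(config)

print(json.dumps(
    {
        "cronbach_alpha": round(report["cronbach_alpha"], 3),
        "full_test_positive_rate": round(report["full_test_positive_rate"], 3),
        "cat_positive_rate": round(report["cat_positive_rate"], 3),
        "median_items": report["median_items"],
        "r": round(report["score_correlation"]["r"], 3),
        "npv": round(report["diagnostics"]["npv"], 3),
        "ppv": round(report["diagnostics"]["ppv"], 3),
        "fnr_chi2_p": round(report["fairness"]["p_value"], 3),
    },
    indent=2,
))
print(f"\nfull report bundle in {out}/ (see report.md)")
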