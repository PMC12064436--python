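"""Run the whole workflow in one configuration-driven call.

Equivalent to scripts 01–05 through the library's orchestrator, writing every
stage artifact, the reproducibility manifest and the run report under
results/pipeline_run/.  Pass a YAML config path to override the defaults.
"""

import sys
from pathlib import Path

from mixedfci.pipeline import PipelineConfig, run_pipeline, write_report

ROOT = Path(__file__).resolve().parents[1] / "results"

DEFAULT = {
    "seed": 20250927,
    "outdir": str(ROOT / "pipeline_run"),
    "simulation": {"n_observed": 20, "n_latent": 2, "n_samples": 2000,
                   "expected_degree": 2.0, "min_outcome_parents": 2},
    "imputation": {"m": 5},
    "discovery": {"pdsep_pool_cap": 6},
}


def main() -> None:
    if len(sys.argv) > 1:
        config = PipelineConfig.from_yaml(sys.argv[1])
    else:
        config = PipelineConfig.from_dict(DEFAULT)
    result = run_pipeline(config)
    print(write_report(result))
    print(f"artifacts in {config.outdir}")


if __name__ == "__main__":
    main()
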