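"""Prior sensitivity: widen the uniform prior on the field sds from
U(0, 10) to U(0, 100) and report the largest changes in SIR medians and
correlation medians.  Writes results/run/sensitivity.json.
"""

import json
import sys

from comap.pipeline import RunConfig, sensitivity_rerun


def main(seed: int = 0) -> None:
    config = RunConfig(seed=seed, outdir="results/run")
    report = sensitivity_rerun(config, {"prior_sd_upper": 100.0})
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
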