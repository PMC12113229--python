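"""Derive terrain/distance covariates and screen collinearity."""

import json
from pathlib import Path

import pandas as pd

from common import RESULTS, load_config
from ecoreserve.pipeline import run_preprocess, run_simulate


def main() -> None:
    cfg = load_config()
    run_simulate(cfg)
    man = run_preprocess(cfg)
    rep = json.loads(
        (Path(cfg.output_dir) / "preprocess" / "collinearity.json")
        .read_text()
    )
    rows = [{"covariate": n, "status": "retained",
             "vif": rep["vif"].get(n)} for n in rep["retained"]]
    rows += [{"covariate": n, "status": f"dropped: {why}", "vif": None}
             for n, why in rep["dropped"].items()]
    rows += [{"covariate": n, "status": "exempt (non-continuous)",
              "vif": None} for n in rep["exempt"]]
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "collinearity_screen.csv", index=False)
    print(f"preprocess: {'skipped (fresh)' if man.get('skipped') else 'done'}")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
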