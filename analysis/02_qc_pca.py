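"""Sample-level QC: principal component analysis of each omics layer,
annotated with the design factors. In this design the developmental-stage
trend and the location contrasts dominate the leading components."""

import json

import numpy as np

from _common import pipeline_config
from omicnet.pipeline import run_pipeline


def main() -> None:
    res = run_pipeline(pipeline_config(), upto="qc")
    for layer, fm in (("genes", res.genes), ("metabolites", res.metabolites)):
        ve = json.loads((res.outdir / "qc" / f"pca_{layer}_variance.json").read_text())
        print(f"{layer}: variance explained PC1/PC2 = "
              + "/".join(f"{v:.3f}" for v in ve["variance_explained"]))
        import pandas as pd
        scores = pd.read_csv(res.outdir / "qc" / f"pca_{layer}.tsv", sep="\t",
                             index_col=0)
        stage_idx = res.design.stage_index().to_numpy()
        for pc in ("PC1", "PC2"):
            r = np.corrcoef(scores[pc].to_numpy(), stage_idx)[0, 1]
            print(f"  |cor({pc}, stage index)| = {abs(r):.3f}")


if __name__ == "__main__":
    main()
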