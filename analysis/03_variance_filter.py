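"""Split transcripts into low- and high-variability components by EM on the
coefficient of variation and keep the high component for all downstream
stages (metabolites are not filtered)."""

import json

from _common import pipeline_config
from omicnet.pipeline import run_pipeline


def main() -> None:
    res = run_pipeline(pipeline_config(), upto="filter")
    fit = json.loads((res.outdir / "filter" / "mixture_fit.json").read_text())
    print(f"mixture means: {fit['means'][0]:.3f} (low) / {fit['means'][1]:.3f} (high), "
          f"weights {fit['weights'][0]:.2f}/{fit['weights'][1]:.2f}, "
          f"converged={fit['converged']} in {fit['n_iter']} iterations")
    print(f"retained {res.filtered_genes.n_features} / {res.genes.n_features} transcripts")


if __name__ == "__main__":
    main()
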