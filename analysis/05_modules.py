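"""Weighted co-expression modules (beta = 7, topological overlap, average
linkage) for the differential features of each layer, with eigengenes and
module-membership (kME) statistics."""

from _common import pipeline_config
from omicnet.pipeline import run_pipeline


def main() -> None:
    res = run_pipeline(pipeline_config(), upto="modules")
    for layer, ms in (("gene", res.gene_modules), ("metabolite", res.metab_modules)):
        sizes = {m: len(ms.members(m)) for m in ms.module_names}
        n_grey = int((ms.assignment == "grey").sum())
        print(f"{layer} modules: {sizes} (+{n_grey} grey)")
        top = {m: ms.kme.loc[ms.members(m), m].idxmax() for m in ms.module_names}
        print(f"  hub (top own-module kME): {top}")


if __name__ == "__main__":
    main()
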