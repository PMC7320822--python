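"""Two-way Pearson integration: every metabolite against each gene-module
eigengene and every module gene against each metabolite-module eigengene
(p < 0.01), tabulated per module pair with reciprocal-support flags."""

from _common import pipeline_config
from omicnet.pipeline import run_pipeline


def main() -> None:
    res = run_pipeline(pipeline_config(), upto="integrate")
    fwd = res.integration_forward.table
    rev = res.integration_reverse.table
    print(f"metabolite vs gene-ME: {int(fwd['significant'].sum())} significant pairs")
    print(f"gene vs metabolite-ME: {int(rev['significant'].sum())} significant pairs")
    rec = res.links[res.links["reciprocal"]].sort_values("support", ascending=False)
    print("reciprocally supported module pairs (gene module, metabolite module, "
          "support, sign):")
    for row in rec.itertuples(index=False):
        print(f"  {row.gene_module:9s} {row.metab_module:9s} {row.support:4d} "
              f"{'+' if row.sign > 0 else '-'}")


if __name__ == "__main__":
    main()
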