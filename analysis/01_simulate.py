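"""Generate the synthetic two-layer dataset that drives the whole analysis:
2,000 transcripts and 500 metabolites over a 3 varieties x 3 locations x
6 stages x 2 replicates design, with planted modules, cross-layer couplings
and one regulator carrying signal in every evidence channel."""

from _common import pipeline_config
from omicnet.pipeline import run_pipeline


def main() -> None:
    res = run_pipeline(pipeline_config(), upto="simulate")
    truth = res.truth
    print(f"genes: {res.genes.data.shape}, metabolites: {res.metabolites.data.shape}")
    print(f"samples: {len(res.design.sample_ids)} "
          f"({res.design.n_levels('variety')} varieties x "
          f"{res.design.n_levels('location')} locations x "
          f"{res.design.n_levels('stage')} stages)")
    n_mod = {m for m in truth.module_assignment_true.values() if m != 'none'}
    print(f"planted modules: {sorted(n_mod)}")
    print(f"planted regulator: {truth.planted_regulator} with "
          f"{len(truth.regulator_targets_true[truth.planted_regulator])} targets")
    print(f"outputs under {res.outdir / 'simulate'}")


if __name__ == "__main__":
    main()
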