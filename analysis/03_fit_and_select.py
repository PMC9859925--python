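"""Fit the candidate dose-response configurations and compare by AIC.

For each endpoint: the no-effect null, the fully shared exponential curve,
and the parallel-curve model (potency per compound, background per study,
shared plateau and steepness).  Writes the AIC comparison to
results/aic_<endpoint>.tsv.
"""

from pathlib import Path

import pfasrpf as p

SEED = 20260920
OUT = Path("results")


def main() -> None:
    for endpoint in ("RAG1", "RAG2"):
        table = p.read_summary_table(OUT / f"summary_{endpoint}.tsv", endpoint)
        fits = [p.fit_model(table, spec, seed=SEED) for spec in p.default_candidates()]
        selected = p.select_model(fits)
        with open(OUT / f"aic_{endpoint}.tsv", "w") as fh:
            fh.write("model\tk\tloglik\taic\tselected\n")
            for fit in fits:
                name = ("null" if not fit.spec.include_effect
                        else "shared" if fit.spec.b_by == "shared" else "parallel")
                fh.write(f"{name}\t{fit.k}\t{fit.loglik:.4f}\t{fit.aic:.4f}"
                         f"\t{'yes' if fit is selected else 'no'}\n")
        print(f"{endpoint}: selected "
              f"{'parallel' if selected.spec.is_parallel else 'non-parallel'} model "
              f"(AIC {selected.aic:.1f}); potencies b = "
              + ", ".join(f"{c}={v:.2f}µM" for c, v in selected.params.b.items()))


if __name__ == "__main__":
    main()
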