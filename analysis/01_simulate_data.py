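"""Generate the synthetic RAG1 and RAG2 concentration-response experiments.

Stands in for the wet-lab inputs: two endpoints, four PFASs with
endpoint-specific potencies (magnitudes mirroring the published BMC10
table), shared plateau and steepness, two independent studies in triplicate,
lognormal well noise at 15% CV.  Writes Cq-level TSVs plus the summary
tables under results/synthetic/.
"""

from pathlib import Path

import pfasrpf as p

OUT = Path("results/synthetic")
SEED = 20260920

RAG2_POTENCIES = {"PFOA": 8.8, "PFOS": 13.3, "PFNA": 4.9, "PFHxS": 33.2}


def design_for(endpoint: str, seed: int) -> p.SimDesign:
    if endpoint == "RAG1":
        return p.SimDesign(seed=seed, endpoint="RAG1")
    return p.SimDesign(
        seed=seed, endpoint="RAG2", compounds=RAG2_POTENCIES,
        concentrations={c: p.default_grid(33.0 if c == "PFNA" else 100.0)
                        for c in RAG2_POTENCIES},
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for offset, endpoint in enumerate(("RAG1", "RAG2")):
        design = design_for(endpoint, SEED + offset)
        records, series, design_map = p.simulate_qpcr_experiment(design)
        with open(OUT / f"cq_{endpoint}.tsv", "w") as fh:
            fh.write("sample\tgene\tcq\n")
            for r in records:
                fh.write(f"{r.sample}\t{r.gene}\t{r.cq!r}\n")
        with open(OUT / f"standard_curve_{endpoint}.tsv", "w") as fh:
            fh.write("gene\tdilution\tcq\n")
            for gene, pts in series.items():
                for dil, cq in pts:
                    fh.write(f"{gene}\t{dil!r}\t{cq!r}\n")
        with open(OUT / f"design_{endpoint}.tsv", "w") as fh:
            fh.write("sample\tcompound\tstudy\tconcentration\n")
            for sample, (compound, study, conc) in design_map.items():
                fh.write(f"{sample}\t{compound}\t{study}\t{conc!r}\n")
        table = p.simulate_summary_table(design)
        p.write_summary_table(table, OUT / f"summary_{endpoint}.tsv")
        print(f"{endpoint}: {len(records)} Cq records, {len(table.rows)} summary groups "
              f"-> {OUT}/*_{endpoint}.tsv")


if __name__ == "__main__":
    main()
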