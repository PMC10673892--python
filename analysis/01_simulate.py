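#!/usr/bin/env python
"""Generate the default synthetic study and write its input files.

The study plants everything the later stages must recover: a 75-gene
co-expressed MIA module plus 24 unlabelled ADH discovery targets, 9 linked
metabolites, 1908 flat conserved negatives, four anchor+MDR gene clusters
inside the 100 kb scan window and four near-miss decoys just outside it.
Files go to scratch/study/ (large, regenerable); a small summary goes to
results/.
"""

import argparse
import json
from pathlib import Path

from miaminer import SimulationConfig, generate_study, write_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=ROOT / "scratch" / "study")
    args = ap.parse_args()

    config = SimulationConfig(seed=args.seed)
    study = generate_study(config)
    paths = write_study(study, args.outdir)

    summary = {
        "seed": args.seed,
        "n_samples": study.tpm.shape[1],
        "n_tissues": config.n_tissues,
        "n_genes": config.n_genes,
        "n_module_genes_labelled": len(study.truth.module_gene_ids),
        "n_module_adh_targets": len(study.truth.module_adh_gene_ids),
        "n_negatives": len(study.truth.negative_gene_ids),
        "n_metabolites": study.metabolites.shape[0],
        "n_linked_metabolites": len(study.truth.linked_metabolite_ids),
        "n_planted_clusters": len(study.truth.planted_clusters),
        "n_decoys": len(study.truth.decoy_gene_ids),
        "proteome_size": len(study.proteome),
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "study_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"wrote {len(paths)} study files to {args.outdir}")
    for k, v in summary.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
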