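#!/usr/bin/env python
"""Compute the per-window transcript-feature table for the simulated genes.

Learns the AUG-context PSSM from the top-expressed genes, then scores every
5'UTR-anchored 30-nt window: folding energies (Nussinov proxy), AUG context
features, composition and (optionally) HOMER motif scores.
"""

import argparse
import json
from pathlib import Path

from tcpscan import features, profiles
from tcpscan.folding import NussinovBackend


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--motifs", type=Path, default=None,
                    help="optional HOMER motif file")
    ap.add_argument("--max-windows", type=int, default=5000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ann = profiles.read_annotations(args.sim / "transcripts.fa",
                                    args.sim / "utr5.tsv", args.sim / "mrna.tsv")
    pssm = features.build_context_pssm(ann, top_fraction=0.05)
    motifs = features.read_homer_motifs(args.motifs) if args.motifs else []
    windows = [(a.gene_id, s) for a in ann for s in range(a.utr5_len)]
    windows = windows[: args.max_windows]
    table = features.assemble_feature_table(windows, ann, pssm, motifs,
                                            NussinovBackend())
    table.to_csv(args.out / "features.tsv", sep="\t")
    registry = {"columns": list(table.columns),
                "n_motifs": len(motifs),
                "dist_sentinel": features.DIST_SENTINEL,
                "score_sentinel": pssm.score_sentinel}
    (args.out / "feature_registry.json").write_text(json.dumps(registry, indent=2))
    print(f"feature table: {table.shape[0]} windows x {table.shape[1]} features "
          f"-> features.tsv (+ registry)")


if __name__ == "__main__":
    main()
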