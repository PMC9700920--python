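"""Build patient sentences and train the code embedding.

Writes sentences.txt (one whitespace-joined sentence per cohort patient, with
a sidecar line index) and embeddings.tsv (token -> vector).  Prints corpus
statistics and, as a qualitative check, the nearest neighbours of a few
tokens — codes from the same planted cluster should dominate.
"""

import argparse

import numpy as np

from study_config import ARTIFACTS, study_config

from readmit.embedding import load_embedding
from readmit.pipeline import stage_embed


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = study_config(args.seed)
    stage_embed(cfg, ARTIFACTS)

    lines = (ARTIFACTS / "sentences.txt").read_text().splitlines()
    lengths = [len(l.split()) for l in lines if l]
    print(f"{len(lines)} sentences, mean length {np.mean(lengths):.1f} tokens")
    emb = load_embedding(ARTIFACTS / "embeddings.tsv")
    print(f"vocabulary: {len(emb)} tokens, dimension {emb.dimension}")
    for probe in emb.tokens[1:4]:
        sims = sorted(
            ((emb.similarity(probe, t), t) for t in emb.tokens if t != probe),
            reverse=True,
        )[:5]
        nbrs = ", ".join(f"{t} ({s:.2f})" for s, t in sims)
        print(f"  nearest to {probe}: {nbrs}")


if __name__ == "__main__":
    main()
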