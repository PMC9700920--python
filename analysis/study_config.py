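"""Shared study configuration for the numbered analysis drivers.

One synthetic population of 10,000 patients over a 2011-2017 observation
window, with the final two calendar years as the index window, a 6% base
30-day readmission rate, and a unit log-odds latent-risk effect.  Embeddings
use 32 dimensions and 5 epochs — small enough to retrain per CV split on a
single core, large enough to separate the planted code clusters.
"""

from pathlib import Path

from readmit.config import RunConfig
from readmit.embedding import CBOWConfig
from readmit.synth import SynthConfig

ARTIFACTS = Path(__file__).resolve().parents[1] / "results" / "study"


def study_config(seed: int = 1) -> RunConfig:
    return RunConfig(
        synth=SynthConfig(n_patients=10_000, risk_effect=1.0),
        embedding=CBOWConfig(dimension=32, window=5, min_count=5, epochs=5),
        seed=seed,
    )
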