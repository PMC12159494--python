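"""Shared settings for the analysis drivers: desk-scale study
conditions and output locations.

Every driver re-derives its inputs deterministically from SEED, so the
scripts can be run independently and in any order.
"""

from __future__ import annotations

from pathlib import Path

from vasowave.core import AcquisitionSpec
from vasowave.atlas import build_atlas
from vasowave.synth import simulate_cohort

SEED = 42
RESULTS = Path(__file__).resolve().parent.parent / "results"

#: desk-scale resting acquisition: 6.4 x 6.4 mm, 10 min at 0.4 s
SPEC = AcquisitionSpec(64, 64, 1500)
N_SCANS_PER_ARM = 3


def atlas():
    return build_atlas(SPEC)


def cohort(arm: str, atlas_obj=None):
    """The study cohort for one arm (deterministic in SEED)."""
    return simulate_cohort(arm, N_SCANS_PER_ARM, SPEC, seed=SEED,
                           atlas=atlas_obj or atlas())


def out_dir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
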