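"""Shared plumbing for the numbered analysis drivers.

Every driver works from the same exported synthetic world under
``results/world`` (seed 0); the first driver creates it, later drivers
load it so each script can also be run on its own.
"""

from __future__ import annotations

from pathlib import Path

from mycolink import WorldConfig, export_world, generate_world, load_world

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
WORLD_DIR = RESULTS / "world"
SEED = 0


def get_world():
    if (WORLD_DIR / "truth.json").exists():
        return load_world(WORLD_DIR)
    world = generate_world(WorldConfig(seed=SEED))
    export_world(world, WORLD_DIR)
    return world
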