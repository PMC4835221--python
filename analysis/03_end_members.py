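#!/usr/bin/env python
"""Derive the mixing-model end members from the simulated bulk soil and
groundwater samples: per-slope-position surface compositions (depth-
regression intercepts at 0 cm) plus the pooled catchment set."""

import argparse
from pathlib import Path

from rootwater import Source, build_end_member_sets
from rootwater.io import read_water_samples, write_end_members

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path,
                    default=Path(__file__).resolve().parents[1] / "results")
args = parser.parse_args()

samples = read_water_samples(args.results / "catchment" / "water_samples.csv")
sets = build_end_member_sets(
    [s for s in samples if s.source == Source.BULK_SOIL],
    [s for s in samples if s.source == Source.GROUNDWATER],
)
write_end_members(sets, args.results / "end_members.csv")

for key, em in sets.items():
    tag = key.value if hasattr(key, "value") else key
    print(f"{tag:9s} surface ({em.surface.d18O:6.2f}, {em.surface.d2H:7.2f})  "
          f"groundwater ({em.groundwater.d18O:6.2f}, {em.groundwater.d2H:7.2f})")
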