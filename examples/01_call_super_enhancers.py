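"""Call super-enhancers on a small synthetic tissue and compare to truth.

Builds a seeded bundle, stitches H3K27ac peaks (< 12.5 kb gaps), ranks the
stitched regions by signal area, and applies the slope-1 tangent cutoff.
"""

from pathlib import Path
import tempfile

from regland import io as rio
from regland.simulate import SimulationConfig, simulate
from regland.superenhancer import call_super_enhancers, rank_by_signal, stitch_enhancers

with tempfile.TemporaryDirectory() as tmp:
    bundle = Path(tmp) / "bundle"
    manifest = simulate(SimulationConfig(seed=1), bundle)

    peaks = rio.read_bed(bundle / "h3k27ac_peaks.bed")
    track = rio.read_bedgraph(bundle / "h3k27ac.bedgraph")
    call = call_super_enhancers(rank_by_signal(stitch_enhancers(peaks), track))

    print(f"stitched regions : {len(call.enhancers)}")
    print(f"super-enhancers  : {call.cutoff_index} (planted: {len(manifest.se_intervals[manifest.focal])})")
    top = call.enhancers[0]
    bottom = call.enhancers[-1]
    print(f"strongest region : {top.interval.chrom}:{top.interval.start}-{top.interval.end} "
          f"signal={top.signal:.0f}")
    print(f"weakest region   : signal={bottom.signal:.0f}")
    # The SE/typical split sits where the ranked-signal curve's tangent has
    # slope 1; planted SEs carry ~100x the signal area of typical enhancers,
    # so the call recovers exactly the planted set.
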