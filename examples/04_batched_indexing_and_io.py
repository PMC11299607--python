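"""Batch indexing of many frames plus JSON / stream output.

Pads-and-prunes a set of variable-size frames to a fixed spot count,
indexes the batch, writes the results as JSON and as a CrystFEL-stream-like
text file, and prints the indexing rate.
"""

import tempfile
from pathlib import Path

from toro_indexer import (
    GeometryConfig,
    IndexerParams,
    UnitCell,
    index_batch,
    prune_and_pad,
    simulate_frame,
    write_solutions,
)

cell = UnitCell(40.0, 45.0, 50.0, 90.0, 90.0, 90.0, "orthorhombic", "P")
geom = GeometryConfig(wavelength=1.0, distance=100.0)
params = IndexerParams.from_preset("rt", lattice_size=2000)

frames = [
    simulate_frame(
        cell, geom, n_spots=n, noise_sigma=0.25 * params.max_error_beta,
        outlier_fraction=0.15, seed=100 + i, frame_id=f"frame-{i:03d}",
    ).spots
    for i, n in enumerate((40, 55, 30, 70, 45))
]

batch = prune_and_pad(frames, params.max_spots)
print(f"batch: {len(batch)} frames padded/pruned to {params.max_spots} spots")

results = index_batch(batch, cell, params)
indexed = sum(bool(sols) for sols in results)
print(f"indexing rate: {indexed}/{len(batch)} frames "
      f"({100 * indexed / len(batch):.0f}%)")
for fid, sols in zip(batch.frame_ids, results):
    if sols:
        print(f"  {fid}: {sols[0].num_inliers} inliers, "
              f"penalty {sols[0].penalty:.4f}")

outdir = Path(tempfile.mkdtemp())
pairs = list(zip(batch.frame_ids, results))
write_solutions(pairs, outdir / "solutions.json", format="json")
write_solutions(pairs, outdir / "solutions.stream", format="stream")
print(f"\nwrote {outdir / 'solutions.json'} and .stream; stream excerpt:")
print("\n".join((outdir / "solutions.stream").read_text().splitlines()[:8]))
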