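"""Segment a µCT stack end to end and print its whole-test morphometrics.

Creates a phantom stack on disk, then runs the same file-based pipeline a
user would run on a real scan (`foramct run`): infill removal, calcite
threshold, fill, wall split, thickness, watershed chambers.  Prints the
morphometric summary; every image and CSV lands next to the input.
"""

import dataclasses
from pathlib import Path

from foramct import (
    PhantomSpec,
    generate_phantom,
    process,
    read_stack,
    recovery_config,
    run_single,
    write_stack,
)

out = Path("scratch/example_run")
spec = PhantomSpec(n_chambers=5, infill_frac=0.3, rng_seed=42)
grid, truth = generate_phantom(spec)
out.mkdir(parents=True, exist_ok=True)
stack = out / "SPEC_042.tif"
write_stack(grid, stack)

cfg = dataclasses.replace(recovery_config(spec), input=stack, out_root=out)
manifest = run_single(cfg)
print(f"{len(manifest)} files written under {out}/")

# re-load and summarise in memory
products = process(read_stack(stack, cfg.spacing), cfg)
m = products.morphometrics
print(f"calcite volume:  {m.calcite_volume_um3:12.0f} um^3")
print(f"test volume:     {m.test_volume_um3:12.0f} um^3")
print(f"chamber volume:  {m.chamber_volume_um3:12.0f} um^3")
print(f"surface area:    {m.surface_area_um2:12.0f} um^2")
print(f"porosity:        {m.porosity_pct:12.2f} %   (truth: {truth.porosity_pct:.2f} %)")
print(f"chambers found:  {len(products.chamber_records):12d}     (truth: 5)")
print(f"outer wall mean thickness: {products.outer_thickness_summary.mean_um:.2f} um (truth: 6.0 um)")
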