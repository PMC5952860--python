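"""Build a synthetic joint with known lesions and run the detection pipeline.

The phantom is a metacarpal-head-like cortical shell with a trabecular
lattice, two drilled cortical interruptions (0.7 and 1.0 mm bores) and
sub-cortical voids of 2 and 3 mm^3 beneath them. The pipeline segments the
volume, finds the interruptions in a 4-voxel cortical peel, and attaches the
underlying void volume to each.
"""

from cortigap import InterruptionSpec, PhantomSpec, PipelineConfig, make_joint_phantom, run_joint

spec = PhantomSpec(
    shape_voxels=(96, 96, 96),
    outer_radius_mm=3.4,
    cortex_thickness_mm=0.7,
    interruptions=[
        InterruptionSpec(diameter_mm=0.7, void_volume_mm3=2.0, position=(0, 0, 1)),
        InterruptionSpec(diameter_mm=1.0, void_volume_mm3=3.0, position=(0, 1, 0)),
    ],
    seed=42,
)
vol, truth = make_joint_phantom(spec)
result = run_joint(vol, PipelineConfig(compute_morphometry=False), joint_id="demo")

m = result.metrics
print(f"interruptions detected : {m.n_interruptions} (truth: {truth.n_interruptions})")
print(f"total surface          : {m.total_surface_mm2:.2f} mm^2")
print(f"total volume           : {m.total_volume_mm3:.2f} mm^3 "
      "(cortical interruption + attached trabecular void)")
for row in m.per_interruption:
    print(f"  lesion {row.interruption_ids}: surface {row.surface_mm2:.2f} mm^2, "
          f"volume {row.volume_mm3:.2f} mm^3")
expected = sum(c.peel_channel_volume_mm3 + c.void_volume_mm3 for c in truth.components)
print(f"ground-truth volume    : {expected:.2f} mm^3")
print("The per-lesion volumes should bracket the carved channel+void volumes;")
print("small overshoot reflects the 0.738 mm opening's fringe at the void surface.")
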