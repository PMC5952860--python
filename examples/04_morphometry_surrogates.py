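"""Structural parameter surrogates on a lesion-free phantom.

Local-thickness (largest inscribed sphere) maps yield trabecular thickness
and separation, cortical thickness, and cortical porosity. Densities in
mg HA/cm^3 need a scanner calibration phantom and are replaced by the bone
volume fraction (BV/TV) and mean attenuation.
"""

from cortigap import PhantomSpec, PipelineConfig, make_joint_phantom, run_joint

spec = PhantomSpec(shape_voxels=(96, 96, 96), outer_radius_mm=3.4,
                   cortex_thickness_mm=0.7, seed=7)
vol, truth = make_joint_phantom(spec)
res = run_joint(vol, PipelineConfig(), joint_id="morpho-demo")
m = res.morphometry

print(f"BV/TV (total)      : {m.bvtv_total:.3f}")
print(f"BV/TV (trabecular) : {m.bvtv_trab:.3f}")
print(f"mean attenuation   : {m.mean_attenuation:.0f} gray units")
print(f"Tb.Th              : {m.tb_th_mm * 1000:.0f} um")
print(f"Tb.Sp              : {m.tb_sp_mm * 1000:.0f} um (drawn pore size: 630 um)")
print(f"Tb.SpSD            : {m.tb_spsd_mm * 1000:.0f} um")
print(f"Tb.N ({m.tb_n_method:>11s}) : {m.tb_n_per_mm:.2f} /mm")
print(f"Ct.Th              : {m.ct_th_mm * 1000:.0f} um (drawn shell: 700 um)")
print(f"Ct.Po              : {100 * m.ct_po_fraction:.2f} %")
print(f"Ct.Po.Dm           : {m.ct_po_dm_mm * 1000:.0f} um")
print("Tb.Th exceeds the drawn 250 um rod width because the 40% threshold")
print("thickens rods and merges them at lattice nodes into plate-like blobs;")
print("noise-induced porosity on an intact shell stays well below 1%.")
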