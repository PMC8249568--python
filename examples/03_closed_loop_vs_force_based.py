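"""Closed-loop check against the conventional force-based route.

The membrane solver pressurizes the vessel (pressure is the known condition,
deformation the unknown) and records the equilibrium hoop stress. The motion-
based pipeline then sees only the resulting geometry sequence and must
recover that stress from the observed wall motion alone — the two directions
of vascular mechanics meeting in the middle.
"""

from sws4d import (
    PlaqueSpec,
    compute_stenosis_profile,
    compute_strain_series,
    compute_stress_series,
    default_materials,
    forward_pressurized_sequence,
    laplace_hoop_stress,
    make_stenosis_model,
    propagate_cycle,
)

materials = default_materials()
vessel = make_stenosis_model(PlaqueSpec(composition="lipid_rich", burden_target=0.509))

seq = forward_pressurized_sequence(vessel, target_pulsation=0.12, materials=materials)
p_es = float(seq.ground_truth["pressure_kpa"].max())
print(f"peak transmural pressure for 12% pulsation: {p_es:.2f} kPa "
      f"({p_es / 0.13332:.0f} mmHg)")

cycle = propagate_cycle(seq)
strains = compute_strain_series(cycle.grids, mode="cumulative")
profile = compute_stenosis_profile(seq.frames[0])
stresses = compute_stress_series(
    strains, profile,
    {"normal": materials["normal"], "lipid_rich": materials["lipid_rich"]},
    lesion_class="lipid_rich",
)

es_idx = next(i for i, f in enumerate(seq.frames) if f.phase == "end_systole")
es = next(st for st in stresses if st.frame_index == es_idx)
row = 20  # ~10 mm from the ostium, well inside the normal segment
recovered = float(es.principal_cauchy[0][row].mean())
truth = float(seq.ground_truth["hoop_stress"][es_idx, row])
thin_wall = laplace_hoop_stress(
    p_es,
    float(seq.frames[es_idx].ring_radius[row]),
    float(vessel.wall_thickness[row] / (seq.frames[es_idx].ring_radius[row] / vessel.lumen.ring_radius[row])),
)
print(f"normal-segment hoop stress at end-systole:")
print(f"  force-based (membrane equilibrium): {truth:.2f} kPa")
print(f"  motion-based (inverse pipeline):    {recovered:.2f} kPa "
      f"({100 * abs(recovered - truth) / truth:.3f} % off)")
print(f"  thin-wall Laplace estimate:         {thin_wall:.2f} kPa")
# Agreement within a fraction of a percent: the inverse method reads the
# same mechanical state off the motion that the forward solver imposed.
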