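"""Stability monitoring of a conformational ensemble.

Builds a small synthetic three-chain complex with harmonic fluctuations,
then computes the two standard stability monitors: the backbone RMSD time
series from the starting structure (with its linear drift) and the
mass-weighted radius of gyration.  A flat RMSD and a constant R_G indicate
the complex neither relaxes away from its reference nor dissociates.
"""

from pmhcdyn import (
    SyntheticSpec,
    generate_ensemble,
    radius_of_gyration,
    rmsd_series,
    select_all,
    select_backbone,
    toy_complex_topology,
)

topology, mean = toy_complex_topology(
    n_residues_presenter=10, n_residues_peptide=3, n_residues_receptor=8,
    charged_fraction=0.4, seed=1,
)
spec = SyntheticSpec(
    topology=topology, mean_coordinates=mean,
    n_frames=2000, noise_sigma=0.25, frame_interval=1.0, seed=2,
)
ensemble = generate_ensemble(spec)

backbone = select_backbone(topology)
series = rmsd_series(ensemble, mean, backbone, reference_label="mean structure")
rg = radius_of_gyration(ensemble, select_all(topology))

print(f"frames:         {ensemble.n_frames} ({ensemble.n_frames / 1000:.1f} ns at 1 ps/frame)")
print(f"average RMSD:   {series.average:.2f} A")
print(f"maximum RMSD:   {series.maximum:.2f} A")
print(f"RMSD drift:     {series.drift:.1f} +- {series.drift_stderr:.1f} pm/ns")
print(f"<R_G>:          {rg.mean:.2f} +- {rg.sem:.4f} A")
print()
print("A drift compatible with zero and a stable R_G mean say the ensemble")
print("is stationary: no net relaxation, no unfolding, no dissociation.")
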