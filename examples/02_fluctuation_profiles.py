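"""Comparing per-residue flexibility between two ensembles.

Generates a "stiff" and a "floppy" variant of the same complex (different
per-residue fluctuation amplitudes), computes their backbone RMSF profiles,
the per-residue difference map and a paired t-test on the profiles.  The
positive sign convention: a positive difference means the first ensemble is
more mobile at that residue.
"""

import numpy as np

from pmhcdyn import (
    SyntheticSpec,
    compare_profiles_ttest,
    generate_ensemble,
    profile_difference,
    rmsf_profile,
    select_backbone,
    toy_complex_topology,
)

topology, mean = toy_complex_topology(10, 3, 8, charged_fraction=0.4, seed=3)
backbone = select_backbone(topology)


def make_profile(sigma, seed):
    spec = SyntheticSpec(topology=topology, mean_coordinates=mean,
                         n_frames=3000, noise_sigma=sigma, seed=seed)
    return rmsf_profile(generate_ensemble(spec), backbone, scope="backbone")


floppy = make_profile(sigma=0.45, seed=4)
stiff = make_profile(sigma=0.30, seed=5)

diff = profile_difference(floppy, stiff)
report = compare_profiles_ttest(floppy, stiff, alpha=0.05)

print(f"mean RMSF (floppy): {np.mean(floppy.rmsf):.3f} A  (expect ~sqrt(3)*0.45 = 0.779)")
print(f"mean RMSF (stiff):  {np.mean(stiff.rmsf):.3f} A  (expect ~sqrt(3)*0.30 = 0.520)")
print(f"mean difference:    {report.mean_difference:+.3f} A")
print(f"paired t-test:      t = {report.statistic:.1f}, p = {report.pvalue:.2e}, "
      f"significant at 5%: {report.significant}")
print()
print("Every residue of the floppy variant fluctuates more, so the paired")
print("test across residues flags a highly significant mobility increase.")
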