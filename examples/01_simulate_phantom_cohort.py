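"""Generate a small synthetic PET/CT phantom cohort and inspect it.

Each phantom carries a CT (air border, soft tissue, vertebral bodies)
and a PET with per-patient liver and bone-marrow plateaus, voxel noise
and planted ellipsoidal lesions whose minimum SUV is a known fraction of
the patient's liver uptake.
"""

from fltseg import CohortSpec, generate_cohort

spec = CohortSpec(n_patients=3, seed=42)
cohort = generate_cohort(spec)

print(f"{len(cohort)} scans generated ({spec.n_patients} patients x {len(spec.stages)} stages)")
print(f"grid {spec.grid_shape} voxels at {spec.voxel_spacing} mm\n")
print(f"{'scan':>14} {'liver SUV':>10} {'marrow SUV':>11} {'lesions':>8}")
for (pid, stage), (pair, gt) in sorted(cohort.items()):
    print(
        f"{pid + '/' + stage:>14} {gt.true_liver_suv:10.2f} "
        f"{gt.true_marrow_suv:11.2f} {len(gt.lesion_masks):8d}"
    )

pair, gt = cohort[("P01", "baseline")]
lid, mask = next(iter(gt.lesion_masks.items()))
print(
    f"\nlesion {lid}: designed min SUV {gt.lesion_min_suv[lid]:.2f}, "
    f"realized voxel min {pair.pet[mask].min():.2f} "
    f"({mask.sum()} voxels)"
)
print(
    "True uptakes are drawn from the cohort distributions "
    "(liver 5.1 +/- 1.4, marrow 7.8 +/- 2.7 SUV); the realized lesion "
    "minimum should match the designed value closely."
)
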