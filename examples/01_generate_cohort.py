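"""Generate a small synthetic screening cohort and inspect its manifest.

Builds a longitudinal cohort (3 visits per subject, breast masks, a lesion
emerging at the final visit for positive subjects with a subtler precursor in
the last negative visit), then prints the manifest summary: cohort sizes,
train/validation/test split, scanner-period distribution and final grades.
"""

from diffanomaly import CohortConfig, generate_cohort

config = CohortConfig(
    n_negative=12, n_positive=6, n_visits=3,
    volume_shape=(6, 32, 32), lesion_radius_vox=2.5,
    precursor_contrast=0.2, lesion_contrast=0.7,
    scanner_shift_prob=0.3, seed=7,
)
cohort = generate_cohort(config)
manifest = cohort.manifest

print("subjects per cohort and split:")
print(manifest.groupby(["cohort", "split"]).subject_id.nunique().to_string())
print("\nvisits acquired on the shifted 'period 1' scanner:",
      int((manifest.scanner_period == 1).sum()), "of", len(manifest))
final = manifest[manifest.visit_index == config.n_visits - 1]
print("final-visit grade distribution:")
print(final.groupby(["cohort", "grade"]).size().to_string())

subject = cohort.subjects[-1]  # a positive subject
print(f"\nsubject {subject.subject_id}: lesion of",
      int(subject.lesion_mask.sum()), "voxels at", subject.lesion_center)
# The grades of visits 1..n-1 are all 1 (negative screens); only the final
# visit of a positive subject carries the lesion.
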