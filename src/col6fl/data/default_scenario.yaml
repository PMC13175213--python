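# Default two-site benchmark scenario.
#
# Class-conditional texture bounds are uniform sampling intervals for the
# procedural matrix phenotypes.  Intervals overlap pairwise so the four-class
# task is learnable but not trivially saturated:
#   control              - dense, highly oriented, intact fibrils
#   glycine_substitution - speckled: many puncta, poorly oriented fibrils
#   pseudoexon_insertion - intermediate density, washed-out bead periodicity
#   exon_skipping        - sparse, heavily fragmented fibrils
texture_bounds:
  control:
    filament_density: [5.0, 8.0]
    orientation_coherence: [0.60, 0.90]
    bead_spacing: [8.0, 12.0]
    bead_contrast: [0.35, 0.65]
    fragmentation: [0.00, 0.15]
    puncta_rate: [0.0, 2.0]
  glycine_substitution:
    filament_density: [3.5, 6.5]
    orientation_coherence: [0.25, 0.55]
    bead_spacing: [8.0, 12.0]
    bead_contrast: [0.35, 0.65]
    fragmentation: [0.20, 0.50]
    puncta_rate: [8.0, 14.0]
  pseudoexon_insertion:
    filament_density: [2.8, 5.3]
    orientation_coherence: [0.50, 0.80]
    bead_spacing: [8.0, 12.0]
    bead_contrast: [0.00, 0.15]
    fragmentation: [0.15, 0.40]
    puncta_rate: [1.0, 4.0]
  exon_skipping:
    filament_density: [1.2, 3.4]
    orientation_coherence: [0.45, 0.75]
    bead_spacing: [8.0, 12.0]
    bead_contrast: [0.35, 0.65]
    fragmentation: [0.60, 0.95]
    puncta_rate: [1.0, 4.0]

# Two sites with the published image distribution (large site: 300 images,
# small site: 31) and deliberately different acquisition physics so the
# benchmark is non-IID in both covariates and label proportions.
sites:
  - site_id: NIH
    brightness_gain: 1.0
    blur_sigma: 1.0
    noise_sd: 0.02
    background_level: 0.08
    native_size: [512, 512]
    class_counts:
      control: 84
      glycine_substitution: 94
      pseudoexon_insertion: 51
      exon_skipping: 71
    patients_per_class:
      control: 22
      glycine_substitution: 25
      pseudoexon_insertion: 14
      exon_skipping: 19
    images_per_patient: [2, 6]
  - site_id: UCL
    brightness_gain: 1.6
    blur_sigma: 2.0
    noise_sd: 0.06
    background_level: 0.20
    native_size: [640, 640]
    class_counts:
      control: 7
      glycine_substitution: 5
      pseudoexon_insertion: 8
      exon_skipping: 11
    patients_per_class:
      control: 2
      glycine_substitution: 2
      pseudoexon_insertion: 3
      exon_skipping: 3
    images_per_patient: [2, 6]

# Held-out test images per site (patient-level selection).
test_counts:
  NIH: 20
  UCL: 4
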