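# Example configuration entries for common reference atlases.
#
# Atlas files do not store a bregma reference, so the loaders require an
# explicit bregma voxel.  The entries below are *templates*: fill in the
# bregma voxel your lab uses for its atlas version (values differ across
# atlas versions and published conventions), then pass the file paths and
# bregma to `histoatlas atlas-info` / `plan` / `reconstruct-probe`.
waxholm_rat_v4:
  volume: WHS_SD_rat_atlas_v4.nii.gz
  label: WHS_SD_rat_atlas_v4.label
  bregma_voxel: null  # user-supplied, e.g. from your lab's calibration
allen_mouse_ccf_25um:
  volume: annotation_25.nii.gz
  label: structures.csv
  bregma_voxel: null
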