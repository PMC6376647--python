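# Desk-scale settings for the 128x128 five-plane synthetic stacks.
# Disk radii and the peak separation scale with the image scale (the same
# proportion by which the cells are smaller than full-frame microscopy);
# scale-free values (peak threshold, matching distance, learning schedule)
# keep their full-scale defaults.

model:
  base_filters: 8

schedule:
  patch_sizes: [64, 96, 48, 80, 64, 96]

targets:
  max_radius: 4

adapt:
  peak_min_distance: 3
  pseudo_radius: 3

detect:
  triplet_start: 3
  peak_min_distance: 3

stack:
  in_focus_index: 3
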