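# Default tumor-region catalog: 20 parametric solids, all contained in the
# body cylinder (radius 30 mm, height 100 mm, axis z) with enough margin to
# survive the four augmentation rototranslations. Lengths in mm.
geometries:
  - {name: ring_central,      kind: ring,         params: {r_major: 15.0, r_minor: 5.0}}
  - {name: sphere_center,     kind: sphere,       params: {radius: 10.0}}
  - {name: sphere_small_off,  kind: sphere,       params: {radius: 6.0},  translate_mm: [10.0, 0.0, 15.0]}
  - {name: sphere_large,      kind: sphere,       params: {radius: 14.0}, translate_mm: [0.0, 0.0, -20.0]}
  - {name: sphere_edge,       kind: sphere,       params: {radius: 7.0},  translate_mm: [-14.0, 8.0, 25.0]}
  - {name: ellipsoid_axial,   kind: ellipsoid,    params: {semi_axes: [8.0, 8.0, 20.0]}}
  - {name: ellipsoid_flat,    kind: ellipsoid,    params: {semi_axes: [15.0, 10.0, 6.0]}, translate_mm: [0.0, 0.0, 18.0]}
  - {name: ellipsoid_tilted,  kind: ellipsoid,    params: {semi_axes: [12.0, 6.0, 10.0]}, rotate_z_deg: 45.0, translate_mm: [5.0, -5.0, -12.0]}
  - {name: box_cube,          kind: box,          params: {half_sizes: [8.0, 8.0, 8.0]}}
  - {name: box_slab,          kind: box,          params: {half_sizes: [14.0, 5.0, 10.0]}, translate_mm: [0.0, 6.0, 20.0]}
  - {name: box_rod,           kind: box,          params: {half_sizes: [5.0, 5.0, 22.0]},  rotate_z_deg: 30.0, translate_mm: [-8.0, -8.0, 0.0]}
  - {name: shell_thick,       kind: shell,        params: {r_inner: 6.0, r_outer: 12.0}}
  - {name: shell_thin,        kind: shell,        params: {r_inner: 10.0, r_outer: 14.0}, translate_mm: [0.0, 0.0, -22.0]}
  - {name: shell_offset,      kind: shell,        params: {r_inner: 4.0, r_outer: 9.0},   translate_mm: [12.0, -6.0, 10.0]}
  - {name: bifocal_axial,     kind: multi_sphere, params: {centers: [[0.0, 0.0, -18.0], [0.0, 0.0, 18.0]], radii: [8.0, 8.0]}}
  - {name: bifocal_radial,    kind: multi_sphere, params: {centers: [[-12.0, 0.0, 0.0], [12.0, 0.0, 0.0]], radii: [7.0, 9.0]}}
  - {name: trifocal,          kind: multi_sphere, params: {centers: [[0.0, 12.0, -15.0], [10.0, -6.0, 0.0], [-10.0, -6.0, 15.0]], radii: [6.0, 7.0, 6.0]}}
  # --- infinite-ratio-only geometries (17..19) ---
  - {name: ring_high,         kind: ring,         params: {r_major: 12.0, r_minor: 4.5}, translate_mm: [0.0, 0.0, 25.0]}
  - {name: sphere_tiny_pair,  kind: multi_sphere, params: {centers: [[8.0, 8.0, -25.0], [-8.0, -8.0, 25.0]], radii: [5.5, 5.5]}}
  - {name: ellipsoid_long,    kind: ellipsoid,    params: {semi_axes: [6.0, 10.0, 25.0]}, translate_mm: [6.0, 0.0, 0.0]}
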