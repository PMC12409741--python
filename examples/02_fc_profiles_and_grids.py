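"""From BOLD runs to seed-based FC profiles, and from the sphere to a 2-D grid.

An FC profile is the Pearson correlation of one seed's time series (a vertex,
or a parcel's mean series) against every cortical vertex.  For convolutional
modelling each hemisphere is resampled onto a grid that is uniform in azimuth
and in sin(elevation); at adequate grid density the nearest-neighbour mapping
is exactly invertible.
"""

import numpy as np

import fclatent as fl

mesh = fl.make_sphere_mesh(250, 0.1, seed=1)
parc = fl.make_parcellation(mesh, 12, 4, 0, seed=1)
spec = fl.CohortSpec(n_subjects=2, n_sessions=1, n_timepoints=400, seed=1)
runs = fl.simulate_bold(mesh, parc, spec)

# a single-vertex seed profile
seed_vertex = int(mesh.cortex_indices[10])
prof = fl.vertex_fc_profile(runs[0], mesh, seed_vertex)
print(f"vertex profile: {prof.values.size} correlations, "
      f"range [{prof.values.min():.3f}, {prof.values.max():.3f}], "
      f"self-correlation {prof.values[10]:.1f}")

# a parcel seed averages member time series before correlating
pprof = fl.parcel_fc_profile(runs[0], mesh, parc, 0)
print(f"parcel 0 profile: mean |r| = {np.abs(pprof.values).mean():.3f}")

# resample the sphere onto a 64x64 azimuth x sin(elevation) grid
rmap = fl.build_resampling_map(fl.spherical_coords(mesh), mesh, 64, 64)
img = fl.to_grid(prof.values, rmap)
valid = rmap.mask_left.sum() + rmap.mask_right.sum()
print(f"grid: 2 hemispheres x 64x64, {valid} valid pixels")

back = fl.from_grid(img, rmap)
print(f"roundtrip exact: {np.array_equal(back, prof.values)}")

# training set: 10% of vertices per subject as seeds
pset = fl.sample_training_profiles(runs, mesh, fraction=0.1, seed=1)
print(f"training profiles: {len(pset)} "
      f"({pset.provenance.groupby('subject').size().iloc[0]} per subject)")
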