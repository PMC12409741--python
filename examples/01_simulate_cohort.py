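"""Build a synthetic cortex and a small BOLD cohort with planted networks.

The generator places vertices on two unit hemispheres, masks a polar cap as
the "medial wall", tiles the cortex into contiguous parcels grouped into
functional networks, and synthesizes BOLD runs in which vertices of the same
network share a time course.  Each subject carries a persistent trait: a
fraction of its parcels (p_swap) is reassigned to a different network in
every session, so subjects are identifiable across sessions.
"""

import numpy as np

import fclatent as fl

mesh = fl.make_sphere_mesh(n_per_hemisphere=300, medial_wall_fraction=0.1, seed=0)
print(f"mesh: {mesh.n_vertices} vertices, {mesh.n_cortex} cortical "
      f"({mesh.medial_mask.sum()} on the medial wall)")

parc = fl.make_parcellation(mesh, n_parcels=18, n_networks=6, n_unassigned=0, seed=0)
sizes = [parc.parcel_vertices(p).size for p in range(parc.n_parcels)]
print(f"parcellation: {parc.n_parcels} parcels in {parc.n_networks} networks, "
      f"sizes {min(sizes)}..{max(sizes)} vertices")

spec = fl.CohortSpec(n_subjects=4, n_sessions=2, n_timepoints=400,
                     p_swap=0.15, noise_sd=0.5, seed=0)
runs = fl.simulate_bold(mesh, parc, spec)
print(f"cohort: {len(runs)} runs of shape {runs[0].data.shape} (cortex x time)")

# the planted structure is visible in raw vertex correlations
run = runs[0]
vparc = parc.vertex_parcel[mesh.cortex_indices]
nets = np.array([parc.networks.index(parc.parcel_network[p]) for p in vparc])
c = np.corrcoef(run.data)
same = (nets[:, None] == nets[None, :]) & ~np.eye(len(nets), dtype=bool)
print(f"mean r within networks:  {c[same].mean():.3f}")
print(f"mean r between networks: {c[~same & ~np.eye(len(nets), dtype=bool)].mean():.3f}")
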