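"""The latent analysis battery: silhouette, dispersion, fingerprinting,
subclustering and density maps, all on a small trained embedding.

Group-averaged parcel embeddings should segregate by network (positive
silhouette); per-subject embeddings of the same parcel should sit closer to
each other across sessions than different subjects do (fingerprinting).
"""

import numpy as np

import fclatent as fl

# --- build a cohort and train (same recipe as example 03) -------------------
mesh = fl.make_sphere_mesh(300, 0.1, seed=3)
parc = fl.make_parcellation(mesh, 18, 6, 0, seed=3)
spec = fl.CohortSpec(n_subjects=8, n_sessions=2, n_timepoints=400,
                     p_swap=0.15, noise_sd=0.5, seed=3)
runs = fl.simulate_bold(mesh, parc, spec)
rmap = fl.build_resampling_map(fl.spherical_coords(mesh), mesh, 32, 32)
profiles = fl.sample_training_profiles(runs, mesh, fraction=0.1, seed=3)
model = fl.train(profiles, rmap, fl.VAEConfig.small(epochs=6, seed=3))

pset = fl.parcel_profile_matrix(runs, mesh, parc)
post = fl.embed_profiles(model, pset, rmap)
df = pset.provenance.copy()
df[["m0", "m1"]] = post.mu

# --- network segregation (silhouette, Euclidean in latent space) -----------
mean = df.groupby("seed")[["m0", "m1"]].mean()
labels = np.array([parc.parcel_network[int(p)] for p in mean.index])
res = fl.silhouette(mean.to_numpy(), labels, metric="euclidean")
print("per-network mean silhouette:")
for net, val in sorted(res.network_mean.items()):
    # a single-parcel network has no within-network distance, so no silhouette
    print(f"  {net}: " + (f"{val:+.3f}" if np.isfinite(val)
                          else "undefined (single parcel)"))

# --- dispersion: inter- vs intra-subject spread per parcel ------------------
parcel0 = df[df["seed"] == 0]
inter = fl.dispersion(parcel0.groupby("subject")[["m0", "m1"]].mean().to_numpy())
intra = np.mean([
    fl.dispersion(g[["m0", "m1"]].to_numpy())
    for _, g in parcel0.groupby("subject")
])
print(f"parcel 0 dispersion: inter={inter:.4f} intra={intra:.4f} "
      f"SNR={fl.dispersion_snr(inter, intra):.2f}")

# --- fingerprinting across sessions -----------------------------------------
barcodes = []
for sess in (0, 1):
    sub = df[df["session"] == sess].sort_values(["subject", "seed"])
    barcodes.append(np.stack([
        fl.latent_barcode(g[["m0", "m1"]].to_numpy())
        for _, g in sub.groupby("subject")
    ]))
fp = fl.fingerprint(barcodes[0], barcodes[1])
print(f"fingerprint accuracy: {fp.accuracy:.2f} "
      f"({fp.hits_1}+{fp.hits_2} of {2 * spec.n_subjects} identifications)")

# --- subclustering one network's parcels x subjects --------------------------
net0 = [p for p, lab in enumerate(parc.parcel_network) if lab == parc.networks[0]]
pts = df[df["seed"].isin(net0)][["m0", "m1"]].to_numpy()
cluster_labels, centroids, _ = fl.subcluster(pts, k=2, seed=3)
print(f"k=2 subclusters of {parc.networks[0]}: sizes "
      f"{np.bincount(cluster_labels).tolist()}, centroid distance "
      f"{np.linalg.norm(centroids[0] - centroids[1]):.3f}")

# --- latent density map ------------------------------------------------------
density = fl.density_map(df[["m0", "m1"]].to_numpy(),
                         (-4, 4, -4, 4, 32), bandwidth=1.0)
print(f"density map: 32x32, peak={density.max():.4f}, total={density.sum():.3f}")
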