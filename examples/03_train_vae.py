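"""Train a small beta-VAE on reformatted FC profiles and inspect the latents.

The encoder applies five stride-2 convolutions per hemisphere (circular
padding along azimuth, zero padding along elevation), merges hemispheres by
channel concatenation, and outputs a posterior mean and SD per latent
dimension.  The loss is squared reconstruction error over valid pixels plus
beta times the closed-form KL divergence to a standard normal prior.
"""

import numpy as np

import fclatent as fl

mesh = fl.make_sphere_mesh(300, 0.1, seed=2)
parc = fl.make_parcellation(mesh, 18, 6, 0, seed=2)
spec = fl.CohortSpec(n_subjects=6, n_sessions=2, n_timepoints=400,
                     p_swap=0.15, noise_sd=0.5, seed=2)
runs = fl.simulate_bold(mesh, parc, spec)
rmap = fl.build_resampling_map(fl.spherical_coords(mesh), mesh, 32, 32)
profiles = fl.sample_training_profiles(runs, mesh, fraction=0.1, seed=2)
print(f"training on {len(profiles)} profiles")

config = fl.VAEConfig.small(zdim=2, beta=2.0, epochs=6, seed=2)
model = fl.train(profiles, rmap, config)
print(model.loss_trace.to_string(index=False,
                                 float_format=lambda v: f"{v:.4f}"))

# embed every parcel of every (subject, session)
pset = fl.parcel_profile_matrix(runs, mesh, parc)
post = fl.embed_profiles(model, pset, rmap)
print(f"embedded {post.mu.shape[0]} parcel profiles into "
      f"{post.mu.shape[1]} latent dimensions")
print(f"posterior mu range: [{post.mu.min():.2f}, {post.mu.max():.2f}], "
      f"sigma median: {np.median(post.sigma):.3f}")

# a latent traversal decodes what each coordinate encodes
values, images = fl.traverse_latent(model, dim=0, lo=-2.0, hi=2.0, steps=5)
deltas = [np.abs(img.left - images[2].left).mean() for img in images]
print("traversal dim 0, mean |change| vs midpoint:",
      " ".join(f"{d:.3f}" for d in deltas))

fl.save_model(model, "example_model.npz")
print("saved example_model.npz")
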