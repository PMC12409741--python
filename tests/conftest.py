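"""Shared fixtures: a desk-scale cohort with planted network structure and a
model trained on it, built once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import fclatent as fl

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def mesh():
    """800 vertices per hemisphere, 10% medial wall."""
    return fl.make_sphere_mesh(800, 0.1, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def parcellation(mesh):
    """36 parcels in 6 networks, none unassigned."""
    return fl.make_parcellation(mesh, 36, 6, 0, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def cohort_spec():
    return fl.CohortSpec(
        n_subjects=12, n_sessions=2, n_timepoints=600,
        p_swap=0.15, noise_sd=0.5, seed=FIXTURE_SEED,
    )


@pytest.fixture(scope="session")
def cohort(mesh, parcellation, cohort_spec):
    return fl.simulate_bold(mesh, parcellation, cohort_spec)


@pytest.fixture(scope="session")
def rmap(mesh):
    return fl.build_resampling_map(fl.spherical_coords(mesh), mesh, 32, 32)


@pytest.fixture(scope="session")
def training_profiles(cohort, mesh):
    return fl.sample_training_profiles(cohort, mesh, fraction=0.1, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def trained_model(training_profiles, rmap):
    """10-epoch beta-VAE (zdim 2, beta 2, batch 32) on the 32x32 fixture."""
    cfg = fl.VAEConfig.small(epochs=10, seed=FIXTURE_SEED)
    return fl.train(training_profiles, rmap, cfg)


@pytest.fixture(scope="session")
def parcel_embeddings(cohort, mesh, parcellation, trained_model, rmap):
    """Per-(subject, session, parcel) posterior means with provenance."""
    pset = fl.parcel_profile_matrix(cohort, mesh, parcellation)
    post = fl.embed_profiles(trained_model, pset, rmap)
    df = pset.provenance.copy()
    df["m0"] = post.mu[:, 0]
    df["m1"] = post.mu[:, 1]
    return df


@pytest.fixture(scope="session")
def small_mesh():
    """250 vertices per hemisphere — exact-roundtrip regime for a 64x64 grid."""
    return fl.make_sphere_mesh(250, 0.1, seed=1)


@pytest.fixture(scope="session")
def small_rmap(small_mesh):
    return fl.build_resampling_map(
        fl.spherical_coords(small_mesh), small_mesh, 64, 64
    )


def group_mean_embeddings(df, parcellation):
    """Average parcel embeddings across subjects/sessions -> (points, labels)."""
    mean = df.groupby("seed")[["m0", "m1"]].mean()
    labels = np.array([parcellation.parcel_network[int(p)] for p in mean.index])
    keep = labels != "None"
    return mean.to_numpy()[keep], labels[keep]


def session_barcodes(df):
    """Latent barcodes per subject for each of the first two sessions."""
    out = {}
    for sess in sorted(df["session"].unique())[:2]:
        sub = df[df["session"] == sess].sort_values(["subject", "seed"])
        out[sess] = np.stack([
            fl.latent_barcode(g[["m0", "m1"]].to_numpy())
            for _, g in sub.groupby("subject")
        ])
    return list(out.values())
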