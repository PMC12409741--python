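"""Synthetic cortical data: spherical meshes, parcellations, and BOLD cohorts.

Real analyses of seed-based functional connectivity run on two-hemisphere
spherical meshes (each hemisphere inflated to its own unit sphere) with a
medial-wall exclusion mask, a parcel atlas grouped into functional networks,
and multi-subject multi-session BOLD time series.  This module generates all
three with the statistical structure those analyses assume:

* network-structured vertex covariance (shared network time courses),
* trait-like subject-specific network-membership deviations that persist
  across a subject's sessions,
* independent session-level vertex noise, and
* a per-subject FC-strength scale ``gamma`` that can encode cohort or
  age effects (weaker overall FC pulls latent embeddings toward the origin).

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning — one child stream per subject and per session — so enlarging a
cohort never perturbs the data of earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SurfaceMesh",
    "Parcellation",
    "CohortSpec",
    "BoldRun",
    "make_sphere_mesh",
    "make_parcellation",
    "simulate_bold",
]

UNASSIGNED = "None"


@dataclass(frozen=True)
class SurfaceMesh:
    """Two unit spheres (one per hemisphere) with a medial-wall mask.

    Vertices are indexed globally, left hemisphere first.  ``medial_mask``
    is True on medial-wall vertices, which carry no data in any FC profile.
    """

    coords: np.ndarray        # (n_total, 3) unit vectors
    hemisphere: np.ndarray    # (n_total,) array of "L"/"R"
    medial_mask: np.ndarray   # (n_total,) bool

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("mesh coordinates must have unit norm (tol 1e-9)")
        if self.coords.shape[0] != self.hemisphere.shape[0] != self.medial_mask.shape[0]:
            raise ValueError("mesh field lengths disagree")

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def cortex_indices(self) -> np.ndarray:
        """Global indices of non-medial-wall vertices, in mesh order."""
        return np.flatnonzero(~self.medial_mask)

    @property
    def n_cortex(self) -> int:
        return int((~self.medial_mask).sum())

    def hemi_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)


@dataclass(frozen=True)
class Parcellation:
    """Vertex→parcel and parcel→network assignment.

    ``vertex_parcel`` is -1 on medial-wall vertices; every other vertex has
    exactly one parcel.  Parcels whose network label is ``"None"`` are
    excluded from all network-level statistics.
    """

    vertex_parcel: np.ndarray          # (n_total,) int, -1 on medial wall
    parcel_network: tuple[str, ...]    # one label per parcel

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_network)

    @property
    def networks(self) -> tuple[str, ...]:
        """Distinct non-"None" network labels, sorted."""
        return tuple(sorted(set(self.parcel_network) - {UNASSIGNED}))

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @property
    def assigned_parcels(self) -> np.ndarray:
        """Parcel ids with a real network label."""
        return np.array(
            [p for p, net in enumerate(self.parcel_network) if net != UNASSIGNED],
            dtype=int,
        )

    def parcel_vertices(self, parcel: int) -> np.ndarray:
        return np.flatnonzero(self.vertex_parcel == parcel)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated resting-state cohort.

    ``gamma`` scales the network signal per subject (scalar, or one value
    per subject), emulating cohort-level differences in overall FC strength.
    ``p_swap`` is the fraction of network-labeled parcels whose effective
    network membership is reassigned per subject — a stable, trait-like
    deviation reused across that subject's sessions.
    """

    n_subjects: int = 12
    n_sessions: int = 2
    n_timepoints: int = 600
    within_weight: float = 1.0
    p_swap: float = 0.15
    noise_sd: float = 0.5
    gamma: float | Sequence[float] = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_swap <= 1.0):
            raise ValueError("p_swap must lie in [0, 1]")
        if self.noise_sd < 0 or self.within_weight < 0:
            raise ValueError("variance parameters must be non-negative")
        if self.n_subjects < 1 or self.n_sessions < 1 or self.n_timepoints < 2:
            raise ValueError("cohort sizes must be positive (>=2 timepoints)")

    def gamma_of(self, subject: int) -> float:
        if np.isscalar(self.gamma):
            return float(self.gamma)
        return float(np.asarray(self.gamma, dtype=float)[subject])


@dataclass(frozen=True)
class BoldRun:
    """One session's BOLD matrix over non-medial-wall vertices."""

    data: np.ndarray   # (n_cortex, T)
    subject: int
    session: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD matrix contains non-finite values")


def _fibonacci_sphere(n: int, rng: np.random.Generator, jitter: float = 0.15) -> np.ndarray:
    """Quasi-uniform unit-sphere layout: golden-angle spiral plus a small
    seeded tangential perturbation, renormalized to the sphere."""
    k = np.arange(n, dtype=float)
    # open spiral avoids placing points exactly at the poles
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if jitter > 0:
        scale = jitter * 2.0 / np.sqrt(n)   # ~ fraction of mean spacing
        pts = pts + rng.normal(scale=scale, size=pts.shape)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def make_sphere_mesh(
    n_per_hemisphere: int,
    medial_wall_fraction: float = 0.0,
    seed: int = 0,
) -> SurfaceMesh:
    """Build a two-hemisphere unit-sphere mesh with a polar medial-wall cap.

    ``round(medial_wall_fraction * n_per_hemisphere)`` vertices nearest the
    north pole (z = +1) of each hemisphere are masked as medial wall.
    """
    if n_per_hemisphere < 12:
        raise ValueError("need at least 12 vertices per hemisphere")
    if not (0.0 <= medial_wall_fraction < 0.5):
        raise ValueError("medial_wall_fraction must lie in [0, 0.5)")
    ss = np.random.SeedSequence(seed)
    child_l, child_r = ss.spawn(2)
    coords_l = _fibonacci_sphere(n_per_hemisphere, np.random.default_rng(child_l))
    coords_r = _fibonacci_sphere(n_per_hemisphere, np.random.default_rng(child_r))
    n_mask = int(round(medial_wall_fraction * n_per_hemisphere))
    masks = []
    for coords in (coords_l, coords_r):
        mask = np.zeros(n_per_hemisphere, dtype=bool)
        if n_mask > 0:
            # the n_mask vertices with the largest z form a contiguous cap
            order = np.argsort(-coords[:, 2])
            mask[order[:n_mask]] = True
        masks.append(mask)
    return SurfaceMesh(
        coords=np.vstack([coords_l, coords_r]),
        hemisphere=np.array(["L"] * n_per_hemisphere + ["R"] * n_per_hemisphere),
        medial_mask=np.concatenate(masks),
    )


def make_parcellation(
    mesh: SurfaceMesh,
    n_parcels: int,
    n_networks: int,
    n_unassigned: int = 0,
    seed: int = 0,
) -> Parcellation:
    """Voronoi parcels on the sphere, grouped into functional networks.

    Parcel seed vertices are drawn from the non-medial-wall cortex and each
    cortical vertex joins the nearest seed within its own hemisphere, so
    parcels are spatially contiguous and never span hemispheres.
    ``n_unassigned`` parcels receive the network label "None" and are
    excluded from network-level statistics downstream.
    """
    cortex = mesh.cortex_indices
    if not (0 <= n_unassigned < n_parcels <= cortex.size):
        raise ValueError("need 0 <= n_unassigned < n_parcels <= cortex size")
    if not (1 <= n_networks <= n_parcels - n_unassigned):
        raise ValueError("need 1 <= n_networks <= n_parcels - n_unassigned")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # split parcel seeds across hemispheres proportionally to cortex size
    cortex_l = cortex[mesh.hemisphere[cortex] == "L"]
    cortex_r = cortex[mesh.hemisphere[cortex] == "R"]
    n_l = int(round(n_parcels * cortex_l.size / cortex.size))
    n_l = min(max(n_l, 1), n_parcels - 1) if cortex_r.size else n_parcels
    seeds_l = rng.choice(cortex_l, size=n_l, replace=False)
    seeds_r = rng.choice(cortex_r, size=n_parcels - n_l, replace=False)
    seed_verts = np.concatenate([seeds_l, seeds_r])

    vertex_parcel = np.full(mesh.n_vertices, -1, dtype=int)
    for hemi, hemi_seeds, offset in (("L", seeds_l, 0), ("R", seeds_r, n_l)):
        verts = cortex[mesh.hemisphere[cortex] == hemi]
        if verts.size == 0:
            continue
        # chordal nearest neighbour == great-circle nearest neighbour
        d = np.linalg.norm(
            mesh.coords[verts][:, None, :] - mesh.coords[hemi_seeds][None, :, :], axis=2
        )
        vertex_parcel[verts] = offset + np.argmin(d, axis=1)

    order = rng.permutation(n_parcels)
    labels = [""] * n_parcels
    for p in order[:n_unassigned]:
        labels[p] = UNASSIGNED
    assigned = order[n_unassigned:]
    width = len(str(max(n_networks - 1, 0)))
    for rank, p in enumerate(assigned):
        # first pass guarantees every network owns at least one parcel
        net = rank if rank < n_networks else int(rng.integers(n_networks))
        labels[p] = f"Net{net:0{width}d}"
    return Parcellation(vertex_parcel=vertex_parcel, parcel_network=tuple(labels))


def _effective_networks(
    parcellation: Parcellation, p_swap: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-parcel effective network index for one subject.

    Assigned parcels keep their atlas network except for a seeded fraction
    ``p_swap`` reassigned to a random *other* network; "None" parcels are
    given a random network for signal generation (they are cortex with an
    unknown label, not silent tissue).
    """
    nets = parcellation.networks
    net_index = {n: i for i, n in enumerate(nets)}
    k = len(nets)
    eff = np.empty(parcellation.n_parcels, dtype=int)
    for p, lab in enumerate(parcellation.parcel_network):
        eff[p] = net_index[lab] if lab != UNASSIGNED else int(rng.integers(k))
    assigned = parcellation.assigned_parcels
    n_swap = int(round(p_swap * assigned.size))
    if n_swap > 0 and k > 1:
        swapped = rng.choice(assigned, size=n_swap, replace=False)
        for p in swapped:
            choices = [i for i in range(k) if i != eff[p]]
            eff[p] = choices[int(rng.integers(k - 1))]
    return eff


def subject_membership(
    parcellation: Parcellation, spec: CohortSpec, subject: int
) -> np.ndarray:
    """The effective per-parcel network indices for one subject (trait-like:
    identical across all of that subject's sessions)."""
    subj_ss = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)[subject]
    rng = np.random.default_rng(subj_ss.spawn(1)[0])
    return _effective_networks(parcellation, spec.p_swap, rng)


def simulate_bold(
    mesh: SurfaceMesh,
    parcellation: Parcellation,
    spec: CohortSpec,
) -> list[BoldRun]:
    """Simulate a cohort of BOLD runs with planted network structure.

    Each session draws one standard-normal time course per network; the
    series at a cortical vertex is::

        gamma_subject * within_weight * course[effective_network(parcel(v))]
        + noise_sd * eps_v

    with iid unit-normal vertex noise.  The subject's effective membership
    (including ``p_swap`` reassignments) is drawn once and reused across
    sessions.  Output rows follow ``mesh.cortex_indices`` order.
    """
    if parcellation.vertex_parcel.shape[0] != mesh.n_vertices:
        raise ValueError("parcellation does not match mesh")
    cortex = mesh.cortex_indices
    vparc = parcellation.vertex_parcel[cortex]
    if (vparc < 0).any():
        raise ValueError("some cortical vertices have no parcel")
    k = parcellation.n_networks
    runs: list[BoldRun] = []
    for s, subj_ss in enumerate(np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)):
        streams = subj_ss.spawn(1 + spec.n_sessions)
        eff = _effective_networks(
            parcellation, spec.p_swap, np.random.default_rng(streams[0])
        )
        vertex_net = eff[vparc]
        g = spec.gamma_of(s)
        for sess in range(spec.n_sessions):
            rng = np.random.default_rng(streams[1 + sess])
            courses = rng.standard_normal((k, spec.n_timepoints))
            noise = rng.standard_normal((cortex.size, spec.n_timepoints))
            data = g * spec.within_weight * courses[vertex_net] + spec.noise_sd * noise
            runs.append(BoldRun(data=data, subject=s, session=sess))
    return runs
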