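"""Seed-based functional-connectivity (FC) profiles.

An FC profile is the vector of Pearson correlations between one seed time
series — a single vertex, the unweighted mean over a parcel's vertices, or a
network average — and the BOLD series at every non-medial-wall cortical
vertex.  Vertex profiles sampled from a cohort are the training samples for
the latent embedding model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import BoldRun, Parcellation, SurfaceMesh

__all__ = [
    "FCProfile",
    "ProfileSet",
    "vertex_fc_profile",
    "parcel_fc_profile",
    "network_fc_profile",
    "sample_training_profiles",
    "concatenate_sessions",
    "parcel_profile_matrix",
]


class DegenerateInputError(ValueError):
    """Raised when an input is constant where variance is required."""


@dataclass(frozen=True)
class FCProfile:
    """One seed's correlation map over all cortical vertices.

    ``undefined`` flags target vertices whose series had zero variance;
    their correlation entries are set to 0.
    """

    seed_id: object                  # vertex id, parcel id, or network label
    values: np.ndarray               # (n_cortex,) r in [-1, 1]
    subject: int | None = None
    session: int | None = None
    undefined: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        v = self.values
        if v.size and (np.nanmin(v) < -1 - 1e-9 or np.nanmax(v) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class ProfileSet:
    """An ordered stack of FC profiles plus a provenance table.

    ``profiles`` is (n_samples, n_cortex); ``provenance`` has columns
    subject, session, seed with no duplicate triples.
    """

    profiles: np.ndarray
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if self.profiles.shape[0] != len(self.provenance):
            raise ValueError("profile count and provenance length disagree")
        if self.provenance.duplicated(["subject", "session", "seed"]).any():
            raise ValueError("duplicate (subject, session, seed) in provenance")

    def __len__(self) -> int:
        return self.profiles.shape[0]


def _correlate_against_all(seed_series: np.ndarray, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of one series against every row of ``data``.

    Zero-variance target rows are flagged and given r = 0.
    """
    s = seed_series - seed_series.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise DegenerateInputError("seed time series is constant")
    x = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    undefined = np.flatnonzero(norms == 0)
    norms_safe = np.where(norms == 0, 1.0, norms)
    r = (x @ s) / (norms_safe * s_norm)
    r[undefined] = 0.0
    return np.clip(r, -1.0, 1.0), undefined


def vertex_fc_profile(bold: BoldRun, mesh: SurfaceMesh, seed_vertex: int) -> FCProfile:
    """FC profile seeded at one vertex (global mesh index).

    The seed must be cortical (non-medial-wall) and its series non-constant;
    its row in the BOLD matrix is located through ``mesh.cortex_indices``.
    """
    if bold.data.shape[0] != mesh.n_cortex:
        raise ValueError("BOLD row count does not match cortex size")
    if bold.data.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    cortex = mesh.cortex_indices
    pos = np.searchsorted(cortex, seed_vertex)
    if pos >= cortex.size or cortex[pos] != seed_vertex:
        raise ValueError(f"vertex {seed_vertex} is medial wall or out of range")
    r, undef = _correlate_against_all(bold.data[pos], bold.data)
    r[pos] = 1.0
    return FCProfile(seed_id=int(seed_vertex), values=r,
                     subject=bold.subject, session=bold.session, undefined=undef)


def parcel_fc_profile(
    bold: BoldRun, mesh: SurfaceMesh, parcellation: Parcellation, parcel: int
) -> FCProfile:
    """FC profile seeded at the unweighted mean series of a parcel."""
    if bold.data.shape[0] != mesh.n_cortex:
        raise ValueError("BOLD row count does not match cortex size")
    cortex = mesh.cortex_indices
    members = np.flatnonzero(parcellation.vertex_parcel[cortex] == parcel)
    if members.size == 0:
        raise ValueError(f"parcel {parcel} is empty")
    mean_series = bold.data[members].mean(axis=0)
    r, undef = _correlate_against_all(mean_series, bold.data)
    return FCProfile(seed_id=int(parcel), values=r,
                     subject=bold.subject, session=bold.session, undefined=undef)


def network_fc_profile(
    profiles: ProfileSet, parcellation: Parcellation, network: str
) -> FCProfile:
    """Elementwise mean of the profiles whose seed parcel belongs to a network
    (the "network prior" when averaged across subjects)."""
    member_parcels = {
        p for p, lab in enumerate(parcellation.parcel_network) if lab == network
    }
    rows = [
        i for i, seed in enumerate(profiles.provenance["seed"])
        if seed in member_parcels
    ]
    if not rows:
        raise ValueError(f"network {network!r} has no profiles in the set")
    return FCProfile(seed_id=network, values=profiles.profiles[rows].mean(axis=0))


def concatenate_sessions(runs: list[BoldRun], subject: int) -> BoldRun:
    """Concatenate one subject's sessions in time (session order)."""
    mine = sorted((r for r in runs if r.subject == subject), key=lambda r: r.session)
    if not mine:
        raise ValueError(f"no runs for subject {subject}")
    return BoldRun(
        data=np.concatenate([r.data for r in mine], axis=1),
        subject=subject, session=-1,
    )


def sample_training_profiles(
    cohort: list[BoldRun],
    mesh: SurfaceMesh,
    fraction: float = 0.1,
    seed: int = 0,
    per_session: bool = False,
) -> ProfileSet:
    """Draw seeded vertex FC profiles as model-training samples.

    Per subject, ``ceil(fraction * n_cortex)`` distinct cortical vertices are
    drawn without replacement and their profiles computed from that subject's
    sessions concatenated in time (or per session when ``per_session``).
    ``fraction=0.1`` mirrors the 10%-of-vertices training regime; e.g. 10% of
    a 59412-vertex cortex over 100 subjects gives 5942 x 100 = 594200 samples.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    subjects = sorted({r.subject for r in cohort})
    cortex = mesh.cortex_indices
    n_draw = math.ceil(fraction * cortex.size)
    ss = np.random.SeedSequence(seed).spawn(len(subjects))
    rows, prov = [], []
    for subj, subj_ss in zip(subjects, ss):
        rng = np.random.default_rng(subj_ss)
        chosen = np.sort(rng.choice(cortex, size=n_draw, replace=False))
        runs = (
            sorted((r for r in cohort if r.subject == subj), key=lambda r: r.session)
            if per_session
            else [concatenate_sessions(cohort, subj)]
        )
        for run in runs:
            for v in chosen:
                prof = vertex_fc_profile(run, mesh, int(v))
                rows.append(prof.values)
                prov.append((subj, run.session, int(v)))
    return ProfileSet(
        profiles=np.asarray(rows),
        provenance=pd.DataFrame(prov, columns=["subject", "session", "seed"]),
    )


def parcel_profile_matrix(
    cohort: list[BoldRun],
    mesh: SurfaceMesh,
    parcellation: Parcellation,
    parcels: np.ndarray | None = None,
    per_session: bool = True,
) -> ProfileSet:
    """Parcel-seeded profiles for every (subject, session, parcel).

    The workhorse input for the latent analyses: silhouette, dispersion,
    fingerprinting and density maps all start from parcel embeddings.
    """
    if parcels is None:
        parcels = parcellation.assigned_parcels
    subjects = sorted({r.subject for r in cohort})
    rows, prov = [], []
    for subj in subjects:
        runs = (
            sorted((r for r in cohort if r.subject == subj), key=lambda r: r.session)
            if per_session
            else [concatenate_sessions(cohort, subj)]
        )
        for run in runs:
            for p in parcels:
                prof = parcel_fc_profile(run, mesh, parcellation, int(p))
                rows.append(prof.values)
                prov.append((subj, run.session, int(p)))
    return ProfileSet(
        profiles=np.asarray(rows),
        provenance=pd.DataFrame(prov, columns=["subject", "session", "seed"]),
    )
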