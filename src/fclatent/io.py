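"""File I/O: GIFTI, HDF5 and TSV containers, plus the pipeline runner.

HDF5 is the canonical container for matrices (meshes, BOLD cohorts, profile
sets, resampling maps); TSV for anything human-inspected (parcellations,
embeddings, provenance); GIFTI (.surf.gii / .func.gii) for interoperability
with surface-based neuroimaging tools.  Vertex indexing is 0-based
everywhere, and the stored vertex order is preserved exactly on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .fc import ProfileSet
from .reformat import ResamplingMap
from .synthetic import BoldRun, Parcellation, SurfaceMesh

__all__ = [
    "ParseError",
    "write_mesh_h5", "read_mesh_h5",
    "write_mesh_gifti", "read_mesh_gifti",
    "write_vertex_map_gifti", "read_vertex_map_gifti",
    "write_cohort_h5", "read_cohort_h5",
    "write_parcellation_tsv", "read_parcellation_tsv",
    "write_profiles_h5", "read_profiles_h5",
    "write_resampling_map_h5", "read_resampling_map_h5",
    "write_embeddings_tsv", "read_embeddings_tsv",
    "read_surface_data",
    "RunConfig", "run_pipeline",
]


class ParseError(ValueError):
    """A file could not be interpreted; the message names the offending field."""


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

def write_mesh_h5(mesh: SurfaceMesh, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "mesh"
        f["coords"] = mesh.coords
        f["hemisphere"] = np.array([h.encode() for h in mesh.hemisphere])
        f["medial_mask"] = mesh.medial_mask


def read_mesh_h5(path) -> SurfaceMesh:
    with h5py.File(path, "r") as f:
        for key in ("coords", "hemisphere", "medial_mask"):
            if key not in f:
                raise ParseError(f"mesh file missing dataset '{key}'")
        return SurfaceMesh(
            coords=f["coords"][()],
            hemisphere=np.array([h.decode() for h in f["hemisphere"][()]]),
            medial_mask=f["medial_mask"][()].astype(bool),
        )


def _sphere_triangles(coords: np.ndarray) -> np.ndarray:
    # the convex hull of points on a sphere is a valid surface triangulation
    from scipy.spatial import ConvexHull
    return ConvexHull(coords).simplices.astype(np.int32)


def write_mesh_gifti(mesh: SurfaceMesh, out_dir, stem: str = "sphere") -> list[Path]:
    """One .surf.gii per hemisphere plus a medial-wall mask .func.gii each."""
    import nibabel as nib
    from nibabel.gifti import GiftiDataArray, GiftiImage

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for hemi in ("L", "R"):
        idx = mesh.hemi_indices(hemi)
        coords = mesh.coords[idx].astype(np.float32)
        img = GiftiImage(darrays=[
            GiftiDataArray(coords, intent="NIFTI_INTENT_POINTSET"),
            GiftiDataArray(_sphere_triangles(coords), intent="NIFTI_INTENT_TRIANGLE"),
        ])
        surf = out_dir / f"{stem}.{hemi}.surf.gii"
        nib.save(img, surf)
        mask = GiftiImage(darrays=[GiftiDataArray(
            mesh.medial_mask[idx].astype(np.float32), intent="NIFTI_INTENT_NONE")])
        maskf = out_dir / f"{stem}.{hemi}.medialwall.func.gii"
        nib.save(mask, maskf)
        written += [surf, maskf]
    return written


def read_mesh_gifti(out_dir, stem: str = "sphere") -> SurfaceMesh:
    import nibabel as nib

    out_dir = Path(out_dir)
    coords, hemis, masks = [], [], []
    for hemi in ("L", "R"):
        surf = nib.load(out_dir / f"{stem}.{hemi}.surf.gii")
        pts = [d for d in surf.darrays if d.intent == 1008]  # POINTSET
        if not pts:
            raise ParseError(f"{stem}.{hemi}.surf.gii has no POINTSET array")
        xyz = pts[0].data.astype(float)
        mask_img = nib.load(out_dir / f"{stem}.{hemi}.medialwall.func.gii")
        coords.append(xyz)
        hemis += [hemi] * xyz.shape[0]
        masks.append(mask_img.darrays[0].data.astype(bool))
    return SurfaceMesh(
        coords=np.vstack(coords),
        hemisphere=np.array(hemis),
        medial_mask=np.concatenate(masks),
    )


def write_vertex_map_gifti(values, mesh: SurfaceMesh, out_dir, stem: str) -> list[Path]:
    """Export a cortex-ordered per-vertex map as per-hemisphere metric files
    (medial-wall vertices filled with 0)."""
    import nibabel as nib
    from nibabel.gifti import GiftiDataArray, GiftiImage

    values = np.asarray(values, dtype=float)
    full = np.zeros(mesh.n_vertices)
    full[mesh.cortex_indices] = values
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for hemi in ("L", "R"):
        idx = mesh.hemi_indices(hemi)
        img = GiftiImage(darrays=[GiftiDataArray(
            full[idx].astype(np.float32), intent="NIFTI_INTENT_NONE")])
        path = out_dir / f"{stem}.{hemi}.func.gii"
        nib.save(img, path)
        written.append(path)
    return written


def read_vertex_map_gifti(out_dir, stem: str, mesh: SurfaceMesh) -> np.ndarray:
    import nibabel as nib

    out_dir = Path(out_dir)
    full = np.empty(mesh.n_vertices)
    for hemi in ("L", "R"):
        idx = mesh.hemi_indices(hemi)
        img = nib.load(out_dir / f"{stem}.{hemi}.func.gii")
        data = img.darrays[0].data
        if data.shape[0] != idx.size:
            raise ParseError(f"metric {stem}.{hemi} has {data.shape[0]} values, "
                             f"mesh hemisphere has {idx.size} vertices")
        full[idx] = data
    return full[mesh.cortex_indices]


# ---------------------------------------------------------------------------
# BOLD cohort / profiles / resampling map
# ---------------------------------------------------------------------------

def write_cohort_h5(runs: list[BoldRun], path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "bold_cohort"
        for i, run in enumerate(runs):
            g = f.create_group(f"run_{i:04d}")
            g.create_dataset("bold", data=run.data.astype(np.float32))
            g.attrs["subject"] = run.subject
            g.attrs["session"] = run.session


def read_cohort_h5(path) -> list[BoldRun]:
    runs = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            if "bold" not in g:
                raise ParseError(f"group '{name}' missing dataset 'bold'")
            runs.append(BoldRun(
                data=g["bold"][()].astype(float),
                subject=int(g.attrs["subject"]),
                session=int(g.attrs["session"]),
            ))
    return runs


def write_parcellation_tsv(parc: Parcellation, vertex_path, network_path) -> None:
    pd.DataFrame({
        "vertex_id": np.arange(parc.vertex_parcel.size),
        "parcel_id": parc.vertex_parcel,
    }).to_csv(vertex_path, sep="\t", index=False)
    pd.DataFrame({
        "parcel_id": np.arange(parc.n_parcels),
        "network_label": list(parc.parcel_network),
    }).to_csv(network_path, sep="\t", index=False)


def read_parcellation_tsv(vertex_path, network_path) -> Parcellation:
    v = pd.read_csv(vertex_path, sep="\t")
    n = pd.read_csv(network_path, sep="\t")
    for df, cols, which in ((v, ("vertex_id", "parcel_id"), vertex_path),
                            (n, ("parcel_id", "network_label"), network_path)):
        for c in cols:
            if c not in df.columns:
                raise ParseError(f"{which}: missing column '{c}'")
    return Parcellation(
        vertex_parcel=v.sort_values("vertex_id")["parcel_id"].to_numpy(),
        parcel_network=tuple(n.sort_values("parcel_id")["network_label"].astype(str)),
    )


def write_profiles_h5(pset: ProfileSet, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "profiles"
        f.create_dataset("profiles", data=pset.profiles.astype(np.float32))
    pset.provenance.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)


def read_profiles_h5(path) -> ProfileSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "profiles" not in f:
            raise ParseError("profile file missing dataset 'profiles'")
        mat = f["profiles"][()].astype(float)
    prov = pd.read_csv(path.with_suffix(".tsv"), sep="\t")
    return ProfileSet(profiles=mat, provenance=prov)


def write_resampling_map_h5(rmap: ResamplingMap, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "resampling_map"
        f.attrs["H"], f.attrs["W"] = rmap.shape
        f["pix2vert_L"] = rmap.pix2vert_left
        f["pix2vert_R"] = rmap.pix2vert_right
        f["pix2cortex_L"] = rmap.pix2cortex_left
        f["pix2cortex_R"] = rmap.pix2cortex_right
        f["vert2pix"] = rmap.vert2pix
        f["vert_hemi"] = np.array([h.encode() for h in rmap.vert_hemi])
        f["mask_L"] = rmap.mask_left
        f["mask_R"] = rmap.mask_right


def read_resampling_map_h5(path) -> ResamplingMap:
    with h5py.File(path, "r") as f:
        return ResamplingMap(
            shape=(int(f.attrs["H"]), int(f.attrs["W"])),
            pix2vert_left=f["pix2vert_L"][()],
            pix2vert_right=f["pix2vert_R"][()],
            pix2cortex_left=f["pix2cortex_L"][()],
            pix2cortex_right=f["pix2cortex_R"][()],
            vert2pix=f["vert2pix"][()],
            vert_hemi=np.array([h.decode() for h in f["vert_hemi"][()]]),
            mask_left=f["mask_L"][()].astype(bool),
            mask_right=f["mask_R"][()].astype(bool),
        )


def write_embeddings_tsv(provenance: pd.DataFrame, mu: np.ndarray,
                         sigma: np.ndarray, path) -> None:
    """Columns: subject, session, seed, mu_1..mu_N, sigma_1..sigma_N."""
    n = mu.shape[1]
    df = provenance[["subject", "session", "seed"]].copy()
    for d in range(n):
        df[f"mu_{d + 1}"] = mu[:, d]
    for d in range(n):
        df[f"sigma_{d + 1}"] = sigma[:, d]
    df.to_csv(path, sep="\t", index=False)


def read_embeddings_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "mu_1" not in df.columns:
        raise ParseError("embedding table missing column 'mu_1'")
    return df


def read_surface_data(path):
    """Load a mesh, BOLD cohort, profile set or resampling map by content.

    HDF5 files are dispatched on their 'kind' attribute; malformed files
    raise ParseError naming what is missing rather than crashing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with h5py.File(path, "r") as f:
            kind = f.attrs.get("kind", None)
    except OSError as exc:
        raise ParseError(f"{path}: not a readable HDF5 container ({exc})") from None
    readers = {
        "mesh": read_mesh_h5,
        "bold_cohort": read_cohort_h5,
        "profiles": read_profiles_h5,
        "resampling_map": read_resampling_map_h5,
    }
    if kind not in readers:
        raise ParseError(f"{path}: unknown or missing 'kind' attribute ({kind!r})")
    return readers[kind](path)


# ---------------------------------------------------------------------------
# pipeline runner
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    "out_dir": str,
    "stages": list,
    "seed": int,
    "n_verts": int, "medial_wall_fraction": float,
    "n_parcels": int, "n_networks": int, "n_unassigned": int,
    "subjects": int, "sessions": int, "timepoints": int,
    "p_swap": float, "noise_sd": float, "within_weight": float,
    "fraction": float,
    "height": int, "width": int,
    "zdim": int, "beta": float, "epochs": int, "batch": int, "lr": float,
    "channels": list,
    "log_level": str,
}

_DEFAULTS = dict(
    out_dir="fclatent_run", stages=(), seed=0,
    n_verts=400, medial_wall_fraction=0.05,
    n_parcels=24, n_networks=6, n_unassigned=2,
    subjects=4, sessions=2, timepoints=300,
    p_swap=0.15, noise_sd=0.5, within_weight=1.0,
    fraction=0.1, height=32, width=32,
    zdim=2, beta=2.0, epochs=2, batch=32, lr=1e-3,
    channels=(8, 16, 16, 32, 32), log_level="INFO",
)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected so a saved
    config re-runs any command bit-reproducibly (per device)."""

    values: dict

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(_CONFIG_FIELDS)
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        merged.update(d)
        return cls(values=merged)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __getitem__(self, key):
        return self.values[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages end to end and write a manifest.

    Stages (in fixed order): simulate -> fc -> reformat -> train -> embed.
    Each stage reads the previous stage's artifacts from the run directory;
    the manifest records every output with its content hash and the seed.
    """
    from . import fc as fcmod, reformat as rf, synthetic as syn, vae as vaemod

    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    order = ["simulate", "fc", "reformat", "train", "embed"]
    todo = [s for s in order if s in config["stages"]]
    unknown = set(config["stages"]) - set(order)
    if unknown:
        raise ParseError(f"unknown stages: {sorted(unknown)}")
    manifest = {"seed": config["seed"], "stages": {}, "outputs": {}}

    def record(stage, *paths):
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["outputs"][str(p)] = _sha256(Path(p))

    try:
        for stage in todo:
            if stage == "simulate":
                mesh = syn.make_sphere_mesh(
                    config["n_verts"], config["medial_wall_fraction"], seed=config["seed"])
                parc = syn.make_parcellation(
                    mesh, config["n_parcels"], config["n_networks"],
                    config["n_unassigned"], seed=config["seed"])
                spec = syn.CohortSpec(
                    n_subjects=config["subjects"], n_sessions=config["sessions"],
                    n_timepoints=config["timepoints"], p_swap=config["p_swap"],
                    noise_sd=config["noise_sd"], within_weight=config["within_weight"],
                    seed=config["seed"])
                runs = syn.simulate_bold(mesh, parc, spec)
                write_mesh_h5(mesh, out / "mesh.h5")
                write_cohort_h5(runs, out / "bold.h5")
                write_parcellation_tsv(parc, out / "vertex_parcel.tsv",
                                       out / "parcel_network.tsv")
                record(stage, out / "mesh.h5", out / "bold.h5",
                       out / "vertex_parcel.tsv", out / "parcel_network.tsv")
            elif stage == "fc":
                mesh = read_mesh_h5(out / "mesh.h5")
                runs = read_cohort_h5(out / "bold.h5")
                pset = fcmod.sample_training_profiles(
                    runs, mesh, fraction=config["fraction"], seed=config["seed"])
                write_profiles_h5(pset, out / "profiles.h5")
                record(stage, out / "profiles.h5")
            elif stage == "reformat":
                mesh = read_mesh_h5(out / "mesh.h5")
                coords = rf.spherical_coords(mesh)
                rmap = rf.build_resampling_map(
                    coords, mesh, config["height"], config["width"])
                write_resampling_map_h5(rmap, out / "rmap.h5")
                record(stage, out / "rmap.h5")
            elif stage == "train":
                pset = read_profiles_h5(out / "profiles.h5")
                rmap = read_resampling_map_h5(out / "rmap.h5")
                cfg = vaemod.VAEConfig(
                    zdim=config["zdim"], beta=config["beta"],
                    batch_size=config["batch"], lr=config["lr"],
                    epochs=config["epochs"], lr_decay_every=config["epochs"],
                    channels=tuple(config["channels"]),
                    grid=(config["height"], config["width"]), seed=config["seed"])
                model = vaemod.train(pset, rmap, cfg)
                vaemod.save_model(model, out / "model.npz")
                model.loss_trace.to_csv(out / "loss_trace.tsv", sep="\t", index=False)
                record(stage, out / "model.npz", out / "loss_trace.tsv")
            elif stage == "embed":
                pset = read_profiles_h5(out / "profiles.h5")
                rmap = read_resampling_map_h5(out / "rmap.h5")
                model = vaemod.load_model(out / "model.npz")
                post = vaemod.embed_profiles(model, pset, rmap)
                write_embeddings_tsv(pset.provenance, post.mu, post.sigma,
                                     out / "embeddings.tsv")
                record(stage, out / "embeddings.tsv")
    except Exception:
        for stage in todo:
            manifest["stages"].setdefault(stage, "failed"
                                          if stage not in manifest["stages"] else "ok")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
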