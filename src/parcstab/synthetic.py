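"""Synthetic surfaces, parcellations and BOLD-like time series.

Real inputs to the pipeline are cortical surfaces with anatomical atlases and
preprocessed per-vertex fMRI series.  This module generates topologically
faithful stand-ins so every stage runs without any download:

* icospheres — closed triangulated spheres from recursive icosahedron
  subdivision (10·4^k + 2 vertices) standing in for an inflated hemisphere;
* graph-Voronoi parcellations — multi-source BFS from random seed vertices,
  giving connected, non-empty parcels of roughly equal size, standing in for
  a 64- or 150-region anatomical atlas;
* block-covariance time series — each parcel carries a latent Gaussian signal
  with within-block correlation ``rho_in`` and between-block ``rho_out``;
  every vertex observes its parcel's latent signal plus i.i.d. Gaussian noise.
  The exact latent covariance is returned for recovery tests.

What this emulates: community-structured functional connectivity sampled on a
closed surface.  What it does not: hemodynamics, spatially autocorrelated
noise, subject registration error.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import trimesh

from .mesh import Parcellation, TriangleMesh

__all__ = [
    "SyntheticScenario",
    "make_icosphere",
    "random_parcellation",
    "block_covariance",
    "synthetic_timeseries",
    "make_fixture",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic dataset.

    Defaults describe a small but complete pipeline: a subdivision-3 icosphere
    (642 vertices) carved into 64 parcels, 3 subjects with 200 time points,
    4 parcel communities with strong within-block (0.6) and weak
    between-block (0.1) latent correlation, and unit-variance vertex noise.
    """

    subdivisions: int = 3
    n_parcels: int = 64
    n_subjects: int = 3
    n_timepoints: int = 200
    n_blocks: int = 4
    rho_in: float = 0.6
    rho_out: float = 0.1
    sigma: float = 1.0
    master_seed: int = 0

    def __post_init__(self):
        if self.n_parcels < 2:
            raise ValueError("need at least 2 parcels")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if not 0 <= self.rho_out <= self.rho_in < 1:
            raise ValueError("require 0 <= rho_out <= rho_in < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def make_icosphere(subdivisions: int) -> TriangleMesh:
    """Closed icosphere with 10·4^k + 2 vertices and 20·4^k faces."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions)
    return TriangleMesh(np.asarray(ico.vertices, float),
                        np.asarray(ico.faces, np.int64))


def random_parcellation(mesh: TriangleMesh, n_parcels: int,
                        rng: np.random.Generator | int = 0,
                        min_size: int | None = None) -> Parcellation:
    """Graph-Voronoi parcellation: multi-source BFS from random seed vertices.

    Each vertex is labelled by the seed it is closest to in hop distance
    (ties broken by BFS arrival order), so parcels are connected and
    non-empty by construction.  Seed draws whose smallest parcel falls below
    ``min_size`` (default: a quarter of the mean parcel size) are redrawn —
    anatomical atlases do not contain near-singleton regions, and such
    parcels are trivially destroyed by any perturbation.
    """
    if n_parcels > mesh.vertex_count:
        raise ValueError(f"{n_parcels} parcels > {mesh.vertex_count} vertices")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if min_size is None:
        min_size = max(1, mesh.vertex_count // (4 * n_parcels))
    adj = mesh.vertex_adjacency
    for _ in range(100):
        seeds = rng.choice(mesh.vertex_count, size=n_parcels, replace=False)
        labels = np.full(mesh.vertex_count, -1, dtype=np.int64)
        queue: deque[int] = deque()
        for k, s in enumerate(seeds):
            labels[s] = k
            queue.append(int(s))
        while queue:
            v = queue.popleft()
            for u in adj[v]:
                if labels[u] < 0:
                    labels[u] = labels[v]
                    queue.append(int(u))
        if np.bincount(labels, minlength=n_parcels).min() >= min_size:
            return Parcellation(mesh, labels)
    raise RuntimeError(
        f"could not draw a parcellation with min parcel size {min_size} "
        f"in 100 attempts")


def block_covariance(n_parcels: int, n_blocks: int,
                     rho_in: float, rho_out: float) -> tuple[np.ndarray, np.ndarray]:
    """Latent parcel correlation matrix with block structure; returns (cov, block_of)."""
    block_of = np.arange(n_parcels) % n_blocks
    same = block_of[:, None] == block_of[None, :]
    cov = np.where(same, rho_in, rho_out)
    np.fill_diagonal(cov, 1.0)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("latent covariance is not positive definite") from None
    return cov, block_of


def synthetic_timeseries(scenario: SyntheticScenario, parc: Parcellation
                         ) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-subject vertex time series plus the ground-truth latent covariance.

    Each subject's parcel signals are drawn from N(0, cov); each vertex series
    is its parcel's latent signal plus independent N(0, sigma^2) noise.
    """
    p = parc.n_parcels
    cov, _ = block_covariance(p, scenario.n_blocks, scenario.rho_in, scenario.rho_out)
    dense = parc.dense_labels()
    rng = np.random.default_rng(
        np.random.SeedSequence((scenario.master_seed, 2)))
    subjects = []
    for _ in range(scenario.n_subjects):
        latent = rng.multivariate_normal(
            np.zeros(p), cov, size=scenario.n_timepoints, method="cholesky")
        noise = scenario.sigma * rng.standard_normal(
            (scenario.n_timepoints, parc.v_tot))
        subjects.append(latent[:, dense] + noise)
    return subjects, cov


def make_fixture(scenario: SyntheticScenario, out_dir: str | Path
                 ) -> dict:
    """Write a complete on-disk bundle: mesh, labels, time series, manifest.

    Files are plain text (OFF mesh, label list, per-subject CSV matrices) so
    the bundle is portable and diffable; the manifest records every parameter
    and seed.  Returns the manifest dictionary.
    """
    from . import io as sio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh = make_icosphere(scenario.subdivisions)
    parc = random_parcellation(mesh, scenario.n_parcels,
                               np.random.default_rng(
                                   np.random.SeedSequence((scenario.master_seed, 1))))
    subjects, cov = synthetic_timeseries(scenario, parc)

    sio.write_surface(out / "surface.off", mesh)
    sio.write_labels(out / "labels.txt", parc.labels)
    np.savetxt(out / "latent_covariance.csv", cov, delimiter=",")
    ts_files = []
    for i, ts in enumerate(subjects):
        name = f"timeseries_subject{i}.csv"
        np.savetxt(out / name, ts, delimiter=",", fmt="%.6g")
        ts_files.append(name)
    manifest = {
        "scenario": asdict(scenario),
        "surface": "surface.off",
        "labels": "labels.txt",
        "latent_covariance": "latent_covariance.csv",
        "timeseries": ts_files,
        "vertex_count": mesh.vertex_count,
        "face_count": mesh.face_count,
        "n_parcels": parc.n_parcels,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
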