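"""Random parcellation-modification algorithm and its calibration.

Starting from a standard parcellation (SP), each modified parcellation (MP)
instance randomly selects a fraction ``N`` of parcels and expands each selected
parcel ``i`` by region growth across its boundary until it has absorbed more
than a quota

    e_i = T% * V_i * V_tot / (100 * sum_{j in selected} V_j)

of vertices from neighbouring parcels, where ``V_i`` is the selected parcel's
vertex count and ``V_tot`` the mesh total.  Quotas are proportional to parcel
size among the selected parcels, and sum exactly to ``T% * V_tot / 100``, so
every instance relabels strictly more than ``T%`` of the surface.

Growth starts from a small seed set drawn from the parcel's boundary faces,
expands once around the seeds, removes vertices already inside the target
parcel, and then repeatedly absorbs the neighbourhood of one randomly chosen
member until the growing set exceeds the quota (overshoot is therefore at
most one vertex neighbourhood).  Grown vertices are then relabelled to the
target parcel.  Within one instance a vertex is moved at most once (a
*forbidden* set accumulates) and selected parcels are processed sequentially
in random order on the evolving labelling.

The moved-vertex percentage ``T%`` is the knob that controls perturbation
magnitude; :func:`calibrate_t_percent` searches it so that the mean
coefficient of variation of parcel vertex counts across instances matches a
target (10% being the conventional between-subject variability of a
parcellation unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .mesh import Parcellation, TriangleMesh, classify_faces

__all__ = [
    "PerturbationConfig",
    "GrowSet",
    "ModifiedParcellation",
    "QuotaUnreachableError",
    "EmptiedParcelError",
    "InstanceFailureError",
    "CalibrationError",
    "growth_quota",
    "select_parcels",
    "grow_set",
    "apply_modification",
    "generate_instance",
    "generate_instances",
    "parcel_volume_cv",
    "calibrate_t_percent",
]


class QuotaUnreachableError(RuntimeError):
    """The growth frontier was exhausted before the quota was met."""


class EmptiedParcelError(RuntimeError):
    """Applying a grow set would leave a donor parcel with no vertices."""


class InstanceFailureError(RuntimeError):
    """An instance kept failing past the retry cap."""


class CalibrationError(RuntimeError):
    """The CV target could not be bracketed or reached."""


@dataclass(frozen=True)
class PerturbationConfig:
    """Inputs of the modification algorithm.

    t_percent
        Percentage of total surface vertices to move (default 3).
    n_fraction
        Fraction of parcels whose area is increased (default 0.30).
    m
        Number of modified-parcellation instances (default 100).
    master_seed
        Seed of the whole ensemble; instance ``k`` uses the counter-based
        sub-seed ``(master_seed, k, retry)`` so instances are independent.
    seed_set_size
        Boundary vertices seeding each grow set (3; a single-vertex variant
        is supported as well).
    """

    t_percent: float = 3.0
    n_fraction: float = 0.30
    m: int = 100
    master_seed: int = 0
    seed_set_size: int = 3
    retry_cap: int = 5

    def __post_init__(self):
        if not 0 < self.t_percent < 100:
            raise ValueError("t_percent must be in (0, 100)")
        if not 0 < self.n_fraction <= 1:
            raise ValueError("n_fraction must be in (0, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.seed_set_size < 1:
            raise ValueError("seed_set_size must be >= 1")


@dataclass
class GrowSet:
    """A completed growing set for one selected parcel."""

    target_parcel: int
    quota: float
    members: np.ndarray           # vertex indices, disjoint from the target parcel
    donor_counts: dict[int, int]  # vertices taken per donor parcel


@dataclass
class ModifiedParcellation:
    """One MP instance: the relabelled surface plus provenance."""

    base: Parcellation
    labels: np.ndarray
    expanded_parcels: list[int]
    moved_vertices: np.ndarray
    instance_index: int
    instance_seed: tuple[int, ...]
    grow_sets: list[GrowSet] = field(default_factory=list, repr=False)

    @property
    def parcellation(self) -> Parcellation:
        return Parcellation(self.base.mesh, self.labels)

    @property
    def moved_fraction(self) -> float:
        return len(self.moved_vertices) / self.base.v_tot


def growth_quota(t_percent: float, target_size: int,
                 selected_sizes: Sequence[int], v_tot: int) -> float:
    """Vertex quota e_i for one selected parcel.

    e_i = t% * V_i * V_tot / (100 * sum_j V_j) over the selected parcels; the
    quotas of all selected parcels therefore sum exactly to t% * V_tot / 100.
    """
    selected_sizes = list(selected_sizes)
    if not selected_sizes:
        raise ValueError("empty parcel selection")
    if target_size not in selected_sizes:
        raise ValueError("target_size must be one of selected_sizes")
    return t_percent * target_size * v_tot / (100.0 * sum(selected_sizes))


def select_parcels(parc: Parcellation, n_fraction: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniformly sample round(n_fraction * P) distinct parcel ids (at least one)."""
    n = max(1, round(n_fraction * parc.n_parcels))
    return rng.choice(parc.parcel_ids, size=n, replace=False)


def grow_set(mesh: TriangleMesh, labels: np.ndarray, target_parcel: int,
             quota: float, rng: np.random.Generator, seed_set_size: int = 3,
             forbidden: np.ndarray | None = None) -> GrowSet:
    """Grow a vertex set across the target parcel's boundary until ``|G| > quota``.

    ``labels`` is the current (possibly already partially modified) labelling.
    ``forbidden`` marks vertices already moved in this instance; they are never
    absorbed and growth does not pass through them.
    """
    adj = mesh.vertex_adjacency
    is_target = labels == target_parcel
    if forbidden is None:
        forbidden = np.zeros(mesh.vertex_count, dtype=bool)

    # step 1: seed vertices drawn from the target parcel's boundary faces
    fc = classify_faces(Parcellation(mesh, labels))
    bfaces = mesh.faces[fc.boundary_faces]
    touches_target = is_target[bfaces].any(axis=1)
    candidates = np.unique(bfaces[touches_target])
    candidates = candidates[~forbidden[candidates]]
    if len(candidates) == 0:
        raise QuotaUnreachableError(
            f"parcel {target_parcel} has no usable boundary-face vertices to seed from")
    seeds = rng.choice(candidates, size=min(seed_set_size, len(candidates)),
                       replace=False)

    # steps 2-4: expand once around the seeds, then drop vertices that are
    # inside the target parcel (or already moved) to obtain the members;
    # if that leaves nothing, keep expanding the raw growing set (which may
    # pass through the target parcel's interior) until a donor vertex appears
    in_set = np.zeros(mesh.vertex_count, dtype=bool)
    in_set[seeds] = True
    in_set[np.unique(np.concatenate([adj[v] for v in seeds]))] = True
    member = in_set & ~is_target & ~forbidden
    while not member.any():
        new = np.unique(np.concatenate([adj[v] for v in np.flatnonzero(in_set)]))
        new = new[~in_set[new] & ~forbidden[new]]
        if len(new) == 0:
            raise QuotaUnreachableError(
                f"parcel {target_parcel}: no reachable donor vertices")
        in_set[new] = True
        member = in_set & ~is_target & ~forbidden

    # step 5: repeat the single-vertex expansion of step 2 — pick one member
    # and absorb its neighbourhood — until |G| > e_i, so the growing set
    # overshoots the quota by at most one vertex neighbourhood; even a zero
    # quota yields at least one member
    stalled: set[int] = set()
    while member.sum() <= quota:
        frontier = np.array([v for v in np.flatnonzero(member) if v not in stalled])
        if len(frontier) == 0:
            raise QuotaUnreachableError(
                f"parcel {target_parcel}: donors depleted at "
                f"{int(member.sum())}/{quota:.2f} vertices")
        v = int(rng.choice(frontier))
        new = adj[v]
        new = new[~member[new] & ~is_target[new] & ~forbidden[new]]
        if len(new) == 0:
            # neighbourhood exhausted; the member set only grows, so this
            # vertex can never contribute again
            stalled.add(v)
            continue
        member[new] = True

    members = np.flatnonzero(member)
    donor_ids, counts = np.unique(labels[members], return_counts=True)
    return GrowSet(target_parcel=int(target_parcel), quota=float(quota),
                   members=members,
                   donor_counts=dict(zip(donor_ids.tolist(), counts.tolist())))


def apply_modification(labels: np.ndarray, gs: GrowSet) -> np.ndarray:
    """Relabel the grow-set members to the target parcel (step 6)."""
    for donor, taken in gs.donor_counts.items():
        remaining = int((labels == donor).sum()) - taken
        if remaining <= 0:
            raise EmptiedParcelError(
                f"moving {taken} vertices would empty donor parcel {donor}")
    new_labels = labels.copy()
    new_labels[gs.members] = gs.target_parcel
    return new_labels


def generate_instance(mesh: TriangleMesh, parc: Parcellation,
                      config: PerturbationConfig, instance_index: int
                      ) -> ModifiedParcellation:
    """One MP instance; retries with a fresh sub-seed on quota/emptied failures."""
    base_sizes = parc.sizes
    last_err: Exception | None = None
    for retry in range(config.retry_cap):
        seed_key = (config.master_seed, instance_index, retry)
        rng = np.random.default_rng(np.random.SeedSequence(seed_key))
        try:
            selected = select_parcels(parc, config.n_fraction, rng)
            order = rng.permutation(len(selected))
            sel_sizes = [base_sizes[int(p)] for p in selected]
            labels = parc.labels.copy()
            forbidden = np.zeros(mesh.vertex_count, dtype=bool)
            grow_sets = []
            for pos in order:
                target = int(selected[pos])
                e_i = growth_quota(config.t_percent, base_sizes[target],
                                   sel_sizes, parc.v_tot)
                gs = grow_set(mesh, labels, target, e_i, rng,
                              seed_set_size=config.seed_set_size,
                              forbidden=forbidden)
                labels = apply_modification(labels, gs)
                forbidden[gs.members] = True
                grow_sets.append(gs)
            moved = np.flatnonzero(labels != parc.labels)
            return ModifiedParcellation(
                base=parc, labels=labels,
                expanded_parcels=[int(p) for p in selected],
                moved_vertices=moved, instance_index=instance_index,
                instance_seed=seed_key, grow_sets=grow_sets)
        except (QuotaUnreachableError, EmptiedParcelError) as err:
            last_err = err
    raise InstanceFailureError(
        f"instance {instance_index} failed {config.retry_cap} times; "
        f"last error: {last_err}")


def generate_instances(mesh: TriangleMesh, parc: Parcellation,
                       config: PerturbationConfig) -> list[ModifiedParcellation]:
    """The full ensemble of ``config.m`` modified parcellations."""
    return [generate_instance(mesh, parc, config, k) for k in range(config.m)]


def volume_cv_from_counts(counts: np.ndarray) -> tuple[float, np.ndarray]:
    """CV (%) per parcel from an instances × parcels count matrix.

    CV uses the sample (n-1) standard deviation over instances divided by the
    mean count; the summary value is the unweighted mean over parcels.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need an (instances >= 2) x parcels count matrix")
    cvs = 100.0 * counts.std(axis=0, ddof=1) / counts.mean(axis=0)
    return float(cvs.mean()), cvs


def parcel_volume_cv(base: Parcellation,
                     instances: Sequence[ModifiedParcellation]
                     ) -> tuple[float, dict[int, float]]:
    """Mean and per-parcel coefficient of variation (%) of parcel vertex counts."""
    if len(instances) < 2:
        raise ValueError("need at least 2 instances to compute a CV")
    ids = base.parcel_ids
    counts = np.zeros((len(instances), len(ids)))
    for r, inst in enumerate(instances):
        got, c = np.unique(inst.labels, return_counts=True)
        if len(got) != len(ids) or (got != ids).any():
            missing = set(ids.tolist()) - set(got.tolist())
            raise ValueError(f"instance {inst.instance_index} lost parcels {missing}")
        counts[r] = c
    mean_cv, cvs = volume_cv_from_counts(counts)
    return mean_cv, dict(zip(ids.tolist(), cvs.tolist()))


def _ensemble_cv(mesh: TriangleMesh, parc: Parcellation, t_percent: float,
                 template: PerturbationConfig, ensemble_seed: int) -> float:
    cfg = PerturbationConfig(
        t_percent=t_percent, n_fraction=template.n_fraction, m=template.m,
        master_seed=ensemble_seed, seed_set_size=template.seed_set_size,
        retry_cap=template.retry_cap)
    mean_cv, _ = parcel_volume_cv(parc, generate_instances(mesh, parc, cfg))
    return mean_cv


def calibrate_t_percent(mesh: TriangleMesh, parc: Parcellation,
                        target_cv_percent: float,
                        config: PerturbationConfig | None = None,
                        bounds: tuple[float, float] = (0.5, 15.0),
                        tolerance: float = 0.5,
                        rng: np.random.Generator | None = None,
                        max_iter: int = 25) -> tuple[float, float, int]:
    """Bisection on t_percent until the achieved mean parcel-volume CV hits the target.

    All evaluations share one ensemble seed (paired ensembles), under which the
    achieved CV is monotone in t_percent.  Returns ``(t_percent, achieved_cv,
    ensemble_seed)``.
    """
    if target_cv_percent <= 0:
        raise ValueError("target_cv_percent must be positive")
    if config is None:
        config = PerturbationConfig()
    if rng is None:
        rng = np.random.default_rng(config.master_seed)
    ensemble_seed = int(rng.integers(2**31))

    lo, hi = bounds
    cv_lo = _ensemble_cv(mesh, parc, lo, config, ensemble_seed)
    if abs(cv_lo - target_cv_percent) <= tolerance:
        return lo, cv_lo, ensemble_seed
    cv_hi = _ensemble_cv(mesh, parc, hi, config, ensemble_seed)
    if abs(cv_hi - target_cv_percent) <= tolerance:
        return hi, cv_hi, ensemble_seed
    if not (cv_lo < target_cv_percent < cv_hi):
        raise CalibrationError(
            f"bounds do not bracket the target: CV({lo})={cv_lo:.2f}, "
            f"CV({hi})={cv_hi:.2f}, target={target_cv_percent}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cv_mid = _ensemble_cv(mesh, parc, mid, config, ensemble_seed)
        if abs(cv_mid - target_cv_percent) <= tolerance:
            return mid, cv_mid, ensemble_seed
        if cv_mid < target_cv_percent:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"no t_percent within tolerance {tolerance} after {max_iter} bisections "
        f"(bracket [{lo}, {hi}])")
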