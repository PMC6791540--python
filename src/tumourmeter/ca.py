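"""Stochastic cellular-automaton growth of a subcutaneous tumour on a 3D voxel lattice.

Two cell populations (a baseline population and an optional aggressive
sub-clone) occupy voxels on a regular grid sitting on a rigid base plane at
z = 0 (the body wall).  Each day, cells with at least one empty
face-neighbour divide with a fixed probability and place the daughter into
an empty face-neighbour chosen with an upward bias; during a treatment
window every cell dies independently with probability ``lam``.  Six seeding
presets generate the characteristic morphologies of subcutaneous tumours:
single/double/triple peaks, a needle-trail "igloo", an aggressive-subclone
"birthday cake", and an ulcerating "volcano".

Update rules in detail (one day = one CA step):

1. Every occupied voxel with >= 1 EMPTY face-neighbour attempts division
   with probability ``p_divi`` (POP_B: ``p_divi * mutant_p_divi_factor``,
   capped at 1).
2. Each divider picks a target among its EMPTY face-neighbours with weight
   1 for lateral/downward targets and ``1 + bias`` for the +z target.
3. Conflicts (two parents choosing the same voxel) are resolved
   first-come-wins over a randomly permuted parent order; losers do not
   divide that day.
4. If ``treatment_start <= day < treatment_start + lam_len``, every tumour
   cell (daughters included) independently becomes EMPTY with probability
   ``lam``.
5. For the volcano preset, an ulceration crater is carved once, on day
   ``ulceration_day``.

Voxels are solid cubes of edge ``voxel_edge`` mm; ground-truth volume is
the occupied-voxel count times the voxel volume.  NECROTIC voxels (lost to
ulceration) count neither towards volume nor as division targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._errors import BoundaryError, ConfigurationError, GeometryError

EMPTY = 0
POP_A = 1
POP_B = 2
NECROTIC = 3

MORPHOLOGIES = (
    "one_peak",
    "two_peak",
    "three_peak",
    "igloo",
    "birthday_cake",
    "volcano",
)

# Face-neighbour offsets; index 4 is the +z (upward) direction.
_DIRS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)
_UP = 4


@dataclass(frozen=True)
class StepCounters:
    """Per-step bookkeeping used by the conservation checks."""

    births: int = 0
    deaths: int = 0
    ulcerated: int = 0


@dataclass
class Lattice:
    """3D voxel grid of cell states resting on the z=0 base plane."""

    state: np.ndarray  # uint8, shape (nx, ny, nz)
    voxel_edge: float = 0.2  # mm
    counters: StepCounters | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.uint8)
        if self.state.ndim != 3:
            raise GeometryError("lattice state must be a 3D array")
        if self.voxel_edge <= 0:
            raise ConfigurationError("voxel_edge must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.state.shape  # type: ignore[return-value]

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of live tumour voxels (POP_A or POP_B)."""
        return (self.state == POP_A) | (self.state == POP_B)

    def population_counts(self) -> dict[str, int]:
        return {
            "pop_a": int((self.state == POP_A).sum()),
            "pop_b": int((self.state == POP_B).sum()),
            "necrotic": int((self.state == NECROTIC).sum()),
        }

    def cell_count(self) -> int:
        return int(self.occupied.sum())

    def copy(self) -> "Lattice":
        return Lattice(self.state.copy(), self.voxel_edge)

    def touches_boundary(self) -> bool:
        """True when any live voxel sits on a lateral face or the top face."""
        occ = self.occupied
        return bool(
            occ[0, :, :].any()
            or occ[-1, :, :].any()
            or occ[:, 0, :].any()
            or occ[:, -1, :].any()
            or occ[:, :, -1].any()
        )


@dataclass
class GrowthCurve:
    """Per-day volume series for one tumour under one volume method."""

    days: np.ndarray
    volume_mm3: np.ndarray
    method: str = "GT"  # GT | SC | CYL | ELL
    arm: str = "control"  # control | treated
    empty_days: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=np.int64)
        self.volume_mm3 = np.asarray(self.volume_mm3, dtype=np.float64)
        if self.days.shape != self.volume_mm3.shape:
            raise ConfigurationError("days and volume_mm3 must have equal length")
        if np.any(self.volume_mm3 < 0):
            raise ConfigurationError("volumes must be non-negative")

    def volume_at(self, day: int) -> float:
        idx = np.nonzero(self.days == day)[0]
        if idx.size == 0:
            raise KeyError(f"curve has no entry for day {day}")
        return float(self.volume_mm3[idx[0]])


@dataclass
class SimulationParams:
    """Growth/treatment parameters plus lattice geometry and morphology preset."""

    bias: float = 1.0
    p_divi: float = 0.1
    lam: float = 0.4
    lam_len: int = 10
    treatment_start: int = 15
    total_days: int = 30
    morphology: str = "one_peak"
    mutant_p_divi_factor: float = 2.0
    ulceration_day: int = 20
    crater_fraction: float = 0.15
    dims: tuple[int, int, int] = (100, 100, 50)
    voxel_edge: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if self.bias < 0:
            problems.append("bias must be >= 0")
        if not 0.0 <= self.p_divi <= 1.0:
            problems.append("p_divi must lie in [0, 1]")
        if not 0.0 <= self.lam <= 1.0:
            problems.append("lam must lie in [0, 1]")
        if self.lam_len < 0 or self.treatment_start < 0:
            problems.append("treatment schedule indices must be >= 0")
        if self.treatment_start + self.lam_len > self.total_days:
            problems.append("treatment_start + lam_len must not exceed total_days")
        if self.total_days < 1:
            problems.append("total_days must be >= 1")
        if self.morphology not in MORPHOLOGIES:
            problems.append(
                f"unknown morphology {self.morphology!r}; expected one of {MORPHOLOGIES}"
            )
        if self.mutant_p_divi_factor < 1.0:
            problems.append("mutant_p_divi_factor must be >= 1")
        if not 0.0 <= self.crater_fraction < 1.0:
            problems.append("crater_fraction must lie in [0, 1)")
        if len(self.dims) != 3 or any(int(d) < 4 for d in self.dims):
            problems.append("dims must be a triple of integers >= 4")
        if self.voxel_edge <= 0:
            problems.append("voxel_edge must be positive")
        if problems:
            raise ConfigurationError("; ".join(problems))

    def with_lam(self, lam: float) -> "SimulationParams":
        return replace(self, lam=lam)


def _hemisphere_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, np.arange(0, r + 1), indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def _place_cluster(state: np.ndarray, centre: tuple[int, int], radius: int, margin: int = 5) -> None:
    nx, ny, nz = state.shape
    cx, cy = centre
    if not (margin + radius <= cx < nx - margin - radius):
        raise GeometryError("seed cluster violates the lateral margin in x")
    if not (margin + radius <= cy < ny - margin - radius):
        raise GeometryError("seed cluster violates the lateral margin in y")
    if nz < radius + 2:
        raise GeometryError("lattice too shallow for the seed cluster")
    off = _hemisphere_offsets(radius)
    state[cx + off[:, 0], cy + off[:, 1], off[:, 2]] = POP_A


def init_tumour(
    morphology: str,
    dims: Sequence[int] = (100, 100, 50),
    seed: int = 0,
    *,
    voxel_edge: float = 0.2,
    seed_radius: int = 3,
    trail_length: int = 20,
    peak_separation: int = 16,
) -> Lattice:
    """Seed a lattice according to one of the six morphology presets.

    ``seed`` is accepted for interface symmetry; all presets place their
    seed clusters deterministically so that paired simulations start from
    identical configurations.
    """
    if morphology not in MORPHOLOGIES:
        raise ConfigurationError(
            f"unknown morphology {morphology!r}; expected one of {MORPHOLOGIES}"
        )
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3:
        raise GeometryError("dims must be a (nx, ny, nz) triple")
    nx, ny, nz = dims
    state = np.zeros(dims, dtype=np.uint8)
    cx, cy = nx // 2, ny // 2
    r = int(seed_radius)

    if morphology in ("one_peak", "volcano"):
        _place_cluster(state, (cx, cy), r)
    elif morphology == "two_peak":
        half = peak_separation // 2
        _place_cluster(state, (cx - half, cy), r)
        _place_cluster(state, (cx + half, cy), r)
    elif morphology == "three_peak":
        half = peak_separation // 2
        _place_cluster(state, (cx - half, cy - half), r)
        _place_cluster(state, (cx + half, cy - half), r)
        _place_cluster(state, (cx, cy + half), r)
    elif morphology == "igloo":
        _place_cluster(state, (cx, cy), r)
        x0 = cx + r + 1
        x1 = x0 + trail_length
        if x1 > nx - 5:
            raise GeometryError("lattice too narrow for the igloo needle trail")
        state[x0:x1, cy, 0:2] = POP_A
    elif morphology == "birthday_cake":
        _place_cluster(state, (cx, cy), r)
        # aggressive sub-clone: radius-1 ball at the apex, restricted to the mound
        apex = np.array([cx, cy, r])
        sub = np.vstack([apex, apex + _DIRS])
        inside = (
            (sub[:, 0] >= 0)
            & (sub[:, 0] < nx)
            & (sub[:, 1] >= 0)
            & (sub[:, 1] < ny)
            & (sub[:, 2] >= 0)
            & (sub[:, 2] < nz)
        )
        sub = sub[inside]
        occ_here = state[sub[:, 0], sub[:, 1], sub[:, 2]] == POP_A
        sub = sub[occ_here]
        state[sub[:, 0], sub[:, 1], sub[:, 2]] = POP_B

    return Lattice(state, voxel_edge)


def _neighbour_empty_table(state: np.ndarray, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each coordinate, which of the 6 face-neighbours is in-bounds and EMPTY.

    Returns (valid: bool (n, 6), targets: int64 (n, 6) linear indices,
    garbage where invalid).
    """
    nx, ny, nz = state.shape
    nb = coords[:, None, :] + _DIRS[None, :, :]  # (n, 6, 3)
    inb = (
        (nb[..., 0] >= 0)
        & (nb[..., 0] < nx)
        & (nb[..., 1] >= 0)
        & (nb[..., 1] < ny)
        & (nb[..., 2] >= 0)
        & (nb[..., 2] < nz)
    )
    flat = state.ravel()
    nb_clipped = nb.copy()
    nb_clipped[..., 0] = np.clip(nb[..., 0], 0, nx - 1)
    nb_clipped[..., 1] = np.clip(nb[..., 1], 0, ny - 1)
    nb_clipped[..., 2] = np.clip(nb[..., 2], 0, nz - 1)
    lin = (nb_clipped[..., 0] * ny + nb_clipped[..., 1]) * nz + nb_clipped[..., 2]
    valid = inb & (flat[lin] == EMPTY)
    return valid, lin


def step(
    lattice: Lattice,
    params: SimulationParams,
    day: int,
    rng: np.random.Generator,
) -> Lattice:
    """Advance the lattice by one day: division sweep, then treatment deaths.

    Returns a new Lattice; ``result.counters`` carries the exact birth /
    death / ulceration tallies for the day.
    """
    state = lattice.state.copy()
    births = deaths = ulcerated = 0

    occ = (state == POP_A) | (state == POP_B)
    coords = np.argwhere(occ)
    if coords.shape[0] > 0 and params.p_divi > 0:
        valid, lin = _neighbour_empty_table(state, coords)
        frontier = valid.any(axis=1)
        pops = state[coords[:, 0], coords[:, 1], coords[:, 2]]
        p = np.where(
            pops == POP_B,
            min(1.0, params.p_divi * params.mutant_p_divi_factor),
            params.p_divi,
        )
        divides = frontier & (rng.random(coords.shape[0]) < p)
        if divides.any():
            dvalid = valid[divides]
            dlin = lin[divides]
            dpop = pops[divides]
            w = np.ones(6, dtype=np.float64)
            w[_UP] = 1.0 + params.bias
            weights = dvalid * w[None, :]
            cum = np.cumsum(weights, axis=1)
            u = rng.random(dvalid.shape[0]) * cum[:, -1]
            choice = (u[:, None] >= cum).sum(axis=1)
            targets = dlin[np.arange(dlin.shape[0]), choice]
            # first-come-wins over a random parent permutation
            perm = rng.permutation(targets.shape[0])
            _, first = np.unique(targets[perm], return_index=True)
            winners = perm[first]
            flat = state.ravel()
            flat[targets[winners]] = dpop[winners]
            births = int(winners.shape[0])

    in_window = params.treatment_start <= day < params.treatment_start + params.lam_len
    if in_window and params.lam > 0:
        occ2 = (state == POP_A) | (state == POP_B)
        cells = np.argwhere(occ2)
        kill = rng.random(cells.shape[0]) < params.lam
        state[cells[kill, 0], cells[kill, 1], cells[kill, 2]] = EMPTY
        deaths = int(kill.sum())

    out = Lattice(state, lattice.voxel_edge)

    if params.morphology == "volcano" and day == params.ulceration_day:
        before = out.cell_count()
        out = apply_ulceration(out, params.crater_fraction, rng)
        ulcerated = before - out.cell_count()

    out.counters = StepCounters(births=births, deaths=deaths, ulcerated=ulcerated)
    return out


def apply_ulceration(
    lattice: Lattice, crater_fraction: float, rng: np.random.Generator
) -> Lattice:
    """Carve a crater: mark the ``floor(f * N)`` live voxels nearest the apex NECROTIC.

    The apex is the top of the tallest occupied column; proximity is
    Euclidean distance to that point, random tie-breaking within equal
    distances.
    """
    if not 0.0 <= crater_fraction < 1.0:
        raise ConfigurationError("crater_fraction must lie in [0, 1)")
    occ = lattice.occupied
    n = int(occ.sum())
    if n == 0:
        raise ConfigurationError("cannot ulcerate an empty lattice")
    n_remove = int(np.floor(crater_fraction * n))
    if n_remove == 0:
        return lattice
    heights = np.where(occ.any(axis=2), occ.shape[2] - 1 - np.argmax(occ[:, :, ::-1], axis=2), -1)
    ax, ay = np.unravel_index(np.argmax(heights), heights.shape)
    apex = np.array([ax, ay, heights[ax, ay]], dtype=np.float64)
    cells = np.argwhere(occ)
    d = np.linalg.norm(cells - apex[None, :], axis=1)
    order = np.lexsort((rng.random(d.shape[0]), d))
    doomed = cells[order[:n_remove]]
    state = lattice.state.copy()
    state[doomed[:, 0], doomed[:, 1], doomed[:, 2]] = NECROTIC
    return Lattice(state, lattice.voxel_edge)


def ground_truth_volume(lattice: Lattice) -> float:
    """Occupied-voxel count times voxel volume, in mm^3."""
    return float(lattice.cell_count()) * lattice.voxel_edge**3


def simulate(params: SimulationParams) -> tuple[list[Lattice], GrowthCurve]:
    """Run a full trajectory; returns (snapshots for days 0..total_days, GT curve).

    Identical ``params`` (including ``seed``) give bit-identical output.
    Raises BoundaryError if the tumour reaches a lateral or top face.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lat = init_tumour(
        params.morphology, params.dims, params.seed, voxel_edge=params.voxel_edge
    )
    snapshots = [lat]
    volumes = [ground_truth_volume(lat)]
    for day in range(params.total_days):
        lat = step(lat, params, day, rng)
        if lat.touches_boundary():
            raise BoundaryError(
                f"tumour reached the lattice boundary on day {day} "
                f"(morphology={params.morphology}, seed={params.seed})"
            )
        snapshots.append(lat)
        volumes.append(ground_truth_volume(lat))
    curve = GrowthCurve(
        days=np.arange(params.total_days + 1),
        volume_mm3=np.asarray(volumes),
        method="GT",
        arm="treated" if params.lam > 0 and params.lam_len > 0 else "control",
    )
    return snapshots, curve


def save_lattice(lattice: Lattice, path: str) -> None:
    """Write the state array as .npy with a JSON sidecar holding dims/voxel_edge."""
    import json
    from pathlib import Path

    p = Path(path)
    np.save(p.with_suffix(".npy"), lattice.state)
    sidecar = {"dims": list(lattice.dims), "voxel_edge": lattice.voxel_edge}
    p.with_suffix(".json").write_text(json.dumps(sidecar))


def load_lattice(path: str) -> Lattice:
    import json
    from pathlib import Path

    p = Path(path)
    state = np.load(p.with_suffix(".npy"))
    sidecar = json.loads(p.with_suffix(".json").read_text())
    return Lattice(state, float(sidecar["voxel_edge"]))
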