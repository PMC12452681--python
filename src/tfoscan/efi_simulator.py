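"""Forward simulation of EFI matrices for normal and folded insertions.

The simulator stands in for bench rigs (plastic cochlea, temporal bone)
and patient measurements, which cannot be shipped with the package.  It is
deliberately geometric rather than biophysical: contacts are laid out
along a planar spiral approximating the cochlear duct, a fold-over
reflects the apical contacts back alongside the array, and impedances
follow a distance kernel

    Z_ij = floor + amp * exp(-d_ij / lambda)        (i != j)
    Z_ii = access_i + amp

with Euclidean inter-contact distance ``d_ij`` in millimetres and
per-contact access resistance ``access_i``.  Multiplicative log-normal
noise models measurement jitter.  Because the fold is expressed purely in
the geometry, the mirror symmetry of cross-impedances about the fold
contact emerges from the kernel rather than being painted onto the matrix
— keeping the simulator independent of the detector it exercises.

Default kernel values put simulated in-vivo cross-impedances in the
0.5–2 kΩ range characteristic of patient recordings; the bench preset
scales them up, as plastic-cochlea measurements run higher.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .efi_model import MAX_CONTACTS, EFIMatrix

__all__ = [
    "ArrayFamily",
    "ArrayGeometry",
    "ImpedanceKernel",
    "FaultSpec",
    "BenchmarkCase",
    "make_geometry",
    "simulate_efi",
    "generate_benchmark",
    "bench_kernel",
]

#: Valid fold locations: a fold must leave contacts on both sides.
FOLD_RANGE = range(2, 9)


class ArrayFamily(str, enum.Enum):
    PRE_CURVED = "pre-curved"
    STRAIGHT_LATERAL_WALL = "straight-lateral-wall"


# Spiral tightness presets: a pre-curved (perimodiolar) array hugs a
# tighter spiral than a straight lateral-wall array.  Rates are capped so
# the chord distance between any two contacts grows monotonically with
# their separation (total turn over the array < 180 deg) — the geometric
# counterpart of the monotone cross-impedance decay of a normal insertion.
_FAMILY_TURN_RATE_DEG_PER_MM = {
    ArrayFamily.PRE_CURVED: 10.0,
    ArrayFamily.STRAIGHT_LATERAL_WALL: 6.0,
}

#: Lateral offset (mm) between the folded-back limb and the main limb;
#: a folded array lies alongside itself, not on top of itself.
_FOLD_OFFSET_MM = 0.35


@dataclass(frozen=True)
class ArrayGeometry:
    """Contact positions (mm) along a spiral path, apical contact first."""

    positions: np.ndarray
    family: ArrayFamily
    fold_at: int | None = None
    contact_pitch: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")

    @property
    def n_contacts(self) -> int:
        return self.positions.shape[0]

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix, mm."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))


def _spiral_path(turn_rate_deg_per_mm: float, total_len: float, step: float = 0.01) -> np.ndarray:
    """Planar constant-curvature-rate path traversed at unit speed.

    The heading angle grows linearly with arc length, with the turn rate
    itself tightening toward the apical end the way the cochlear duct
    curls tighter toward the apex.
    """
    n = int(total_len / step) + 1
    s = np.arange(n) * step
    # tighter curvature apically (larger s = deeper insertion)
    rate = np.deg2rad(turn_rate_deg_per_mm) * (1.0 + 0.015 * s)
    heading = np.cumsum(rate * step)
    xy = np.cumsum(
        np.stack([np.cos(heading), np.sin(heading)], axis=1) * step, axis=0
    )
    return xy


def make_geometry(
    family: ArrayFamily | str = ArrayFamily.PRE_CURVED,
    fold_at: int | None = None,
    n_contacts: int = MAX_CONTACTS,
    contact_pitch: float = 1.0,
) -> ArrayGeometry:
    """Lay out contacts along the spiral; optionally fold the tip back.

    ``fold_at=f`` reflects the contacts apical to ``f`` (labels < f) back
    alongside the array so contact ``f-k`` comes to lie next to contact
    ``f+k`` — the mirror adjacency that produces the characteristic
    symmetric cross-impedance pattern about the fold.

    Raises ``ValueError`` for ``fold_at`` outside 2..8: a fold at the very
    tip (contact 1) leaves no reflected limb, and the clinical fold range
    motivating the detector is apical.
    """
    family = ArrayFamily(family)
    if fold_at is not None and fold_at not in FOLD_RANGE:
        raise ValueError(f"fold_at must be in {FOLD_RANGE.start}..{FOLD_RANGE.stop - 1} or None")

    path = _spiral_path(
        _FAMILY_TURN_RATE_DEG_PER_MM[family], total_len=n_contacts * contact_pitch + 1.0
    )
    # arc-length positions: label 16 (basal) at path start, label 1 (apical)
    # deepest in; positions array is indexed apical-first.
    arc = np.arange(n_contacts) * contact_pitch
    idx = np.round(arc / 0.01).astype(int)
    pos_basal_first = path[idx]
    positions = pos_basal_first[::-1].copy()

    if fold_at is not None:
        f = fold_at - 1  # 0-based index of the fold contact
        # unit lateral normal at the fold region, for the side-by-side offset
        tangent = positions[min(f + 1, n_contacts - 1)] - positions[f]
        norm = np.linalg.norm(tangent)
        normal = (
            np.array([-tangent[1], tangent[0]]) / norm if norm > 0 else np.array([0.0, 1.0])
        )
        for k in range(1, f + 1):
            mirror = f + k
            if mirror < n_contacts:
                positions[f - k] = positions[mirror] + _FOLD_OFFSET_MM * normal
            else:
                # fold limb longer than the remaining array: extrapolate
                # past the basal end along the last segment
                tail = positions[n_contacts - 1] - positions[n_contacts - 2]
                tail = tail / np.linalg.norm(tail)
                over = mirror - (n_contacts - 1)
                positions[f - k] = (
                    positions[n_contacts - 1]
                    + over * contact_pitch * tail
                    + _FOLD_OFFSET_MM * normal
                )

    return ArrayGeometry(
        positions=positions,
        family=family,
        fold_at=fold_at,
        contact_pitch=contact_pitch,
    )


@dataclass(frozen=True)
class ImpedanceKernel:
    """Distance-to-impedance kernel parameters (kΩ, mm).

    ``access_kohm`` may be a per-contact vector; when None, values are
    drawn uniformly from 3–8 kΩ (typical monopolar contact impedances)
    using ``seed``.  ``noise_sigma`` is the sigma of multiplicative
    log-normal measurement noise; 0.03 approximates a few-percent
    repeatability jitter.
    """

    access_kohm: tuple[float, ...] | None = None
    amp_kohm: float = 1.5
    lambda_mm: float = 3.0
    floor_kohm: float = 0.5
    noise_sigma: float = 0.03
    seed: int = 0

    def access_vector(self, n: int) -> np.ndarray:
        if self.access_kohm is not None:
            acc = np.asarray(self.access_kohm, dtype=float)
            if acc.shape != (n,):
                raise ValueError(f"access_kohm must have length {n}")
            return acc
        rng = np.random.default_rng(self.seed)
        return rng.uniform(3.0, 8.0, size=n)


def bench_kernel(seed: int = 0, noise_sigma: float = 0.03) -> ImpedanceKernel:
    """Plastic-cochlea-style preset: cross-impedances several-fold higher
    than in vivo, same spatial pattern."""
    return ImpedanceKernel(
        amp_kohm=6.0, floor_kohm=2.0, lambda_mm=3.0, noise_sigma=noise_sigma, seed=seed
    )


@dataclass(frozen=True)
class FaultSpec:
    """Electrode faults to inject after the volume-conduction model."""

    opens: frozenset[int] = frozenset()
    shorts_to_ground: frozenset[int] = frozenset()
    partial_short_pairs: tuple[tuple[int, int], ...] = ()
    airpocket: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "opens", frozenset(self.opens))
        object.__setattr__(self, "shorts_to_ground", frozenset(self.shorts_to_ground))
        pair_members = {x for p in self.partial_short_pairs for x in p}
        if self.opens & self.shorts_to_ground or pair_members & (
            self.opens | self.shorts_to_ground
        ):
            raise ValueError("fault label sets must be disjoint")


def simulate_efi(
    g: ArrayGeometry,
    k: ImpedanceKernel | None = None,
    f: FaultSpec | None = None,
    meta: dict | None = None,
) -> EFIMatrix:
    """Render the geometry into a trans-impedance matrix (kΩ).

    Deterministic for a fixed kernel seed.  Faults overwrite the modelled
    values: an open contact gets a main impedance above the 30 kΩ QC
    limit, a short-to-ground falls below 0.5 kΩ, a partial-short pair has
    its cross-impedance raised toward the smaller main impedance, and the
    air-pocket condition scales the apical row's cross-impedances past
    the 5 kΩ integrity limit.
    """
    k = k or ImpedanceKernel()
    f = f or FaultSpec()
    n = g.n_contacts
    d = g.distances()
    z = k.floor_kohm + k.amp_kohm * np.exp(-d / k.lambda_mm)
    access = k.access_vector(n)
    np.fill_diagonal(z, access + k.amp_kohm)

    rng = np.random.default_rng(k.seed)
    if k.noise_sigma > 0:
        z = z * np.exp(rng.normal(0.0, k.noise_sigma, size=z.shape))

    labels = list(range(1, n + 1))
    for lbl in f.opens:
        i = lbl - 1
        z[i, i] = rng.uniform(40.0, 80.0)
    for lbl in f.shorts_to_ground:
        i = lbl - 1
        z[i, i] = rng.uniform(0.05, 0.3)
    for a, b in f.partial_short_pairs:
        i, j = a - 1, b - 1
        level = 0.95 * min(z[i, i], z[j, j])
        z[i, j] = z[j, i] = level
    if f.airpocket:
        row = z[0].copy()
        row[1:] *= 10.0
        z[0] = np.where(np.arange(n) == 0, z[0], row)

    info = {
        "array_family": g.family.value,
        "fold_at": g.fold_at,
        "simulated": True,
    }
    if meta:
        info.update(meta)
    return EFIMatrix(values=z, labels=tuple(labels), meta=info)


@dataclass(frozen=True)
class BenchmarkCase:
    """One benchmark matrix with its ground truth."""

    case_id: str
    matrix: EFIMatrix
    family: ArrayFamily
    fold_at: int | None  # None = normal insertion

    @property
    def is_tfo(self) -> bool:
        return self.fold_at is not None


def generate_benchmark(
    n_normal: int,
    n_tfo: int,
    family_mix: float = 0.5,
    noise_sigma: float = 0.03,
    seed: int = 0,
    fold_range: Iterable[int] = FOLD_RANGE,
) -> list[BenchmarkCase]:
    """Seeded benchmark of normal and folded simulated measurements.

    Folds are drawn uniformly over ``fold_range`` (default contacts 2..8),
    families per ``family_mix`` (fraction pre-curved).  Each matrix gets
    its own sub-seed ``seed + index`` so the set is reproducible and could
    be generated in parallel.
    """
    if n_normal < 0 or n_tfo < 0:
        raise ValueError("counts must be >= 0")
    fold_choices = list(fold_range)
    rng = np.random.default_rng(seed)
    cases: list[BenchmarkCase] = []
    specs: list[int | None] = [None] * n_normal + [
        int(rng.choice(fold_choices)) for _ in range(n_tfo)
    ]
    families = [
        ArrayFamily.PRE_CURVED
        if rng.random() < family_mix
        else ArrayFamily.STRAIGHT_LATERAL_WALL
        for _ in specs
    ]
    for idx, (fold, family) in enumerate(zip(specs, families)):
        sub_seed = seed + idx
        geom = make_geometry(family, fold_at=fold)
        kern = ImpedanceKernel(noise_sigma=noise_sigma, seed=sub_seed)
        m = simulate_efi(geom, kern, meta={"source_id": f"case{idx:04d}"})
        cases.append(
            BenchmarkCase(
                case_id=f"case{idx:04d}", matrix=m, family=family, fold_at=fold
            )
        )
    return cases
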