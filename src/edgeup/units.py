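"""Construction of the polyhedral edge-unit library.

The local geometry of a small structure's surface is modelled as the face,
edge, or vertex of a polyhedron: the intersection of one, two, or three
half-spaces, rasterized as a binary pattern on a supersampled 6x6x6 voxel
grid.  Each high-resolution pattern is paired with its 3x3x3 block-mean
downsampled version, which is what gets fitted to image neighborhoods; the
high-resolution pattern supplies the 2x2x2 substitution block that doubles
the output resolution.

One-plane units are enumerated by sweeping planes through the 6x6x6 cube
over a configurable set of orientations and a dense offset grid; two- and
three-plane units are elementwise products (set intersections) of those.
Near-constant products -- slivers at the very periphery of the cube, which
carry almost no edge signal -- are removed by a spread cutoff on the binary
pattern (standard deviation >= ``sd_cutoff``).  Patterns are deduplicated up
to complement: an affine fit with a sign-free scale cannot distinguish a
pattern from its complement, so only one canonical representative is kept.
"""

from __future__ import annotations

import json
import base64
import dataclasses
from typing import Iterator, Sequence

import numpy as np
import h5py

__all__ = [
    "GenerationConfig",
    "HighResUnit",
    "LowResUnit",
    "UnitLibrary",
    "LibraryError",
    "LibraryIOError",
    "enumerate_one_plane_units",
    "product_unit",
    "population_variance",
    "downsample_unit",
    "build_library",
    "save_library",
    "load_library",
]

FORMAT_VERSION = 1

#: edge length of the supersampled unit cube, in high-resolution voxels
UNIT_SIZE = 6
N_VOXELS = UNIT_SIZE ** 3

# voxel-center coordinates of the 6x6x6 unit cube, centered on the origin,
# in high-resolution voxel units
_ax = np.arange(UNIT_SIZE) - (UNIT_SIZE - 1) / 2.0
_gx, _gy, _gz = np.meshgrid(_ax, _ax, _ax, indexing="ij")
VOXEL_CENTERS = np.stack([_gx, _gy, _gz], axis=-1).reshape(-1, 3)


class LibraryError(ValueError):
    """Invalid library configuration or empty generation result."""


class LibraryIOError(OSError):
    """Corrupt, truncated, or version-incompatible library file."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_AXIS_DIRS = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
_FACE_DIAG_DIRS = [
    (1, 1, 0), (1, 0, 1), (0, 1, 1),
    (1, -1, 0), (1, 0, -1), (0, 1, -1),
]
_BODY_DIAG_DIRS = [(1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1)]


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    theta = 2 * np.pi * i / golden
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def plane_normals(angular_density: int) -> np.ndarray:
    """Signed plane normals for a given angular density tier.

    The tiers are nested (every density includes all directions of the
    densities below it), so the set of enumerable patterns grows
    monotonically with ``angular_density``:

    * 0 -- the 3 coordinate axes (6 signed directions),
    * 1 -- + the 6 face diagonals (18 signed),
    * 2 -- + the 4 body diagonals (26 signed),
    * d >= 3 -- + ``8 * 2**(d-3)`` Fibonacci-sphere points.
    """
    if angular_density < 0:
        raise LibraryError(f"angular_density must be >= 0, got {angular_density}")
    vecs: list[np.ndarray] = []
    tiers: list[Sequence] = [_AXIS_DIRS]
    if angular_density >= 1:
        tiers.append(_FACE_DIAG_DIRS)
    if angular_density >= 2:
        tiers.append(_BODY_DIAG_DIRS)
    for tier in tiers:
        for v in tier:
            v = np.asarray(v, dtype=float)
            v = v / np.linalg.norm(v)
            vecs.append(v)
            vecs.append(-v)
    for d in range(3, angular_density + 1):
        for v in _fibonacci_sphere(8 * 2 ** (d - 3)):
            vecs.append(v)
    return np.array(vecs)


@dataclasses.dataclass(frozen=True)
class GenerationConfig:
    """Sampling and filtering parameters for library construction.

    Parameters
    ----------
    angular_density:
        Direction tier for plane normals (see :func:`plane_normals`).
        0 enumerates axis-aligned geometry only; 1 (the tool default for
        anatomical volumes) adds the face diagonals.
    offset_step_vox:
        Spacing of the signed plane offsets, in high-resolution voxels.
        The default 0.5 equals a quarter of a low-resolution voxel and
        resolves every half-voxel plane position representable on the
        output grid.
    sd_cutoff:
        Minimum standard deviation of a 2-/3-plane binary pattern.  Units
        below the cutoff are slivers at the very periphery of the cube and
        are excluded.  1-plane units are never filtered.
    max_planes:
        Maximum number of intersecting half-spaces per unit (1..3).
    """

    angular_density: int = 1
    offset_step_vox: float = 0.5
    sd_cutoff: float = 0.19
    max_planes: int = 3

    def __post_init__(self) -> None:
        if self.max_planes not in (1, 2, 3):
            raise LibraryError(f"max_planes must be 1, 2 or 3, got {self.max_planes}")
        if self.offset_step_vox <= 0:
            raise LibraryError("offset_step_vox must be positive")
        if not 0 <= self.sd_cutoff < 0.5:
            raise LibraryError("sd_cutoff must lie in [0, 0.5)")
        if self.angular_density < 0:
            raise LibraryError("angular_density must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "GenerationConfig":
        return cls(**json.loads(s))


# --------------------------------------------------------------------------
# unit-level types and operations
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class HighResUnit:
    """A binary 6x6x6 edge pattern formed by 1-3 intersecting half-spaces.

    ``pattern`` holds 0/1 values; ``plane_params`` records the generating
    (unit normal, signed offset) pairs; ``complemented`` is True when the
    stored pattern is the complement of the generated intersection (the
    canonical representative under complement dedup).
    """

    pattern: np.ndarray
    n_planes: int
    plane_params: tuple[tuple[tuple[float, float, float], float], ...] = ()
    complemented: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.pattern)
        if p.shape != (UNIT_SIZE,) * 3:
            raise LibraryError(f"pattern must be {UNIT_SIZE}^3, got {p.shape}")
        if not np.isin(p, (0, 1)).all():
            raise LibraryError("pattern values must be exactly 0 or 1")
        if p.min() == p.max():
            raise LibraryError("constant pattern is not a valid unit")
        if self.n_planes not in (1, 2, 3):
            raise LibraryError(f"n_planes must be in 1..3, got {self.n_planes}")

    def key(self) -> bytes:
        """216-bit canonical ordering/dedup key (fixed axis order)."""
        return pattern_key(self.pattern)

    def __eq__(self, other: object) -> bool:  # pattern identity
        if not isinstance(other, HighResUnit):
            return NotImplemented
        return self.n_planes == other.n_planes and np.array_equal(
            self.pattern, other.pattern
        )


@dataclasses.dataclass(frozen=True)
class LowResUnit:
    """3x3x3 block-mean downsample of a :class:`HighResUnit` with fit stats.

    ``mean`` is <E> and ``centered_ssq`` is sum E*(E - <E>), the denominator
    of the closed-form scale coefficient.
    """

    values: np.ndarray
    mean: float
    centered_ssq: float
    parent: HighResUnit


def pattern_key(pattern: np.ndarray) -> bytes:
    """Pack a binary 6x6x6 pattern into its 27-byte ordering key."""
    return np.packbits(np.asarray(pattern, dtype=bool).reshape(-1)).tobytes()


def canonical_pattern_key(pattern: np.ndarray) -> tuple[bytes, bool]:
    """Dedup key up to complement.

    Returns ``(key, is_identity)`` where ``key`` is the smaller of the
    pattern's and its complement's bit keys and ``is_identity`` says whether
    the pattern itself (rather than its complement) is the canonical
    representative.
    """
    b = np.asarray(pattern, dtype=bool)
    k = pattern_key(b)
    kc = pattern_key(~b)
    return (k, True) if k <= kc else (kc, False)


def population_variance(u: HighResUnit | np.ndarray) -> float:
    """Population variance p*(1-p) of a binary pattern (divide by 216)."""
    p = u.pattern if isinstance(u, HighResUnit) else np.asarray(u)
    frac = float(np.count_nonzero(p)) / p.size
    return frac * (1.0 - frac)


def product_unit(a: HighResUnit, b: HighResUnit) -> HighResUnit | None:
    """Elementwise product (intersection) of two units.

    Returns None when the product is constant (the half-spaces do not carve
    a pattern out of the cube), which callers must drop.
    """
    prod = np.asarray(a.pattern, dtype=bool) & np.asarray(b.pattern, dtype=bool)
    if prod.all() or not prod.any():
        return None
    return HighResUnit(
        pattern=prod.astype(np.uint8),
        n_planes=a.n_planes + b.n_planes,
        plane_params=a.plane_params + b.plane_params,
    )


def downsample_unit(u: HighResUnit) -> LowResUnit:
    """Non-overlapping 2x2x2 block means of the high-resolution pattern."""
    vals = block_mean(np.asarray(u.pattern, dtype=np.float64))
    mean = float(vals.mean())
    centered_ssq = float((vals * (vals - mean)).sum())
    return LowResUnit(values=vals, mean=mean, centered_ssq=centered_ssq, parent=u)


def block_mean(arr: np.ndarray) -> np.ndarray:
    """2x2x2 block-mean downsampling of an even-dimensioned 3D array."""
    n = np.asarray(arr.shape)
    if np.any(n % 2):
        raise ValueError(f"block_mean needs even dims, got {arr.shape}")
    m = n // 2
    return arr.reshape(m[0], 2, m[1], 2, m[2], 2).mean(axis=(1, 3, 5))


def enumerate_one_plane_units(
    config: GenerationConfig | None = None, *, canonicalize: bool = False
) -> list[HighResUnit]:
    """All unique half-space binarizations of the 6x6x6 cube.

    A voxel is 1 iff its center lies in the closed half-space
    ``normal . x <= offset`` -- by the central symmetry of a cubic voxel
    this is exactly the ">= half the voxel covered" rule.  Constant
    patterns (planes missing the cube) are dropped; duplicates are removed.
    With ``canonicalize=True`` patterns are additionally deduplicated up to
    complement, as in the final library.
    """
    config = config or GenerationConfig()
    normals = plane_normals(config.angular_density)
    if normals.size == 0:
        raise LibraryError("empty plane sampling specification")
    half_diag = (UNIT_SIZE / 2.0) * np.sqrt(3.0)
    offsets = np.arange(-half_diag, half_diag + 1e-12, config.offset_step_vox)
    dots = VOXEL_CENTERS @ normals.T  # (216, D)

    out: dict[bytes, HighResUnit] = {}
    for j in range(normals.shape[0]):
        normal = tuple(float(x) for x in normals[j])
        col = dots[:, j]
        for off in offsets:
            pat = col <= off
            s = int(pat.sum())
            if s == 0 or s == N_VOXELS:
                continue
            if canonicalize:
                key, identity = canonical_pattern_key(pat)
                stored = pat if identity else ~pat
            else:
                key, identity, stored = pattern_key(pat), True, pat
            if key not in out:
                out[key] = HighResUnit(
                    pattern=stored.reshape((UNIT_SIZE,) * 3).astype(np.uint8),
                    n_planes=1,
                    plane_params=((normal, float(off)),),
                    complemented=not identity,
                )
    return list(out.values())


# --------------------------------------------------------------------------
# library container
# --------------------------------------------------------------------------


class UnitLibrary:
    """Ordered, deduplicated collection of edge units with cached fit stats.

    The canonical storage is array-based: ``patterns`` (U, 6, 6, 6) uint8,
    ``n_planes`` (U,), ``low`` (U, 27) float64 block means, plus the cached
    per-unit ``mean`` and ``centered_ssq``.  Units are ordered by
    (n_planes, 216-bit pattern key), which fixes the tie-break indices used
    during fitting.  ``lib[i]`` materializes the (HighResUnit, LowResUnit)
    pair for unit i.
    """

    def __init__(
        self,
        patterns: np.ndarray,
        n_planes: np.ndarray,
        config: GenerationConfig,
    ) -> None:
        patterns = np.asarray(patterns, dtype=np.uint8)
        if patterns.ndim != 4 or patterns.shape[1:] != (UNIT_SIZE,) * 3:
            raise LibraryError(f"patterns must be (U, 6, 6, 6), got {patterns.shape}")
        if len(patterns) == 0:
            raise LibraryError("library is empty")
        self.patterns = patterns
        self.n_planes = np.asarray(n_planes, dtype=np.int8)
        self.config = config
        self.low = (
            patterns.astype(np.float64)
            .reshape(-1, 3, 2, 3, 2, 3, 2)
            .mean(axis=(2, 4, 6))
            .reshape(len(patterns), 27)
        )
        self.mean = self.low.mean(axis=1)
        centered = self.low - self.mean[:, None]
        self.centered_ssq = np.einsum("ij,ij->i", centered, self.low)
        # whitened centered regressors for the matched-filter fast path
        self._whitened = centered / np.sqrt(self.centered_ssq)[:, None]
        self._whitened32 = self._whitened.astype(np.float32)
        # central 2x2x2 substitution blocks, flattened in (x, y, z) order
        c0 = UNIT_SIZE // 2 - 1
        self.centers = (
            patterns[:, c0 : c0 + 2, c0 : c0 + 2, c0 : c0 + 2]
            .reshape(len(patterns), 8)
            .astype(np.float64)
        )

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.patterns)

    def __getitem__(self, i: int) -> tuple[HighResUnit, LowResUnit]:
        hi = HighResUnit(pattern=self.patterns[i], n_planes=int(self.n_planes[i]))
        lo = LowResUnit(
            values=self.low[i].reshape(3, 3, 3),
            mean=float(self.mean[i]),
            centered_ssq=float(self.centered_ssq[i]),
            parent=hi,
        )
        return hi, lo

    def __iter__(self) -> Iterator[tuple[HighResUnit, LowResUnit]]:
        return (self[i] for i in range(len(self)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UnitLibrary):
            return NotImplemented
        return (
            self.config == other.config
            and np.array_equal(self.patterns, other.patterns)
            and np.array_equal(self.n_planes, other.n_planes)
        )

    @property
    def counts_by_nplanes(self) -> dict[int, int]:
        return {n: int(np.count_nonzero(self.n_planes == n)) for n in (1, 2, 3)}

    @property
    def whitened32(self) -> np.ndarray:
        return self._whitened32

    @property
    def whitened(self) -> np.ndarray:
        return self._whitened


def _sd_bounds(sd_cutoff: float) -> tuple[int, int]:
    # pattern SD >= cutoff  <=>  p(1-p) >= cutoff^2  <=>  ones count in [lo, hi]
    var = sd_cutoff**2
    lo = int(np.ceil(N_VOXELS * 0.5 * (1.0 - np.sqrt(1.0 - 4.0 * var))))
    return lo, N_VOXELS - lo


def build_library(config: GenerationConfig | None = None) -> UnitLibrary:
    """Enumerate -> products -> spread filter -> dedup -> order.

    One-plane units are enumerated over the configured plane sampling; two-
    plane units are all pairwise products of (signed) one-plane patterns;
    three-plane units are products of one-plane patterns with retained
    two-plane units.  The SD cutoff is applied to 2- and 3-plane units only.
    Everything is deduplicated up to complement and ordered by
    (n_planes, pattern key).
    """
    config = config or GenerationConfig()
    ones = enumerate_one_plane_units(config)  # signed factor set
    factors = np.array(
        [np.asarray(u.pattern, dtype=bool).reshape(-1) for u in ones]
    )
    lo, hi = _sd_bounds(config.sd_cutoff)

    registry: dict[bytes, tuple[np.ndarray, int]] = {}
    for pat in factors:
        key, identity = canonical_pattern_key(pat)
        if key not in registry:
            registry[key] = (pat if identity else ~pat, 1)

    def _absorb(products: np.ndarray, n_planes: int, store: list | None) -> None:
        counts = products.sum(axis=1)
        ok = (counts >= lo) & (counts <= hi)
        for pat in products[ok]:
            key, identity = canonical_pattern_key(pat)
            if key not in registry:
                registry[key] = (pat if identity else ~pat, n_planes)
                if store is not None:
                    store.append(pat)

    two_plane: list[np.ndarray] = []
    if config.max_planes >= 2:
        for i in range(len(factors)):
            _absorb(factors[i] & factors[i + 1 :], 2, two_plane)
    if config.max_planes >= 3 and two_plane:
        two_arr = np.array(two_plane)
        for i in range(len(factors)):
            _absorb(factors[i] & two_arr, 3, None)

    if not registry:
        raise LibraryError("library generation produced no units")
    items = sorted(registry.items(), key=lambda kv: (kv[1][1], kv[0]))
    patterns = np.array([pat for _, (pat, _) in items], dtype=np.uint8).reshape(
        -1, UNIT_SIZE, UNIT_SIZE, UNIT_SIZE
    )
    n_planes = np.array([n for _, (_, n) in items], dtype=np.int8)
    return UnitLibrary(patterns, n_planes, config)


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------


def save_library(lib: UnitLibrary, path: str) -> None:
    """Persist a library (HDF5 by default, JSON when path ends in .json)."""
    if str(path).endswith(".json"):
        _save_json(lib, path)
        return
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["generation_config"] = lib.config.to_json()
        packed = np.packbits(lib.patterns.reshape(len(lib), -1), axis=1)
        f.create_dataset("patterns_packed", data=packed)
        f.create_dataset("n_planes", data=lib.n_planes)
        f.create_dataset("low", data=lib.low)
        f.create_dataset("mean", data=lib.mean)
        f.create_dataset("centered_ssq", data=lib.centered_ssq)


def load_library(path: str) -> UnitLibrary:
    if str(path).endswith(".json"):
        return _load_json(path)
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != FORMAT_VERSION:
                raise LibraryIOError(
                    f"library format version {version} unsupported "
                    f"(expected {FORMAT_VERSION}): {path}"
                )
            config = GenerationConfig.from_json(f.attrs["generation_config"])
            packed = f["patterns_packed"][...]
            n_planes = f["n_planes"][...]
            low = f["low"][...]
            mean = f["mean"][...]
            cssq = f["centered_ssq"][...]
    except OSError as exc:
        raise LibraryIOError(f"cannot read library file {path}: {exc}") from exc
    patterns = (
        np.unpackbits(packed, axis=1, count=N_VOXELS)
        .reshape(-1, UNIT_SIZE, UNIT_SIZE, UNIT_SIZE)
        .astype(np.uint8)
    )
    lib = UnitLibrary(patterns, n_planes, config)
    if not (
        np.array_equal(lib.low, low)
        and np.array_equal(lib.mean, mean)
        and np.array_equal(lib.centered_ssq, cssq)
    ):
        raise LibraryIOError(f"cached statistics inconsistent in {path}")
    return lib


def _save_json(lib: UnitLibrary, path: str) -> None:
    packed = np.packbits(lib.patterns.reshape(len(lib), -1), axis=1)
    doc = {
        "format_version": FORMAT_VERSION,
        "generation_config": json.loads(lib.config.to_json()),
        "patterns_packed_b64": base64.b64encode(packed.tobytes()).decode("ascii"),
        "n_planes": lib.n_planes.tolist(),
        "low": lib.low.tolist(),
        "mean": lib.mean.tolist(),
        "centered_ssq": lib.centered_ssq.tolist(),
    }
    with open(path, "w") as f:
        json.dump(doc, f)


def _load_json(path: str) -> UnitLibrary:
    try:
        with open(path) as f:
            doc = json.load(f)
    except (OSError, json.JSONDecodeError) as exc:
        raise LibraryIOError(f"cannot read library file {path}: {exc}") from exc
    if doc.get("format_version") != FORMAT_VERSION:
        raise LibraryIOError(
            f"library format version {doc.get('format_version')} unsupported"
        )
    config = GenerationConfig(**doc["generation_config"])
    n = len(doc["n_planes"])
    packed = np.frombuffer(
        base64.b64decode(doc["patterns_packed_b64"]), dtype=np.uint8
    ).reshape(n, -1)
    patterns = (
        np.unpackbits(packed, axis=1, count=N_VOXELS)
        .reshape(-1, UNIT_SIZE, UNIT_SIZE, UNIT_SIZE)
        .astype(np.uint8)
    )
    lib = UnitLibrary(patterns, np.array(doc["n_planes"]), config)
    if not (
        np.array_equal(lib.low, np.array(doc["low"]))
        and np.array_equal(lib.centered_ssq, np.array(doc["centered_ssq"]))
    ):
        raise LibraryIOError(f"cached statistics inconsistent in {path}")
    return lib
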