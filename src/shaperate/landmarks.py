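"""TPS landmark I/O, generalized Procrustes analysis, species mean shapes.

Landmark configurations are k x 2 matrices (two-dimensional digitizing).
GPA is full Procrustes: translation to the centroid, scaling to unit centroid
size, and least-squares rotation (determinant +1 only — a reflection in
consistently-lateral digitizing indicates a data error, so it is never
"corrected" silently).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "ProcrustesResult",
    "ShapeMatrix",
    "read_tps",
    "write_tps",
    "centroid_size",
    "align_gpa",
    "species_means",
    "subset_landmarks",
    "procrustes_distance",
]


class TPSError(ValueError):
    """Malformed TPS input."""


@dataclass
class LandmarkConfiguration:
    """One specimen's raw landmark coordinates.

    ``coords`` is a k x 2 array in digitizer units (already multiplied by the
    TPS SCALE factor when one was present on read).
    """

    specimen_id: str
    coords: np.ndarray
    species_id: str | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be a k x 2 matrix")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinate")
        self.coords = coords

    @property
    def k(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# TPS dialect
# ---------------------------------------------------------------------------

def read_tps(source) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations.

    Accepts a path or an open text stream. Recognized records: ``LM=``,
    coordinate lines, ``ID=``, ``IMAGE=``, ``SCALE=``. Coordinates are
    multiplied by SCALE when present. ``ID`` becomes ``specimen_id``; the
    IMAGE basename (extension stripped) is the fallback.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r") as fh:
            lines = fh.read().splitlines()
    else:
        lines = source.read().splitlines()

    configs: list[LandmarkConfiguration] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.upper().startswith("LM="):
            raise TPSError(f"expected LM= record, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSError(f"bad LM count in {line!r}") from exc
        coords = np.empty((k, 2))
        for j in range(k):
            if i >= n_lines:
                raise TPSError(f"LM={k} but only {j} coordinate lines")
            parts = lines[i].strip().split()
            i += 1
            if len(parts) != 2:
                raise TPSError(f"expected 2 coordinates, got {lines[i - 1]!r}")
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TPSError(f"non-numeric coordinate in {lines[i - 1]!r}") from exc
        spec_id: str | None = None
        image: str | None = None
        scale: float | None = None
        while i < n_lines:
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
            elif upper.startswith("IMAGE="):
                image = line.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                try:
                    scale = float(line.split("=", 1)[1])
                except ValueError as exc:
                    raise TPSError(f"bad SCALE in {line!r}") from exc
            else:
                raise TPSError(f"unexpected line between records: {line!r}")
            i += 1
        if spec_id is None:
            if image is not None:
                spec_id = os.path.splitext(os.path.basename(image))[0]
            else:
                spec_id = f"specimen_{len(configs)}"
        if scale is not None:
            coords = coords * scale
        configs.append(LandmarkConfiguration(spec_id, coords, scale=scale))
    if not configs:
        raise TPSError("empty TPS file")
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise TPSError(f"inconsistent landmark counts across file: {sorted(ks)}")
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration], target) -> None:
    """Write configurations in this package's own TPS dialect.

    Coordinates are written in final units (SCALE already applied on read) and
    no SCALE record is emitted, so ``read_tps(write_tps(...))`` round-trips
    coordinates bit-exactly.
    """
    own = not hasattr(target, "write")
    fh = open(target, "w") if own else target
    try:
        for c in configs:
            fh.write(f"LM={c.k}\n")
            for x, y in c.coords:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={c.specimen_id}\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Procrustes machinery
# ---------------------------------------------------------------------------

def centroid_size(config) -> float:
    """Square root of the summed squared landmark distances to the centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 landmarks")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _preshape(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    return centered / np.sqrt((centered**2).sum())


def _optimal_rotations(shapes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Batched 2-D Kabsch rotations (det +1) aligning each shape to target."""
    H = np.einsum("nki,kj->nij", shapes, target)  # n x 2 x 2 cross-products
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(U @ Vt)
    D = np.repeat(np.eye(2)[None], len(shapes), axis=0)
    D[:, 1, 1] = np.sign(det)
    R = U @ D @ Vt
    return np.einsum("nki,nij->nkj", shapes, R)


@dataclass
class ProcrustesResult:
    """Output of generalized Procrustes analysis.

    ``aligned`` holds one row per specimen, flattened as
    (lm1_x, lm1_y, lm2_x, lm2_y, ...). Every aligned configuration has its
    centroid at the origin and centroid size 1.
    """

    specimen_ids: tuple[str, ...]
    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.k = self.consensus.shape[0]

    def aligned_configs(self) -> np.ndarray:
        """Aligned coordinates as an n x k x 2 array."""
        return self.aligned.reshape(len(self.specimen_ids), self.k, 2)


def align_gpa(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-8,
    max_iter: int = 100,
    tangent: bool = False,
) -> ProcrustesResult:
    """Generalized Procrustes analysis over all configurations jointly.

    Full Procrustes: every configuration is centered, scaled to unit centroid
    size, and rotated (rotations only, no reflections) to the running
    consensus; the consensus is the renormalized mean and iteration stops when
    its root-summed-squared change drops below ``tol``. The final consensus is
    rotated to its principal axes so output orientation is reproducible.

    With ``tangent=True`` aligned rows are orthogonally projected onto the
    tangent space at the consensus.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations")
    ks = {c.k for c in configs}
    if len(ks) != 1:
        raise ValueError(f"inconsistent landmark counts: {sorted(ks)}")
    sizes = np.array([centroid_size(c) for c in configs])  # raises on degenerate
    shapes = np.stack([_preshape(c.coords) for c in configs])

    consensus = shapes[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        shapes = _optimal_rotations(shapes, consensus)
        new = shapes.mean(axis=0)
        new = new - new.mean(axis=0)
        new /= np.sqrt((new**2).sum())
        change = np.sqrt(((new - consensus) ** 2).sum())
        consensus = new
        if change < tol:
            converged = True
            break

    # principal-axis orientation: rotate so the consensus' major axis is x,
    # with a deterministic sign convention (largest-|coordinate| positive).
    cov = consensus.T @ consensus
    eigval, eigvec = np.linalg.eigh(cov)
    R = eigvec[:, ::-1]  # descending variance
    if np.linalg.det(R) < 0:
        R[:, 1] = -R[:, 1]
    rotated = consensus @ R
    for axis in range(2):
        col = rotated[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            rotated[:, axis] = -col
            R[:, axis] = -R[:, axis]
    if np.linalg.det(R) < 0:  # flipped one axis only: restore orientation
        # flipping both columns keeps det +1 and the convention on axis 0
        R[:, 1] = -R[:, 1]
        rotated[:, 1] = -rotated[:, 1]
    shapes = _optimal_rotations(shapes, rotated)
    # the returned consensus is the plain arithmetic mean of the aligned
    # configurations (centered but NOT renormalized), so the mean-consensus
    # identity is exact; the unit-norm version only steers the iteration.
    consensus = shapes.mean(axis=0)

    aligned = shapes.reshape(len(configs), -1)
    if tangent:
        c = consensus.ravel()
        c = c / np.linalg.norm(c)
        aligned = aligned - np.outer(aligned @ c - 1.0, c)
        consensus = aligned.mean(axis=0).reshape(-1, 2)
    return ProcrustesResult(
        specimen_ids=tuple(c.specimen_id for c in configs),
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
    )


@dataclass(frozen=True)
class ShapeMatrix:
    """Per-species mean Procrustes coordinates, rows bound to ``taxa``."""

    taxa: tuple[str, ...]
    Y: np.ndarray

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != len(self.taxa):
            raise ValueError("Y must have one row per taxon")
        if len(self.taxa) < 2:
            raise ValueError("need at least 2 taxa")
        if Y.shape[1] % 2 != 0:
            raise ValueError("trait columns must come in x/y pairs")
        object.__setattr__(self, "Y", Y)

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    @property
    def k(self) -> int:
        return self.Y.shape[1] // 2

    def reorder(self, taxa: Sequence[str]) -> "ShapeMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return ShapeMatrix(tuple(taxa), self.Y[idx])

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = [f"lm{i}_{ax}" for i in range(1, self.k + 1) for ax in ("x", "y")]
        pd.DataFrame(self.Y, index=list(self.taxa), columns=cols).to_csv(
            path, index_label="taxon"
        )


def species_means(
    result: ProcrustesResult, species_map: Mapping[str, str]
) -> ShapeMatrix:
    """Arithmetic mean of each species' aligned configurations.

    Every specimen must be mapped; taxa are returned in sorted order.
    """
    unmapped = [s for s in result.specimen_ids if s not in species_map]
    if unmapped:
        raise KeyError(f"specimens without a species mapping: {unmapped[:5]}")
    taxa = tuple(sorted(set(species_map[s] for s in result.specimen_ids)))
    rows = np.empty((len(taxa), result.aligned.shape[1]))
    for r, taxon in enumerate(taxa):
        mask = np.array([species_map[s] == taxon for s in result.specimen_ids])
        rows[r] = result.aligned[mask].mean(axis=0)
    return ShapeMatrix(taxa, rows)


def subset_landmarks(Y: ShapeMatrix, indices: Iterable[int]) -> ShapeMatrix:
    """Restrict columns to the x/y pairs of the given 1-based landmark indices."""
    idx = sorted(set(int(i) for i in indices))
    if not idx:
        raise ValueError("empty landmark index set")
    if idx[0] < 1 or idx[-1] > Y.k:
        raise IndexError(f"landmark indices out of range 1..{Y.k}: {idx}")
    cols = [c for i in idx for c in (2 * (i - 1), 2 * (i - 1) + 1)]
    return ShapeMatrix(Y.taxa, Y.Y[:, cols])


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two k x 2 configurations."""
    pa, pb = _preshape(np.asarray(a, float)), _preshape(np.asarray(b, float))
    rotated = _optimal_rotations(pb[None], pa)[0]
    return float(np.sqrt(((pa - rotated) ** 2).sum()))
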