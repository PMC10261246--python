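"""Landmark-based geometric morphometrics: TPS I/O, GPA and shape PCA.

Specimens are k 2-D landmarks digitised from scaled photographs (15 fixed
anatomical points in the cichlid application). Generalised Procrustes
analysis removes position, size and orientation: each configuration is
centred, scaled to unit centroid size, and rotated (rotation only, no
reflection) to the iteratively re-estimated mean shape. PCA is then an
eigen-decomposition of the covariance matrix of the flattened Procrustes
coordinates. Tangent-space projection is available but off by default —
shape variation among close congeners is small enough that the curved and
tangent coordinates are nearly identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np


@dataclass
class LandmarkConfiguration:
    """One specimen's landmarks, in scaled units (image coords x scale)."""

    specimen_id: str
    landmarks: np.ndarray  # (k, 2)
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 2:
            raise ValueError("landmarks must be a (k, 2) array")
        if self.landmarks.shape[0] < 3:
            raise ValueError("need at least 3 landmarks")
        if not np.isfinite(self.landmarks).all():
            raise ValueError(f"non-finite landmark in {self.specimen_id!r}")
        if self.scale <= 0:
            raise ValueError("scale factor must be positive")


@dataclass
class AlignedShapes:
    """Output of GPA: Procrustes coordinates and alignment metadata."""

    specimen_ids: list[str]
    coords: np.ndarray  # (n, k, 2), centred, unit centroid size
    mean_shape: np.ndarray  # (k, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,), pre-alignment, scaled units
    iterations: int
    converged: bool


@dataclass
class ShapePCAResult:
    loadings: np.ndarray  # (2k, m) columns are components
    scores: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,), non-increasing
    percent_variance: np.ndarray  # (m,), sums to 100 over nonzero components


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared landmark distances from their centroid."""
    x = config.landmarks if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = x - x.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


# -- TPS file dialect --------------------------------------------------------

_KEY_RE = re.compile(r"^(LM|ID|IMAGE|SCALE)\s*=\s*(.*)$", re.IGNORECASE)


def read_tps(path: str) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file.

    Each record is ``LM=k`` followed by k ``x y`` coordinate lines and
    optional ``IMAGE=``, ``ID=`` and ``SCALE=`` lines. Coordinates are
    multiplied by the scale factor on load; a missing SCALE means 1.0.
    """
    configs: list[LandmarkConfiguration] = []
    record: dict | None = None

    def flush(rec: dict) -> None:
        k = rec["lm"]
        if len(rec["coords"]) != k:
            raise ValueError(
                f"TPS record {rec['id']!r}: LM={k} but "
                f"{len(rec['coords'])} coordinate lines"
            )
        pts = np.asarray(rec["coords"], dtype=float) * rec["scale"]
        configs.append(LandmarkConfiguration(rec["id"], pts, rec["scale"]))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            m = _KEY_RE.match(line)
            if m:
                key, value = m.group(1).upper(), m.group(2).strip()
                if key == "LM":
                    if record is not None:
                        flush(record)
                    record = {
                        "lm": int(value),
                        "coords": [],
                        "scale": 1.0,
                        "id": f"specimen_{len(configs)}",
                    }
                elif record is None:
                    raise ValueError(f"TPS line before any LM= record: {line!r}")
                elif key == "SCALE":
                    record["scale"] = float(value)
                elif key in ("ID", "IMAGE"):
                    record["id"] = value
            else:
                if record is None:
                    raise ValueError(f"TPS coordinates before LM= header: {line!r}")
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"malformed TPS coordinate line: {line!r}")
                record["coords"].append((float(parts[0]), float(parts[1])))
    if record is not None:
        flush(record)
    if not configs:
        raise ValueError(f"{path}: no TPS records found")
    return configs


def write_tps(configs: list[LandmarkConfiguration], path: str) -> None:
    """Write configurations in the TPS dialect read by :func:`read_tps`."""
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM={cfg.landmarks.shape[0]}\n")
            raw = cfg.landmarks / cfg.scale
            for x, y in raw:
                fh.write(f"{x:.12g} {y:.12g}\n")
            fh.write(f"IMAGE={cfg.specimen_id}\n")
            fh.write(f"ID={cfg.specimen_id}\n")
            fh.write(f"SCALE={cfg.scale:.12g}\n")


# -- generalised Procrustes analysis -----------------------------------------


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (det +1) minimising ||x R - target||."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def procrustes_align(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
    tangent_project: bool = False,
) -> AlignedShapes:
    """Iterative GPA: centre, scale to unit centroid size, rotate to the mean.

    The mean shape is recomputed and renormalised each pass; iteration stops
    when the summed squared change of the mean drops below ``tol`` (or after
    ``max_iter`` passes, flagged as unconverged). Reflections are never used.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = configs[0].landmarks.shape[0]
    ids = []
    sizes = []
    shapes = []
    for cfg in configs:
        if cfg.landmarks.shape[0] != k:
            raise ValueError(
                f"{cfg.specimen_id!r} has {cfg.landmarks.shape[0]} landmarks, expected {k}"
            )
        cs = centroid_size(cfg)
        if cs == 0.0:
            raise ValueError(f"degenerate configuration (zero centroid size): {cfg.specimen_id!r}")
        centred = cfg.landmarks - cfg.landmarks.mean(axis=0)
        shapes.append(centred / cs)
        sizes.append(cs)
        ids.append(cfg.specimen_id)
    x = np.stack(shapes)  # (n, k, 2)

    mean = x[0].copy()
    mean /= np.sqrt((mean**2).sum())
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(x)):
            x[i] = x[i] @ _optimal_rotation(x[i], mean)
        new_mean = x.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        if ((new_mean - mean) ** 2).sum() < tol:
            mean = new_mean
            converged = True
            break
        mean = new_mean
    # final rotation pass against the converged mean
    for i in range(len(x)):
        x[i] = x[i] @ _optimal_rotation(x[i], mean)

    # canonical orientation: principal axes of the mean shape, with the
    # largest-magnitude mean coordinate positive — makes the output invariant
    # to similarity transforms of any input and to input order
    _, _, vt = np.linalg.svd(mean, full_matrices=False)
    rot = vt.T
    if np.linalg.det(rot) < 0:
        rot[:, -1] *= -1.0
    mean = mean @ rot
    pivot = np.unravel_index(np.argmax(np.abs(mean)), mean.shape)
    if mean[pivot] < 0:
        rot = -rot  # 180-degree rotation in 2-D
        mean = -mean
    x = x @ rot

    if tangent_project:
        m = mean.ravel()
        flat = x.reshape(len(x), -1)
        proj = flat - np.outer(flat @ m - 1.0, m)
        x = proj.reshape(x.shape)

    return AlignedShapes(
        specimen_ids=ids,
        coords=x,
        mean_shape=mean,
        centroid_sizes=np.asarray(sizes),
        iterations=iterations,
        converged=converged,
    )


def shape_pca(aligned: AlignedShapes) -> ShapePCAResult:
    """PCA of the covariance matrix of flattened Procrustes coordinates.

    Component sign convention: each loading vector is oriented so that its
    largest-magnitude entry is positive, making scores reproducible across
    runs and input orders (up to that convention).
    """
    n = aligned.coords.shape[0]
    if n < 3:
        raise ValueError("shape PCA needs at least 3 specimens")
    flat = aligned.coords.reshape(n, -1)
    centred = flat - flat.mean(axis=0)
    cov = np.cov(centred, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for c in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[pivot, c] < 0:
            eigvec[:, c] *= -1.0
    scores = centred @ eigvec
    total = eigval.sum()
    pct = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    return ShapePCAResult(
        loadings=eigvec, scores=scores, eigenvalues=eigval, percent_variance=pct
    )
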