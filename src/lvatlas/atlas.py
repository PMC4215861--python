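"""PCA shape atlas: mean shape, orthonormal variation modes, projections.

Shape vectors (concatenated point coordinates in mm, one frame or the ED&ES
concatenation) from all cases are decomposed into principal components of the
sample covariance (divisor n-1).  Coordinates are commensurate and size is a
clinical signal, so the covariance of raw millimetre coordinates is used with
no per-variable standardization.  When the number of cases is smaller than
the vector dimension, the eigendecomposition is computed through the dual
(Gram-matrix) route, which is exact and far cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PCAAtlas:
    """Mean shape + orthonormal modes of a shape population.

    ``modes`` stores at least the retained modes (columns, descending
    eigenvalue); ``eigenvalues`` and ``variance_fractions`` cover every
    nonzero mode so variance bookkeeping is complete regardless of storage.
    """

    mean: np.ndarray               # (d,)
    modes: np.ndarray              # (d, n_stored)
    eigenvalues: np.ndarray        # (n_nonzero,), mm^2, descending
    variance_fractions: np.ndarray
    n_retained: int
    variance_threshold: float
    frame: str = "ED"              # "ED", "ES" or "ED&ES"

    @property
    def n_dim(self) -> int:
        return self.mean.shape[0]

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fractions)

    def scree_table(self) -> pd.DataFrame:
        """Per-mode eigenvalue / variance-fraction / cumulative table."""
        k = np.arange(1, len(self.eigenvalues) + 1)
        return pd.DataFrame({
            "mode": k,
            "eigenvalue_mm2": self.eigenvalues,
            "variance_fraction": self.variance_fractions,
            "cumulative_fraction": self.cumulative_variance,
            "retained": k <= self.n_retained,
        })


def _fix_mode_signs(modes: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude entry of each
    mode is made positive (mode signs are statistically arbitrary)."""
    idx = np.argmax(np.abs(modes), axis=0)
    signs = np.sign(modes[idx, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    return modes * signs


def build_pca(shape_vectors: np.ndarray, variance_threshold: float = 0.90,
              frame: str = "ED", store_modes: str | int = "all") -> PCAAtlas:
    """Fit the PCA atlas to an (n_cases, d) shape-vector matrix.

    ``store_modes``: "all" keeps every nonzero mode (fine for small problems),
    "retained" keeps only the modes needed to reach the variance threshold
    (memory-friendly for cohort-scale atlases), an int keeps that many.
    """
    x = np.asarray(shape_vectors, dtype=float)
    if x.ndim != 2:
        raise ValueError("shape_vectors must be a 2-D (n_cases, d) matrix")
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least 2 cases")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    mean = x.mean(axis=0)
    xc = x - mean

    if d <= n:
        # direct economy SVD of the centered data
        u, sv, vt = np.linalg.svd(xc, full_matrices=False)
        eigvals = sv ** 2 / (n - 1)
        basis = vt.T                                  # (d, r)
    else:
        # dual route: eigendecomposition of the (n, n) Gram matrix
        gram = xc @ xc.T
        w, u = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1]
        w = w[order]
        u = u[:, order]
        eigvals = np.clip(w, 0.0, None) / (n - 1)
        sv = np.sqrt(np.clip(w, 0.0, None))
        basis = None                                  # built lazily below

    total = float(eigvals.sum())
    if total <= 0.0:
        raise ValueError("zero total variance: all shape vectors are identical")
    tol = max(n, d) * np.finfo(float).eps * (eigvals[0] if eigvals[0] > 0 else 1.0)
    nonzero = eigvals > tol
    eigvals = eigvals[nonzero]
    fractions = eigvals / total
    # tiny slack so an exactly-attained threshold is not missed to rounding
    n_retained = int(np.searchsorted(np.cumsum(fractions),
                                     variance_threshold - 1e-12) + 1)
    n_retained = min(n_retained, len(eigvals))

    if store_modes == "all":
        n_store = len(eigvals)
    elif store_modes == "retained":
        n_store = n_retained
    else:
        n_store = min(int(store_modes), len(eigvals))
        n_store = max(n_store, n_retained)
    if basis is not None:
        modes = basis[:, nonzero][:, :n_store]
    else:
        keep = np.flatnonzero(nonzero)[:n_store]
        modes = xc.T @ (u[:, keep] / sv[keep])
    modes = _fix_mode_signs(np.ascontiguousarray(modes))
    return PCAAtlas(mean=mean, modes=modes, eigenvalues=eigvals,
                    variance_fractions=fractions, n_retained=n_retained,
                    variance_threshold=variance_threshold, frame=frame)


def concatenate_frames(ed: np.ndarray, es: np.ndarray) -> np.ndarray:
    """ED-then-ES concatenation of shape vectors (vectors or matrices)."""
    ed = np.asarray(ed, dtype=float)
    es = np.asarray(es, dtype=float)
    if ed.shape != es.shape:
        raise ValueError(f"frame shape mismatch: {ed.shape} vs {es.shape}")
    return np.concatenate([ed, es], axis=-1)


def split_frames(combined: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`concatenate_frames`."""
    combined = np.asarray(combined)
    d = combined.shape[-1]
    if d % 2:
        raise ValueError("combined vector length must be even")
    return combined[..., : d // 2], combined[..., d // 2:]


def project(atlas: PCAAtlas, shape_vectors: np.ndarray,
            n_modes: int | None = None) -> np.ndarray:
    """Mode scores of one or many shape vectors over the retained modes
    (or ``n_modes`` of the stored modes)."""
    x = np.asarray(shape_vectors, dtype=float)
    if x.shape[-1] != atlas.n_dim:
        raise ValueError(f"dimension mismatch: {x.shape[-1]} vs atlas {atlas.n_dim}")
    m = atlas.n_retained if n_modes is None else n_modes
    if m > atlas.modes.shape[1]:
        raise ValueError(f"{m} modes requested but only {atlas.modes.shape[1]} stored")
    return (x - atlas.mean) @ atlas.modes[:, :m]


def reconstruct(atlas: PCAAtlas, scores: np.ndarray) -> np.ndarray:
    """Shape vector(s) from mode scores: mean + modes @ scores."""
    scores = np.asarray(scores, dtype=float)
    m = scores.shape[-1]
    if m > atlas.modes.shape[1]:
        raise ValueError(f"{m} scores given but only {atlas.modes.shape[1]} modes stored")
    return atlas.mean + scores @ atlas.modes[:, :m].T


def mode_extreme_shape(atlas: PCAAtlas, k: int, c: float) -> np.ndarray:
    """Mean shape displaced ``c`` standard deviations along mode ``k``
    (1-based), i.e. mean + c sqrt(lambda_k) phi_k; the standard way of
    visualizing and interpreting what a mode encodes."""
    if not 1 <= k <= atlas.modes.shape[1]:
        raise ValueError(f"mode index {k} out of range 1..{atlas.modes.shape[1]}")
    return atlas.mean + c * np.sqrt(atlas.eigenvalues[k - 1]) * atlas.modes[:, k - 1]


def mode_scores_table(atlas: PCAAtlas, shape_vectors: np.ndarray,
                      prefix: str = "mode") -> pd.DataFrame:
    """Retained-mode scores as a DataFrame with columns mode1..modeM."""
    scores = project(atlas, shape_vectors)
    cols = [f"{prefix}{i}" for i in range(1, scores.shape[1] + 1)]
    return pd.DataFrame(scores, columns=cols)


def interpret_modes(scores: pd.DataFrame | np.ndarray,
                    latents: pd.DataFrame) -> pd.DataFrame:
    """Absolute Pearson correlation between each mode's scores and each
    generator latent factor, with the dominant factor flagged per mode.

    Only meaningful for synthetic cohorts whose latent parameters are known.
    """
    if latents is None or len(latents) == 0:
        raise ValueError("latent parameters are required to interpret modes")
    scores = pd.DataFrame(scores)
    if len(scores) != len(latents):
        raise ValueError("scores and latents must cover the same cases")
    lat = latents.reset_index(drop=True)
    sc = scores.reset_index(drop=True)
    corr = np.zeros((sc.shape[1], lat.shape[1]))
    for j, col in enumerate(lat.columns):
        lv = lat[col].to_numpy(dtype=float)
        lv = lv - lv.mean()
        denom_l = np.sqrt(np.sum(lv ** 2))
        for i, mcol in enumerate(sc.columns):
            mv = sc[mcol].to_numpy(dtype=float)
            mv = mv - mv.mean()
            denom = denom_l * np.sqrt(np.sum(mv ** 2))
            corr[i, j] = np.abs(np.sum(mv * lv) / denom) if denom > 0 else 0.0
    table = pd.DataFrame(corr, columns=list(lat.columns),
                         index=[f"mode{i}" for i in range(1, sc.shape[1] + 1)])
    table["top_factor"] = table.idxmax(axis=1)
    return table
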