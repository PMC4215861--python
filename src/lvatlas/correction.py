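"""Acquisition-protocol bias correction for shape models.

Different MR protocols (e.g. gradient-recalled echo vs steady-state free
precession) place the myocardial surfaces systematically differently.  Given
paired scans of the same subjects under both protocols, a linear map from the
biased protocol to the reference protocol is estimated and applied to every
biased-protocol shape, making the two cohorts directly comparable.

The map is deliberately simple and fully testable: a per-point offset vector
plus a per-axis gain shared across points, estimated by (optionally ridge-
regularized) least squares on aligned, corresponded pairs.  The gain acts on
coordinates centered at the training source mean, so the offset estimate is
decoupled from the gain estimate (the offset is then simply the mean paired
displacement, with standard error noise_sd / sqrt(n_pairs) per coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CorrectionMap:
    """Affine protocol correction
    ``x -> gain * (x - source_mean) + source_mean + offset``."""

    gain: np.ndarray         # (3,) per-axis gain
    offset: np.ndarray       # (n_points, 3) mm, mean displacement
    source_mean: np.ndarray  # (n_points, 3) mm, training source mean shape
    n_pairs: int
    residual_rms: float      # mm, on the training pairs

    @property
    def n_points(self) -> int:
        return self.offset.shape[0]

    def inverse(self) -> "CorrectionMap":
        if np.any(self.gain == 0):
            raise ValueError("gain has a zero component; map is not invertible")
        return CorrectionMap(gain=1.0 / self.gain, offset=-self.offset,
                             source_mean=self.source_mean + self.offset,
                             n_pairs=self.n_pairs,
                             residual_rms=self.residual_rms)


def learn_correction(source: np.ndarray, target: np.ndarray,
                     ridge: float = 0.0) -> CorrectionMap:
    """Estimate the protocol correction from paired shapes.

    Parameters
    ----------
    source, target : (n_pairs, n_points, 3)
        Corresponded, aligned shapes of the same subjects under the biased
        (source) and reference (target) protocol.
    ridge : float
        Non-negative regularization shrinking the gain toward 1.  With
        ``ridge = 0`` and exact affine ground truth the map is recovered
        exactly; at least 2 pairs are then required for identifiability.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 3 or source.shape[2] != 3:
        raise ValueError("source and target must be matching (n_pairs, n_points, 3)")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    n_pairs = source.shape[0]
    if n_pairs < 2 and ridge == 0.0:
        raise ValueError(
            "gain is not identifiable from a single pair; supply >= 2 pairs "
            "or a positive ridge"
        )

    s_mean = source.mean(axis=0)       # (n_points, 3)
    t_mean = target.mean(axis=0)
    s_c = source - s_mean
    t_c = target - t_mean
    # shared per-axis gain from centered data; ridge shrinks toward gain = 1
    num = np.einsum("npk,npk->k", s_c, t_c)
    den = np.einsum("npk,npk->k", s_c, s_c)
    gain = (num + ridge) / (den + ridge) if ridge > 0 else np.where(
        den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    cmap = CorrectionMap(gain=gain, offset=t_mean - s_mean, source_mean=s_mean,
                         n_pairs=n_pairs, residual_rms=0.0)
    residual = apply_correction(cmap, source) - target
    cmap.residual_rms = float(np.sqrt(np.mean(residual ** 2)))
    return cmap


def apply_correction(cmap: CorrectionMap, shapes: np.ndarray) -> np.ndarray:
    """Apply the learned map to one (n_points, 3) shape or a stack
    (n_shapes, n_points, 3); deterministic."""
    shapes = np.asarray(shapes, dtype=float)
    if shapes.shape[-2:] != (cmap.n_points, 3):
        raise ValueError(
            f"shape dimensions {shapes.shape[-2:]} do not match the map "
            f"({cmap.n_points}, 3)"
        )
    return cmap.gain * (shapes - cmap.source_mean) + cmap.source_mean + cmap.offset
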