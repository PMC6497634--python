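"""Binding-helix cross-correlation, free-energy landscapes, and jackknife errors.

The cross-correlation between the helix indicator X_i of residue i and the
binding indicator Y_j of residue j is

    C_ij = <X_i Y_j> / sqrt(<X_i^2> <Y_j^2>)

which for binary indicators is P(X_i=1, Y_j=1) / sqrt(P(X_i=1) P(Y_j=1)) and
lies in [0, 1].  Residues that never form helix (or never bind) have an
undefined C_ij and are masked, not zero-filled.

The free-energy landscape over a distance coordinate d and a helix-content
coordinate c is F(d, c) = -k_B T ln P(d, c) - F_min with P a normalized 2-D
histogram and F_min chosen so the occupied-bin minimum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KB_KCAL", "CorrelationMatrix", "FreeEnergySurface",
           "JackknifeEstimate", "cross_correlation", "landscape", "jackknife",
           "mean_se", "helix_indicator", "HELIX_CLASS"]

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/(mol*K)

HELIX_CLASS = frozenset({"H", "G", "I"})


@dataclass
class CorrelationMatrix:
    values: np.ndarray          # (n_helix_residues, n_binding_residues)
    mask: np.ndarray            # True where C_ij is undefined
    row_labels: list            # helix residues i
    col_labels: list            # binding residues j

    def defined(self) -> np.ndarray:
        return self.values[~self.mask]


@dataclass
class FreeEnergySurface:
    f_values: np.ndarray        # (n_d_bins, n_c_bins), NaN where unoccupied
    d_edges: np.ndarray
    c_edges: np.ndarray
    temperature: float
    f_min: float                # the subtracted constant, kcal/mol

    @property
    def occupied(self) -> np.ndarray:
        return ~np.isnan(self.f_values)


@dataclass
class JackknifeEstimate:
    mean: float
    std_error: float
    block_length: int
    n_blocks: int


def cross_correlation(X: np.ndarray, Y: np.ndarray,
                      row_labels: list | None = None,
                      col_labels: list | None = None) -> CorrelationMatrix:
    """C_ij from frame-aligned binary indicator matrices.

    ``X`` is (n_frames, n_helix_residues), ``Y`` is (n_frames,
    n_binding_residues); frames pooled across trajectories should be
    concatenated along axis 0 before the call.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"frame mismatch: X has {X.shape[0]}, Y has {Y.shape[0]}")
    if not (np.isin(X, (0, 1)).all() and np.isin(Y, (0, 1)).all()):
        raise ValueError("indicators must be binary")
    px = X.mean(axis=0)                     # <X_i^2> = <X_i> for binary
    py = Y.mean(axis=0)
    pxy = X.T @ Y / X.shape[0]
    denom = np.sqrt(np.outer(px, py))
    mask = denom == 0
    values = np.zeros_like(pxy)
    np.divide(pxy, denom, out=values, where=~mask)
    values[mask] = np.nan
    return CorrelationMatrix(
        values=values, mask=mask,
        row_labels=row_labels if row_labels is not None
        else list(range(1, X.shape[1] + 1)),
        col_labels=col_labels if col_labels is not None
        else list(range(1, Y.shape[1] + 1)),
    )


def landscape(d_series: np.ndarray, c_series: np.ndarray,
              temperature: float = 300.0,
              d_bin_width: float = 1.0, c_bin_width: float = 2.0,
              d_edges: np.ndarray | None = None,
              c_edges: np.ndarray | None = None) -> FreeEnergySurface:
    """Free-energy surface F(d, c) = -k_B T ln P(d, c) - F_min.

    Default binning: 1 A in d, 2 % in c; explicit edges override the widths.
    Unoccupied bins are NaN (undefined), and min over occupied bins is 0.
    """
    d = np.asarray(d_series, dtype=float)
    c = np.asarray(c_series, dtype=float)
    if d.shape != c.shape:
        raise ValueError("d and c series must be frame-aligned")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if d_edges is None:
        lo = np.floor(d.min() / d_bin_width) * d_bin_width
        hi = np.ceil(d.max() / d_bin_width) * d_bin_width
        hi = hi if hi > lo else lo + d_bin_width
        d_edges = np.arange(lo, hi + 0.5 * d_bin_width, d_bin_width)
    if c_edges is None:
        lo = np.floor(c.min() / c_bin_width) * c_bin_width
        hi = np.ceil(c.max() / c_bin_width) * c_bin_width
        hi = hi if hi > lo else lo + c_bin_width
        c_edges = np.arange(lo, hi + 0.5 * c_bin_width, c_bin_width)
    counts, d_edges, c_edges = np.histogram2d(d, c, bins=[d_edges, c_edges])
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        neg_logs = -KB_KCAL * temperature * np.log(p)
    f_min = float(np.nanmin(np.where(counts > 0, neg_logs, np.nan)))
    f = np.where(counts > 0, neg_logs - f_min, np.nan)
    return FreeEnergySurface(f, d_edges, c_edges, temperature, f_min)


def jackknife(series: np.ndarray, n_blocks: int | None = None,
              block_length: int | None = None,
              boundaries: np.ndarray | None = None) -> JackknifeEstimate:
    """Delete-one-block jackknife mean and standard error for a correlated series.

    Blocks come from one of: ``boundaries`` (explicit start indices of the
    independent segments, e.g. one per trajectory), ``block_length``, or
    ``n_blocks`` equal contiguous blocks (trailing remainder folded into the
    last block).  The estimate is the mean of leave-one-block-out means and
    SE = sqrt((B-1)/B * sum_b (m_b - mbar)^2).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if boundaries is not None:
        starts = list(np.asarray(boundaries, dtype=int))
        if starts[0] != 0:
            starts = [0] + starts
        edges = starts + [n]
    else:
        if block_length is not None:
            n_blocks = max(1, n // block_length)
        if n_blocks is None:
            raise ValueError("give n_blocks, block_length, or boundaries")
        if n_blocks > n:
            raise ValueError("more blocks than data points")
        base = n // n_blocks
        edges = [i * base for i in range(n_blocks)] + [n]
    nb = len(edges) - 1
    if nb < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    sizes = np.array([edges[b + 1] - edges[b] for b in range(nb)])
    sums = np.array([x[edges[b]:edges[b + 1]].sum() for b in range(nb)])
    total = x.sum()
    loo_means = (total - sums) / (n - sizes)       # leave-one-block-out means
    m_bar = loo_means.mean()
    se = float(np.sqrt((nb - 1) / nb * ((loo_means - m_bar) ** 2).sum()))
    return JackknifeEstimate(mean=float(m_bar), std_error=se,
                             block_length=int(sizes[0]), n_blocks=nb)


def mean_se(series: np.ndarray, n_blocks: int | None = None,
            boundaries: np.ndarray | None = None) -> tuple[float, float]:
    """Jackknife (mean, SE) with a degenerate fallback.

    A series too short to form two blocks gets its plain mean and SE 0 --
    single-frame profiles are exact for that frame, not noisy.
    """
    x = np.asarray(series, dtype=float)
    nb = n_blocks if boundaries is None else len(boundaries) + 1
    if len(x) < 2 or (nb is not None and min(nb, len(x)) < 2):
        return float(x.mean()), 0.0
    if n_blocks is not None:
        n_blocks = min(n_blocks, len(x))
    est = jackknife(x, n_blocks=n_blocks, boundaries=boundaries)
    return est.mean, est.std_error


def helix_indicator(labels: np.ndarray,
                    helix_class: frozenset[str] | set[str] = HELIX_CLASS) -> np.ndarray:
    """X_i indicator matrix from per-frame per-residue secondary-structure labels.

    ``labels`` is (n_frames, n_residues) of single-letter DSSP codes; returns
    an int 0/1 matrix of the same shape (1 where the label is in
    ``helix_class``, default {H, G, I}).
    """
    labels = np.asarray(labels)
    return np.isin(labels, list(helix_class)).astype(int)
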