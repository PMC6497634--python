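"""Helix content from calculated mean residue ellipticity at 222 nm.

A frame's DSSP helix labels are reduced to maximal helical fragments of
lengths n_1, ..., n_Nhel; the calculated mean residue ellipticity is

    [theta_calc] = ([theta]_hel / N) * sum_i max(n_i - k, 0)

with [theta]_hel = 42500 * (1 - 3/N) deg cm^2/dmol for an N-residue peptide
and k the minimum fragment length that produces a CD signal (default 3).
The helix content in percent is

    c = ([theta_calc] - [theta]_coil) / ([theta]_hel - [theta]_coil) * 100

with [theta]_coil = 640 deg cm^2/dmol.  Fragments with n_i <= k contribute
zero (not a negative signal); c itself is reported unclamped, so an all-coil
frame sits at about -1.65 % for N = 40 -- an honest artifact of the two
reference ellipticities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .statcorr import HELIX_CLASS

__all__ = ["HelixContentParams", "fragments_from_labels", "theta_calc",
           "helix_content", "helix_content_series"]


@dataclass
class HelixContentParams:
    n_residues: int = 40
    theta_coil: float = 640.0           # deg cm^2/dmol, complete random coil
    theta_hel_scale: float = 42500.0    # deg cm^2/dmol
    k: int = 3                          # minimum helix fragment length for signal

    def __post_init__(self):
        if self.n_residues <= 3:
            raise ValueError("need more than 3 residues")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.theta_hel <= self.theta_coil:
            raise ValueError("theta_hel must exceed theta_coil")

    @property
    def theta_hel(self) -> float:
        """Mean residue ellipticity of a complete helix: 42500 * (1 - 3/N)."""
        return self.theta_hel_scale * (1.0 - 3.0 / self.n_residues)


def fragments_from_labels(labels: np.ndarray,
                          helix_class=HELIX_CLASS) -> list[int]:
    """Lengths of maximal runs of helix-class labels in one frame's label row."""
    mask = np.isin(np.asarray(labels), list(helix_class)).astype(int)
    if mask.sum() == 0:
        return []
    padded = np.concatenate([[0], mask, [0]])
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [int(e - s) for s, e in zip(starts, ends)]


def theta_calc(fragments: list[int], params: HelixContentParams) -> float:
    """Calculated mean residue ellipticity from helix fragment lengths."""
    total = sum(max(n - params.k, 0) for n in fragments)
    return params.theta_hel / params.n_residues * total


def helix_content(fragments: list[int], params: HelixContentParams,
                  clamp: bool = False) -> float:
    """Helix content c in percent from one frame's fragment set."""
    th = theta_calc(fragments, params)
    c = (th - params.theta_coil) / (params.theta_hel - params.theta_coil) * 100.0
    if clamp:
        c = min(max(c, 0.0), 100.0)
    return c


def helix_content_series(labels: np.ndarray,
                         params: HelixContentParams | None = None,
                         helix_class=HELIX_CLASS,
                         clamp: bool = False) -> np.ndarray:
    """Per-frame helix content (%) from an (n_frames, n_residues) label matrix."""
    labels = np.asarray(labels)
    params = params or HelixContentParams(n_residues=labels.shape[1])
    return np.array([
        helix_content(fragments_from_labels(row, helix_class), params, clamp)
        for row in labels
    ])
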