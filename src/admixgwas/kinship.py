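"""Multi-group genomic kinship, genetic distances and PCoA support.

The kinship between line *l* of background *k* and line *l'* of
background *k'* is

    K[kl, k'l'] = sum_m (W_lm - f_mk) (W_l'm - f_mk')
                  / sqrt(sum_m f_mk (1 - f_mk)) / sqrt(sum_m f_mk' (1 - f_mk')),

with W the 0/1 genotype and f_mk the allele-1 frequency at marker m in
background k.  Centering and scaling each line by the frequencies of
its *own* background makes the coefficient comparable within and across
backgrounds; within a single background it reduces to the classical
frequency-centered genomic-relationship estimator.  A "common" mode
pools all lines into one frequency vector (used for ordination and for
the epistatic variance decomposition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, BACKGROUNDS, DataError, GenotypeMatrix, Pedigree

log = logging.getLogger(__name__)


@dataclass
class GroupFrequencies:
    """Allele-1 frequency per marker, per background (or pooled 'common')."""

    freq: pd.DataFrame  # markers x columns (subset of D/A/F or ['common'])

    def __getitem__(self, background: str) -> np.ndarray:
        return self.freq[background].to_numpy()


def group_allele_freq(G: GenotypeMatrix, pedigree: Pedigree,
                      mode: str = "by-background") -> GroupFrequencies:
    """Mean 0/1 call per marker within each background, or pooled."""
    if (G.calls == MISSING).any():
        raise DataError("genotypes must be complete (impute first)")
    if mode == "common":
        cols = {"common": G.calls.mean(axis=0)}
    else:
        bg = pedigree.background_of(G.lines)
        cols = {}
        for k in BACKGROUNDS:
            sel = bg == k
            if sel.any():
                cols[k] = G.calls[sel].mean(axis=0)
    if not cols:
        raise DataError("no lines")
    return GroupFrequencies(pd.DataFrame(cols, index=G.markers.marker_ids))


@dataclass
class KinshipSet:
    """N x N kinship with its line order, backgrounds, and frequency mode."""

    K: np.ndarray
    lines: list
    backgrounds: np.ndarray  # per line, 'D'/'A'/'F'
    mode: str
    n_markers_used: int = 0
    n_markers_dropped: int = 0

    def block(self, k: str, k2: str) -> np.ndarray:
        sel1 = self.backgrounds == k
        sel2 = self.backgrounds == k2
        return self.K[np.ix_(sel1, sel2)]


def kinship_pair(w_l: np.ndarray, w_l2: np.ndarray,
                 f_k: np.ndarray, f_k2: np.ndarray) -> float:
    """The kinship ratio for one pair of lines (reference implementation)."""
    w_l, w_l2 = np.asarray(w_l, float), np.asarray(w_l2, float)
    f_k, f_k2 = np.asarray(f_k, float), np.asarray(f_k2, float)
    d1 = np.sum(f_k * (1 - f_k))
    d2 = np.sum(f_k2 * (1 - f_k2))
    if d1 <= 0 or d2 <= 0:
        raise DataError("all markers monomorphic in a background")
    num = np.sum((w_l - f_k) * (w_l2 - f_k2))
    return float(num / (np.sqrt(d1) * np.sqrt(d2)))


def kinship_matrix(G: GenotypeMatrix, pedigree: Pedigree,
                   mode: str = "by-background",
                   drop_monomorphic: bool = True) -> KinshipSet:
    """Full N x N kinship.

    Markers monomorphic in every centering frequency vector contribute
    nothing to any numerator or denominator and are dropped with a
    logged count (denominator safety).
    """
    freqs = group_allele_freq(G, pedigree, mode=mode)
    bg = pedigree.background_of(G.lines)
    cols = freqs.freq.columns
    fmat = freqs.freq.to_numpy().T  # groups x markers
    poly = (fmat * (1 - fmat) > 0).any(axis=0)
    n_drop = int((~poly).sum())
    if n_drop and drop_monomorphic:
        log.info("dropping %d markers monomorphic in every background", n_drop)
    keep = poly if drop_monomorphic else np.ones(len(poly), bool)

    key = {l: ("common" if mode == "common" else k) for l, k in zip(G.lines, bg)}
    fs = {c: freqs.freq[c].to_numpy()[keep] for c in cols}
    calls = G.calls[:, keep].astype(float)
    centered = np.empty_like(calls)
    denom = np.empty(G.n_lines)
    for i, line in enumerate(G.lines):
        f = fs[key[line]]
        d = np.sum(f * (1 - f))
        if d <= 0:
            raise DataError(
                f"all retained markers monomorphic in background {key[line]}")
        centered[i] = calls[i] - f
        denom[i] = np.sqrt(d)
    K = (centered @ centered.T) / np.outer(denom, denom)
    K = (K + K.T) / 2.0
    return KinshipSet(K, list(G.lines), bg, mode,
                      n_markers_used=int(keep.sum()), n_markers_dropped=n_drop)


def genetic_distance(K: KinshipSet) -> np.ndarray:
    """Elementwise D = 1 - K (diagonal included, near 0 for inbreds)."""
    return 1.0 - K.K


def pcoa(D: np.ndarray, n_axes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a distance matrix.

    Eigendecomposition of the double-centered squared-distance matrix;
    negative eigenvalues are truncated.  Returns (coordinates, eigenvalues).
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0, None)
    coords = vecs * np.sqrt(pos)
    return coords[:, :n_axes], vals[:n_axes]
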