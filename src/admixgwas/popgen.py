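"""LD extent per group, cross-group persistence of LD phase, sign consistency.

For inbred lines the genotype correlation r between two loci equals the
haplotype correlation, so LD is measured as the Pearson correlation of
the 0/1 call vectors within each group.  Profiles are computed over
locus pairs binned by physical distance (default 0-2 Mbp in 1-kb
windows): per group the mean r^2, and across groups the correlation of
the signed r and of its sign indicator (1 if r > 0 else 0) over the
pairs of each window.  Both groups use one common 0/1 reference-allele
coding, so relabeling an allele flips r consistently in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import DataError, GenotypeMatrix, Pedigree


def pairwise_r(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Signed Pearson correlation of two 0/1 call vectors; r^2 is its square."""
    a = np.asarray(calls_a, float)
    b = np.asarray(calls_b, float)
    if a.std() == 0 or b.std() == 0:
        raise DataError("monomorphic marker: r undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _group_corr(calls: np.ndarray) -> np.ndarray:
    z = calls - calls.mean(axis=0)
    sd = z.std(axis=0)
    z = z / sd
    return (z.T @ z) / calls.shape[0]


@dataclass
class LDProfile:
    table: pd.DataFrame  # per distance window
    n_markers_used: int


def ld_profile(G: GenotypeMatrix, pedigree: Pedigree,
               groups: tuple[str, str] = ("D", "F"),
               max_dist: int = 2_000_000, window: int = 1_000,
               step: int = 1_000, min_carriers: int = 10) -> LDProfile:
    """Distance-binned LD profile of two groups over shared eligible SNPs.

    Only SNPs with at least ``min_carriers`` minor-allele carriers in
    *both* groups enter.  Per window: mean r^2 in each group, the
    cross-group correlation of signed r and of the sign indicator, over
    the pairs whose distance falls in the window; windows with fewer
    than 2 pairs are reported as missing.
    """
    bg = pedigree.background_of(G.lines)
    sub = {}
    for g in groups:
        sel = bg == g
        if not sel.any():
            raise DataError(f"no lines with background {g}")
        sub[g] = G.calls[sel].astype(float)
    mac = [np.minimum(sub[g].sum(axis=0), (1 - sub[g]).sum(axis=0))
           for g in groups]
    elig = (mac[0] >= min_carriers) & (mac[1] >= min_carriers)

    pos_all = G.markers.positions
    chroms = G.markers.chromosomes
    dists, r1s, r2s = [], [], []
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero((chroms == chrom) & elig)
        if sel.size < 2:
            continue
        pos = pos_all[sel]
        c1 = _group_corr(sub[groups[0]][:, sel])
        c2 = _group_corr(sub[groups[1]][:, sel])
        iu = np.triu_indices(sel.size, 1)
        d = np.abs(pos[iu[1]] - pos[iu[0]])
        keep = d <= max_dist
        dists.append(d[keep])
        r1s.append(c1[iu][keep])
        r2s.append(c2[iu][keep])
    if not dists:
        raise DataError("no eligible marker pairs")
    d = np.concatenate(dists)
    r1 = np.concatenate(r1s)
    r2 = np.concatenate(r2s)

    rows = []
    start = 0
    while start < max_dist:
        in_win = (d >= start) & (d < start + window)
        n = int(in_win.sum())
        center = start + window / 2
        if n >= 2:
            a, b = r1[in_win], r2[in_win]
            corr_r = _safe_corr(a, b)
            sign_cons = _safe_corr((a > 0).astype(float), (b > 0).astype(float))
            rows.append((center, float(np.mean(a ** 2)), float(np.mean(b ** 2)),
                         corr_r, sign_cons, n))
        else:
            rows.append((center, np.nan, np.nan, np.nan, np.nan, n))
        start += step
    table = pd.DataFrame(rows, columns=[
        "distance", f"mean_r2_{groups[0]}", f"mean_r2_{groups[1]}",
        "corr_r", "sign_consistency", "n_pairs"])
    return LDProfile(table, int(elig.sum()))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
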