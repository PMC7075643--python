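"""Local-ancestry reconstruction and imputation of admixed inbred lines.

An admixed doubled-haploid (DH) line derives from a single meiosis of a
D x F F1 hybrid, so its genome is a mosaic of parental segments and the
pedigree makes local ancestry deterministic wherever the two parents
carry different alleles ("informative" markers).  The pipeline is:

1. :func:`call_parental_origin` - per shared (low-density) marker, the
   parent whose allele matches the admixed call, where parents differ.
2. :func:`smooth_origins` - isolated discordant calls inside an
   otherwise homogeneous block are set back to undetermined.
3. :func:`segment_mosaic` - recombination breakpoints are placed inside
   each interval between opposite-origin informative markers by
   splitting the intervening dense markers in half (by marker count);
   the result is a tiling :class:`~admixgwas.io_core.AncestryTrack`.
4. :func:`impute_dense` - each dense marker receives the allele of the
   parent named by its segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_core import (MISSING, AncestryTrack, DataError, GenotypeMatrix,
                      MarkerMap, Pedigree)

ORIGIN_D, ORIGIN_F = 0, 1


@dataclass
class OriginCalls:
    """Per shared marker parental origin: 0 = D parent, 1 = F parent, -1 undetermined."""

    line_id: str
    markers: MarkerMap  # shared-panel map
    origins: np.ndarray  # int8, len == len(markers)
    n_mendelian: int = 0
    n_missing: int = 0

    def copy(self) -> "OriginCalls":
        return OriginCalls(self.line_id, self.markers, self.origins.copy(),
                           self.n_mendelian, self.n_missing)


def call_parental_origin(admixed: np.ndarray, parent_d: np.ndarray,
                         parent_f: np.ndarray, markers: MarkerMap,
                         line_id: str = "") -> OriginCalls:
    """Determine the transmitting parent at each informative shared marker.

    A marker is informative when the two parents carry different alleles;
    there the origin is the parent matching the admixed allele.  Where
    parents agree, the origin is undetermined.  An admixed call that
    matches neither parent (possible only where parents agree) is a
    Mendelian inconsistency: kept undetermined and counted.
    """
    admixed = np.asarray(admixed)
    parent_d = np.asarray(parent_d)
    parent_f = np.asarray(parent_f)
    origins = np.full(len(markers), MISSING, dtype=np.int8)
    known = (admixed != MISSING) & (parent_d != MISSING) & (parent_f != MISSING)
    informative = known & (parent_d != parent_f)
    origins[informative & (admixed == parent_d)] = ORIGIN_D
    origins[informative & (admixed == parent_f)] = ORIGIN_F
    mendel = known & (parent_d == parent_f) & (admixed != parent_d)
    n_missing = int(np.sum((admixed == MISSING) & (parent_d != parent_f)))
    return OriginCalls(line_id, markers, origins,
                       n_mendelian=int(mendel.sum()), n_missing=n_missing)


def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal values: list of (start, stop_exclusive, value)."""
    runs = []
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        runs.append((i, j, int(values[i])))
        i = j
    return runs


def smooth_origins(calls: OriginCalls, max_discordant: int = 1,
                   min_flank: int = 2) -> OriginCalls:
    """Set short discordant runs of determined origins to undetermined.

    A run of at most ``max_discordant`` determined calls whose origin
    differs from both flanking runs is discarded, provided each flank
    holds at least ``min_flank`` concordant determined calls of one
    common origin.  Runs at chromosome ends (single flank) are kept.
    The operation is idempotent.
    """
    out = calls.copy()
    chroms = calls.markers.chromosomes
    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        det = sel[out.origins[sel] != MISSING]
        if det.size == 0:
            continue
        runs = _runs(out.origins[det])
        for r, (start, stop, value) in enumerate(runs):
            if stop - start > max_discordant:
                continue
            if r == 0 or r == len(runs) - 1:
                continue
            left = runs[r - 1]
            right = runs[r + 1]
            if (left[1] - left[0] >= min_flank and right[1] - right[0] >= min_flank
                    and left[2] == right[2] and left[2] != value):
                out.origins[det[start:stop]] = MISSING
    return out


@dataclass
class RecombinationInterval:
    chromosome: str
    left_pos: int
    left_origin: int
    right_pos: int
    right_origin: int
    breakpoint: int = 0  # inferred boundary (last bp of the left segment)


def segment_mosaic(calls: OriginCalls, dense_map: MarkerMap,
                   parent_d: str = "", parent_f: str = "",
                   chrom_lengths: Mapping[str, int] | None = None,
                   ) -> tuple[AncestryTrack, list[RecombinationInterval]]:
    """Turn smoothed origin calls into a tiling ancestry track.

    Within each recombination interval (between consecutive determined
    calls of opposite origin) the dense markers strictly between the two
    informative positions are split in half by marker count: the first
    ceil(n/2) keep the left origin, the rest take the right origin; the
    breakpoint is placed midway between the last left and first right
    position (midway between the informative markers when no dense
    marker intervenes).  Chromosome ends extend the nearest determined
    origin.
    """
    track = AncestryTrack(calls.line_id)
    intervals: list[RecombinationInterval] = []
    origin_label = {ORIGIN_D: "D", ORIGIN_F: "F"}
    parent_label = {ORIGIN_D: parent_d, ORIGIN_F: parent_f}
    shared_chroms = calls.markers.chromosomes
    shared_pos = calls.markers.positions
    dense_chroms = dense_map.chromosomes
    dense_pos = dense_map.positions

    for chrom in dict.fromkeys(dense_chroms):  # preserve map order
        dsel = dense_pos[dense_chroms == chrom]
        length = (chrom_lengths or {}).get(chrom, int(dsel.max()) if dsel.size else 0)
        ssel = np.flatnonzero(shared_chroms == chrom)
        det = ssel[calls.origins[ssel] != MISSING]
        if det.size == 0:
            raise DataError(
                f"line {calls.line_id}: no determined origin on chromosome {chrom}")
        pos = shared_pos[det]
        org = calls.origins[det]
        boundaries: list[int] = []  # last bp of each segment but the final one
        origins: list[int] = [int(org[0])]
        for i in range(1, len(det)):
            if org[i] == org[i - 1]:
                continue
            left_pos, right_pos = int(pos[i - 1]), int(pos[i])
            between = dsel[(dsel > left_pos) & (dsel < right_pos)]
            n = len(between)
            if n == 0:
                bp = (left_pos + right_pos) // 2
            else:
                n_left = -(-n // 2)  # ceil: tie goes to the left origin
                last_left = int(between[n_left - 1])
                first_right = int(between[n_left]) if n_left < n else right_pos
                bp = (last_left + first_right) // 2
            boundaries.append(bp)
            origins.append(int(org[i]))
            intervals.append(RecombinationInterval(
                chrom, left_pos, int(org[i - 1]), right_pos, int(org[i]), bp))
        segs = []
        start = 1
        for k, o in enumerate(origins):
            end = boundaries[k] if k < len(boundaries) else max(length, int(pos[-1]))
            segs.append((start, end, origin_label[o], parent_label[o]))
            start = end + 1
        track.segments[chrom] = segs
    track.validate()
    return track, intervals


def interval_marker_fraction(intervals: Sequence[RecombinationInterval],
                             dense_map: MarkerMap) -> float:
    """Fraction of dense markers lying strictly inside recombination intervals."""
    if len(dense_map) == 0:
        return float("nan")
    mask = np.zeros(len(dense_map), dtype=bool)
    chroms = dense_map.chromosomes
    pos = dense_map.positions
    for iv in intervals:
        mask |= ((chroms == iv.chromosome) & (pos > iv.left_pos)
                 & (pos < iv.right_pos))
    return float(mask.mean())


def impute_dense(track: AncestryTrack, parent_d: np.ndarray,
                 parent_f: np.ndarray, dense_map: MarkerMap,
                 ) -> tuple[np.ndarray, int]:
    """Copy, per dense marker, the allele of the parent named by its segment.

    Returns the imputed row and the count of markers left missing
    because the named parent is missing there.
    """
    origin = track.origin_vector(dense_map)
    if (origin == MISSING).any():
        raise DataError(f"track of {track.line_id} does not cover all markers")
    row = np.where(origin == ORIGIN_D, parent_d, parent_f).astype(np.int8)
    n_missing = int(np.sum(row == MISSING))
    return row, n_missing


@dataclass
class ImputationResult:
    genotypes: GenotypeMatrix  # admixed lines x dense markers, imputed
    tracks: dict = field(default_factory=dict)
    intervals: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)  # per line counters


def impute_admixed_panel(G_shared_admixed: GenotypeMatrix,
                         G_dense_parents: GenotypeMatrix,
                         pedigree: Pedigree,
                         max_discordant: int = 1, min_flank: int = 2,
                         chrom_lengths: Mapping[str, int] | None = None,
                         ) -> ImputationResult:
    """Full pipeline: origins -> smoothing -> mosaic -> dense imputation.

    ``G_shared_admixed`` holds admixed lines on the shared (low-density)
    panel; ``G_dense_parents`` holds the parental lines on the dense
    panel, which must contain every shared marker.
    """
    dense_map = G_dense_parents.markers
    shared_map = G_shared_admixed.markers
    shared_idx = np.array([dense_map.index_of(m) for m in shared_map.marker_ids])
    tracks, intervals, stats, rows = {}, {}, {}, []
    for line in G_shared_admixed.lines:
        pd_id, pf_id = pedigree.parents_of(line)
        dense_d = G_dense_parents.row(pd_id)
        dense_f = G_dense_parents.row(pf_id)
        calls = call_parental_origin(
            G_shared_admixed.row(line), dense_d[shared_idx], dense_f[shared_idx],
            shared_map, line_id=line)
        smoothed = smooth_origins(calls, max_discordant, min_flank)
        track, ivs = segment_mosaic(smoothed, dense_map, pd_id, pf_id,
                                    chrom_lengths)
        row, n_miss = impute_dense(track, dense_d, dense_f, dense_map)
        tracks[line] = track
        intervals[line] = ivs
        stats[line] = {
            "n_mendelian": calls.n_mendelian,
            "n_missing_shared": calls.n_missing,
            "n_missing_imputed": n_miss,
            "interval_marker_fraction": interval_marker_fraction(ivs, dense_map),
        }
        rows.append(row)
    G = GenotypeMatrix(list(G_shared_admixed.lines), dense_map,
                       np.stack(rows) if rows else
                       np.empty((0, len(dense_map)), np.int8))
    return ImputationResult(G, tracks, intervals, stats)


def selection_bias_scan(G_admixed: GenotypeMatrix, pedigree: Pedigree,
                        G_parents: GenotypeMatrix) -> np.ndarray:
    """Per-marker |f_o - f_e|: observed admixed allele-1 frequency vs the
    pedigree expectation (mean over admixed lines of the mean of their
    two parents' alleles, so each parent contributes by its number of
    progeny)."""
    if G_admixed.n_lines == 0:
        raise DataError("no admixed lines")
    f_obs = G_admixed.calls.mean(axis=0)
    expect = np.zeros(G_admixed.n_markers)
    for line in G_admixed.lines:
        pd_id, pf_id = pedigree.parents_of(line)
        expect += (G_parents.row(pd_id) + G_parents.row(pf_id)) / 2.0
    f_exp = expect / G_admixed.n_lines
    return np.abs(f_obs - f_exp)
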