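"""Data model and readers/writers shared by the whole package.

Genotypes are fully homozygous inbred calls coded 0/1 (missing = -1).
Every line carries a genetic-background label: ``D`` (dent-like group),
``F`` (flint-like group) or ``A`` (admixed, with one D and one F parent).
Admixed genomes are mosaics of D and F segments; an
:class:`AncestryTrack` records the local origin of every segment.

The *allelic state* of a call combines the SNP allele with the ancestry
of the carrying segment and the genetic background of the carrier.  The
three GWAS models use nested state spaces:

=====  =========================================================
model  allelic states
=====  =========================================================
M1     ``0, 1``
M2     ``0D, 1D, 0F, 1F``           (ancestry == background)
M3     ``0DD, 1DD, 0DA, 1DA, 0FA, 1FA, 0FF, 1FF``
=====  =========================================================

Coordinates are 1-based bp; segment intervals are closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # format-independent missing-call sentinel

BACKGROUNDS = ("D", "A", "F")
ANCESTRIES = ("D", "F")

#: allelic-state labels per GWAS model, in canonical order
STATE_SPACE = {
    "M1": ("0", "1"),
    "M2": ("0D", "1D", "0F", "1F"),
    "M3": ("0DD", "1DD", "0DA", "1DA", "0FA", "1FA", "0FF", "1FF"),
}


class DataError(ValueError):
    """Invalid or inconsistent input data."""


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------


class MarkerMap:
    """Physical map of markers: id, chromosome, 1-based bp position.

    Positions must be strictly increasing within a chromosome (ties are
    rejected) and marker ids must be unique.
    """

    def __init__(self, marker_id: Sequence[str], chromosome: Sequence[str],
                 position: Sequence[int]):
        df = pd.DataFrame({
            "marker_id": np.asarray(marker_id, dtype=object),
            "chromosome": np.asarray(chromosome, dtype=object),
            "position": np.asarray(position, dtype=np.int64),
        })
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise DataError(f"duplicated marker id {dup!r}")
        # sort by (chromosome, position), keep original order of chromosomes
        chrom_order = {c: i for i, c in enumerate(pd.unique(df["chromosome"]))}
        df = df.sort_values(
            by=["chromosome", "position"],
            key=lambda s: s.map(chrom_order) if s.name == "chromosome" else s,
            kind="stable",
        ).reset_index(drop=True)
        for chrom, sub in df.groupby("chromosome", sort=False):
            if (np.diff(sub["position"].to_numpy()) <= 0).any():
                raise DataError(f"duplicated position on chromosome {chrom}")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerMap) and self.table.equals(other.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()

    def index_of(self, marker_id: str) -> int:
        idx = np.flatnonzero(self.marker_ids == marker_id)
        if idx.size == 0:
            raise KeyError(marker_id)
        return int(idx[0])


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    return MarkerMap(df["marker_id"], df["chromosome"], df["position"])


def write_marker_map(mmap: MarkerMap, path) -> None:
    mmap.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


class GenotypeMatrix:
    """Lines x markers matrix of 0/1 calls (missing = -1) plus marker map."""

    def __init__(self, lines: Sequence[str], markers: MarkerMap, calls):
        calls = np.asarray(calls)
        if calls.ndim != 2:
            raise DataError("calls must be 2-D (lines x markers)")
        bad = ~np.isin(calls, (0, 1, MISSING))
        if bad.any():
            raise DataError(
                f"non-{{0,1}} call {calls[bad].flat[0]!r} in genotype matrix")
        if calls.shape != (len(lines), len(markers)):
            raise DataError(
                f"calls shape {calls.shape} does not match "
                f"{len(lines)} lines x {len(markers)} markers")
        self.lines = list(lines)
        if len(set(self.lines)) != len(self.lines):
            raise DataError("duplicated line id in genotype matrix")
        self.markers = markers
        self.calls = calls.astype(np.int8)
        self._line_idx = {l: i for i, l in enumerate(self.lines)}

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def row(self, line_id: str) -> np.ndarray:
        return self.calls[self._line_idx[line_id]]

    def subset_lines(self, line_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._line_idx[l] for l in line_ids]
        return GenotypeMatrix(list(line_ids), self.markers, self.calls[idx])

    def missing_fraction(self) -> float:
        return float(np.mean(self.calls == MISSING))


def read_genotype_matrix(path, markers: MarkerMap) -> GenotypeMatrix:
    """Read the tabular format: header = marker ids, first column = line id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(markers.marker_ids):
        df = df.reindex(columns=markers.marker_ids)
        if df.isna().any().any():
            raise DataError("matrix columns do not match the marker map")
    vals = df.to_numpy()
    bad = ~np.isin(vals, (0, 1, MISSING))
    if bad.any():
        raise DataError(f"non-{{0,1}} call {vals[bad].flat[0]!r} in {path}")
    return GenotypeMatrix([str(i) for i in df.index], markers, vals)


def write_genotype_matrix(G: GenotypeMatrix, path) -> None:
    pd.DataFrame(G.calls, index=G.lines, columns=G.markers.marker_ids).to_csv(
        path, sep="\t", index_label="line_id")


def read_vcf(path) -> tuple[GenotypeMatrix, dict]:
    """Read homozygous-inbred genotypes from a VCF (GT field only).

    Heterozygous calls are treated as missing and counted; non-biallelic
    sites are rejected with a warning.  Returns the matrix and a stats
    dict with ``n_het`` and ``n_skipped_sites``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    n_het = 0
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(
                f"skipping non-biallelic site {var.ID or var.POS}")
            n_skipped += 1
            continue
        gts = var.genotype.array()  # (n_samples, ploidy+1)
        a, b = gts[:, 0], gts[:, 1]
        call = np.full(len(samples), MISSING, dtype=np.int8)
        hom = (a == b) & (a >= 0)
        call[hom] = a[hom]
        het = (a != b) & (a >= 0) & (b >= 0)
        n_het += int(het.sum())
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(call)
    mmap = MarkerMap(ids, chroms, poss)
    calls = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), np.int8)
    G = GenotypeMatrix(samples, mmap, calls)
    return G, {"n_het": n_het, "n_skipped_sites": n_skipped}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF (REF=A, ALT=T placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.markers.chromosomes):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.lines) + "\n")
        code = {0: "0/0", 1: "1/1", MISSING: "./."}
        for m in range(G.n_markers):
            gts = "\t".join(code[int(c)] for c in G.calls[:, m])
            fh.write(f"{G.markers.chromosomes[m]}\t{G.markers.positions[m]}\t"
                     f"{G.markers.marker_ids[m]}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def read_genotypes(path, format: str = "auto"):
    """Dispatch reader.  ``format``: 'vcf', 'matrix-tsv' or 'auto' (by suffix).

    The matrix-tsv format needs a companion map file ``<path>.map`` unless a
    :class:`MarkerMap` is passed explicitly via :func:`read_genotype_matrix`.
    """
    p = str(path)
    if format == "auto":
        format = "vcf" if p.endswith(".vcf") or p.endswith(".vcf.gz") else "matrix-tsv"
    if format == "vcf":
        G, _ = read_vcf(p)
        return G
    return read_genotype_matrix(p, read_marker_map(p + ".map"))


# ---------------------------------------------------------------------------
# pedigree / line info
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineInfo:
    line_id: str
    background: str
    parent1: str | None = None
    parent2: str | None = None

    def __post_init__(self):
        if self.background not in BACKGROUNDS:
            raise DataError(f"unknown background {self.background!r}")
        if self.background == "A":
            if not (self.parent1 and self.parent2):
                raise DataError(
                    f"admixed line {self.line_id} must have two parents")
        elif self.parent1 or self.parent2:
            raise DataError(
                f"pure line {self.line_id} must not have parents recorded")


class Pedigree:
    """Collection of :class:`LineInfo`, with background lookups.

    For every admixed line the two parents must be one D and one F line
    of the pedigree.
    """

    def __init__(self, entries: Iterable[LineInfo]):
        self.entries = list(entries)
        self._by_id = {e.line_id: e for e in self.entries}
        if len(self._by_id) != len(self.entries):
            raise DataError("duplicated line id in pedigree")
        for e in self.entries:
            if e.background == "A":
                pb = {self._parent_background(e.parent1),
                      self._parent_background(e.parent2)}
                if pb != {"D", "F"}:
                    raise DataError(
                        f"admixed line {e.line_id}: parents must be one D "
                        f"and one F line (got {sorted(pb)})")

    def _parent_background(self, pid: str) -> str:
        if pid not in self._by_id:
            raise DataError(f"parent {pid!r} absent from pedigree")
        return self._by_id[pid].background

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, line_id: str) -> bool:
        return line_id in self._by_id

    def __getitem__(self, line_id: str) -> LineInfo:
        return self._by_id[line_id]

    def background_of(self, line_ids: Sequence[str]) -> np.ndarray:
        return np.array([self._by_id[l].background for l in line_ids], dtype=object)

    def parents_of(self, line_id: str) -> tuple[str, str]:
        """Return (dent parent, flint parent) of an admixed line."""
        e = self._by_id[line_id]
        if e.background != "A":
            raise DataError(f"{line_id} is not admixed")
        p1, p2 = self._by_id[e.parent1], self._by_id[e.parent2]
        if p1.background == "D":
            return p1.line_id, p2.line_id
        return p2.line_id, p1.line_id

    def lines_with_background(self, background: str) -> list[str]:
        return [e.line_id for e in self.entries if e.background == background]


def canonical_line_order(line_ids: Sequence[str], pedigree: Pedigree) -> list[str]:
    """D block, then A, then F, each sorted lexicographically."""
    order = {"D": 0, "A": 1, "F": 2}
    return sorted(line_ids, key=lambda l: (order[pedigree[l].background], l))


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str).fillna("")
    entries = [
        LineInfo(r.line_id, r.background, r.parent1 or None, r.parent2 or None)
        for r in df.itertuples()
    ]
    return Pedigree(entries)


def write_pedigree(ped: Pedigree, path) -> None:
    pd.DataFrame(
        [(e.line_id, e.background, e.parent1 or "", e.parent2 or "")
         for e in ped.entries],
        columns=["line_id", "background", "parent1", "parent2"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ancestry tracks
# ---------------------------------------------------------------------------


@dataclass
class AncestryTrack:
    """Per-line mosaic of D/F segments along each chromosome.

    ``segments`` maps chromosome -> list of (start, end, origin, parent)
    closed 1-based intervals that tile the chromosome; adjacent segments
    differ in origin or parent.
    """

    line_id: str
    segments: dict = field(default_factory=dict)

    def validate(self) -> None:
        for chrom, segs in self.segments.items():
            prev = None
            for start, end, origin, parent in segs:
                if origin not in ANCESTRIES:
                    raise DataError(f"bad origin {origin!r} on {chrom}")
                if end < start:
                    raise DataError(f"empty segment on {chrom}")
                if prev is not None:
                    pstart, pend, porigin, pparent = prev
                    if start != pend + 1:
                        raise DataError(
                            f"{self.line_id}/{chrom}: segments must tile "
                            f"(gap or overlap at {start})")
                    if (origin, parent) == (porigin, pparent):
                        raise DataError(
                            f"{self.line_id}/{chrom}: adjacent segments "
                            "with identical origin and parent")
                prev = (start, end, origin, parent)

    def origin_at(self, chrom: str, pos: int) -> str | None:
        for start, end, origin, _parent in self.segments.get(chrom, ()):
            if start <= pos <= end:
                return origin
        return None

    def origin_codes(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Local origin per position on one chromosome: 0=D, 1=F, -1 uncovered."""
        out = np.full(len(positions), MISSING, dtype=np.int8)
        segs = self.segments.get(chrom)
        if not segs:
            return out
        starts = np.array([s[0] for s in segs])
        ends = np.array([s[1] for s in segs])
        codes = np.array([0 if s[2] == "D" else 1 for s in segs], dtype=np.int8)
        j = np.searchsorted(starts, positions, side="right") - 1
        ok = (j >= 0) & (positions <= ends[np.clip(j, 0, len(segs) - 1)])
        out[ok] = codes[j[ok]]
        return out

    def origin_vector(self, markers: MarkerMap) -> np.ndarray:
        """Local origin per marker: 0 = D, 1 = F, -1 = outside all segments."""
        out = np.full(len(markers), MISSING, dtype=np.int8)
        chroms = markers.chromosomes
        pos = markers.positions
        for chrom in self.segments:
            sel = np.flatnonzero(chroms == chrom)
            if sel.size:
                out[sel] = self.origin_codes(chrom, pos[sel])
        return out

    def group_proportion(self, group: str = "D") -> float:
        """Genome-wide proportion of the track covered by ``group`` segments."""
        tot = got = 0
        for segs in self.segments.values():
            for start, end, origin, _ in segs:
                span = end - start + 1
                tot += span
                if origin == group:
                    got += span
        return got / tot if tot else float("nan")


def read_tracks(path) -> dict[str, AncestryTrack]:
    df = pd.read_csv(path, sep="\t",
                     dtype={"line_id": str, "chrom": str, "origin": str,
                            "parent": str})
    tracks: dict[str, AncestryTrack] = {}
    for (line_id, chrom), sub in df.groupby(["line_id", "chrom"], sort=False):
        tr = tracks.setdefault(line_id, AncestryTrack(line_id))
        sub = sub.sort_values("start")
        tr.segments[chrom] = [
            (int(r.start), int(r.end), r.origin, r.parent)
            for r in sub.itertuples()
        ]
    for tr in tracks.values():
        tr.validate()
    return tracks


def write_tracks(tracks: Mapping[str, AncestryTrack], path) -> None:
    rows = []
    for tr in tracks.values():
        for chrom, segs in tr.segments.items():
            for start, end, origin, parent in segs:
                rows.append((tr.line_id, chrom, start, end, origin, parent))
    pd.DataFrame(
        rows, columns=["line_id", "chrom", "start", "end", "origin", "parent"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path) -> pd.DataFrame:
    """Line-level phenotypes: TSV with line_id column, one column per trait."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str}).set_index("line_id")
    if df.index.duplicated().any():
        raise DataError("duplicated line id in phenotype table")
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="line_id")


# ---------------------------------------------------------------------------
# allelic states
# ---------------------------------------------------------------------------


def assign_allelic_state(allele: int, ancestry: str, background: str,
                         model: str) -> str:
    """Canonical allelic-state label for one call.

    For pure backgrounds the segment ancestry necessarily equals the
    background; a mismatch is an error.  M1 drops ancestry and
    background; M2 drops the background (it is confounded with the
    ancestry there); M3 keeps both.
    """
    if allele not in (0, 1):
        raise DataError(f"allele must be 0/1, got {allele!r}")
    if ancestry not in ANCESTRIES or background not in BACKGROUNDS:
        raise DataError(f"bad ancestry/background {ancestry!r}/{background!r}")
    if background != "A" and ancestry != background:
        raise DataError(
            f"pure background {background} cannot carry {ancestry}-ancestry allele")
    if model == "M1":
        return str(allele)
    if model == "M2":
        return f"{allele}{ancestry}"
    if model == "M3":
        return f"{allele}{ancestry}{background}"
    raise DataError(f"unknown model {model!r}")


def state_code_matrix(G: GenotypeMatrix, pedigree: Pedigree,
                      tracks: Mapping[str, AncestryTrack] | None,
                      model: str) -> np.ndarray:
    """Integer state codes (index into ``STATE_SPACE[model]``) per line x marker.

    -1 marks missing calls and admixed calls with undetermined local
    ancestry; such calls are excluded from counts and designs at that
    marker.
    """
    space = STATE_SPACE[model]
    n, m = G.n_lines, G.n_markers
    codes = np.full((n, m), MISSING, dtype=np.int8)
    bg = pedigree.background_of(G.lines)
    calls = G.calls
    valid = calls != MISSING

    # ancestry code per line x marker: 0=D, 1=F, -1 undetermined
    anc = np.full((n, m), MISSING, dtype=np.int8)
    anc[bg == "D"] = 0
    anc[bg == "F"] = 1
    if (bg == "A").any():
        if tracks is None:
            raise DataError("admixed lines present but no ancestry tracks given")
        for i in np.flatnonzero(bg == "A"):
            line = G.lines[i]
            if line not in tracks:
                raise DataError(f"no ancestry track for admixed line {line}")
            anc[i] = tracks[line].origin_vector(G.markers)

    ok = valid & (anc != MISSING)
    if model == "M1":
        codes[valid] = calls[valid]  # M1 ignores ancestry and background
        return codes
    if model == "M2":
        codes[ok] = (2 * anc[ok] + calls[ok]).astype(np.int8)
        return codes
    if model == "M3":
        # background code 0=D,1=A,2=F; state layout: (0DD,1DD,0DA,1DA,0FA,1FA,0FF,1FF)
        bgc = np.select([bg == "D", bg == "A", bg == "F"], [0, 1, 2]).astype(np.int8)
        base = np.empty((n, 1), dtype=np.int8)
        # pure D -> states 0/1; pure F -> 6/7; admixed: D ancestry -> 2/3, F -> 4/5
        base[bgc == 0] = 0
        base[bgc == 1] = 2
        base[bgc == 2] = 6
        offs = np.where((bg == "A")[:, None], 2 * anc, 0)
        codes[ok] = (base + offs + calls)[ok].astype(np.int8)
        return codes
    raise DataError(f"unknown model {model!r}")


def state_counts(G: GenotypeMatrix, pedigree: Pedigree,
                 tracks: Mapping[str, AncestryTrack] | None,
                 model: str) -> pd.DataFrame:
    """Per-marker carrier counts per allelic state (columns in state order).

    Admixed calls with undetermined local ancestry (and missing calls)
    are excluded from the counts at that marker, so rows sum to the
    number of lines minus the excluded calls.
    """
    codes = state_code_matrix(G, pedigree, tracks, model)
    space = STATE_SPACE[model]
    counts = np.stack(
        [np.count_nonzero(codes == s, axis=0) for s in range(len(space))],
        axis=1)
    return pd.DataFrame(counts, index=G.markers.marker_ids, columns=list(space))
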