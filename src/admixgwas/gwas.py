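"""The three GWAS strategies over allelic states.

* M1 - standard single-group model, applied to one background at a
  time; one test per SNP (allele 1 vs allele 0).
* M2 - joint dent+flint model with ancestry-specific allele effects
  (ancestry confounded with background); battery of 4 tests.
* M3 - joint dent+flint+admixed model distinguishing allele ancestry
  from the genetic background of the carrier; battery of 16 tests over
  the four base contrasts Delta_DD, Delta_DA, Delta_FA, Delta_FF
  (each base contrast is allele-1 effect minus allele-0 effect within
  one ancestry x background combination).

Inference is two-step: one ReML fit of the SNP-free polygenic model,
then per-SNP GLS with the plugged covariance and Wald chi-square(1)
tests of every battery contrast.  FDR is controlled jointly over the
whole marker x hypothesis battery of a strategy (Benjamini-Hochberg
step-up by default), and significant SNPs are chained into QTLs within
a 3-Mbp physical window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import io_core, mixedmodel
from .io_core import MISSING, STATE_SPACE, DataError, GenotypeMatrix, Pedigree
from .kinship import KinshipSet, kinship_matrix
from .mixedmodel import ModelError, PolygenicFit

log = logging.getLogger(__name__)

QTL_WINDOW_BP = 3_000_000
MIN_STATE_CARRIERS = 10

#: base simple contrasts per model, in battery column order
BASE_CONTRASTS = {
    "M1": ("",),
    "M2": ("D", "F"),
    "M3": ("DD", "DA", "FA", "FF"),
}


@dataclass(frozen=True)
class ContrastSpec:
    """A linear combination of the base simple contrasts of a model."""

    name: str
    type: str            # simple | general | divergent
    coefficients: tuple  # over BASE_CONTRASTS[model]
    model: str
    interaction: bool = False  # tests SNP x genetic-background interaction

    def design_coefficients(self) -> np.ndarray:
        """Expand to the (intercept + state indicators) design columns."""
        space = STATE_SPACE[self.model]
        c = np.zeros(1 + len(space))
        for w, base in zip(self.coefficients, BASE_CONTRASTS[self.model]):
            if w == 0:
                continue
            c[1 + space.index(f"1{base}")] += w
            c[1 + space.index(f"0{base}")] -= w
        return c


def m1_battery() -> list[ContrastSpec]:
    return [ContrastSpec("Delta", "simple", (1,), "M1")]


def m2_battery() -> list[ContrastSpec]:
    return [
        ContrastSpec("D", "simple", (1, 0), "M2"),
        ContrastSpec("F", "simple", (0, 1), "M2"),
        ContrastSpec("D+F", "general", (1, 1), "M2"),
        ContrastSpec("D-F", "divergent", (1, -1), "M2"),
    ]


def m3_battery() -> list[ContrastSpec]:
    """The 16 M3 hypotheses over (Delta_DD, Delta_DA, Delta_FA, Delta_FF).

    The four contrasts flagged ``interaction`` test an epistatic
    interaction between the SNP and the genetic background.
    """
    rows = [
        ("DD", "simple", (1, 0, 0, 0), False),
        ("DA", "simple", (0, 1, 0, 0), False),
        ("FA", "simple", (0, 0, 1, 0), False),
        ("FF", "simple", (0, 0, 0, 1), False),
        ("DD+FF", "general", (1, 0, 0, 1), False),
        ("DD+DA", "general", (1, 1, 0, 0), False),
        ("FF+FA", "general", (0, 0, 1, 1), False),
        ("DA+FA", "general", (0, 1, 1, 0), False),
        ("DD+DA+FA+FF", "general", (1, 1, 1, 1), False),
        ("DD-FF", "divergent", (1, 0, 0, -1), False),
        ("DD-DA", "divergent", (1, -1, 0, 0), True),
        ("FF-FA", "divergent", (0, 0, -1, 1), True),
        ("DA-FA", "divergent", (0, 1, -1, 0), False),
        ("(DD+DA)-(FF+FA)", "divergent", (1, 1, -1, -1), False),
        ("(DD+FF)-(DA+FA)", "divergent", (1, -1, -1, 1), True),
        ("(DD-DA)-(FF-FA)", "divergent", (1, -1, 1, -1), True),
    ]
    return [ContrastSpec(n, t, c, "M3", i) for n, t, c, i in rows]


def battery(model: str) -> list[ContrastSpec]:
    return {"M1": m1_battery, "M2": m2_battery, "M3": m3_battery}[model]()


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    kept: np.ndarray              # marker indices kept, in map order
    n_low_count: int
    n_redundant: int
    aliases: dict = field(default_factory=dict)  # dropped id -> kept id


def filter_snps(codes: np.ndarray, markers: io_core.MarkerMap, model: str,
                min_count: int = MIN_STATE_CARRIERS) -> FilterResult:
    """Discard SNPs whose minor allelic state has < ``min_count`` carriers
    or which duplicate the state vector of an earlier SNP.

    The minor allelic state is the least-carried state of the model's
    full state space, so a state absent by fixation counts as zero and
    excludes the marker.  Among markers with identical state vectors
    over the analyzed lines only the first in map order is kept; the
    alias mapping is recorded so detected loci can be expanded.
    """
    n_states = len(STATE_SPACE[model])
    counts = np.stack([(codes == s).sum(axis=0) for s in range(n_states)], axis=1)
    ok = counts.min(axis=1) >= min_count
    n_low = int((~ok).sum())
    kept, aliases = [], {}
    seen: dict[bytes, int] = {}
    ids = markers.marker_ids
    for m in np.flatnonzero(ok):
        key = codes[:, m].tobytes()
        first = seen.get(key)
        if first is None:
            seen[key] = m
            kept.append(m)
        else:
            aliases[ids[m]] = ids[first]
    return FilterResult(np.array(kept, dtype=int), n_low, len(aliases), aliases)


def build_design(codes_col: np.ndarray, model: str
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Design for one marker: intercept + one indicator per allelic state.

    Lines with undetermined state (missing call or unresolved local
    ancestry) are dropped marker-wise; the returned boolean mask marks
    the lines kept.  The design is deliberately rank-deficient (the
    state indicators sum to the intercept); estimable contrasts are
    unaffected by the generalized-inverse convention downstream.
    """
    valid = codes_col != MISSING
    space = STATE_SPACE[model]
    sub = codes_col[valid]
    X = np.zeros((sub.size, 1 + len(space)))
    X[:, 0] = 1.0
    X[np.arange(sub.size), 1 + sub] = 1.0
    return X, valid


# ---------------------------------------------------------------------------
# FDR and QTL clustering
# ---------------------------------------------------------------------------


def control_fdr(results: pd.DataFrame, levels=(0.05, 0.20),
                method: str = "fdr_bh") -> pd.DataFrame:
    """BH step-up applied once to the pooled p-values of a strategy.

    Adds a ``q`` column and one boolean ``significant_<pct>`` column per
    level.  ``method='fdr_tsbh'`` selects the adaptive two-stage variant.
    """
    out = results.copy()
    p = out["p"].to_numpy()
    if len(p) == 0:
        out["q"] = np.array([], dtype=float)
        for lv in levels:
            out[f"significant_{int(round(lv * 100))}"] = np.array([], bool)
        return out
    out["q"] = multipletests(p, method=method)[1]
    for lv in levels:
        rej = multipletests(p, alpha=lv, method=method)[0]
        out[f"significant_{int(round(lv * 100))}"] = rej
    return out


@dataclass
class QTLCluster:
    chromosome: str
    hypothesis: str
    members: list
    positions: list
    lead_marker: str
    lead_p: float

    @property
    def span(self) -> int:
        return int(max(self.positions) - min(self.positions))


def cluster_qtls(significant: pd.DataFrame, window: int = QTL_WINDOW_BP
                 ) -> list[QTLCluster]:
    """Chain significant SNPs of one hypothesis into QTLs.

    Single-linkage along each chromosome: consecutive significant
    markers at most ``window`` bp apart join one cluster.  The lead
    marker has the smallest p (ties: smaller position).
    """
    clusters: list[QTLCluster] = []
    for (hyp, chrom), sub in significant.groupby(["hypothesis", "chromosome"],
                                                 sort=False):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window)
        start = 0
        for stop in list(breaks + 1) + [len(sub)]:
            chunk = sub.iloc[start:stop]
            lead = chunk.sort_values(["p", "position"]).iloc[0]
            clusters.append(QTLCluster(
                chromosome=str(chrom), hypothesis=str(hyp),
                members=list(chunk["marker_id"]),
                positions=[int(x) for x in chunk["position"]],
                lead_marker=str(lead["marker_id"]), lead_p=float(lead["p"]),
            ))
            start = stop
    return clusters


def merge_clusters(clusters: list[QTLCluster]) -> list[list[QTLCluster]]:
    """Group per-hypothesis clusters that share markers (model-level QTLs).

    A SNP may be detected by several tests; overlapping clusters count
    as one locus for model-level QTL totals.
    """
    merged: list[tuple[set, list[QTLCluster]]] = []
    for cl in clusters:
        mem = set(cl.members)
        hits = [g for g in merged if g[0] & mem and g[1][0].chromosome == cl.chromosome]
        if hits:
            base = hits[0]
            for other in hits[1:]:
                base[0].update(other[0])
                base[1].extend(other[1])
                merged.remove(other)
            base[0].update(mem)
            base[1].append(cl)
        else:
            merged.append((mem, [cl]))
    return [g[1] for g in merged]


# ---------------------------------------------------------------------------
# the run loop
# ---------------------------------------------------------------------------


@dataclass
class GWASResult:
    model: str
    results: pd.DataFrame            # marker x hypothesis rows
    filter: FilterResult
    fit: PolygenicFit
    lines: list
    n_failed_markers: int = 0

    def significant(self, level_pct: int = 5) -> pd.DataFrame:
        return self.results[self.results[f"significant_{level_pct}"]]


def _analysis_lines(G: GenotypeMatrix, pedigree: Pedigree, model: str,
                    group: str | None, pooled: bool = False) -> list[str]:
    bg = pedigree.background_of(G.lines)
    if model == "M1":
        if pooled:
            return list(G.lines)
        if group is None:
            present = set(bg)
            if len(present) != 1:
                raise DataError(
                    "M1 needs group='D' or 'F' on a multi-background panel")
            group = present.pop()
        return [l for l, b in zip(G.lines, bg) if b == group]
    if model == "M2":
        return [l for l, b in zip(G.lines, bg) if b in ("D", "F")]
    if model == "M3":
        return list(G.lines)
    raise DataError(f"unknown model {model!r}")


def run_gwas(y: pd.Series | np.ndarray, G: GenotypeMatrix, pedigree: Pedigree,
             tracks=None, model: str = "M3", group: str | None = None,
             kset: KinshipSet | None = None, fit: PolygenicFit | None = None,
             min_count: int = MIN_STATE_CARRIERS,
             fdr_levels=(0.05, 0.20), fdr_method: str = "fdr_bh",
             reestimate_scale: bool = True, refit_reml: bool = False,
             warm_start=None, test_markers=None,
             m1_pooled: bool = False) -> GWASResult:
    """Run one GWAS strategy end to end on a complete genotype panel.

    ``y`` is a pandas Series indexed by line id (or an array aligned to
    ``G.lines``).  The null polygenic model is fitted once by ReML
    (unless ``fit`` is given), its variance parameters are plugged into
    V = G + R, and every battery contrast is Wald-tested per kept SNP.
    With ``refit_reml`` the variance parameters are re-estimated per SNP
    (the exact, much slower, one-step fit).  ``test_markers`` restricts
    the per-SNP testing to the given marker ids (filtering and the null
    fit still use the whole panel).  ``m1_pooled`` applies M1 to the
    whole multi-background panel with a genetic-background fixed effect
    added to the design (off by default).
    """
    lines = _analysis_lines(G, pedigree, model, group, pooled=m1_pooled)
    subG = G.subset_lines(lines)
    if isinstance(y, pd.Series):
        yv = y.reindex(lines).to_numpy(float)
        if np.isnan(yv).any():
            raise DataError("phenotype missing for some analyzed lines")
    else:
        yv = np.asarray(y, float)
        if len(yv) == len(G.lines) and len(lines) != len(G.lines):
            idx = {l: i for i, l in enumerate(G.lines)}
            yv = yv[[idx[l] for l in lines]]
    if len(yv) != len(lines):
        raise DataError("phenotype vector does not match analyzed lines")

    codes = io_core.state_code_matrix(subG, pedigree, tracks, model)
    filt = filter_snps(codes, subG.markers, model, min_count=min_count)

    if kset is None:
        kset = kinship_matrix(subG, pedigree, mode="by-background")
    bg = pedigree.background_of(lines)
    groups = [k for k in ("D", "A", "F") if (bg == k).any()]
    X0 = np.stack([(bg == k).astype(float) for k in groups], axis=1)
    if fit is None:
        fit = mixedmodel.reml_fit(yv, X0, kset, warm_start=warm_start)
    plugged = mixedmodel.plug_covariances(fit, kset)
    V = plugged.V
    Vi = np.linalg.inv(V)

    specs = battery(model)
    mm = subG.markers
    tested = filt.kept
    if test_markers is not None:
        want = set(test_markers)
        tested = np.array([m for m in filt.kept if mm.marker_ids[m] in want],
                          dtype=int)
    rows = []
    n_failed = 0
    bg_cols = np.stack([(bg == k).astype(float) for k in groups], axis=1) \
        if (m1_pooled and model == "M1") else None
    for m in tested:
        X, valid = build_design(codes[:, m], model)
        if bg_cols is not None:
            X = np.hstack([X, bg_cols[valid]])
        try:
            if valid.all():
                gls = mixedmodel.gls_fit(yv, X, Vi=Vi,
                                         reestimate_scale=reestimate_scale)
            else:
                Vi_sub = np.linalg.inv(V[np.ix_(valid, valid)])
                gls = mixedmodel.gls_fit(yv[valid], X, Vi=Vi_sub,
                                         reestimate_scale=reestimate_scale)
            if refit_reml:
                sub_kset = _subset_kset(kset, valid)
                mfit = mixedmodel.reml_fit(yv[valid], X[:, 1:], sub_kset,
                                           warm_start=fit.theta)
                mV = _assemble_v(mfit, sub_kset)
                gls = mixedmodel.gls_fit(yv[valid], X, Vi=np.linalg.inv(mV),
                                         reestimate_scale=False)
            for spec in specs:
                c = spec.design_coefficients()
                if bg_cols is not None:
                    c = np.concatenate([c, np.zeros(bg_cols.shape[1])])
                res = mixedmodel.wald_contrast(gls, c)
                rows.append((mm.marker_ids[m], mm.chromosomes[m],
                             int(mm.positions[m]), model, spec.name, spec.type,
                             spec.interaction, res.estimate, res.se, res.wald,
                             res.p))
        except (ModelError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            log.warning("marker %s skipped: %s", mm.marker_ids[m], exc)
    results = pd.DataFrame(rows, columns=[
        "marker_id", "chromosome", "position", "model", "hypothesis", "type",
        "interaction", "estimate", "se", "wald", "p"])
    results = control_fdr(results, levels=fdr_levels, method=fdr_method)
    return GWASResult(model, results, filt, fit, lines, n_failed)


def _subset_kset(kset: KinshipSet, valid: np.ndarray) -> KinshipSet:
    return KinshipSet(kset.K[np.ix_(valid, valid)],
                      [l for l, v in zip(kset.lines, valid) if v],
                      kset.backgrounds[valid], kset.mode)


def _assemble_v(fit: PolygenicFit, kset: KinshipSet) -> np.ndarray:
    return mixedmodel.plug_covariances(fit, kset).V
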