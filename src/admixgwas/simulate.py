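"""Synthetic two-group panels with admixed DH progeny and QTL regimes.

Founders of the two pure groups are drawn under the Balding-Nichols
model: an ancestral allele frequency p_m ~ Uniform(0.05, 0.95) per
marker, group frequencies f_D, f_F ~ Beta with mean p_m and variance
F_ST p_m (1 - p_m), and one Bernoulli(f_k) call per fully inbred line.
Admixed doubled haploids are produced by a single simulated meiosis of
a D x F F1 (crossovers Poisson per chromosome genetic length, uniform
positions) followed by genome doubling, so each admixed line is a
fully homozygous D/F mosaic with a known ancestry track.

Phenotypes follow the structured polygenic model: QTL state effects
plus a polygenic draw with covariance Sigma_G[blocks] o K plus white
noise.  QTL regimes map to characteristic allele-effect patterns over
the base contrasts (Delta_DD, Delta_DA, Delta_FA, Delta_FF):

==========================  ==============================================
regime                      allele-1 effect
==========================  ==============================================
conserved                   (b, b, b, b): same everywhere
ancestry_divergent          (b, b, -b, -b): depends on ancestry only
background_interacting      (b, -b, -b, b): reverses between pure and
                            admixed backgrounds (epistasis with the
                            genetic background)
admixed_only                (0, b, b, 0): expressed only in admixed lines
background_linear           b * (genome-wide D proportion of the line)
background_epistatic        b when the line carries allele 1 at a
                            designated group-differentiated modifier locus
==========================  ==============================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io_core
from .io_core import (AncestryTrack, GenotypeMatrix, LineInfo, MarkerMap,
                      Pedigree)
from .kinship import KinshipSet, kinship_matrix

STATE_REGIMES = {
    "conserved": (1, 1, 1, 1),
    "ancestry_divergent": (1, 1, -1, -1),
    "background_interacting": (1, -1, -1, 1),
    "admixed_only": (0, 1, 1, 0),
}


@dataclass
class QTLSpec:
    marker_index: int | None             # None: auto-pick an eligible marker
    regime: str
    effect: float
    state_effects: tuple | None = None   # explicit (DD, DA, FA, FF) override
    modifier_index: int | None = None    # for background_epistatic


@dataclass
class SimConfig:
    """Study conditions for one synthetic panel."""

    seed: int = 0
    n_dent: int = 100
    n_flint: int = 100
    n_admixed: int = 100
    n_markers: int = 2000
    n_chromosomes: int = 10
    genetic_length: float = 1.6          # Morgan per chromosome
    physical_length: int = 200_000_000   # bp per chromosome
    fst: float = 0.1
    freq_range: tuple = (0.05, 0.95)
    sigma_G: np.ndarray = field(
        default_factory=lambda: 0.7 * np.ones((3, 3)) + 0.3 * np.eye(3))
    sigma2_E: float = 1.0
    qtls: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "sigma_G" in d:
            d["sigma_G"] = np.asarray(d["sigma_G"], float)
        if "qtls" in d:
            d["qtls"] = [q if isinstance(q, QTLSpec) else QTLSpec(**q)
                         for q in d["qtls"]]
        return cls(**d)


@dataclass
class SimTruth:
    qtl_effects: list                 # (QTLSpec, realized per-line effects)
    sigma_G: np.ndarray
    sigma2_E: float
    seed: int


@dataclass
class SimPanel:
    genotypes: GenotypeMatrix         # all lines, canonical order
    pedigree: Pedigree
    tracks: dict                      # admixed line -> AncestryTrack
    phenotypes: pd.Series | None
    truth: SimTruth | None
    config: SimConfig


def _marker_map(cfg: SimConfig, rng) -> MarkerMap:
    per = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per[: cfg.n_markers % cfg.n_chromosomes] += 1
    ids, chroms, poss = [], [], []
    for c in range(cfg.n_chromosomes):
        n = per[c]
        spacing = cfg.physical_length / (n + 1)
        base = spacing * (1 + np.arange(n))
        jitter = rng.uniform(-0.4, 0.4, n) * spacing
        pos = np.round(base + jitter).astype(np.int64)
        poss.extend(pos)
        chroms.extend([f"chr{c + 1}"] * n)
        ids.extend(f"chr{c + 1}_m{i + 1}" for i in range(n))
    return MarkerMap(ids, chroms, poss)


def simulate_founders(cfg: SimConfig, rng=None
                      ) -> tuple[GenotypeMatrix, Pedigree, np.ndarray]:
    """Balding-Nichols founders of the two pure groups.

    Returns the pure-line genotypes (D block then F block), their
    pedigree, and the (2, M) matrix of realized group frequencies.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    mmap = _marker_map(cfg, rng)
    M = len(mmap)
    p = rng.uniform(*cfg.freq_range, M)
    if cfg.fst > 0:
        a = p * (1 - cfg.fst) / cfg.fst
        b = (1 - p) * (1 - cfg.fst) / cfg.fst
        f = rng.beta(np.broadcast_to(a, (2, M)), np.broadcast_to(b, (2, M)))
    else:
        f = np.broadcast_to(p, (2, M)).copy()
    dent = (rng.random((cfg.n_dent, M)) < f[0]).astype(np.int8)
    flint = (rng.random((cfg.n_flint, M)) < f[1]).astype(np.int8)
    lines = ([f"D{i + 1:03d}" for i in range(cfg.n_dent)]
             + [f"F{i + 1:03d}" for i in range(cfg.n_flint)])
    G = GenotypeMatrix(lines, mmap, np.vstack([dent, flint]))
    ped = Pedigree([LineInfo(l, "D") for l in lines[: cfg.n_dent]]
                   + [LineInfo(l, "F") for l in lines[cfg.n_dent:]])
    return G, ped, f


def _meiosis_segments(cfg: SimConfig, rng) -> list[tuple[int, int, int]]:
    """Crossover mosaic of one gamete on one chromosome.

    Returns closed 1-based (start, end, phase) with phase 0/1 choosing
    the transmitting parent; crossover count ~ Poisson(genetic length).
    """
    L = cfg.physical_length
    n_co = rng.poisson(cfg.genetic_length)
    cuts = np.sort(rng.integers(1, L, n_co)) if n_co else np.array([], int)
    phase = int(rng.integers(2))
    segs = []
    start = 1
    for cut in cuts:
        if cut >= start:
            segs.append((start, int(cut), phase))
            start = int(cut) + 1
        phase = 1 - phase
    segs.append((start, L, phase))
    # merge zero-length artifacts / adjacent same-phase segments
    merged = [segs[0]]
    for s in segs[1:]:
        if s[2] == merged[-1][2]:
            merged[-1] = (merged[-1][0], s[1], s[2])
        else:
            merged.append(s)
    return merged


def simulate_dh(G_pure: GenotypeMatrix, ped_pure: Pedigree, cfg: SimConfig,
                rng=None) -> tuple[GenotypeMatrix, Pedigree, dict]:
    """Admixed DH progeny: one recombinant D x F gamete, doubled.

    Parent pairs are drawn uniformly at random (a sparse factorial).
    Returns the full panel (pure + admixed, canonical line order), the
    extended pedigree and the true ancestry tracks.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    dents = ped_pure.lines_with_background("D")
    flints = ped_pure.lines_with_background("F")
    mmap = G_pure.markers
    chrom_names = list(dict.fromkeys(mmap.chromosomes))
    rows, tracks, entries = [], {}, []
    for i in range(cfg.n_admixed):
        pd_id = dents[rng.integers(len(dents))]
        pf_id = flints[rng.integers(len(flints))]
        line = f"A{i + 1:03d}"
        track = AncestryTrack(line)
        row = np.empty(len(mmap), dtype=np.int8)
        for chrom in chrom_names:
            sel = mmap.chromosomes == chrom
            pos = mmap.positions[sel]
            segs = []
            for start, end, phase in _meiosis_segments(cfg, rng):
                origin = "D" if phase == 0 else "F"
                parent = pd_id if phase == 0 else pf_id
                segs.append((start, end, origin, parent))
            track.segments[chrom] = segs
            origin_code = track.origin_codes(chrom, pos)
            src = np.where(origin_code == 0, G_pure.row(pd_id)[sel],
                           G_pure.row(pf_id)[sel])
            row[sel] = src
        track.validate()
        tracks[line] = track
        rows.append(row)
        entries.append(LineInfo(line, "A", pd_id, pf_id))
    ped = Pedigree(ped_pure.entries + entries)
    all_lines = G_pure.lines + [e.line_id for e in entries]
    calls = np.vstack([G_pure.calls] + [r[None, :] for r in rows]) \
        if rows else G_pure.calls
    order = io_core.canonical_line_order(all_lines, ped)
    G = GenotypeMatrix(all_lines, mmap, calls).subset_lines(order)
    return G, ped, tracks


def simulate_phenotypes(G: GenotypeMatrix, ped: Pedigree, tracks: dict,
                        cfg: SimConfig, rng=None,
                        kset: KinshipSet | None = None
                        ) -> tuple[pd.Series, SimTruth]:
    """QTL effects + polygenic draw + white noise, per the polygenic model."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    n = G.n_lines
    bg = ped.background_of(G.lines)
    groups = [k for k in ("D", "A", "F") if (bg == k).any()]
    gidx = np.array([groups.index(b) for b in bg])
    sub_sigma = np.asarray(cfg.sigma_G, float)
    if sub_sigma.shape[0] == 3 and len(groups) < 3:
        full_order = ["D", "A", "F"]
        sel = [full_order.index(g) for g in groups]
        sub_sigma = sub_sigma[np.ix_(sel, sel)]

    y = np.zeros(n)
    qtl_records = []
    if cfg.qtls:
        codes = io_core.state_code_matrix(G, ped, tracks, "M3")
        prop_d = np.array([
            tracks[l].group_proportion("D") if b == "A" else (1.0 if b == "D" else 0.0)
            for l, b in zip(G.lines, bg)])
        for q in cfg.qtls:
            allele1 = G.calls[:, q.marker_index] == 1
            if q.regime in STATE_REGIMES or q.state_effects is not None:
                pat = np.array(q.state_effects if q.state_effects is not None
                               else STATE_REGIMES[q.regime], float) * \
                    (1.0 if q.state_effects is not None else q.effect)
                # map M3 state code -> base combo index (DD,DA,FA,FF)
                combo = codes[:, q.marker_index] // 2
                eff = np.where(allele1 & (codes[:, q.marker_index] >= 0),
                               pat[np.clip(combo, 0, 3)], 0.0)
            elif q.regime == "background_linear":
                eff = np.where(allele1, q.effect * prop_d, 0.0)
            elif q.regime == "background_epistatic":
                if q.modifier_index is None:
                    raise ValueError("background_epistatic needs modifier_index")
                mod = G.calls[:, q.modifier_index] == 1
                eff = np.where(allele1 & mod, q.effect, 0.0)
            else:
                raise ValueError(f"unknown QTL regime {q.regime!r}")
            y += eff
            qtl_records.append((q, eff))

    if np.any(sub_sigma != 0):
        if kset is None:
            kset = kinship_matrix(G, ped, mode="by-background")
        cov = sub_sigma[gidx[:, None], gidx[None, :]] * kset.K
        cov[np.diag_indices_from(cov)] += 1e-8
        y += np.linalg.cholesky(cov) @ rng.standard_normal(n)
    y += np.sqrt(cfg.sigma2_E) * rng.standard_normal(n)
    pheno = pd.Series(y, index=G.lines, name="trait")
    truth = SimTruth(qtl_records, sub_sigma, cfg.sigma2_E, cfg.seed)
    return pheno, truth


def simulate_panel(cfg: SimConfig) -> SimPanel:
    """Founders -> DH progeny -> phenotypes, all from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    G_pure, ped_pure, _f = simulate_founders(cfg, rng)
    G, ped, tracks = simulate_dh(G_pure, ped_pure, cfg, rng)
    pheno, truth = simulate_phenotypes(G, ped, tracks, cfg, rng)
    return SimPanel(G, ped, tracks, pheno, truth, cfg)


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def experiment_null_fdr(cfg: SimConfig, n_reps: int = 20, level: float = 0.05,
                        model: str = "M3", seed: int = 0,
                        fdr_method: str = "fdr_bh") -> pd.DataFrame:
    """Replicated null experiment: realized false-discovery proportion.

    Phenotypes carry no SNP effects, so every discovery is false and the
    per-replicate FDP is 1 when anything is declared significant at the
    nominal level, 0 otherwise; its mean over replicates estimates the
    FDR actually delivered by the joint step-up control.
    """
    from dataclasses import replace

    from .gwas import run_gwas

    rows = []
    warm = None
    for rep, s in enumerate(_rep_seeds(seed, n_reps)):
        panel = simulate_panel(replace(cfg, seed=int(s), qtls=[]))
        res = run_gwas(panel.phenotypes, panel.genotypes, panel.pedigree,
                       panel.tracks, model=model, fdr_levels=(level,),
                       fdr_method=fdr_method, warm_start=warm)
        warm = res.fit.theta
        n_disc = int(res.results[f"significant_{int(round(level * 100))}"].sum())
        rows.append((rep, len(res.results), n_disc,
                     1.0 if n_disc > 0 else 0.0))
    return pd.DataFrame(rows, columns=["rep", "n_tests", "n_discoveries", "fdp"])


def experiment_power(cfg: SimConfig, n_reps: int = 50, alpha: float = 0.05,
                     models=("M1", "M3"), seed: int = 0) -> pd.DataFrame:
    """Replicated power experiment at the planted QTL markers.

    Each replicate simulates a fresh panel under ``cfg`` (which must
    plant at least one QTL), runs the requested strategies, and records
    the p-value of every battery hypothesis at each QTL marker.  Power
    per hypothesis is the fraction of replicates with p < ``alpha``
    among those where the marker survived filtering; replicates where a
    strategy filtered the marker out count as non-detections (p = 1).
    """
    from dataclasses import replace

    from .gwas import run_gwas

    if not cfg.qtls:
        raise ValueError("experiment_power needs at least one planted QTL")
    rows = []
    warms: dict = {}
    for rep, s in enumerate(_rep_seeds(seed, n_reps)):
        panel = panel_with_eligible_qtls(replace(cfg, seed=int(s)))
        qtl_ids = [panel.genotypes.markers.marker_ids[q.marker_index]
                   for q in panel.config.qtls]
        runs = []
        if "M1" in models:
            runs += [("M1", "D"), ("M1", "F")]
        for mdl in models:
            if mdl != "M1":
                runs.append((mdl, None))
        for mdl, grp in runs:
            key = (mdl, grp)
            res = run_gwas(panel.phenotypes, panel.genotypes, panel.pedigree,
                           panel.tracks, model=mdl, group=grp,
                           warm_start=warms.get(key), test_markers=qtl_ids)
            warms[key] = res.fit.theta
            for qid in qtl_ids:
                sub = res.results[res.results["marker_id"] == qid]
                if len(sub) == 0:  # filtered out: counts as a miss
                    for spec in _battery_names(mdl):
                        rows.append((rep, mdl, grp, qid, spec, 1.0, False))
                else:
                    for r in sub.itertuples():
                        rows.append((rep, mdl, grp, qid, r.hypothesis,
                                     float(r.p), True))
    df = pd.DataFrame(rows, columns=["rep", "model", "group", "marker_id",
                                     "hypothesis", "p", "tested"])
    df["detected"] = df["p"] < alpha
    return df


def panel_with_eligible_qtls(cfg: SimConfig) -> SimPanel:
    """Simulate a panel resolving ``marker_index=None`` QTLs to eligible markers.

    A planted QTL only yields a meaningful power comparison when the
    marker survives every strategy's carrier filter; the M3 filter (all
    8 states with >= 10 carriers) is the strictest, so auto-picked QTL
    markers are the M3-eligible markers nearest the center of each
    chromosome, one per QTL, in chromosome order.
    """
    from .gwas import MIN_STATE_CARRIERS

    rng = np.random.default_rng(cfg.seed)
    G_pure, ped_pure, _f = simulate_founders(cfg, rng)
    G, ped, tracks = simulate_dh(G_pure, ped_pure, cfg, rng)
    qtls = list(cfg.qtls)
    if any(q.marker_index is None for q in qtls):
        codes = io_core.state_code_matrix(G, ped, tracks, "M3")
        counts = np.stack([(codes == s).sum(axis=0) for s in range(8)], axis=1)
        eligible = np.flatnonzero(counts.min(axis=1) >= MIN_STATE_CARRIERS)
        if eligible.size < len(qtls):
            raise ValueError("not enough filter-eligible markers to plant QTLs")
        chroms = G.markers.chromosomes
        pos = G.markers.positions
        picks: list[int] = []
        chrom_names = list(dict.fromkeys(chroms))
        for i, q in enumerate(qtls):
            if q.marker_index is not None:
                continue
            chrom = chrom_names[i % len(chrom_names)]
            on_c = eligible[chroms[eligible] == chrom]
            cand = on_c if on_c.size else eligible
            cand = cand[~np.isin(cand, picks)]
            mid = (pos[cand] - pos[cand].mean()) if cand.size else None
            pick = int(cand[np.argmin(np.abs(mid))])
            picks.append(pick)
            qtls[i] = replace_qtl(q, pick)
    cfg = _replace_cfg(cfg, qtls)
    pheno, truth = simulate_phenotypes(G, ped, tracks, cfg, rng)
    return SimPanel(G, ped, tracks, pheno, truth, cfg)


def replace_qtl(q: QTLSpec, marker_index: int) -> QTLSpec:
    return QTLSpec(marker_index, q.regime, q.effect, q.state_effects,
                   q.modifier_index)


def _replace_cfg(cfg: SimConfig, qtls: list) -> SimConfig:
    from dataclasses import replace

    return replace(cfg, qtls=qtls)


def _battery_names(model: str) -> list[str]:
    from .gwas import battery

    return [s.name for s in battery(model)]


def power_summary(power_df: pd.DataFrame) -> pd.DataFrame:
    """Power per (model, group, hypothesis) from :func:`experiment_power`."""
    return (power_df.groupby(["model", "group", "hypothesis"], dropna=False)
            ["detected"].mean().rename("power").reset_index())


def experiment_fdr_power(configs: dict, models=("M1", "M3"), n_reps: int = 20,
                         level: float = 0.05, alpha: float = 0.05,
                         seed: int = 0) -> pd.DataFrame:
    """Summary over a grid of study conditions.

    ``configs`` maps a condition name to a :class:`SimConfig`; configs
    without QTLs contribute empirical FDR rows, configs with QTLs
    contribute per-hypothesis power rows.
    """
    out = []
    for name, cfg in configs.items():
        if cfg.qtls:
            pw = power_summary(experiment_power(
                cfg, n_reps=n_reps, alpha=alpha, models=models, seed=seed))
            pw.insert(0, "condition", name)
            pw["metric"] = "power"
            pw = pw.rename(columns={"power": "value"})
            out.append(pw)
        else:
            for mdl in models:
                if mdl == "M1":
                    continue  # null FDR evaluated for the joint strategies
                fdr = experiment_null_fdr(cfg, n_reps=n_reps, level=level,
                                          model=mdl, seed=seed)
                out.append(pd.DataFrame([{
                    "condition": name, "model": mdl, "group": None,
                    "hypothesis": "all", "value": float(fdr["fdp"].mean()),
                    "metric": "empirical_fdr"}]))
    return pd.concat(out, ignore_index=True)


def shared_panel(G: GenotypeMatrix, every: int = 10) -> GenotypeMatrix:
    """Thin a dense panel to a low-density shared panel (every k-th marker)."""
    idx = np.arange(0, G.n_markers, every)
    mmap = G.markers
    sub_map = MarkerMap(mmap.marker_ids[idx], mmap.chromosomes[idx],
                        mmap.positions[idx])
    return GenotypeMatrix(list(G.lines), sub_map, G.calls[:, idx])
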