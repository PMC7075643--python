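"""Additive + pairwise-epistatic variance decomposition.

The joint panel is modeled ignoring group structure,

    y = 1 mu + g + g_e + e,
    g   ~ N(0, K sigma2_G),
    g_e ~ N(0, (K o K) sigma2_GxG),
    e   ~ N(0, I sigma2_E),

with K the common-frequency kinship and K o K its Hadamard square,
whose entries capture identity at pairs of loci (the lines are fully
homozygous, so no dominance terms arise).  The epistatic component is
tested by a likelihood-ratio test between this model and the one
without g_e; because sigma2_GxG sits on the boundary of its space under
the null, the default reference distribution is the equal mixture
0.5 chi2(0) + 0.5 chi2(1) (plain chi2(1) is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_core import DataError
from .kinship import KinshipSet
from .mixedmodel import reml_components


@dataclass
class EpistasisFit:
    sigma2_G: float
    sigma2_GxG: float
    sigma2_E: float
    loglik_full: float
    loglik_reduced: float
    lr: float
    p: float
    converged: bool
    boundary: bool


def epistasis_test(y: np.ndarray, kset: KinshipSet,
                   null_dist: str = "mixture") -> EpistasisFit:
    """ReML fit of additive+epistatic vs additive model, LR test.

    ``kset`` must be computed in common-frequency mode (the model
    neglects genetic structure on purpose).
    """
    if kset.mode != "common":
        raise DataError("epistasis decomposition expects a common-frequency kinship")
    y = np.asarray(y, float)
    n = len(y)
    K = kset.K
    KK = K * K  # Hadamard square: entries K[i,j]^2
    X = np.ones((n, 1))
    full = reml_components(y, X, [K, KK, np.eye(n)],
                           ["sigma2_G", "sigma2_GxG", "sigma2_E"])
    red = reml_components(y, X, [K, np.eye(n)], ["sigma2_G", "sigma2_E"])
    lr = max(0.0, 2.0 * (full.loglik - red.loglik))
    if null_dist == "mixture":
        p = 0.5 * float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    elif null_dist == "chi2":
        p = float(stats.chi2.sf(lr, df=1))
    else:
        raise ValueError(f"unknown null_dist {null_dist!r}")
    return EpistasisFit(
        sigma2_G=full.variances["sigma2_G"],
        sigma2_GxG=full.variances["sigma2_GxG"],
        sigma2_E=full.variances["sigma2_E"],
        loglik_full=full.loglik,
        loglik_reduced=red.loglik,
        lr=lr, p=p,
        converged=full.converged and red.converged,
        boundary=full.boundary,
    )
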