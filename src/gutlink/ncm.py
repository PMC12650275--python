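"""Sloan neutral community model: fit and simulator.

The model predicts a taxon's occurrence frequency across samples from its
mean relative abundance p under purely neutral dispersal: with detection
limit d = 1/N (N = mean sample depth), the predicted frequency is the upper
tail of Beta(Nm*p, Nm*(1-p)) beyond d, where Nm is the metacommunity-size x
migration product. Nm is fitted by least squares between observed and
predicted frequencies; goodness of fit is R^2 = 1 - SSE/SST (negative for
fits worse than the constant model, the 'poor fit' regime of deterministic
assembly). The 95% band is the Wilson binomial interval of the predicted
frequency at the sample count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from statsmodels.stats.proportion import proportion_confint

from .containers import AsvTable

log = logging.getLogger(__name__)


@dataclass
class NcmFit:
    """Fitted neutral model."""

    nm: float                 # metacommunity size x migration rate
    m: float                  # migration rate: Nm / mean depth
    r_squared: float
    detection_limit: float
    table: pd.DataFrame       # taxon, p, obs_freq, pred_freq, lower, upper
    degenerate: bool = False


def predicted_frequency(p: np.ndarray, nm: float, d: float) -> np.ndarray:
    """Occurrence frequency predicted by the Sloan model at detection limit d."""
    p = np.asarray(p, dtype=float)
    a = np.maximum(nm * p, 1e-12)
    b = np.maximum(nm * (1.0 - p), 1e-12)
    return sps.beta.sf(d, a, b)


def fit_ncm(table: AsvTable, min_taxa: int = 5) -> NcmFit:
    """Fit Nm to the occurrence-frequency vs mean-abundance relation.

    Taxa never observed are excluded. Nm is optimized over [1, 1e6] on a
    log scale (bounded scalar minimization of the SSE).
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[0] < 3:
        raise ValueError("neutral-model fit needs at least 3 samples")
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("all-zero sample in table")
    rel = counts / totals
    p = rel.mean(axis=0)
    keep = p > 0
    p = p[keep]
    taxa = np.asarray(table.asv_ids)[keep]
    if len(p) < min_taxa:
        raise ValueError(f"need at least {min_taxa} taxa with nonzero mean abundance")
    freq = (counts[:, keep] > 0).mean(axis=0)
    n_depth = float(totals.mean())
    d = 1.0 / n_depth

    def sse(log_nm: float) -> float:
        pred = predicted_frequency(p, float(np.exp(log_nm)), d)
        return float(((freq - pred) ** 2).sum())

    res = minimize_scalar(sse, bounds=(0.0, np.log(1e6)), method="bounded")
    nm = float(np.exp(res.x))
    pred = predicted_frequency(p, nm, d)
    sst = float(((freq - freq.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else float("nan")
    degenerate = bool((freq >= 1.0).all())
    if degenerate:
        log.warning("all taxa occur in every sample; neutral fit is degenerate")
    n_samples = counts.shape[0]
    lower, upper = proportion_confint(
        np.round(pred * n_samples), n_samples, alpha=0.05, method="wilson"
    )
    frame = pd.DataFrame(
        {
            "taxon": taxa,
            "p": p,
            "obs_freq": freq,
            "pred_freq": pred,
            "lower": lower,
            "upper": upper,
        }
    ).set_index("taxon")
    return NcmFit(
        nm=nm,
        m=nm / n_depth,
        r_squared=float(r2),
        detection_limit=d,
        table=frame,
        degenerate=degenerate,
    )


def simulate_ncm(
    n_taxa: int, nm: float, depth: int, n_samples: int, seed: int = 0
) -> AsvTable:
    """Community drawn from the Sloan stationary distribution.

    A fixed lognormal metacommunity abundance vector p; per-sample
    proportions ~ Dirichlet(Nm * p) (whose marginals are the Sloan
    Beta(Nm*p_i, Nm*(1-p_i))); counts multinomial at ``depth``.
    """
    if min(n_taxa, depth, n_samples) <= 0 or nm <= 0:
        raise ValueError("all parameters must be positive")
    rng = np.random.default_rng(seed)
    meta = rng.lognormal(0.0, 2.0, size=n_taxa)
    meta /= meta.sum()
    alpha = np.maximum(nm * meta, 1e-9)
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for i in range(n_samples):
        props = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depth, props)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    width = len(str(n_taxa))
    frame = pd.DataFrame(
        counts, index=samples, columns=[f"T{j + 1:0{width}d}" for j in range(n_taxa)]
    )
    groups = pd.Series({s: "sim" for s in samples})
    return AsvTable(frame, groups)
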