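"""Sloan neutral community model fit to occurrence-frequency data.

Under neutral dynamics with immigration, the stationary relative
abundance of a taxon with metacommunity mean relative abundance p is
Beta(N m p, N m (1 - p)), so the probability of detecting it above a
detection limit d is

    F(p) = 1 - I_d(N m p, N m (1 - p)),

with I the regularized incomplete beta function.  The single free
parameter Nm (community size x migration rate) is fitted by least
squares of observed occurrence frequency on F; m follows by dividing by
the community size N, for which the common per-sample read depth is the
standard observable proxy when the true local community size is
unknown.  Taxa are partitioned against a 95% binomial (Wilson) band
around the fitted curve: those detected more often than the model
predicts sit above it, those detected less often below.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.stats.proportion import proportion_confint

from .io_formats import AbundanceTable

logger = logging.getLogger(__name__)

_LOG10_NM_BOUNDS = (0.0, 7.0)  # Nm searched in [1, 1e7]
_N_STARTS = 5


@dataclass
class NCMFit:
    """Fitted Sloan model plus the per-taxon partition table."""

    nm: float  # N * m
    m: float  # migration rate, nm / community_size
    r_squared: float
    detection_limit: float
    community_size: float
    n_samples: int
    taxa: pd.DataFrame  # p_mean, freq_obs, freq_pred, lower, upper, partition
    degenerate: bool = False  # no occupancy variance to fit
    at_bound: bool = False  # optimizer ended on the Nm search bound
    n_excluded: int = 0  # taxa below the detection limit


def sloan_frequency(p, nm: float, detection_limit: float):
    """Predicted occurrence frequency F(p) at a given Nm."""
    p = np.asarray(p, dtype=float)
    a = nm * p
    b = nm * (1.0 - p)
    return 1.0 - special.betainc(a, b, detection_limit)


def fit_ncm(
    table: AbundanceTable,
    community_size: float | None = None,
    detection_limit: float | None = None,
) -> NCMFit:
    """Fit the neutral model to a (rarefied) count table.

    ``community_size`` defaults to the common per-sample read depth N;
    pass the true local community size when it is known (e.g. on
    simulated data).  ``detection_limit`` defaults to 1/N, one read at
    the common depth.
    """
    if table.n_taxa < 10:
        raise ValueError("need >= 10 taxa to fit the neutral model")
    sums = table.sample_sums()
    n_reads = float(sums.mean())
    if sums.nunique() > 1 and (sums.std() / n_reads) > 0.01:
        logger.warning(
            "sample depths vary by >1%%; rarefy first for a clean detection limit"
        )
    if community_size is None:
        community_size = n_reads
    d = detection_limit if detection_limit is not None else 1.0 / n_reads
    rel = table.relative()
    p_mean = rel.mean(axis=1)
    freq_obs = (table.counts > 0).mean(axis=1)
    usable = p_mean >= d
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("excluding %d taxa with mean abundance below d", n_excluded)
    p_fit = p_mean[usable].to_numpy()
    f_fit = freq_obs[usable].to_numpy()
    if p_fit.size < 10:
        raise ValueError("fewer than 10 taxa above the detection limit")

    degenerate = bool(np.allclose(f_fit, f_fit[0]))
    at_bound = False
    if degenerate:
        logger.warning("no occupancy variance: neutral fit is degenerate")
        nm = np.nan
        f_pred_fit = np.full_like(f_fit, f_fit[0])
        r2 = np.nan
    else:

        def sse(log10_nm: float) -> float:
            resid = f_fit - sloan_frequency(p_fit, 10.0**log10_nm, d)
            return float(resid @ resid)

        # coarse global scan on the log scale, then bounded local
        # refinement from each of the best coarse basins: the SSE
        # surface can be flat or multi-modal when occupancy saturates
        lo, hi = _LOG10_NM_BOUNDS
        grid = np.linspace(lo, hi, 141)
        grid_sse = np.array([sse(g) for g in grid])
        order = np.argsort(grid_sse)[:_N_STARTS]
        best = None
        for i in order:
            a = grid[max(int(i) - 1, 0)]
            b = grid[min(int(i) + 1, len(grid) - 1)]
            res = optimize.minimize_scalar(
                sse, bounds=(a, b), method="bounded", options={"xatol": 1e-8}
            )
            if best is None or res.fun < best[1]:
                best = (float(res.x), float(res.fun))
        if best is None or not np.isfinite(best[1]):
            raise RuntimeError("neutral model optimizer failed to evaluate")
        log10_nm = float(best[0])
        if min(log10_nm - lo, hi - log10_nm) < 1e-6:
            at_bound = True
            logger.warning("fitted Nm sits on the search bound 10^%g", log10_nm)
        nm = 10.0**log10_nm
        f_pred_fit = sloan_frequency(p_fit, nm, d)
        ss_res = float(((f_fit - f_pred_fit) ** 2).sum())
        ss_tot = float(((f_fit - f_fit.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot

    n_samples = table.n_samples
    if np.isnan(nm):
        lower = np.full_like(f_pred_fit, np.nan)
        upper = np.full_like(f_pred_fit, np.nan)
    else:
        lower, upper = proportion_confint(
            np.round(f_pred_fit * n_samples), n_samples, alpha=0.05, method="wilson"
        )
    taxa = pd.DataFrame(
        {
            "p_mean": p_fit,
            "freq_obs": f_fit,
            "freq_pred": f_pred_fit,
            "lower": lower,
            "upper": upper,
        },
        index=p_mean.index[usable],
    )
    taxa["partition"] = np.select(
        [taxa["freq_obs"] > taxa["upper"], taxa["freq_obs"] < taxa["lower"]],
        ["above", "below"],
        default="neutral",
    )
    return NCMFit(
        nm=float(nm),
        m=float(nm / community_size),
        r_squared=float(r2),
        detection_limit=d,
        community_size=float(community_size),
        n_samples=n_samples,
        taxa=taxa,
        degenerate=degenerate,
        at_bound=at_bound,
        n_excluded=n_excluded,
    )


def partition_taxa(fit: NCMFit) -> pd.Series:
    """Per-taxon label: above / neutral / below the 95% prediction band."""
    return fit.taxa["partition"].copy()
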