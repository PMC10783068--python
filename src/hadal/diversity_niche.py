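"""Alpha diversity, Levins niche breadth, and factorial tests.

Shannon entropy is reported in nats so that Pielou's evenness is exactly
H / ln(richness).  Chao1 is the bias-corrected estimator by default,
which stays defined when no doubletons are observed.  Levins breadth
B = 1 / sum(P_ij^2) measures how evenly a taxon spreads across samples
(1 = found in one sample only, n_samples = perfectly uniform).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io_formats import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class NicheBreadth:
    """Per-taxon Levins breadth and its community-level mean."""

    per_taxon: pd.Series  # taxon -> B_i in [1, n_samples]
    bcom: float  # mean of B_i over taxa in the group
    weighted: bool = False


@dataclass
class AnovaResult:
    """Two-way crossed ANOVA (Type-I SS) with Tukey HSD follow-ups."""

    table: pd.DataFrame  # rows: factor_a, factor_b, interaction, residual
    tukey: dict  # factor name -> TukeyHSDResults
    ss_total: float
    zero_mse: bool  # MS_error == 0; F reported as inf


def _chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0  # classic estimator's f2=0 fallback
    return s_obs + f1 * f1 / (2.0 * f2)


def alpha_diversity(
    table: AbundanceTable, bias_corrected_chao1: bool = True, base: float = np.e
) -> pd.DataFrame:
    """Per-sample richness, Chao1, Shannon, Simpson and Pielou evenness.

    Pielou is NaN for single-taxon samples, where evenness is undefined.
    """
    out = {}
    log = np.log if base == np.e else (lambda x: np.log(x) / np.log(base))
    for sample in table.sample_ids:
        counts = table.counts[sample].to_numpy()
        total = counts.sum()
        if total == 0:
            raise ValueError(f"sample {sample!r} has zero total count")
        p = counts[counts > 0] / total
        richness = p.size
        shannon = float(-(p * log(p)).sum())
        simpson = float(1.0 - (p**2).sum())
        pielou = shannon / float(log(richness)) if richness > 1 else np.nan
        out[sample] = {
            "richness": richness,
            "chao1": _chao1(counts, bias_corrected_chao1),
            "shannon": shannon,
            "simpson": simpson,
            "pielou": pielou,
        }
    return pd.DataFrame(out).T


def levins_breadth(table: AbundanceTable, weighted: bool = False) -> NicheBreadth:
    """Levins niche breadth per taxon; Bcom aggregates across taxa.

    ``weighted=True`` weights the community mean by taxon total
    abundance instead of the default unweighted mean.
    """
    totals = table.counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("excluding %d zero-total taxa from niche breadth", zero.sum())
    counts = table.counts.loc[~zero]
    prop = counts.div(counts.sum(axis=1), axis=0)
    b = 1.0 / (prop**2).sum(axis=1)
    b.name = "levins_B"
    if weighted:
        w = totals[~zero] / totals[~zero].sum()
        bcom = float((b * w).sum())
    else:
        bcom = float(b.mean())
    return NicheBreadth(b, bcom, weighted)


def two_way_anova(
    values: pd.Series,
    factor_a: pd.Series,
    factor_b: pd.Series,
    tukey: bool = True,
) -> AnovaResult:
    """Crossed two-way ANOVA of a response on two categorical factors.

    Type-I sums of squares (exact decomposition on balanced designs);
    every crossed cell must contain at least one observation.  When the
    residual mean square is zero the F statistics are reported as inf
    and flagged.
    """
    df = pd.DataFrame(
        {
            "y": pd.to_numeric(values),
            "A": factor_a.astype(str),
            "B": factor_b.astype(str),
        }
    ).dropna()
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = df.groupby(["A", "B"], observed=True).size()
    full = pd.MultiIndex.from_product([df["A"].unique(), df["B"].unique()])
    empty = full.difference(cells.index)
    if len(empty) > 0:
        raise ValueError(f"empty design cell(s): {list(empty)}")
    model = ols("y ~ C(A) + C(B) + C(A):C(B)", data=df).fit()
    tab = anova_lm(model, typ=1)
    tab = tab.rename(
        index={
            "C(A)": "factor_a",
            "C(B)": "factor_b",
            "C(A):C(B)": "interaction",
            "Residual": "residual",
        }
    )
    ss_total = float(((df["y"] - df["y"].mean()) ** 2).sum())
    mse = tab.loc["residual", "sum_sq"] / max(tab.loc["residual", "df"], 1)
    zero_mse = bool(np.isclose(mse, 0.0))
    if zero_mse:
        effects = tab.index != "residual"
        tol = 1e-12 * max(ss_total, 1.0)
        nonzero = tab.loc[effects, "sum_sq"] > tol
        tab.loc[effects, "F"] = np.where(nonzero, np.inf, 0.0)
        tab.loc[effects, "PR(>F)"] = np.where(nonzero, 0.0, 1.0)
    tukey_out = {}
    if tukey:
        for name, col in (("factor_a", "A"), ("factor_b", "B")):
            if df.groupby(col, observed=True).size().min() >= 2 and not zero_mse:
                tukey_out[name] = pairwise_tukeyhsd(df["y"], df[col])
    return AnovaResult(tab, tukey_out, ss_total, zero_mse)


def spearman_depth(
    values: pd.Series,
    depth: pd.Series,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation of a per-sample quantity with depth.

    Uses midranks for ties; the p-value is a two-sided permutation test
    (``n_perm`` label permutations) for n < 20 and the large-sample
    t approximation otherwise.  Constant input gives (nan, nan).
    """
    x = pd.to_numeric(values).to_numpy(dtype=float)
    y = pd.to_numeric(depth).to_numpy(dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        logger.warning("constant input: Spearman rho undefined")
        return (np.nan, np.nan)
    rho, p_asym = stats.spearmanr(x, y)
    if x.size >= 20:
        return float(rho), float(p_asym)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(rx)
        if abs(np.corrcoef(perm, ry)[0, 1]) >= obs - 1e-12:
            hits += 1
    return float(rho), (hits + 1) / (n_perm + 1)
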