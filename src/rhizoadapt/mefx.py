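"""Microbial-effect response ratios and reaction-norm slope comparisons.

The microbial effect of a genotype in a glasshouse nitrogen environment is
ME = (live - sterile) / sterile computed from the genotype's cell means; it
is positive when the live soil inoculum increased the trait. Uncertainty is
propagated from the live and sterile cell standard errors either by the
delta method,

    Var(ME) ~= Var(L)/S^2 + L^2 Var(S)/S^4,

or by Monte-Carlo resampling of the cell means (the default for inference,
since the ratio distribution is skewed when the sterile mean is noisy).

Reaction norms regress ME on a standardized genotype-level predictor
(historic soil nitrogen, or a microbiome trait such as diazotroph richness).
Whether the slopes differ between the two glasshouse nitrogen environments is
tested by a parametric bootstrap: every genotype's ME in both environments is
perturbed by its propagated SE, both norms are refit, and the two-sided
P-value is the sign-crossing frequency of the simulated slope difference.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import TraitTable

__all__ = [
    "MicrobialEffectEstimate",
    "SlopeComparison",
    "compute_microbial_effect",
    "propagate_me_uncertainty",
    "fit_reaction_norm",
    "slope_difference_test",
    "me_vs_microbiome",
]

#: Monte-Carlo draws with a sterile mean below this fraction of the observed
#: sterile mean are redrawn (keeps the simulated ratio away from the pole).
STERILE_FLOOR_FRACTION = 0.05

#: Above this coefficient of variation of the sterile mean the ratio
#: distribution is heavy-tailed and a warning is emitted.
CV_WARN = 0.33


@dataclass
class MicrobialEffectEstimate:
    genotype: str
    glasshouse_n: str
    trait: str
    live_mean: float
    sterile_mean: float
    live_se: float
    sterile_se: float
    n_live: int
    n_sterile: int
    me: float
    me_se: float = np.nan
    usable: bool = True


@dataclass
class SlopeComparison:
    predictor: str
    trait: str
    slope_low: float
    slope_low_se: float
    slope_high: float
    slope_high_se: float
    delta: float
    p_value: float
    n_sim: int
    sim_quantiles: dict

    def to_dict(self) -> dict:
        return dict(
            predictor=self.predictor,
            trait=self.trait,
            slope_low=self.slope_low,
            slope_low_se=self.slope_low_se,
            slope_high=self.slope_high,
            slope_high_se=self.slope_high_se,
            delta=self.delta,
            p_value=self.p_value,
            n_sim=self.n_sim,
            sim_quantiles=self.sim_quantiles,
        )


def compute_microbial_effect(
    traits: TraitTable, trait: str, min_reps: int = 2
) -> list[MicrobialEffectEstimate]:
    """ME = (live mean - sterile mean) / sterile mean per genotype and
    glasshouse nitrogen level.

    Cells with fewer than ``min_reps`` plants are dropped with a warning; a
    non-positive sterile mean flags the estimate unusable (the ratio has no
    interpretation there).
    """
    if trait not in traits.data.columns:
        raise KeyError(f"trait {trait!r} not in table")
    out: list[MicrobialEffectEstimate] = []
    df = traits.data.dropna(subset=[trait])
    for (genotype, glasshouse_n), cell in df.groupby(["genotype", "nitrogen"]):
        live = cell.loc[cell["microbe"] == "live", trait].astype(float)
        sterile = cell.loc[cell["microbe"] == "sterile", trait].astype(float)
        if len(live) < min_reps or len(sterile) < min_reps:
            warnings.warn(
                f"genotype {genotype} ({glasshouse_n} N): <{min_reps} reps in a "
                "microbe cell; dropped",
                stacklevel=2,
            )
            continue
        lm, sm = float(live.mean()), float(sterile.mean())
        lse = float(live.std(ddof=1) / np.sqrt(len(live)))
        sse = float(sterile.std(ddof=1) / np.sqrt(len(sterile)))
        usable = sm > 0
        me = (lm - sm) / sm if usable else np.nan
        if not usable:
            warnings.warn(
                f"genotype {genotype} ({glasshouse_n} N): sterile mean <= 0; "
                "microbial effect unusable",
                stacklevel=2,
            )
        out.append(
            MicrobialEffectEstimate(
                genotype=str(genotype), glasshouse_n=str(glasshouse_n),
                trait=trait, live_mean=lm, sterile_mean=sm,
                live_se=lse, sterile_se=sse,
                n_live=len(live), n_sterile=len(sterile),
                me=me, usable=usable,
            )
        )
    return out


def propagate_me_uncertainty(
    est: MicrobialEffectEstimate,
    method: str = "montecarlo",
    n_draws: int = 10000,
    seed: int = 0,
    return_draws: bool = False,
):
    """Standard error of the microbial effect.

    delta: first-order Taylor expansion assuming independent cell means.
    montecarlo: normal draws of both cell means; sterile draws below
    ``STERILE_FLOOR_FRACTION`` of the observed sterile mean are redrawn.
    """
    if not est.usable:
        raise ValueError("cannot propagate uncertainty for an unusable estimate")
    if not (np.isfinite(est.live_se) and np.isfinite(est.sterile_se)):
        raise ValueError("cell standard errors must be finite")
    S, L = est.sterile_mean, est.live_mean
    if est.sterile_se > CV_WARN * abs(S):
        warnings.warn(
            f"sterile-mean CV {est.sterile_se / abs(S):.2f} > {CV_WARN}; the "
            "ratio distribution is heavy-tailed, interpret the SE with care",
            stacklevel=2,
        )
    if method == "delta":
        var = est.live_se**2 / S**2 + L**2 * est.sterile_se**2 / S**4
        se = float(np.sqrt(var))
        return (se, None) if return_draws else se
    if method != "montecarlo":
        raise ValueError("method must be 'delta' or 'montecarlo'")
    if n_draws < 1000:
        raise ValueError("montecarlo propagation needs n_draws >= 1000")
    rng = np.random.default_rng(seed)
    if est.live_se == 0.0 and est.sterile_se == 0.0:
        draws = np.full(n_draws, est.me)
        return (0.0, draws) if return_draws else 0.0
    floor = STERILE_FLOOR_FRACTION * S
    Ld = rng.normal(L, est.live_se, size=n_draws)
    Sd = rng.normal(S, est.sterile_se, size=n_draws)
    bad = Sd <= floor
    while bad.any():
        Sd[bad] = rng.normal(S, est.sterile_se, size=int(bad.sum()))
        bad = Sd <= floor
    draws = (Ld - Sd) / Sd
    se = float(np.std(draws, ddof=1))
    return (se, draws) if return_draws else se


def attach_uncertainty(
    estimates: list[MicrobialEffectEstimate],
    method: str = "montecarlo",
    n_draws: int = 10000,
    seed: int = 0,
) -> list[MicrobialEffectEstimate]:
    """Fill ``me_se`` on each usable estimate (seeded per estimate)."""
    rng = np.random.default_rng(seed)
    for est in estimates:
        if est.usable:
            est.me_se = propagate_me_uncertainty(
                est, method=method, n_draws=n_draws,
                seed=int(rng.integers(2**31 - 1)),
            )
    return estimates


def _ols_line(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: reaction norm undefined")
    if w is None:
        w = np.ones_like(x)
    W = w / w.sum()
    xb = float(np.sum(W * x))
    yb = float(np.sum(W * y))
    sxx = float(np.sum(W * (x - xb) ** 2))
    slope = float(np.sum(W * (x - xb) * (y - yb)) / sxx)
    intercept = yb - slope * xb
    resid = y - (intercept + slope * x)
    dof = max(len(x) - 2, 1)
    se = float(np.sqrt(np.sum(W * resid**2) * len(x) / dof / (len(x) * sxx)))
    return slope, intercept, se


def fit_reaction_norm(
    estimates: list[MicrobialEffectEstimate],
    x: pd.Series,
    weighted: bool = False,
    standardize_x: bool = True,
) -> dict:
    """OLS line of the microbial effect on a genotype-level predictor.

    ``x`` is indexed by genotype and standardized by default; weighting by
    inverse squared ``me_se`` is optional (plain fitted lines are the
    default).
    """
    usable = [e for e in estimates if e.usable]
    if len(usable) < 3:
        raise ValueError("need >= 3 genotypes with usable estimates")
    genos = [e.genotype for e in usable]
    missing = [g for g in genos if g not in x.index]
    if missing:
        raise ValueError(f"predictor missing for genotypes: {missing[:5]}")
    xv = x.loc[genos].to_numpy(float)
    if standardize_x:
        if np.ptp(xv) == 0:
            raise ValueError("constant predictor: reaction norm undefined")
        xv = (xv - xv.mean()) / xv.std(ddof=0)
    me = np.array([e.me for e in usable])
    w = None
    if weighted:
        se = np.array([e.me_se for e in usable])
        if not np.isfinite(se).all() or (se <= 0).any():
            raise ValueError("weighted fit requires positive finite me_se")
        w = 1.0 / se**2
    slope, intercept, se_slope = _ols_line(xv, me, w)
    return dict(slope=slope, intercept=intercept, se=se_slope,
                genotypes=genos, x=xv, me=me)


def _paired_arrays(est_low, est_high, x, standardize_x=True):
    low = {e.genotype: e for e in est_low if e.usable}
    high = {e.genotype: e for e in est_high if e.usable}
    shared = sorted(set(low) & set(high) & set(map(str, x.index)))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genotypes with usable estimates")
    xv = x.loc[shared].to_numpy(float)
    if np.ptp(xv) == 0:
        raise ValueError("constant predictor: slopes undefined")
    if standardize_x:
        xv = (xv - xv.mean()) / xv.std(ddof=0)
    me_l = np.array([low[g].me for g in shared])
    me_h = np.array([high[g].me for g in shared])
    se_l = np.array([low[g].me_se for g in shared])
    se_h = np.array([high[g].me_se for g in shared])
    if not (np.isfinite(se_l).all() and np.isfinite(se_h).all()):
        raise ValueError("all estimates need a propagated me_se before testing")
    return shared, xv, me_l, me_h, se_l, se_h


def slope_difference_test(
    est_low: list[MicrobialEffectEstimate],
    est_high: list[MicrobialEffectEstimate],
    x: pd.Series,
    n_sim: int = 10000,
    seed: int = 0,
    predictor_name: str = "historic_soil_nitrogen",
    standardize_x: bool = True,
) -> SlopeComparison:
    """Parametric-bootstrap test of slope_high - slope_low.

    Each simulation independently perturbs every genotype's ME in both
    environments by its propagated SE, refits both reaction norms, and
    records the slope difference; the two-sided P-value is
    2 * min(Pr(delta* <= 0), Pr(delta* >= 0)) with the (1+b)/(1+n) convention,
    capped at 1.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    shared, xv, me_l, me_h, se_l, se_h = _paired_arrays(
        est_low, est_high, x, standardize_x
    )
    trait = est_low[0].trait if est_low else ""
    xc = xv - xv.mean()
    sxx = float(np.sum(xc**2))

    def slope(me_mat):
        return (me_mat @ xc) / sxx

    s_l, s_h = float(slope(me_l[None, :])[0]), float(slope(me_h[None, :])[0])
    rng = np.random.default_rng(seed)
    sim_l = rng.normal(me_l, se_l, size=(n_sim, len(shared)))
    sim_h = rng.normal(me_h, se_h, size=(n_sim, len(shared)))
    slopes_l = slope(sim_l)
    slopes_h = slope(sim_h)
    delta_sim = slopes_h - slopes_l
    b_le = int(np.sum(delta_sim <= 0))
    b_ge = int(np.sum(delta_sim >= 0))
    p = 2.0 * min((1 + b_le) / (1 + n_sim), (1 + b_ge) / (1 + n_sim))
    p = min(p, 1.0)
    qs = np.quantile(delta_sim, [0.025, 0.25, 0.5, 0.75, 0.975])
    return SlopeComparison(
        predictor=predictor_name,
        trait=trait,
        slope_low=s_l,
        slope_low_se=float(np.std(slopes_l, ddof=1)),
        slope_high=s_h,
        slope_high_se=float(np.std(slopes_h, ddof=1)),
        delta=s_h - s_l,
        p_value=float(p),
        n_sim=n_sim,
        sim_quantiles={
            "q025": float(qs[0]), "q25": float(qs[1]), "q50": float(qs[2]),
            "q75": float(qs[3]), "q975": float(qs[4]),
        },
    )


def me_vs_microbiome(
    est_low: list[MicrobialEffectEstimate],
    est_high: list[MicrobialEffectEstimate],
    microbiome_trait: pd.Series,
    n_sim: int = 10000,
    seed: int = 0,
    predictor_name: str = "microbiome_trait",
) -> SlopeComparison:
    """Slope comparison with a genotype-level microbiome trait (e.g.
    diazotroph richness or ammonia-oxidizer relative abundance) as the
    reaction-norm predictor — identical machinery to
    :func:`slope_difference_test`."""
    missing = sorted(
        {e.genotype for e in est_low + est_high if e.usable}
        - set(map(str, microbiome_trait.index))
    )
    if missing:
        raise ValueError(f"microbiome trait missing for genotypes: {missing[:5]}")
    return slope_difference_test(
        est_low, est_high, microbiome_trait,
        n_sim=n_sim, seed=seed, predictor_name=predictor_name,
    )
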