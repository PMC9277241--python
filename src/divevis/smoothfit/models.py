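"""The two dive models built on the GAM engine.

* dive rate: negative binomial (log link) count of dives per 5-min fix,
  with a tensor-product smooth of solar angle x Secchi-disc depth, a
  shrinkage smooth of cloud cover, a cyclic smooth of time of day, a
  random intercept per bird, and AR(1) working correlation within trips;
* dive depth: Gaussian (identity link) maximum depth per dive bout, with
  the same solar x Zsd tensor, cloud, cyclic time of day, a shrinkage
  smooth of water depth, a random bird intercept and a categorical
  movement-state effect (reference: rest).  No AR(1) term.

Both use shrinkage bases throughout, so terms without support are
regressed to (near) zero rather than formally dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import (CyclicTerm, FactorTerm, RandomInterceptTerm, SplineTerm,
                    TensorTerm)
from .fitting import GamFit, auc_presence, fit_gam

__all__ = ["DiveRateModel", "DiveDepthModel", "fit_dive_rate_model",
           "fit_dive_depth_model"]

logger = logging.getLogger(__name__)

_RATE_COLS = ["solar_deg", "zsd_m", "cloud_pct", "tod_h", "bird_id", "dive_count"]
_DEPTH_COLS = ["solar_deg", "zsd_m", "cloud_pct", "tod_h", "water_depth_m",
               "bird_id", "hmm_state", "max_depth_m"]


def _drop_missing(data: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, int]:
    ok = data[cols].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropping %d rows with missing covariates", n_dropped)
    return data.loc[ok].reset_index(drop=True), n_dropped


@dataclass
class DiveRateModel:
    """Fitted dive-rate model plus its headline summaries."""

    fit: GamFit
    table: pd.DataFrame
    deviance_explained: float
    auc: float
    rho: float | None
    n_dropped: int

    def surface(self, solar_grid: np.ndarray, zsd_grid: np.ndarray) -> pd.DataFrame:
        """Tensor-term effect on a solar x Zsd grid (link scale)."""
        gg = pd.DataFrame({
            "solar_deg": np.repeat(solar_grid, len(zsd_grid)),
            "zsd_m": np.tile(zsd_grid, len(solar_grid)),
        })
        gg["effect"] = self.fit.predict_term(gg, "te(solar_deg,zsd_m)")
        return gg


@dataclass
class DiveDepthModel:
    """Fitted bout-depth model plus state contrasts."""

    fit: GamFit
    table: pd.DataFrame
    deviance_explained: float
    state_contrasts: pd.DataFrame
    n_dropped: int

    def surface(self, solar_grid: np.ndarray, zsd_grid: np.ndarray,
                bird: str | None = None) -> pd.DataFrame:
        label = "te(solar_deg,zsd_m)" if bird is None else f"te(solar_deg,zsd_m):{bird}"
        gg = pd.DataFrame({
            "solar_deg": np.repeat(solar_grid, len(zsd_grid)),
            "zsd_m": np.tile(zsd_grid, len(solar_grid)),
        })
        if bird is not None:
            gg["bird_id"] = bird
        gg["effect"] = self.fit.predict_term(gg, label)
        return gg


def fit_dive_rate_model(
    fix_table: pd.DataFrame,
    k_tensor: tuple[int, int] = (5, 5),
    k_1d: int = 10,
    gamma: float = 1.2,
    ar1: bool = True,
    group_col: str = "trip_id",
    theta: float | None = None,
) -> DiveRateModel:
    """Dive count per 5-min fix vs visibility covariates.

    ``fix_table`` needs solar_deg, zsd_m, cloud_pct, tod_h, bird_id,
    dive_count, plus ``trip_id`` when AR(1) whitening is on.  Rows with
    missing covariates are dropped (count reported on the result).
    """
    cols = list(_RATE_COLS) + ([group_col] if ar1 else [])
    data, n_dropped = _drop_missing(fix_table, [c for c in cols if c in fix_table.columns])
    if data["dive_count"].max() == 0:
        raise ValueError("all dive counts are zero; rate model undefined")
    terms = [
        TensorTerm("solar_deg", "zsd_m", k=k_tensor),
        SplineTerm("cloud_pct", k=k_1d),
        CyclicTerm("tod_h", k=k_1d, period=24.0),
        RandomInterceptTerm("bird_id"),
    ]
    fit = fit_gam(terms, data, "dive_count", family="nb", gamma=gamma,
                  rho="auto" if ar1 else None,
                  group_col=group_col if ar1 else None, theta=theta)
    return DiveRateModel(
        fit=fit,
        table=fit.term_table(),
        deviance_explained=fit.deviance_explained,
        auc=auc_presence(fit),
        rho=fit.rho,
        n_dropped=n_dropped,
    )


def fit_dive_depth_model(
    bout_table: pd.DataFrame,
    k_tensor: tuple[int, int] = (5, 5),
    k_1d: int = 10,
    gamma: float = 1.2,
    per_individual_tensor: bool = False,
) -> DiveDepthModel:
    """Maximum depth per dive bout vs visibility covariates.

    ``bout_table`` needs solar_deg, zsd_m, cloud_pct, tod_h,
    water_depth_m, bird_id, hmm_state (rest/ars/transit) and max_depth_m.
    ``per_individual_tensor`` fits one solar x Zsd tensor per bird
    (shared smoothing parameters) instead of a pooled surface.
    """
    data, n_dropped = _drop_missing(bout_table,
                                    [c for c in _DEPTH_COLS if c in bout_table.columns])
    terms: list = []
    if per_individual_tensor:
        for bird in sorted(data["bird_id"].astype(str).unique()):
            terms.append(_PerBirdTensor(bird, k=k_tensor))
    else:
        terms.append(TensorTerm("solar_deg", "zsd_m", k=k_tensor))
    terms += [
        SplineTerm("cloud_pct", k=k_1d),
        CyclicTerm("tod_h", k=k_1d, period=24.0),
        SplineTerm("water_depth_m", k=k_1d),
        RandomInterceptTerm("bird_id"),
        FactorTerm("hmm_state", reference="rest"),
    ]
    fit = fit_gam(terms, data, "max_depth_m", family="gaussian", gamma=gamma)

    rows = []
    for b, sl in zip(fit.blocks, fit.slices):
        if b.label == "factor(hmm_state)":
            factor = next(t for t in terms if isinstance(t, FactorTerm))
            for j, lv in enumerate(factor.level_names):
                est = float(fit.coef[sl][j])
                se = float(np.sqrt(fit.Vb[sl, sl][j, j]))
                from scipy import stats as _st
                dfe = max(fit.n_obs - fit.edf_total, 1.0)
                rows.append({
                    "state": lv, "reference": "rest", "contrast_m": est,
                    "se_m": se, "p_value": float(2 * _st.t.sf(abs(est / se), dfe)),
                })
    return DiveDepthModel(
        fit=fit,
        table=fit.term_table(),
        deviance_explained=fit.deviance_explained,
        state_contrasts=pd.DataFrame(rows),
        n_dropped=n_dropped,
    )


class _PerBirdTensor(TensorTerm):
    """Solar x Zsd tensor restricted to one bird's rows (zero elsewhere)."""

    def __init__(self, bird: str, k=(5, 5)):
        super().__init__("solar_deg", "zsd_m", k=k)
        self.bird = bird
        self.label = f"te(solar_deg,zsd_m):{bird}"

    def build(self, data: pd.DataFrame):
        block = super().build(data)
        mask = (data["bird_id"].astype(str) == self.bird).to_numpy()
        inner = block.predictor

        def predictor(newdata: pd.DataFrame) -> np.ndarray:
            xb = inner(newdata)
            if "bird_id" in newdata.columns:
                m = (newdata["bird_id"].astype(str) == self.bird).to_numpy()
                xb = xb * m[:, None]
            return xb

        block.X = block.X * mask[:, None]
        block.predictor = predictor
        block.label = self.label
        return block
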