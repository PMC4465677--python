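"""AIC multimodel inference: ranking, candidate sets, model averaging.

Candidate sets mirror the study design: for the multiseason and
two-species families each habitat covariate enters occupancy and
detection in every combination of {absent, additive, interaction} except
absent from both (8 models per covariate) plus the shared factor-only
null model, giving 25 warmth (solar) models, 25 soil models and 9 plant
composition models per family (59 in total, counting the null once per
separately ranked group).  The multistate family is a 12-model grid over
conditional occupancy {constant, Season} x detection
{Season, State+Season, State x Season} x conditional detection
{constant, Season}.

Model averaging is applied on the probability scale: averaged
probabilities are Akaike-weighted means of per-model predicted
probabilities, with unconditional variance
``sum_m w_m [var_m + (p_m - pbar)^2]`` capturing model-selection
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from occucam.habitat_covariates import SiteCovariates
from occucam.occupancy_models import FitResult, ModelSpec, predict_probabilities

COVARIATE_GROUPS = {
    "solar": ("Direct", "Diffuse", "Total"),
    "soil": ("CN", "pH", "P"),
    "plant": ("Axis1",),
}


def aic(neg2LL: float, K: int) -> float:
    """Akaike's information criterion, ``-2 log L + 2 K``."""
    if K < 0:
        raise ValueError("K must be non-negative")
    return neg2LL + 2 * K


def rank_models(fits) -> pd.DataFrame:
    """Rank fitted (or tabulated) models by AIC.

    ``fits`` is a list of :class:`FitResult`, or a DataFrame with
    columns ``label``, ``neg2LL`` and ``K``.  Returns a table with
    ``AIC``, ``dAIC`` (difference from the best model) and Akaike
    weights ``w = exp(-dAIC/2) / sum exp(-dAIC/2)``, sorted ascending by
    AIC with ties broken by fewer parameters then label.
    """
    if isinstance(fits, pd.DataFrame):
        table = fits[["label", "neg2LL", "K"]].copy()
    else:
        fits = list(fits)
        if not fits:
            raise ValueError("no models to rank")
        shapes = {f.designs.y.shape for f in fits}
        if len(shapes) > 1:
            raise ValueError(f"fits are not on the same data (shapes {shapes})")
        table = pd.DataFrame(
            {
                "label": [f.label for f in fits],
                "neg2LL": [f.neg2LL for f in fits],
                "K": [f.K for f in fits],
            }
        )
    table["AIC"] = table["neg2LL"] + 2 * table["K"]
    table["dAIC"] = table["AIC"] - table["AIC"].min()
    rel = np.exp(-0.5 * table["dAIC"])
    table["weight"] = rel / rel.sum()
    table = table.sort_values(
        ["AIC", "K", "label"], kind="stable"
    ).reset_index(drop=True)
    return table


def build_candidate_set(
    family: str, covariate_group: str | None = None, **spec_kwargs
) -> list[ModelSpec]:
    """Enumerate one covariate group's candidate models.

    Multiseason / two-species: the factor-only null model plus, for each
    covariate in the group, the 8 combinations of covariate mode on
    occupancy x detection (excluding absent from both).  Multistate:
    the full 12-model grid (``covariate_group`` is ignored).
    """
    if family == "multistate":
        specs = []
        for r_mode in ("constant", "season"):
            for det_state in ("none", "additive", "interaction"):
                for delta_mode in ("constant", "season"):
                    specs.append(
                        ModelSpec(
                            family="multistate",
                            r_mode=r_mode,
                            det_state=det_state,
                            delta_mode=delta_mode,
                        )
                    )
        return specs
    if covariate_group not in COVARIATE_GROUPS:
        raise ValueError(
            f"unknown covariate group {covariate_group!r}; "
            f"choose from {sorted(COVARIATE_GROUPS)}"
        )
    specs = [ModelSpec(family=family, **spec_kwargs)]  # shared null model
    for cov in COVARIATE_GROUPS[covariate_group]:
        for occ_mode in ("none", "additive", "interaction"):
            for det_mode in ("none", "additive", "interaction"):
                if occ_mode == "none" and det_mode == "none":
                    continue
                specs.append(
                    ModelSpec(
                        family=family,
                        covariate=cov,
                        occ_mode=occ_mode,
                        det_mode=det_mode,
                        **spec_kwargs,
                    )
                )
    return specs


def full_candidate_set(family: str, **spec_kwargs) -> list[ModelSpec]:
    """All covariate groups' candidates (the null model once per group)."""
    return [
        spec
        for group in ("solar", "soil", "plant")
        for spec in build_candidate_set(family, group, **spec_kwargs)
    ]


@dataclass
class AveragedPrediction:
    """Model-averaged probabilities on a covariate grid."""

    covariate: str | None
    grid: np.ndarray  # raw scale
    probability: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    weights: pd.Series  # label -> Akaike weight
    kind: str


def _median_raw(
    covariates: SiteCovariates, name: str, season_or_species: str
) -> float:
    season = season_or_species if season_or_species in ("winter", "summer") else "summer"
    col = covariates.column_for(name, season)
    return float(covariates.data[col].median())


def model_average(
    fits: list[FitResult],
    covariate: str | None,
    grid,
    season_or_species: str = "winter",
    kind: str = "occupancy",
    covariates: SiteCovariates | None = None,
    effort: float = 7.0,
    ci_level: float = 0.95,
    ci_scale: str = "probability",
) -> AveragedPrediction:
    """Probability-scale model averaging over a fitted candidate set.

    Predictions are taken model by model on the raw-scale ``grid`` of
    ``covariate`` and combined with Akaike weights (renormalised over
    the models actually supplied).  Models built on a *different*
    covariate hold it at its observed median (from the raw
    ``covariates`` table); a model on Total solar radiation evaluated
    against a Direct or Diffuse grid uses Total = grid + median(other
    component), keeping the physical constraint Total = Direct +
    Diffuse.  The unconditional variance adds the between-model spread
    to the within-model variance.  ``ci_scale`` is 'probability'
    (normal approximation on p, the default) or 'logit'.
    """
    if not fits:
        raise ValueError("no fitted models to average")
    ranking = rank_models(fits)
    weights = ranking.set_index("label")["weight"]
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    n = len(grid)
    pbar = np.zeros(n)
    preds = {}
    any_cov_model = False
    for f in fits:
        w = float(weights[f.label])
        own = f.spec.covariate
        uses = {
            "occupancy": f.spec.occ_mode != "none",
            "detection": f.spec.det_mode != "none",
        }.get(kind, False)
        if uses and own == covariate:
            any_cov_model = True
            out = predict_probabilities(
                f, grid, season_or_species, kind=kind, effort=effort, ci_level=ci_level
            )
            p = np.atleast_1d(out["probability"])
            se = np.atleast_1d(out["se"])
        elif uses:
            if covariates is None:
                raise ValueError(
                    "need the raw covariate table to hold other covariates at "
                    "their medians"
                )
            if own == "Total" and covariate in ("Direct", "Diffuse"):
                other = "Diffuse" if covariate == "Direct" else "Direct"
                values = grid + _median_raw(covariates, other, season_or_species)
            else:
                values = np.full(n, _median_raw(covariates, own, season_or_species))
            out = predict_probabilities(
                f, values, season_or_species, kind=kind, effort=effort, ci_level=ci_level
            )
            p = np.atleast_1d(out["probability"])
            se = np.atleast_1d(out["se"])
        else:
            out = predict_probabilities(
                f, None, season_or_species, kind=kind, effort=effort, ci_level=ci_level
            )
            p = np.full(n, out["probability"])
            se = np.full(n, out["se"])
        preds[f.label] = (w, p, se)
        pbar += w * p
    if covariate is not None and not any_cov_model:
        raise ValueError(
            f"covariate {covariate!r} appears in no model's {kind} structure"
        )
    var = np.zeros(n)
    for w, p, se in preds.values():
        var += w * (se**2 + (p - pbar) ** 2)
    se_bar = np.sqrt(var)
    from scipy.stats import norm

    z = float(norm.ppf(1 - (1 - ci_level) / 2))
    if ci_scale == "logit":
        eps = 1e-12
        pc = np.clip(pbar, eps, 1 - eps)
        eta = np.log(pc / (1 - pc))
        se_eta = se_bar / (pc * (1 - pc))
        lo = 1 / (1 + np.exp(-(eta - z * se_eta)))
        hi = 1 / (1 + np.exp(-(eta + z * se_eta)))
    else:
        lo = np.clip(pbar - z * se_bar, 0.0, 1.0)
        hi = np.clip(pbar + z * se_bar, 0.0, 1.0)
    return AveragedPrediction(
        covariate=covariate,
        grid=grid,
        probability=pbar,
        se=se_bar,
        ci_low=lo,
        ci_high=hi,
        weights=weights,
        kind=kind,
    )
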