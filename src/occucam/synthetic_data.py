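"""Synthetic camera-trap study generator.

Emulates the sampling design the package targets: a 25-camera grid
surveyed over four seasons (two winters, two summers) of 13 weekly
occasions each, with per-site habitat covariates spanning the published
ranges (winter direct solar radiation 0.0-5.0 total mols m^-2 day^-1
with mean 0.7, soil C:N 11-24, available P 3-41 ug g^-1, ...), weekly
effort of 0-7 active camera days, and detection histories drawn under
each of the three occupancy model families with known parameters.

Covariates are drawn from truncated normal distributions calibrated so
the truncated mean matches the published mean within the published
range; total solar radiation is direct + diffuse by construction.
Effort is 7 minus a zero-inflated binomial count of outage days: a
whole-week outage (SD card or camera failure) yields structural
missingness, otherwise individual days drop out rarely.  Default true
parameters are chosen so the fixture's naive occupancies and detection
frequencies are of the same order as the published seasonal summaries
(rusa deer present and well detected in all seasons, red deer almost
absent in winter).

Everything is driven by one ``numpy.random.default_rng`` seed; the same
seed reproduces the same bundle byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from occucam.datasets import COVARIATE_RANGES
from occucam.detection_data import (
    DetectionHistory,
    SeasonLayout,
    TwoSpeciesHistory,
    subset_seasons,
)
from occucam.habitat_covariates import SiteCovariates
from occucam.pao import write_pao

import pandas as pd


def default_layout() -> SeasonLayout:
    """Two winters and two summers of 13 weekly occasions each."""
    return SeasonLayout.from_lengths(
        [("winter", 2010), ("summer", 2010), ("winter", 2011), ("summer", 2011)],
        13,
        starts=[
            date(2010, 6, 14), date(2010, 12, 13),
            date(2011, 6, 13), date(2011, 12, 12),
        ],
    )


@dataclass
class SimulationConfig:
    """Study conditions and true parameters for the generator.

    Probabilities are on the probability scale at the mean covariate
    value; ``det_solar_slope`` and ``occ_solar_slope`` act on the logit
    scale per unit of centred sqrt(direct solar radiation), reproducing
    the qualitative published pattern (activity increases with direct
    solar radiation).
    """

    n_sites: int = 25
    layout: SeasonLayout = field(default_factory=default_layout)
    covariate_ranges: dict = field(default_factory=lambda: dict(COVARIATE_RANGES))
    # effort model
    p_week_outage: float = 0.01
    p_day_outage: float = 0.005
    # single-species (rusa) occupancy and weekly detection by season level
    psi: dict = field(default_factory=lambda: {"winter": 0.80, "summer": 0.90})
    p: dict = field(default_factory=lambda: {"winter": 0.22, "summer": 0.20})
    occ_solar_slope: float = 0.5
    det_solar_slope: float = 0.8
    # multistate blocks: conditional male occupancy R, conditional male
    # detection delta, and the logit boost of detection at male sites
    r: dict = field(default_factory=lambda: {"winter": 0.70, "summer": 0.40})
    delta: dict = field(default_factory=lambda: {"winter": 0.50, "summer": 0.25})
    p_state3_boost: float = 0.5
    # second species (red deer): near-absent in winter
    psi_b: dict = field(default_factory=lambda: {"winter": 0.04, "summer": 0.55})
    p_b: dict = field(default_factory=lambda: {"winter": 0.10, "summer": 0.12})
    eta: float = 0.0  # log-scale co-occurrence factor (0 = independence)
    seed: int = 0

    def __post_init__(self) -> None:
        for block in (self.psi, self.p, self.r, self.delta, self.psi_b, self.p_b):
            for v in block.values():
                if not 0.0 < v < 1.0:
                    raise ValueError("true probabilities must lie strictly in (0, 1)")


def _truncnorm_mean_match(lo: float, hi: float, mean: float) -> tuple[float, float]:
    """(loc, scale) of a truncated normal on [lo, hi] with the given mean."""
    if not lo < mean < hi:
        raise ValueError(f"mean {mean} outside range ({lo}, {hi})")
    scale = (hi - lo) / 4.0

    def gap(loc: float) -> float:
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return truncnorm.mean(a, b, loc=loc, scale=scale) - mean

    span = hi - lo
    loc = brentq(gap, lo - 3 * span, hi + 3 * span)
    return loc, scale


def _draw_truncnorm(rng, lo, hi, mean, size) -> np.ndarray:
    loc, scale = _truncnorm_mean_match(lo, hi, mean)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_landscape(config: SimulationConfig, seed: int | None = None) -> SiteCovariates:
    """Draw per-site habitat covariates matching the configured ranges.

    Direct and diffuse solar radiation are drawn per season level; total
    is their sum.  The NMDS Axis 1 score is generated correlated with
    sqrt(direct solar radiation), mirroring the published association
    between open, previously burnt vegetation and high radiation.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_sites
    cols = {}
    for season in ("winter", "summer"):
        for stem in ("direct", "diffuse"):
            lo, hi, mean = config.covariate_ranges[f"{stem}_{season}"]
            cols[f"{stem}_{season}"] = _draw_truncnorm(rng, lo, hi, mean, n)
        cols[f"total_{season}"] = cols[f"direct_{season}"] + cols[f"diffuse_{season}"]
    for name in ("cn", "ph", "p_avail"):
        lo, hi, mean = config.covariate_ranges[name]
        cols[name] = _draw_truncnorm(rng, lo, hi, mean, n)
    x = np.sqrt(cols["direct_winter"])
    xz = (x - x.mean()) / (x.std() or 1.0)
    axis1 = 0.6 * xz + 0.8 * rng.normal(size=n)
    cols["axis1"] = axis1 - axis1.mean()
    quartile = np.searchsorted(np.quantile(cols["axis1"], [0.25, 0.5, 0.75]), cols["axis1"])
    cols["community"] = quartile + 1
    site_ids = [f"C{i + 1:02d}" for i in range(n)]
    frame = pd.DataFrame(cols, index=pd.Index(site_ids, name="site_id"))
    return SiteCovariates(frame)


def _simulate_effort(config: SimulationConfig, rng) -> np.ndarray:
    shape = (config.n_sites, config.layout.total_weeks)
    out = np.where(
        rng.random(shape) < config.p_week_outage,
        0,
        7 - rng.binomial(7, config.p_day_outage, size=shape),
    )
    return out.astype(int)


def _eta_arrays(config: SimulationConfig, covariates: SiteCovariates):
    """Per-site-season linear predictors for psi and p (species A)."""
    layout = config.layout
    n, T = config.n_sites, layout.n_seasons
    eta_psi = np.empty((n, T))
    eta_p = np.empty((n, T))
    for t, season in enumerate(layout.seasons):
        x = np.sqrt(covariates.data[f"direct_{season.label}"].to_numpy())
        xc = x - x.mean()
        eta_psi[:, t] = logit(config.psi[season.label]) + config.occ_solar_slope * xc
        eta_p[:, t] = logit(config.p[season.label]) + config.det_solar_slope * xc
    return eta_psi, eta_p


def simulate_history(
    config: SimulationConfig,
    family: str,
    seed: int | None = None,
    covariates: SiteCovariates | None = None,
    effort: np.ndarray | None = None,
):
    """Draw a detection history under one model family.

    Latent occupancy states are drawn per site-season, weekly
    observations per surveyed week given the state.  Returns a
    :class:`DetectionHistory` (binary or multistate) or a
    :class:`TwoSpeciesHistory` for ``family='twospecies'``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if covariates is None:
        covariates = generate_landscape(config, seed=rng.integers(2**31))
    if effort is None:
        effort = _simulate_effort(config, rng)
    layout = config.layout
    n, W = config.n_sites, layout.total_weeks
    wk_season = layout.week_season_index()
    site_ids = covariates.site_ids
    eta_psi, eta_p = _eta_arrays(config, covariates)
    psi = expit(eta_psi)
    p_week = expit(eta_p)[:, wk_season]
    m = effort > 0

    if family == "multiseason":
        occupied = rng.random(psi.shape) < psi
        occ_week = occupied[:, wk_season]
        det = (rng.random((n, W)) < p_week) & occ_week & m
        obs = np.where(m, det.astype(int), -1)
        return DetectionHistory(site_ids, layout, obs, effort, "binary", "rusa")

    if family == "multistate":
        occupied = rng.random(psi.shape) < psi
        labels = [s.label for s in layout.seasons]
        r = np.array([[config.r[lab] for lab in labels]] * n)
        delta = np.array([[config.delta[lab] for lab in labels]] * n)
        male = occupied & (rng.random(psi.shape) < r)
        p1_week = p_week
        p2_week = expit(eta_p + config.p_state3_boost)[:, wk_season]
        occ_week = occupied[:, wk_season]
        male_week = male[:, wk_season]
        delta_week = delta[:, wk_season]
        u = rng.random((n, W))
        v = rng.random((n, W))
        det2 = occ_week & ~male_week & (u < p1_week)
        det3 = occ_week & male_week & (u < p2_week)
        code = np.zeros((n, W), dtype=int)
        code[det2] = 1
        code[det3] = np.where(v[det3] < delta_week[det3], 2, 1)
        obs = np.where(m, np.where(occ_week, code, 0), -1)
        return DetectionHistory(site_ids, layout, obs, effort, "multistate", "rusa")

    if family == "twospecies":
        labels = [s.label for s in layout.seasons]
        psi_a = psi
        psi_b = np.array([[config.psi_b[lab] for lab in labels]] * n)
        p_b_week = np.array([[config.p_b[lab] for lab in labels]] * n)[:, wk_season]
        p_ab = psi_a * psi_b * np.exp(config.eta)
        p_ab = np.clip(p_ab, np.maximum(0.0, psi_a + psi_b - 1.0), np.minimum(psi_a, psi_b))
        u = rng.random(psi_a.shape)
        both = u < p_ab
        a_only = (u >= p_ab) & (u < psi_a)
        b_only = (u >= psi_a) & (u < psi_a + psi_b - p_ab)
        occ_a = both | a_only
        occ_b = both | b_only
        det_a = (rng.random((n, W)) < p_week) & occ_a[:, wk_season] & m
        det_b = (rng.random((n, W)) < p_b_week) & occ_b[:, wk_season] & m
        obs_a = np.where(m, det_a.astype(int), -1)
        obs_b = np.where(m, det_b.astype(int), -1)
        return TwoSpeciesHistory(
            DetectionHistory(site_ids, layout, obs_a, effort, "binary", "rusa"),
            DetectionHistory(site_ids, layout, obs_b, effort, "binary", "red"),
        )

    raise ValueError(f"unknown family {family!r}")


@dataclass
class StudyFixture:
    """A complete synthetic study: covariates plus all derived histories."""

    config: SimulationConfig
    covariates: SiteCovariates
    rusa: DetectionHistory          # binary, all four seasons
    multistate: DetectionHistory    # 3-level codes, all four seasons
    red: DetectionHistory           # binary, all four seasons
    twospecies: TwoSpeciesHistory   # final summer only

    def write_bundle(self, directory) -> dict[str, Path]:
        """Write PAO files, a covariate CSV and a true-parameter manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "rusa_pao": directory / "rusa_multiseason.pao",
            "multistate_pao": directory / "rusa_multistate.pao",
            "red_pao": directory / "red_multiseason.pao",
            "covariates_csv": directory / "site_covariates.csv",
            "manifest_yaml": directory / "manifest.yaml",
        }
        write_pao(self.rusa, self.covariates, paths["rusa_pao"],
                  title="synthetic multiseason history (rusa)")
        write_pao(self.multistate, None, paths["multistate_pao"],
                  title="synthetic multistate history (rusa, adult males)")
        write_pao(self.red, None, paths["red_pao"],
                  title="synthetic multiseason history (red)")
        self.covariates.data.to_csv(paths["covariates_csv"])
        manifest = {
            "seed": int(self.config.seed),
            "n_sites": int(self.config.n_sites),
            "psi": dict(self.config.psi),
            "p": dict(self.config.p),
            "r": dict(self.config.r),
            "delta": dict(self.config.delta),
            "p_state3_boost": float(self.config.p_state3_boost),
            "psi_b": dict(self.config.psi_b),
            "p_b": dict(self.config.p_b),
            "eta": float(self.config.eta),
            "occ_solar_slope": float(self.config.occ_solar_slope),
            "det_solar_slope": float(self.config.det_solar_slope),
        }
        paths["manifest_yaml"].write_text(
            yaml.safe_dump(manifest, sort_keys=True, default_flow_style=False)
        )
        return paths


def make_study_fixture(seed: int = 0, config: SimulationConfig | None = None) -> StudyFixture:
    """A 25-site, 4-season synthetic study with internally consistent pieces.

    One weekly event process drives everything: multistate codes are
    drawn first; the binary history is their collapse (any detection);
    the second species is simulated on the same effort matrix; the
    two-species history is the final summer's paired slice.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    else:
        from dataclasses import replace

        config = replace(config, seed=seed)
    rng = np.random.default_rng(seed)
    covariates = generate_landscape(config, seed=int(rng.integers(2**31)))
    effort = _simulate_effort(config, rng)
    multistate = simulate_history(
        config, "multistate", seed=int(rng.integers(2**31)),
        covariates=covariates, effort=effort,
    )
    rusa = multistate.binarised()
    pair = simulate_history(
        config, "twospecies", seed=int(rng.integers(2**31)),
        covariates=covariates, effort=effort,
    )
    red = pair.b
    last_summer = config.layout.n_seasons - 1
    twospecies = TwoSpeciesHistory(
        subset_seasons(rusa, [last_summer]), subset_seasons(red, [last_summer])
    )
    return StudyFixture(config, covariates, rusa, multistate, red, twospecies)
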