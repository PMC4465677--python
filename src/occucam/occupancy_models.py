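"""Hierarchical site-occupancy likelihoods and maximum-likelihood fitting.

Three model families, all with logit links on every probability:

* **multiseason** -- single species over repeated seasons with *implicit
  dynamics*: each season's occupancy state is drawn independently, so a
  site contributes, per season,
  ``psi * prod_w p^y (1-p)^(1-y) + (1-psi) * 1{all y = 0}``
  over its surveyed weeks.
* **multistate** -- ordered latent states per site-season: (1) species
  absent, (2) present without adult males, (3) adult males present.
  Parameters are occupancy ``psi`` (state 2 or 3), conditional male
  occupancy ``R`` (state 3 given occupied), weekly detection ``p1``
  (state 2) and ``p2`` (state 3), and conditional male detection
  ``delta`` (a detection includes a male, given a detection at a
  state-3 site).  Weekly codes 0/1/2 have state-3 probabilities
  ``1-p2``, ``p2 (1-delta)``, ``p2 delta``.
* **twospecies** -- two species on the same grid in one (or more)
  season(s); four latent states per site-season (both, A only, B only,
  neither) with state probabilities from ``psi_A``, ``psi_B`` and an
  optional log-scale co-occurrence factor ``eta`` (``eta = 0`` gives
  independence, ``psi_AB = psi_A psi_B``, the default).  Detections are
  conditionally independent across species and weeks given the state.

Model structure follows the study design the package targets: a
two-level Season factor (winter/summer, shared across years) or a
Species factor is always present on occupancy and detection; at most one
habitat covariate enters per model, either additively (same slope in
both factor levels) or with a factor interaction (level-specific
slopes); weekly sampling effort ("Number", active camera days) enters
detection linearly on the logit scale for the multiseason and
two-species families.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logit

from occucam.detection_data import (
    DetectionHistory,
    SeasonLayout,
    TwoSpeciesHistory,
)
from occucam.habitat_covariates import (
    SiteCovariates,
    apply_transform,
    transform_covariates,
)

FAMILIES = ("multiseason", "multistate", "twospecies")
MODES = ("none", "additive", "interaction")

_NEG_INF = -np.inf


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic model structure.

    ``covariate`` names the single habitat covariate (canonical names:
    Direct, Diffuse, Total, CN, pH, P, Axis1) with ``occ_mode`` /
    ``det_mode`` giving how it enters occupancy and detection (``none``,
    ``additive``, ``interaction``).  ``effort`` adds the active-days
    term to detection (forced off for the multistate family, whose
    candidate set carries no effort term).  The multistate blocks are
    ``r_mode`` (conditional occupancy: constant or season),
    ``det_state`` (State entering detection: none, additive or
    interaction with Season) and ``delta_mode`` (conditional detection:
    constant or season).  ``co_occurrence`` frees the two-species
    interaction factor eta (fixed at 0 / independence by default).
    """

    family: str
    covariate: str | None = None
    occ_mode: str = "none"
    det_mode: str = "none"
    effort: bool = True
    r_mode: str = "constant"
    det_state: str = "none"
    delta_mode: str = "constant"
    co_occurrence: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.occ_mode not in MODES or self.det_mode not in MODES:
            raise ValueError("covariate modes must be none/additive/interaction")
        if self.covariate is None and (self.occ_mode != "none" or self.det_mode != "none"):
            raise ValueError("covariate mode set but no covariate named")
        if self.family == "multistate":
            if self.covariate is not None:
                raise ValueError("multistate specs carry no habitat covariate")
            object.__setattr__(self, "effort", False)
            if self.r_mode not in ("constant", "season"):
                raise ValueError("r_mode must be constant/season")
            if self.det_state not in MODES:
                raise ValueError("det_state must be none/additive/interaction")
            if self.delta_mode not in ("constant", "season"):
                raise ValueError("delta_mode must be constant/season")
        if self.co_occurrence and self.family != "twospecies":
            raise ValueError("co_occurrence only applies to the two-species family")

    @property
    def factor(self) -> str:
        return "Species" if self.family == "twospecies" else "Season"

    def _cov_part(self, mode: str) -> str:
        if mode == "none" or self.covariate is None:
            return ""
        sep = "+" if mode == "additive" else "*"
        return f"{sep}{self.covariate}"

    @property
    def label(self) -> str:
        if self.family == "multistate":
            r = "." if self.r_mode == "constant" else "Season"
            p = {"none": "Season", "additive": "State+Season",
                 "interaction": "State*Season"}[self.det_state]
            dl = "." if self.delta_mode == "constant" else "Season"
            return f"psi(Season) R({r}) p({p}) delta({dl})"
        occ = self.factor + self._cov_part(self.occ_mode)
        det = self.factor + self._cov_part(self.det_mode)
        if self.effort:
            det += "+Number"
        return f"psi({occ}) p({det})"

    def __str__(self) -> str:  # pragma: no cover
        return self.label


_BLOCK_RE = re.compile(r"(psi|p|R|delta)\s*\(([^)]*)\)")


def parse_spec(text: str, family: str | None = None) -> ModelSpec:
    """Parse a compact model-spec string.

    Mirrors the field's notation, e.g.
    ``"psi(Season+Direct) p(Season*Direct+Number)"`` or
    ``"psi(Season) R(.) p(State+Season) delta(Season)"``.  ``*``, ``x``
    and the multiplication sign all denote an interaction.
    """
    blocks = {m.group(1): m.group(2) for m in _BLOCK_RE.finditer(text)}
    if "psi" not in blocks or "p" not in blocks:
        raise ValueError(f"spec must contain psi(...) and p(...): {text!r}")

    def terms(block: str) -> list[str]:
        out = []
        for tok in re.split(r"[+]", block.replace("×", "*")):
            tok = tok.strip()
            if tok:
                out.append(tok)
        return out

    multistate = "R" in blocks or "delta" in blocks or "State" in blocks["p"]
    if multistate or family == "multistate":
        r = blocks.get("R", ".").strip()
        dl = blocks.get("delta", ".").strip()
        p = blocks["p"].replace(" ", "")
        if p in ("Season",):
            det_state = "none"
        elif p in ("State+Season", "Season+State"):
            det_state = "additive"
        elif p.lower() in ("state*season", "statexseason", "season*state"):
            det_state = "interaction"
        else:
            raise ValueError(f"unrecognised multistate detection block {blocks['p']!r}")
        return ModelSpec(
            family="multistate",
            r_mode="season" if r.lower() == "season" else "constant",
            det_state=det_state,
            delta_mode="season" if dl.lower() == "season" else "constant",
        )

    def mode_and_cov(block: str) -> tuple[str, str | None, bool, str]:
        mode, cov, effort, factor = "none", None, False, "Season"
        for term in terms(block):
            interaction = "*" in term or re.fullmatch(r"\w+x\w+", term) is not None
            parts = re.split(r"[*]|x(?=[A-Z])", term)
            parts = [p for p in parts if p]
            for p in parts:
                if p in ("Season", "Species"):
                    factor = p
                elif p == "Number":
                    effort = True
                else:
                    cov = p
            if interaction and any(p not in ("Season", "Species", "Number") for p in parts):
                mode = "interaction"
            elif cov is not None and mode == "none":
                mode = "additive"
        return mode, cov, effort, factor

    occ_mode, occ_cov, _, occ_factor = mode_and_cov(blocks["psi"])
    det_mode, det_cov, effort, det_factor = mode_and_cov(blocks["p"])
    cov = occ_cov or det_cov
    if occ_cov and det_cov and occ_cov != det_cov:
        raise ValueError("occupancy and detection must share the single covariate")
    fam = family or ("twospecies" if "Species" in (occ_factor, det_factor) else "multiseason")
    return ModelSpec(
        family=fam, covariate=cov, occ_mode=occ_mode, det_mode=det_mode, effort=effort
    )


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class _Block:
    """One linear predictor: design array + column descriptors."""

    X: np.ndarray  # (..., n_cols)
    cols: list[str]

    @property
    def width(self) -> int:
        return len(self.cols)


@dataclass
class Designs:
    """Design matrices plus the observation arrays a likelihood needs."""

    spec: ModelSpec
    layout: SeasonLayout
    site_ids: list[str]
    occ: _Block
    det: _Block
    r: _Block | None = None
    delta: _Block | None = None
    y: np.ndarray | None = None
    y_b: np.ndarray | None = None
    mask: np.ndarray | None = None
    effort_days: np.ndarray | None = None
    cov_range: tuple[float, float] | None = None  # transformed scale
    slices: dict = field(default_factory=dict)
    param_names: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def season_slices(self) -> list[slice]:
        return [s.week_slice for s in self.layout.seasons]


def _factor_levels(layout: SeasonLayout) -> bool:
    """Whether both season levels occur (else the factor column drops)."""
    return len({s.label for s in layout.seasons}) == 2


def _cov_values(
    spec: ModelSpec, covariates: SiteCovariates | None, layout: SeasonLayout,
    site_ids: list[str],
) -> np.ndarray | None:
    """Transformed covariate value per (site, season), or None."""
    if spec.covariate is None:
        return None
    if covariates is None:
        raise ValueError(f"spec names covariate {spec.covariate!r} but no covariates given")
    if not covariates.transformed:
        covariates = transform_covariates(covariates)
    out = np.empty((len(site_ids), layout.n_seasons))
    for t, season in enumerate(layout.seasons):
        out[:, t] = covariates.values_for(spec.covariate, season.label, site_ids)
    return out


def _occ_det_blocks(
    spec: ModelSpec, layout: SeasonLayout, cov_st: np.ndarray | None,
    effort: np.ndarray, prefix_occ: str = "psi", prefix_det: str = "p",
) -> tuple[_Block, _Block]:
    """Occupancy (site x season) and detection (site x week) designs."""
    S = effort.shape[0]
    T, W = layout.n_seasons, layout.total_weeks
    has_factor = _factor_levels(layout)
    seas_summer = np.array([s.label == "summer" for s in layout.seasons], dtype=float)
    week_summer = (layout.week_labels() == "summer").astype(float)
    wk_season = layout.week_season_index()

    occ_cols, occ_parts = ["intercept"], [np.ones((S, T))]
    if has_factor:
        occ_cols.append("factor")
        occ_parts.append(np.broadcast_to(seas_summer, (S, T)))
    if spec.occ_mode != "none":
        occ_cols.append("cov")
        occ_parts.append(cov_st)
        if spec.occ_mode == "interaction":
            if not has_factor:
                raise ValueError("interaction mode needs both factor levels present")
            occ_cols.append("cov_x_factor")
            occ_parts.append(cov_st * seas_summer)
    occ = _Block(np.stack(occ_parts, axis=-1), occ_cols)

    det_cols, det_parts = ["intercept"], [np.ones((S, W))]
    if has_factor:
        det_cols.append("factor")
        det_parts.append(np.broadcast_to(week_summer, (S, W)))
    if spec.det_mode != "none":
        cov_sw = cov_st[:, wk_season]
        det_cols.append("cov")
        det_parts.append(cov_sw)
        if spec.det_mode == "interaction":
            if not has_factor:
                raise ValueError("interaction mode needs both factor levels present")
            det_cols.append("cov_x_factor")
            det_parts.append(cov_sw * week_summer)
    if spec.effort:
        det_cols.append("effort")
        det_parts.append(effort.astype(float))
    det = _Block(np.stack(det_parts, axis=-1), det_cols)
    return occ, det


def _names(prefix: str, cols: list[str]) -> list[str]:
    return [f"{prefix}:{c}" for c in cols]


def build_design(
    spec: ModelSpec,
    covariates: SiteCovariates | None,
    history: DetectionHistory | TwoSpeciesHistory,
) -> Designs:
    """Assemble design matrices and parameter layout for a model spec.

    Raw covariate tables are transformed (sqrt / log) on the way in;
    already-transformed tables pass through unchanged.
    """
    if spec.family == "twospecies":
        return _build_twospecies(spec, covariates, history)
    if isinstance(history, TwoSpeciesHistory):
        raise ValueError(f"{spec.family} family expects a single-species history")
    layout = history.layout
    site_ids = history.site_ids
    cov_st = _cov_values(spec, covariates, layout, site_ids)
    occ, det = _occ_det_blocks(spec, layout, cov_st, history.effort)

    d = Designs(
        spec=spec, layout=layout, site_ids=site_ids, occ=occ, det=det,
        y=history.observations, mask=history.effort > 0,
        effort_days=history.effort,
        cov_range=(float(cov_st.min()), float(cov_st.max())) if cov_st is not None else None,
    )
    if spec.family == "multistate":
        if history.kind != "multistate":
            raise ValueError("multistate family expects a multistate history")
        S, T = occ.X.shape[0], layout.n_seasons
        has_factor = _factor_levels(layout)
        seas_summer = np.array([s.label == "summer" for s in layout.seasons], dtype=float)
        week_summer = (layout.week_labels() == "summer").astype(float)
        W = layout.total_weeks
        # conditional occupancy R
        r_cols, r_parts = ["intercept"], [np.ones((S, T))]
        if spec.r_mode == "season":
            r_cols.append("factor")
            r_parts.append(np.broadcast_to(seas_summer, (S, T)))
        d.r = _Block(np.stack(r_parts, axis=-1), r_cols)
        # weekly detection for states 2 (index 0) and 3 (index 1)
        state3 = np.zeros((S, W, 2))
        state3[:, :, 1] = 1.0
        p_cols = ["intercept"]
        p_parts = [np.ones((S, W, 2))]
        if has_factor:
            p_cols.append("factor")
            p_parts.append(np.broadcast_to(week_summer[None, :, None], (S, W, 2)))
        if spec.det_state in ("additive", "interaction"):
            p_cols.append("state")
            p_parts.append(state3)
            if spec.det_state == "interaction":
                p_cols.append("state_x_factor")
                p_parts.append(state3 * week_summer[None, :, None])
        d.det = _Block(np.stack(p_parts, axis=-1), p_cols)
        # conditional detection delta
        dl_cols, dl_parts = ["intercept"], [np.ones((S, W))]
        if spec.delta_mode == "season":
            dl_cols.append("factor")
            dl_parts.append(np.broadcast_to(week_summer, (S, W)))
        d.delta = _Block(np.stack(dl_parts, axis=-1), dl_cols)
        names = (
            _names("psi", d.occ.cols) + _names("R", d.r.cols)
            + _names("p", d.det.cols) + _names("delta", d.delta.cols)
        )
        widths = [d.occ.width, d.r.width, d.det.width, d.delta.width]
        keys = ["occ", "r", "det", "delta"]
    else:
        if history.kind != "binary":
            raise ValueError("multiseason family expects a binary history")
        names = _names("psi", occ.cols) + _names("p", det.cols)
        widths = [occ.width, det.width]
        keys = ["occ", "det"]
    start = 0
    for key, w in zip(keys, widths):
        d.slices[key] = slice(start, start + w)
        start += w
    d.param_names = names
    return d


def _build_twospecies(
    spec: ModelSpec, covariates: SiteCovariates | None,
    history: TwoSpeciesHistory,
) -> Designs:
    if not isinstance(history, TwoSpeciesHistory):
        raise ValueError("two-species family expects a TwoSpeciesHistory")
    a, b = history.a, history.b
    if not np.array_equal(a.effort, b.effort):
        raise ValueError("species histories must share the effort matrix")
    layout = a.layout
    site_ids = a.site_ids
    S, W, T = a.n_sites, layout.total_weeks, layout.n_seasons
    cov_st = _cov_values(spec, covariates, layout, site_ids)

    # occupancy design: (site, season, species) rows; factor = species B
    occ_cols, occ_parts = ["intercept", "factor"], [
        np.ones((S, T, 2)),
        np.broadcast_to(np.array([0.0, 1.0]), (S, T, 2)),
    ]
    if spec.occ_mode != "none":
        occ_cols.append("cov")
        occ_parts.append(np.broadcast_to(cov_st[:, :, None], (S, T, 2)))
        if spec.occ_mode == "interaction":
            occ_cols.append("cov_x_factor")
            occ_parts.append(cov_st[:, :, None] * np.array([0.0, 1.0]))
    occ = _Block(np.stack(occ_parts, axis=-1), occ_cols)

    wk_season = layout.week_season_index()
    det_cols, det_parts = ["intercept", "factor"], [
        np.ones((S, W, 2)),
        np.broadcast_to(np.array([0.0, 1.0]), (S, W, 2)),
    ]
    if spec.det_mode != "none":
        cov_sw = cov_st[:, wk_season]
        det_cols.append("cov")
        det_parts.append(np.broadcast_to(cov_sw[:, :, None], (S, W, 2)))
        if spec.det_mode == "interaction":
            det_cols.append("cov_x_factor")
            det_parts.append(cov_sw[:, :, None] * np.array([0.0, 1.0]))
    if spec.effort:
        det_cols.append("effort")
        det_parts.append(np.broadcast_to(a.effort.astype(float)[:, :, None], (S, W, 2)))
    det = _Block(np.stack(det_parts, axis=-1), det_cols)

    d = Designs(
        spec=spec, layout=layout, site_ids=site_ids, occ=occ, det=det,
        y=a.observations, y_b=b.observations, mask=a.effort > 0,
        effort_days=a.effort,
        cov_range=(float(cov_st.min()), float(cov_st.max())) if cov_st is not None else None,
    )
    names = _names("psi", occ.cols) + _names("p", det.cols)
    d.slices["occ"] = slice(0, occ.width)
    d.slices["det"] = slice(occ.width, occ.width + det.width)
    if spec.co_occurrence:
        names.append("eta")
        d.slices["eta"] = slice(len(names) - 1, len(names))
    d.param_names = names
    return d


# ---------------------------------------------------------------------------
# likelihoods (all return -2 log L)


def _season_sums(arr: np.ndarray, slices: list[slice]) -> np.ndarray:
    """Sum a (S, W) array within each season -> (S, T)."""
    return np.stack([arr[:, sl].sum(axis=1) for sl in slices], axis=1)


def _season_any(arr: np.ndarray, slices: list[slice]) -> np.ndarray:
    return np.stack([arr[:, sl].any(axis=1) for sl in slices], axis=1)


def nll_multiseason(params: np.ndarray, history: DetectionHistory, designs: Designs) -> float:
    """-2 log-likelihood of the implicit-dynamics single-species model."""
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        return np.inf
    d = designs
    beta = params[d.slices["occ"]]
    alpha = params[d.slices["det"]]
    eta_occ = d.occ.X @ beta  # (S, T)
    eta_det = d.det.X @ alpha  # (S, W)
    y, m = d.y, d.mask
    llw = np.where(y == 1, log_expit(eta_det), log_expit(-eta_det)) * m
    slices = d.season_slices()
    ll_det = _season_sums(llw, slices)
    any_det = _season_any((y == 1) & m, slices)
    occupied = log_expit(eta_occ) + ll_det
    log_l = np.where(any_det, occupied, np.logaddexp(occupied, log_expit(-eta_occ)))
    return float(-2.0 * log_l.sum())


def nll_multistate(params: np.ndarray, history: DetectionHistory, designs: Designs) -> float:
    """-2 log-likelihood of the three-state (none / no-male / male) model."""
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        return np.inf
    d = designs
    beta = params[d.slices["occ"]]
    gamma = params[d.slices["r"]]
    alpha = params[d.slices["det"]]
    dpar = params[d.slices["delta"]]
    eta_occ = d.occ.X @ beta  # (S, T)
    eta_r = d.r.X @ gamma  # (S, T)
    eta_p = d.det.X @ alpha  # (S, W, 2): [...,0] = p1 (state 2), [...,1] = p2
    eta_dl = d.delta.X @ dpar  # (S, W)
    y, m = d.y, d.mask
    lp1, lq1 = log_expit(eta_p[..., 0]), log_expit(-eta_p[..., 0])
    lp2, lq2 = log_expit(eta_p[..., 1]), log_expit(-eta_p[..., 1])
    ld, l1md = log_expit(eta_dl), log_expit(-eta_dl)

    ll2w = np.where(y == 1, lp1, np.where(y == 0, lq1, 0.0)) * m
    ll3w = np.where(y == 0, lq2, np.where(y == 1, lp2 + l1md, lp2 + ld)) * m
    slices = d.season_slices()
    ll2 = _season_sums(ll2w, slices)
    ll3 = _season_sums(ll3w, slices)
    any_det = _season_any((y > 0) & m, slices)
    any_male = _season_any((y == 2) & m, slices)

    b1 = np.where(any_det, _NEG_INF, log_expit(-eta_occ))
    b2 = log_expit(eta_occ) + log_expit(-eta_r) + np.where(any_male, _NEG_INF, ll2)
    b3 = log_expit(eta_occ) + log_expit(eta_r) + ll3
    log_l = np.logaddexp(np.logaddexp(b1, b2), b3)
    return float(-2.0 * log_l.sum())


def nll_twospecies(
    params: np.ndarray, history: TwoSpeciesHistory, designs: Designs
) -> float:
    """-2 log-likelihood of the two-species co-occurrence model.

    State probabilities outside the feasible simplex under an extreme
    co-occurrence factor are clipped, with a quadratic penalty added to
    keep the optimiser away from the boundary.
    """
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        return np.inf
    d = designs
    beta = params[d.slices["occ"]]
    alpha = params[d.slices["det"]]
    eta_cooc = float(params[d.slices["eta"]][0]) if "eta" in d.slices else 0.0
    eta_occ = d.occ.X @ beta  # (S, T, 2)
    psi_a, psi_b = expit(eta_occ[..., 0]), expit(eta_occ[..., 1])
    psi_ab = psi_a * psi_b * np.exp(eta_cooc)
    lo = np.maximum(0.0, psi_a + psi_b - 1.0)
    hi = np.minimum(psi_a, psi_b)
    clipped = np.clip(psi_ab, lo, hi)
    penalty = 1e4 * float(np.sum((psi_ab - clipped) ** 2))
    psi_ab = clipped
    tiny = 1e-300
    log_states = np.stack(
        [
            np.log(np.maximum(psi_ab, tiny)),
            np.log(np.maximum(psi_a - psi_ab, tiny)),
            np.log(np.maximum(psi_b - psi_ab, tiny)),
            np.log(np.maximum(1.0 - psi_a - psi_b + psi_ab, tiny)),
        ],
        axis=-1,
    )  # (S, T, 4): AB, A only, B only, neither

    eta_det = d.det.X @ alpha  # (S, W, 2)
    ya, yb, m = d.y, d.y_b, d.mask
    lla_w = np.where(ya == 1, log_expit(eta_det[..., 0]), log_expit(-eta_det[..., 0])) * m
    llb_w = np.where(yb == 1, log_expit(eta_det[..., 1]), log_expit(-eta_det[..., 1])) * m
    slices = d.season_slices()
    lla = _season_sums(lla_w, slices)
    llb = _season_sums(llb_w, slices)
    any_a = _season_any((ya == 1) & m, slices)
    any_b = _season_any((yb == 1) & m, slices)
    lla_abs = np.where(any_a, _NEG_INF, 0.0)
    llb_abs = np.where(any_b, _NEG_INF, 0.0)
    state_ll = np.stack(
        [lla + llb, lla + llb_abs, lla_abs + llb, lla_abs + llb_abs], axis=-1
    )
    total = log_states + state_ll
    mx = total.max(axis=-1)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    log_l = mx + np.log(np.exp(total - mx[..., None]).sum(axis=-1))
    return float(-2.0 * log_l.sum() + penalty)


_NLL = {
    "multiseason": nll_multiseason,
    "multistate": nll_multistate,
    "twospecies": nll_twospecies,
}


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """A maximised model: estimates, -2LL, AIC, covariance, diagnostics."""

    spec: ModelSpec
    params: np.ndarray
    param_names: list[str]
    neg2LL: float
    K: int
    AIC: float
    vcov: np.ndarray | None
    vcov_ok: bool
    n_starts: int
    best_start: int
    grad_norm: float
    boundary: bool
    designs: Designs

    @property
    def label(self) -> str:
        return self.spec.label

    def estimates(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.params))


def _naive_start(designs: Designs, history) -> np.ndarray:
    x0 = np.zeros(designs.n_params)
    if isinstance(history, TwoSpeciesHistory):
        obs_list = [history.a.observations, history.b.observations]
        m = history.a.effort > 0
    else:
        obs_list = [history.observations]
        m = history.effort > 0

    def _safe_logit(p: float) -> float:
        return float(logit(np.clip(p, 0.02, 0.98)))

    det_any = np.zeros(0, dtype=bool)
    rates = []
    for obs in obs_list:
        detected = ((obs > 0) & m).any(axis=1)
        det_any = detected if det_any.size == 0 else det_any | detected
        surveyed = m[detected].sum()
        rate = ((obs > 0) & m)[detected].sum() / surveyed if surveyed else 0.2
        rates.append(rate)
    naive = det_any.mean() if det_any.size else 0.5
    x0[designs.slices["occ"].start] = _safe_logit(naive)
    x0[designs.slices["det"].start] = _safe_logit(float(np.mean(rates)))
    return x0


def _numeric_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            f_pp = fun(x + ei + ej)
            f_pm = fun(x + ei - ej)
            f_mp = fun(x - ei + ej)
            f_mm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[i] * h[j])
    return H


def fit(
    spec: ModelSpec,
    history: DetectionHistory | TwoSpeciesHistory,
    covariates: SiteCovariates | None = None,
    n_starts: int = 10,
    seed: int = 0,
    designs: Designs | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one model by multi-start quasi-Newton.

    ``n_starts`` random N(0, 1) starting vectors are tried in addition
    to one naive start (logits of the raw naive occupancy and detection
    frequency); the best converged start wins, ties broken by lower
    -2LL then lower start index.  The covariance of the estimates comes
    from the inverse numerical Hessian of the negative log-likelihood;
    if that matrix is singular, ``vcov_ok`` is False and a
    pseudo-inverse is reported.
    """
    if designs is None:
        designs = build_design(spec, covariates, history)
    nll = _NLL[spec.family]

    if spec.family == "multiseason" and isinstance(history, DetectionHistory):
        per_season_det = [
            ((history.season_block(t) > 0).any()) for t in range(history.layout.n_seasons)
        ]
        if not all(per_season_det):
            warnings.warn(
                "a season has no detections; occupancy for that season is "
                "weakly identified",
                stacklevel=2,
            )

    def objective(x: np.ndarray) -> float:
        return nll(x, history, designs)

    rng = np.random.default_rng(seed)
    starts = [_naive_start(designs, history)]
    starts += [rng.normal(scale=1.0, size=designs.n_params) for _ in range(n_starts)]
    results = []
    for i, x0 in enumerate(starts):
        try:
            res = minimize(
                objective, x0, method="BFGS",
                options={"gtol": 1e-8, "maxiter": 2000},
            )
            results.append((i, res))
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            results.append((i, exc))
    ok = [(i, r) for i, r in results if not isinstance(r, Exception) and np.isfinite(r.fun)]
    if not ok:
        details = "; ".join(f"start {i}: {r}" for i, r in results)
        raise RuntimeError(f"all optimisation starts failed: {details}")
    best_i, best = min(ok, key=lambda t: (t[1].fun, t[0]))

    K = designs.n_params
    neg2ll = float(best.fun)
    half = lambda x: 0.5 * objective(x)  # noqa: E731  (Hessian of -log L)
    H = _numeric_hessian(half, best.x)
    vcov_ok = True
    try:
        vcov = np.linalg.inv(H)
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
        vcov_ok = False
    # symmetrise against finite-difference noise
    vcov = 0.5 * (vcov + vcov.T)

    psi_hat = expit(designs.occ.X @ best.x[designs.slices["occ"]])
    boundary = bool(np.any(psi_hat > 0.999) or np.any(psi_hat < 0.001))

    return FitResult(
        spec=spec,
        params=best.x,
        param_names=list(designs.param_names),
        neg2LL=neg2ll,
        K=K,
        AIC=neg2ll + 2 * K,
        vcov=vcov,
        vcov_ok=vcov_ok,
        n_starts=len(starts),
        best_start=best_i,
        grad_norm=float(np.linalg.norm(best.jac)) if best.jac is not None else np.nan,
        boundary=boundary,
        designs=designs,
    )


# ---------------------------------------------------------------------------
# prediction


_KIND_BLOCK = {
    "occupancy": "occ",
    "detection": "det",
    "conditional_occupancy": "r",
    "conditional_detection": "delta",
}


def _prediction_row(
    cols: list[str], factor: float, cov: float | None, effort: float, state: float
) -> np.ndarray:
    values = {
        "intercept": 1.0,
        "factor": factor,
        "cov": cov,
        "cov_x_factor": (cov if cov is not None else 0.0) * factor,
        "effort": effort,
        "state": state,
        "state_x_factor": state * factor,
    }
    row = []
    for c in cols:
        v = values[c]
        if v is None:
            raise ValueError("model has a covariate column but no value supplied")
        row.append(v)
    return np.asarray(row, dtype=float)


def predict_probabilities(
    fitres: FitResult,
    covariate_values=None,
    season_or_species: str = "winter",
    kind: str = "occupancy",
    effort: float = 7.0,
    state: int = 3,
    ci_level: float = 0.95,
) -> dict:
    """Probability, SE and CI on a covariate grid, by the delta method.

    ``covariate_values`` are on the raw scale (the model's sqrt / log
    transform is applied internally).  ``season_or_species`` is
    'winter'/'summer' for seasonal families or 'A'/'B' for the
    two-species family.  For the multistate family ``kind`` may also be
    'conditional_occupancy' or 'conditional_detection', and ``state``
    (2 or 3) selects which detection probability is meant.  SEs are
    delta-method on the logit scale; the CI is the inverse-logit of
    ``eta +- z * se``.  Values outside the fitted covariate range are
    flagged as extrapolation.
    """
    d = fitres.designs
    spec = fitres.spec
    if kind not in _KIND_BLOCK:
        raise ValueError(f"kind must be one of {sorted(_KIND_BLOCK)}")
    block_key = _KIND_BLOCK[kind]
    if block_key not in d.slices:
        raise ValueError(f"{kind!r} not defined for family {spec.family!r}")
    block: _Block = getattr(d, "det" if block_key == "det" else block_key)
    if block_key == "occ":
        block = d.occ
    elif block_key == "r":
        block = d.r
    elif block_key == "delta":
        block = d.delta

    if spec.family == "twospecies":
        factor = {"A": 0.0, "B": 1.0}[season_or_species]
    else:
        factor = {"winter": 0.0, "summer": 1.0}[season_or_species]
        if "factor" not in block.cols:
            factor = 0.0

    uses_cov = "cov" in block.cols
    if covariate_values is None:
        cov_t = np.array([None]) if not uses_cov else None
        if cov_t is None:
            raise ValueError("model block has a covariate; supply covariate_values")
        grid_t = [None]
        scalar = True
    else:
        raw = np.atleast_1d(np.asarray(covariate_values, dtype=float))
        grid_t = list(apply_transform(spec.covariate, raw)) if uses_cov else [None] * len(raw)
        scalar = np.isscalar(covariate_values) or np.ndim(covariate_values) == 0

    sl = d.slices[block_key]
    theta = fitres.params[sl]
    V = fitres.vcov[sl, sl] if fitres.vcov is not None else None
    state3 = 1.0 if state == 3 else 0.0
    z = float(-_norm_ppf((1 - ci_level) / 2))
    probs, ses, los, his, extrap = [], [], [], [], []
    for c in grid_t:
        x = _prediction_row(block.cols, factor, c, effort, state3)
        eta = float(x @ theta)
        p = float(expit(eta))
        if V is not None:
            se_eta = float(np.sqrt(max(x @ V @ x, 0.0)))
            lo, hi_ = float(expit(eta - z * se_eta)), float(expit(eta + z * se_eta))
            se_p = p * (1 - p) * se_eta
        else:  # pragma: no cover
            se_p, lo, hi_ = np.nan, np.nan, np.nan
        probs.append(p)
        ses.append(se_p)
        los.append(lo)
        his.append(hi_)
        out_of_range = (
            uses_cov
            and d.cov_range is not None
            and not (d.cov_range[0] - 1e-12 <= c <= d.cov_range[1] + 1e-12)
        )
        extrap.append(bool(out_of_range))
    squeeze = (lambda a: a[0]) if scalar else np.asarray
    return {
        "probability": squeeze(probs),
        "se": squeeze(ses),
        "ci_low": squeeze(los),
        "ci_high": squeeze(his),
        "extrapolated": squeeze(extrap),
    }


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))
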