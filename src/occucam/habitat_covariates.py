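"""Plant-composition pipeline and habitat covariates.

Vegetation at each camera location is scored by species within seven
fixed height tiers on a modified Braun-Blanquet cover-abundance scale
(1 = <1%, 2 = 1-5%, 3 = 6-25%, 4 = 26-50%, 5 = 51-75%, 6 = 76-100%).
Scores are converted to class midpoints and summed over tiers to give a
per-species *importance value* (a volume-weighted abundance), which is
standardised by site totals, fourth-root transformed, and fed into
Bray-Curtis similarities, non-metric multidimensional scaling (NMDS),
group-average (UPGMA) clustering, and SIMPER decomposition of
between-group dissimilarity.

The module also holds the per-site habitat covariates used by the
occupancy models -- direct / diffuse / total solar radiation (total
mols m^-2 day^-1, measured separately for winter and summer), mineral
soil C:N ratio, pH, Bray-2 available P (ug g^-1), and the NMDS Axis 1
score -- together with the model-scale transforms (square root for
solar radiation, which may be exactly zero; natural log for the soil
fertility measures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

#: class -> midpoint of the percentage cover range (class 1 is "<1%")
COVER_MIDPOINTS = {0: 0.0, 1: 0.5, 2: 3.0, 3: 15.5, 4: 38.0, 5: 63.0, 6: 88.0}

HEIGHT_TIERS = (
    "0-30cm", "30cm-2m", "2-5m", "5-12m", "12-25m", ">25m", "epiphyte",
)

#: canonical covariate names -> SiteCovariates column stems
SOLAR_COVARIATES = {"Direct": "direct", "Diffuse": "diffuse", "Total": "total"}
SOIL_COVARIATES = {"CN": "cn", "pH": "ph", "P": "p_avail"}
PLANT_COVARIATES = {"Axis1": "axis1"}
ALL_COVARIATES = {**SOLAR_COVARIATES, **SOIL_COVARIATES, **PLANT_COVARIATES}


@dataclass
class SiteCovariates:
    """Per-site habitat measurements.

    ``data`` is indexed by site id.  Solar radiation columns are
    season-specific (``direct_winter``, ``direct_summer``, ...); soil and
    ordination columns (``cn``, ``ph``, ``p_avail``, ``axis1``) are
    constant across seasons.  ``transformed`` marks frames already on the
    model scale, with ``transforms`` recording what was applied per
    column so predictions can accept raw values.
    """

    data: pd.DataFrame
    transformed: bool = False
    transforms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate site ids in covariate table")
        if not self.transformed:
            self._validate_raw()

    def _validate_raw(self) -> None:
        df = self.data
        for stem in ("direct", "diffuse", "total"):
            for col in df.columns:
                if col == stem or col.startswith(stem + "_"):
                    if (pd.to_numeric(df[col], errors="coerce") < 0).any():
                        raise ValueError(f"negative solar radiation in {col!r}")
        if "p_avail" in df.columns and (df["p_avail"] <= 0).any():
            raise ValueError("available P must be positive")
        for season in ("winter", "summer"):
            cols = [f"{stem}_{season}" for stem in ("direct", "diffuse", "total")]
            if all(c in df.columns for c in cols):
                gap = df[cols[2]] - df[cols[0]] - df[cols[1]]
                if np.abs(gap).max() > 1e-6:
                    raise ValueError(
                        f"total solar != direct + diffuse in {season} "
                        f"(max gap {np.abs(gap).max():.3g})"
                    )

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    def column_for(self, name: str, season: str | None = None) -> str:
        """Resolve a canonical covariate name to a column of ``data``."""
        if name not in ALL_COVARIATES:
            raise KeyError(f"unknown covariate {name!r}; choose from {sorted(ALL_COVARIATES)}")
        stem = ALL_COVARIATES[name]
        if name in SOLAR_COVARIATES and season is not None:
            seasonal = f"{stem}_{season}"
            if seasonal in self.data.columns:
                return seasonal
        if stem in self.data.columns:
            return stem
        raise KeyError(
            f"covariate {name!r} (column {stem!r}"
            + (f" or {stem}_{season!r}" if season else "")
            + ") absent from covariate table"
        )

    def values_for(self, name: str, season: str | None, site_ids) -> np.ndarray:
        col = self.column_for(name, season)
        return self.data.loc[list(site_ids), col].to_numpy(dtype=float)


def transform_covariates(raw: SiteCovariates) -> SiteCovariates:
    """Apply the model-scale transforms to a raw covariate table.

    Square root for the solar radiation columns (zeros are legitimate:
    fully shaded sites receive no direct radiation, and sqrt(0) = 0
    needs no offset), natural logarithm for soil C:N ratio, pH and
    available P.  NMDS Axis 1 scores pass through unchanged.
    """
    if raw.transformed:
        raise ValueError("covariates already transformed")
    df = raw.data.copy()
    transforms: dict = {}
    solar_stems = tuple(SOLAR_COVARIATES.values())
    soil_stems = tuple(SOIL_COVARIATES.values())
    for col in df.columns:
        stem = col.rsplit("_", 1)[0] if col.endswith(("_winter", "_summer")) else col
        if stem in solar_stems:
            vals = df[col].to_numpy(dtype=float)
            if (vals < 0).any():
                raise ValueError(f"negative solar radiation in {col!r}")
            df[col] = np.sqrt(vals)
            transforms[col] = "sqrt"
        elif col in soil_stems:
            vals = df[col].to_numpy(dtype=float)
            if (vals <= 0).any():
                raise ValueError(f"non-positive value in soil covariate {col!r}")
            df[col] = np.log(vals)
            transforms[col] = "log"
    return SiteCovariates(df, transformed=True, transforms=transforms)


def apply_transform(name: str, value):
    """Transform raw covariate values to the model scale by name."""
    value = np.asarray(value, dtype=float)
    if name in SOLAR_COVARIATES:
        if (value < 0).any():
            raise ValueError("negative solar radiation")
        return np.sqrt(value)
    if name in SOIL_COVARIATES:
        if (value <= 0).any():
            raise ValueError("non-positive soil covariate")
        return np.log(value)
    return value


# ---------------------------------------------------------------------------
# plant composition


def cover_to_importance(cover: pd.DataFrame) -> pd.DataFrame:
    """Importance values from long-format cover-abundance scores.

    ``cover`` has columns ``site``, ``species``, ``tier``, ``score``
    (0 = absent, 1-6 = Braun-Blanquet class).  Each score maps to the
    midpoint of its percentage-cover range and midpoints are summed over
    height tiers, giving a sites x species matrix of importance values.
    """
    required = {"site", "species", "tier", "score"}
    if not required <= set(cover.columns):
        raise ValueError(f"cover table needs columns {sorted(required)}")
    scores = cover["score"].to_numpy()
    bad = ~np.isin(scores, list(COVER_MIDPOINTS))
    if bad.any():
        raise ValueError(
            f"cover-abundance scores must be 0-6; found {sorted(set(scores[bad]))}"
        )
    work = cover.assign(midpoint=cover["score"].map(COVER_MIDPOINTS))
    imp = (
        work.pivot_table(
            index="site", columns="species", values="midpoint",
            aggfunc="sum", fill_value=0.0,
        )
        .sort_index()
        .sort_index(axis=1)
    )
    imp.index.name = "site"
    return imp


def standardize_fourth_root(importance: pd.DataFrame, percent: bool = False) -> pd.DataFrame:
    """Standardise rows to site totals, then fourth-root transform.

    Standardisation first (each row becomes proportions of the site
    total, optionally x100), transform second; the transform down-weights
    dominant species so rarer ones influence the similarities.
    """
    mat = importance.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("importance values must be non-negative")
    totals = mat.sum(axis=1)
    if (totals <= 0).any():
        empty = list(importance.index[totals <= 0])
        raise ValueError(f"sites with no recorded species: {empty}")
    out = mat / totals[:, None]
    if percent:
        out = out * 100.0
    return pd.DataFrame(out ** 0.25, index=importance.index, columns=importance.columns)


def bray_curtis(mat: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis similarity, S = 1 - sum|x-y| / sum(x+y).

    Values lie in [0, 1] with unit diagonal.  A pair of all-zero rows
    has undefined similarity and is rejected.
    """
    if not isinstance(mat, pd.DataFrame):
        mat = pd.DataFrame(np.asarray(mat, dtype=float))
    X = mat.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        raise ValueError(
            "Bray-Curtis undefined between all-zero sites: "
            f"{list(mat.index[zero_rows])}"
        )
    sim = 1.0 - squareform(pdist(X, metric="braycurtis"))
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=mat.index, columns=mat.index)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    """NMDS configuration: site coordinates, Kruskal stress-1, diagnostics."""

    coords: pd.DataFrame  # columns Axis1, Axis2, ...
    stress: float
    n_restarts: int
    converged: bool
    restart_stresses: np.ndarray


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    return float(np.sqrt(np.sum((d - dhat) ** 2) / np.sum(d**2)))


def _nmds_once(diss: np.ndarray, n: int, dims: int, rng, max_iter: int, tol: float):
    X = rng.normal(size=(n, dims))
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    best_stress = np.inf
    best_X = X.copy()
    converged = False
    prev = np.inf
    for _ in range(max_iter):
        d = pdist(X)
        if (d == 0).any():
            d = d + 1e-12
        # monotone regression of configuration distances on dissimilarities;
        # ties in the dissimilarities are ordered by current distance
        # (Kruskal's primary treatment of ties)
        order = np.lexsort((d, diss))
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
        stress = _stress1(d, dhat)
        if stress < best_stress:
            best_stress, best_X = stress, X.copy()
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform with disparities dhat (majorisation step)
        ratio = squareform(dhat / d)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = B @ X / n
    return best_X, best_stress, converged


def nmds(
    sim: pd.DataFrame,
    dims: int = 2,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric multidimensional scaling of a similarity matrix.

    Minimises Kruskal stress-1 on dissimilarities ``1 - S`` by
    alternating isotonic (monotone) regression with Guttman majorisation
    steps, from ``restarts`` random Gaussian starts; the configuration
    with the lowest stress wins, ties broken by restart index.  The
    returned configuration is centred and rotated to principal axes so
    that Axis 1 carries the most variance, with a deterministic sign
    convention.
    """
    S = np.asarray(sim, dtype=float)
    n = S.shape[0]
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("similarity matrix must be square and symmetric")
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} sites for {dims}-d ordination")
    diss = squareform(1.0 - S, checks=False)
    rng = np.random.default_rng(seed)
    results = [
        _nmds_once(diss, n, dims, rng, max_iter, tol) for _ in range(restarts)
    ]
    stresses = np.array([r[1] for r in results])
    best = int(np.argmin(stresses))
    X, stress, converged = results[best]
    # principal-axis rotation with a deterministic sign convention
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    for k in range(dims):
        j = int(np.argmax(np.abs(X[:, k])))
        if X[j, k] < 0:
            X[:, k] = -X[:, k]
    index = sim.index if isinstance(sim, pd.DataFrame) else pd.RangeIndex(n)
    coords = pd.DataFrame(
        X, index=index, columns=[f"Axis{k + 1}" for k in range(dims)]
    )
    return OrdinationResult(coords, float(stress), restarts, bool(converged), stresses)


def cluster_group_average(sim: pd.DataFrame, n_groups: int) -> pd.Series:
    """Cut a UPGMA (group-average) tree on Bray-Curtis dissimilarity.

    Returns integer group labels (1..n_groups) indexed by site, with
    groups numbered by first appearance in site order.
    """
    S = np.asarray(sim, dtype=float)
    n = S.shape[0]
    if not 1 <= n_groups <= n:
        raise ValueError(f"n_groups must be in 1..{n}")
    diss = squareform(1.0 - S, checks=False)
    tree = linkage(diss, method="average")
    labels = fcluster(tree, t=n_groups, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    out = pd.Series(
        [relabel[lab] for lab in labels],
        index=sim.index if isinstance(sim, pd.DataFrame) else pd.RangeIndex(n),
        name="group",
    )
    return out


def simper(mat: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-species contributions to between-group Bray-Curtis dissimilarity.

    For every pair of groups, the average dissimilarity over cross pairs
    of sites is decomposed by species: species k contributes the mean of
    ``|x_ik - x_jk| / sum_m (x_im + x_jm)`` over cross pairs (i, j), so
    contributions sum exactly to the pair's average dissimilarity.
    Rows are sorted by contribution within each group pair.
    """
    groups = pd.Series(groups, index=mat.index) if not isinstance(groups, pd.Series) else groups
    groups = groups.loc[mat.index]
    X = mat.to_numpy(dtype=float)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("SIMPER needs at least two groups")
    rows = []
    for ga, gb in combinations(labels, 2):
        ia = np.flatnonzero((groups == ga).to_numpy())
        ib = np.flatnonzero((groups == gb).to_numpy())
        if len(ia) == 0 or len(ib) == 0:
            raise ValueError(f"empty group in pair ({ga}, {gb})")
        contrib = np.zeros(X.shape[1])
        for i in ia:
            for j in ib:
                denom = (X[i] + X[j]).sum()
                if denom == 0:
                    raise ValueError(
                        f"Bray-Curtis undefined for all-zero pair "
                        f"({mat.index[i]}, {mat.index[j]})"
                    )
                contrib += np.abs(X[i] - X[j]) / denom
        contrib /= len(ia) * len(ib)
        total = contrib.sum()
        for k, sp in enumerate(mat.columns):
            rows.append(
                {
                    "group_1": ga,
                    "group_2": gb,
                    "species": sp,
                    "contribution": contrib[k],
                    "contribution_pct": 100.0 * contrib[k] / total if total > 0 else 0.0,
                    "mean_dissimilarity": total,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["group_1", "group_2", "contribution", "species"],
        ascending=[True, True, False, True],
        kind="stable",
    ).reset_index(drop=True)
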