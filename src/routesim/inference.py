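"""ABC machinery: rejection, model choice, PLS, GLM posteriors, validation.

A reference table holds one record per simulation: the model label, the
drawn parameters and the summary statistics.  Statistics are standardized
by their pooled standard deviation before Euclidean distances are taken.
Model choice retains the fraction ``delta`` of records closest to the
observed vector and reports per-model proportions; Bayes factors are
ratios of model marginal densities at the observed statistics.  Parameter
estimation uses the ABC-GLM adjustment: an ordinary-least-squares linear
model of (possibly PLS-transformed) statistics on parameters is fitted to
the retained records, and the posterior of each parameter is evaluated on
a regular grid with the remaining parameters integrated by Monte Carlo
over the retained draws.  Calibration is checked with posterior quantiles
of pseudo-observations and a Kolmogorov–Smirnov test against uniformity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .sumstats import StatVector

__all__ = [
    "ReferenceTable",
    "ModelChoiceResult",
    "PosteriorResult",
    "standardize",
    "model_choice",
    "bayes_factor",
    "fit_pls",
    "PLSTransform",
    "glm_estimate",
    "fit_p_value",
    "posterior_quantile_validation",
]

DEFAULT_RETENTIONS = (0.0025, 0.005, 0.01)


@dataclass
class ReferenceTable:
    """Per-simulation records of (model, parameters, statistics)."""

    table: pd.DataFrame
    param_names: list[str]
    stat_names: list[str]

    def __post_init__(self):
        missing = [c for c in ["model", *self.param_names, *self.stat_names]
                   if c not in self.table.columns]
        if missing:
            raise ValueError(f"reference table lacks columns {missing}")
        if self.table[self.stat_names].isna().any().any():
            raise ValueError("reference table has missing statistics")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def models(self) -> list[str]:
        return list(dict.fromkeys(self.table["model"]))

    def n_records(self, model: str) -> int:
        return int((self.table["model"] == model).sum())

    def subset(self, model: str) -> "ReferenceTable":
        sub = self.table[self.table["model"] == model].reset_index(drop=True)
        return ReferenceTable(sub, self.param_names, self.stat_names)

    def stats_matrix(self) -> np.ndarray:
        return self.table[self.stat_names].to_numpy(dtype=float)

    def params_matrix(self, cols: list[str] | None = None) -> np.ndarray:
        return self.table[cols or self.param_names].to_numpy(dtype=float)


def standardize(ref: ReferenceTable, obs: StatVector):
    """Scale statistics by their SD over the pooled reference table.

    Zero-SD statistics carry no distance information and are dropped from
    both the table and the observed vector.  Returns
    ``(scaled_ref_matrix, scaled_obs_vector, kept_names)``.
    """
    X = ref.stats_matrix()
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all statistics have zero variance in the reference table")
    kept = [n for n, k in zip(ref.stat_names, keep) if k]
    obs_vec = obs.as_array(kept)
    return X[:, keep] / sd[keep], obs_vec / sd[keep], kept


def _retained_indices(X: np.ndarray, x_obs: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the ceil(fraction*N) records nearest to the observation.

    Distances are Euclidean on the standardized statistics; ties are
    broken by record index (stable sort).
    """
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty reference table")
    if not 0 < fraction <= 1:
        raise ValueError("retention fraction must lie in (0, 1]")
    k = math.ceil(fraction * n)
    d = np.sqrt(np.square(X - x_obs).sum(axis=1))
    order = np.argsort(d, kind="stable")
    return order[:k]


@dataclass
class ModelChoiceResult:
    """Rejection-based model comparison at one retention fraction."""

    delta: float
    n_retained: int
    proportions: dict[str, float]
    retained_index: np.ndarray
    bayes_factors: dict[tuple[str, str], float] | None = None
    p_values: dict[str, float] | None = None
    marginal_densities: dict[str, float] | None = None


def model_choice(ref: ReferenceTable, obs: StatVector, delta: float = 0.005) -> ModelChoiceResult:
    """Retain the fraction ``delta`` of records closest to ``obs``.

    Reports the proportion of retained records belonging to each model;
    with ``delta=1`` the proportions equal each model's share of the table.
    """
    X, x_obs, _ = standardize(ref, obs)
    idx = _retained_indices(X, x_obs, delta)
    labels = ref.table["model"].to_numpy()[idx]
    props = {m: float((labels == m).mean()) for m in ref.models}
    return ModelChoiceResult(delta, len(idx), props, idx)


def bayes_factor(f_a: float, f_b: float) -> float:
    """Bayes factor B_AB = fM_A(s_obs) / fM_B(s_obs)."""
    if f_b < 0 or f_a < 0:
        raise ValueError("marginal densities must be non-negative")
    if f_b == 0:
        warnings.warn("zero marginal density for model B; Bayes factor is infinite")
        return math.inf
    return f_a / f_b


class PLSTransform:
    """Projection of standardized statistics onto PLS components.

    Components are extracted sequentially (NIPALS), so the first ``k``
    columns of the rotation give the ``k``-component projection.
    """

    def __init__(self, stat_names, sd, x_mean, rotations, max_components):
        self.stat_names = list(stat_names)
        self.sd = sd
        self.x_mean = x_mean
        self.rotations = rotations
        self.max_components = max_components

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        k = n_components or self.max_components
        if k > self.max_components:
            raise ValueError("more components requested than fitted")
        Z = np.atleast_2d(X) / self.sd
        return (Z - self.x_mean) @ self.rotations[:, :k]

    def transform_obs(self, obs: StatVector, n_components: int | None = None) -> np.ndarray:
        return self.transform(obs.as_array(self.stat_names), n_components)[0]


def fit_pls(
    ref: ReferenceTable,
    max_components: int = 6,
    param_cols: list[str] | None = None,
    n_folds: int = 10,
    seed: int = 0,
):
    """PLS regression of parameters on standardized statistics.

    Returns ``(transform, rmsep)`` where ``rmsep`` is a DataFrame of the
    root-mean-squared error of prediction per parameter for each component
    count 1..max_components, estimated by k-fold cross-validation.  The
    RMSEP chart shows how much information the statistics carry on each
    parameter and guides the choice of the component count.
    """
    if param_cols is None:
        param_cols = [
            c for c in ref.param_names if not ref.table[c].isna().any()
        ]
    sd_obs_dummy = StatVector({n: 0.0 for n in ref.stat_names})
    X, _, kept = standardize(ref, sd_obs_dummy)
    if max_components > X.shape[1]:
        raise ValueError(
            f"max_components={max_components} exceeds the {X.shape[1]} usable statistics"
        )
    Y = ref.params_matrix(param_cols)
    rmsep = np.zeros((max_components, Y.shape[1]))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for k in range(1, max_components + 1):
        sq = np.zeros(Y.shape[1])
        for train, test in kf.split(X):
            pls = PLSRegression(n_components=k, scale=False)
            pls.fit(X[train], Y[train])
            pred = pls.predict(X[test])
            sq += np.square(pred - Y[test]).sum(axis=0)
        rmsep[k - 1] = np.sqrt(sq / len(Y))
    pls_full = PLSRegression(n_components=max_components, scale=False)
    pls_full.fit(X, Y)
    sd_full = ref.stats_matrix().std(axis=0, ddof=1)
    keep_sd = sd_full[[ref.stat_names.index(n) for n in kept]]
    transform = PLSTransform(
        kept, keep_sd, X.mean(axis=0), pls_full.x_rotations_, max_components
    )
    rmsep_df = pd.DataFrame(
        rmsep, index=pd.RangeIndex(1, max_components + 1, name="n_components"),
        columns=param_cols,
    )
    return transform, rmsep_df


@dataclass
class PosteriorResult:
    """ABC-GLM posterior summaries for one model."""

    param_names: list[str]
    grids: dict[str, np.ndarray]
    densities: dict[str, np.ndarray]
    modes: dict[str, float]
    hpd_intervals: dict[str, tuple[float, float]]
    marginal_density: float
    n_retained: int
    n_pls: int | None
    degenerate: dict[str, float] = field(default_factory=dict)
    _internals: dict = field(default_factory=dict, repr=False)

    def cdf_at(self, name: str, value: float) -> float:
        """Posterior CDF of one parameter at ``value`` (grid trapezoid)."""
        g, d = self.grids[name], self.densities[name]
        cum = np.concatenate([[0.0], np.cumsum(np.diff(g) * (d[1:] + d[:-1]) / 2.0)])
        cum /= cum[-1] if cum[-1] > 0 else 1.0
        return float(np.interp(value, g, cum))


def _log_mvn_terms(S_retained, obs_vec, theta, coef, cov):
    """Cholesky pieces for vectorized multivariate-normal evaluations."""
    q = cov.shape[0]
    jitter = max(np.trace(cov) / q * 1e-9, 1e-300)
    for _ in range(12):
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(q))
            break
        except np.linalg.LinAlgError:
            jitter *= 100.0
    else:
        raise np.linalg.LinAlgError("residual covariance is not positive definite")
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    c0 = 0.5 * (q * math.log(2.0 * math.pi) + logdet)
    mu = coef[0] + theta @ coef[1:]
    y = obs_vec - mu  # (k, q) deviations at the retained draws
    solve = np.linalg.solve
    y_w = solve(chol, y.T).T
    return chol, c0, y_w


def glm_estimate(
    ref_one_model: ReferenceTable,
    obs: StatVector,
    retain: float = 0.005,
    transform: PLSTransform | None = None,
    n_pls: int | None = None,
    param_cols: list[str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_grid: int = 1000,
) -> PosteriorResult:
    """ABC-GLM posterior estimation under a single model.

    Retains the nearest ``retain`` fraction of records, fits the linear
    Gaussian model ``stats = c + B theta + eps`` by OLS on the retained
    set, and evaluates each parameter's posterior density on a regular
    ``n_grid``-point grid over its prior support, integrating the other
    parameters by Monte Carlo over the retained draws.  Also reports the
    model's marginal density ``fM(obs)`` (mean retained likelihood of the
    observation) used for Bayes factors.
    """
    models = ref_one_model.models
    if len(models) != 1:
        raise ValueError("glm_estimate needs a single-model reference table")
    if param_cols is None:
        # drop parameters undefined under this model (all-NaN columns)
        param_cols = [
            c for c in ref_one_model.param_names
            if not ref_one_model.table[c].isna().any()
        ]
    if transform is not None:
        S_all = transform.transform(ref_one_model.stats_matrix(), n_pls)
        obs_vec = transform.transform_obs(obs, n_pls)
        # distances in the transformed space
        sdt = S_all.std(axis=0, ddof=1)
        sdt[sdt == 0] = 1.0
        idx = _retained_indices(S_all / sdt, obs_vec / sdt, retain)
    else:
        Z, z_obs, kept = standardize(ref_one_model, obs)
        S_all, obs_vec = Z, z_obs
        idx = _retained_indices(Z, z_obs, retain)

    S = S_all[idx]
    theta_full = ref_one_model.params_matrix(param_cols)
    theta = theta_full[idx]
    k, p = theta.shape
    degenerate = {
        name: float(theta[0, j])
        for j, name in enumerate(param_cols)
        if np.ptp(theta[:, j]) == 0
    }
    X = np.column_stack([np.ones(k), theta])
    coef, *_ = np.linalg.lstsq(X, S, rcond=None)
    resid = S - X @ coef
    dof = max(k - p - 1, 1)
    cov = resid.T @ resid / dof
    chol, c0, y_w = _log_mvn_terms(S, obs_vec, theta, coef, cov)
    a = np.square(y_w).sum(axis=1)  # quadratic form per retained draw
    log_f_obs = -0.5 * a - c0
    marginal = float(np.exp(log_f_obs).mean())

    if bounds is None:
        bounds = {
            name: (float(theta_full[:, j].min()), float(theta_full[:, j].max()))
            for j, name in enumerate(param_cols)
        }
    B = coef[1:]  # (p, q)
    grids, densities, modes, hpds = {}, {}, {}, {}
    for j, name in enumerate(param_cols):
        lo, hi = bounds[name]
        if name in degenerate or hi <= lo:
            v = degenerate.get(name, lo)
            grid = np.array([v])
            dens = np.array([math.inf])
            grids[name], densities[name] = grid, dens
            modes[name] = v
            hpds[name] = (v, v)
            continue
        grid = np.linspace(lo, hi, n_grid)
        bj_w = np.linalg.solve(chol, B[j])  # whitened effect of parameter j
        g = float(bj_w @ bj_w)
        b = y_w @ bj_w  # (k,)
        dx = grid[None, :] - theta[:, j, None]  # (k, n_grid)
        logpdf = -0.5 * (a[:, None] - 2.0 * dx * b[:, None] + dx * dx * g) - c0
        m = logpdf.max()
        dens = np.exp(logpdf - m).mean(axis=0)
        area = np.trapezoid(dens, grid)
        if area <= 0 or not np.isfinite(area):
            dens = np.full(n_grid, 1.0 / (hi - lo))
        else:
            dens = dens / area
        grids[name], densities[name] = grid, dens
        modes[name] = float(grid[np.argmax(dens)])
        hpds[name] = _hpd_from_grid(grid, dens, 0.95)

    return PosteriorResult(
        param_names=list(param_cols),
        grids=grids,
        densities=densities,
        modes=modes,
        hpd_intervals=hpds,
        marginal_density=marginal,
        n_retained=k,
        n_pls=(n_pls or (transform.max_components if transform else None)),
        degenerate=degenerate,
        _internals={
            "chol": chol, "c0": c0, "coef": coef, "theta": theta, "S": S,
            "obs_vec": obs_vec, "log_f_obs": log_f_obs,
        },
    )


def _hpd_from_grid(grid: np.ndarray, dens: np.ndarray, mass: float) -> tuple[float, float]:
    """Highest-posterior-density interval from gridded density values."""
    w = np.empty_like(grid)
    w[:-1] = np.diff(grid)
    w[-1] = w[-2]
    probs = dens * w
    probs = probs / probs.sum()
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(probs[order])
    n_in = int(np.searchsorted(cum, mass)) + 1
    sel = np.sort(order[:n_in])
    return float(grid[sel[0]]), float(grid[sel[-1]])


def fit_p_value(result: PosteriorResult) -> float:
    """Goodness-of-fit probability of the observation under the GLM.

    The fraction of retained records whose marginal density under the
    fitted model is at most that of the observation: near 1 when the
    observation sits in the core of the retained cloud, near 0 when it is
    an outlier (no fit).
    """
    internals = result._internals
    chol, c0, coef, theta, S = (
        internals["chol"], internals["c0"], internals["coef"],
        internals["theta"], internals["S"],
    )
    mu = coef[0] + theta @ coef[1:]
    f_obs = result.marginal_density
    f_records = np.empty(len(S))
    for i in range(len(S)):
        y_w = np.linalg.solve(chol, (S[i] - mu).T).T
        a = np.square(y_w).sum(axis=1)
        f_records[i] = np.exp(-0.5 * a - c0).mean()
    return float((f_records <= f_obs).mean())


def posterior_quantile_validation(
    ref_one_model: ReferenceTable,
    simulate_stats,
    n_pseudo: int = 100,
    seed: int = 0,
    retain: float = 0.005,
    transform: PLSTransform | None = None,
    param_cols: list[str] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    param_sampler=None,
    n_grid: int = 200,
):
    """Posterior-quantile calibration check with pseudo-observations.

    Draws ``n_pseudo`` parameter vectors (by default uniformly from the
    per-parameter bounds), simulates a statistic vector for each with
    ``simulate_stats(params_dict, seed)``, estimates the posterior, and
    records the posterior CDF at the true value of each parameter.  For a
    well-calibrated estimator these quantiles are uniform on (0, 1); a
    one-sample Kolmogorov–Smirnov test per parameter quantifies deviation.

    Returns ``(quantiles_df, ks_df)``.
    """
    if param_cols is None:
        param_cols = [
            c for c in ref_one_model.param_names
            if not ref_one_model.table[c].isna().any()
        ]
    rng = np.random.default_rng(seed)
    if bounds is None:
        theta_full = ref_one_model.params_matrix(param_cols)
        bounds = {
            name: (float(theta_full[:, j].min()), float(theta_full[:, j].max()))
            for j, name in enumerate(param_cols)
        }
    rows = []
    for i in range(n_pseudo):
        if param_sampler is not None:
            truth = param_sampler(rng)
        else:
            truth = {n: rng.uniform(*bounds[n]) for n in param_cols}
        stats = simulate_stats(truth, int(rng.integers(2**31)))
        if stats is None:  # failed simulation (e.g. no colonization)
            continue
        post = glm_estimate(
            ref_one_model, stats, retain=retain, transform=transform,
            param_cols=param_cols, bounds=bounds, n_grid=n_grid,
        )
        rows.append({n: post.cdf_at(n, truth[n]) for n in param_cols})
    quantiles = pd.DataFrame(rows)
    ks = pd.DataFrame(
        {
            n: sps.kstest(quantiles[n].to_numpy(), "uniform")
            for n in param_cols
        },
        index=["statistic", "p_value"],
    ).T
    return quantiles, ks


def quantile_ks(quantiles: np.ndarray):
    """KS test of posterior quantiles against Uniform(0,1)."""
    return sps.kstest(np.asarray(quantiles, dtype=float), "uniform")
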