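"""Bayesian threshold (probit) animal model fitted by Gibbs sampling.

The binary outcome Y is modelled through a latent liability z = eta + e,
e ~ N(0, 1), with Y = 1 iff z > 0 and linear predictor

    eta = X beta + Z1 a + Z2 ss

where beta are fixed effects, a ~ N(0, H sigma2_a) are additive genetic
effects structured by the single-step relationship matrix, and
ss ~ N(0, I sigma2_ss) are iid service-sire effects. Data augmentation draws
the liabilities from their truncated-normal full conditionals; location
effects are updated by single-site Gibbs from exact conjugate conditionals;
variances are drawn from scaled inverse chi-square conditionals. The
residual variance is fixed at 1 for identification, with a single threshold
at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit
from scipy.special import ndtr, ndtri

from .config import GibbsConfig

__all__ = [
    "ModelDesign",
    "GibbsState",
    "PosteriorSummary",
    "build_design",
    "truncated_liability_draw",
    "sample_liabilities",
    "sample_location",
    "sample_variances",
    "run_gibbs",
    "heritability",
    "effective_sample_size",
    "geweke_z",
    "convergence_diagnostics",
]

_VARIANCE_FLOOR = 1e-8
_DIVERGENCE_LIMIT = 1e6


# --------------------------------------------------------------------------
# design


@dataclass
class ModelDesign:
    """Assembled incidence structure for one analysis (one parity).

    ``W = [X | Z1 | Z2]`` is stored as one CSR matrix; ``n_beta``,
    ``n_animals`` and ``n_ss`` give the block widths in that order. The
    first level of every fixed factor except the first one is dropped
    (corner constraint) since X with multiple full factors is rank
    deficient.
    """

    W: sp.csr_matrix
    y: np.ndarray  # int8, -1 marks a missing outcome (liability unconstrained)
    n_beta: int
    n_animals: int
    n_ss: int
    beta_labels: list[str]
    ss_labels: np.ndarray
    animal_column: np.ndarray  # record -> 0-based animal index

    @property
    def n_records(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_coef(self) -> int:
        return self.n_beta + self.n_animals + self.n_ss

    def slices(self) -> tuple[slice, slice, slice]:
        nb, na = self.n_beta, self.n_animals
        return slice(0, nb), slice(nb, nb + na), slice(nb + na, self.n_coef)


def build_design(
    phenotypes: pd.DataFrame,
    n_animals: int,
    factors: list[str] | None = None,
) -> ModelDesign:
    """Build X, Z1, Z2 from a phenotype table.

    Expected columns: ``animal_id`` (1-based pedigree ids), ``service_sire``,
    ``y`` (0/1, NA allowed), plus one column per fixed factor. Factors default
    to every non-reserved column that has at least one observed value; the
    first listed factor keeps all its levels (it absorbs the overall mean),
    later factors drop their first observed level.
    """
    reserved = {"animal_id", "service_sire", "y", "parity"}
    if factors is None:
        factors = [
            c
            for c in phenotypes.columns
            if c not in reserved and phenotypes[c].notna().any()
        ]
    n_rec = phenotypes.shape[0]
    rows = np.arange(n_rec)

    cols: list[np.ndarray] = []
    col_rows: list[np.ndarray] = []
    labels: list[str] = []
    next_col = 0
    for k, f in enumerate(factors):
        vals = phenotypes[f]
        if vals.isna().any():
            raise ValueError(f"factor {f!r} has missing values in this record subset")
        levels = np.sort(pd.unique(vals.to_numpy()))
        drop_first = k > 0
        use = levels[1:] if drop_first else levels
        for lev in use:
            m = (vals == lev).to_numpy()
            col_rows.append(rows[m])
            cols.append(np.full(int(m.sum()), next_col))
            labels.append(f"{f}={lev}")
            next_col += 1
    n_beta = next_col

    animal = phenotypes["animal_id"].to_numpy(dtype=np.int64)
    if animal.min() < 1 or animal.max() > n_animals:
        raise ValueError("animal_id outside 1..n_animals")
    ss_labels = np.sort(pd.unique(phenotypes["service_sire"].to_numpy()))
    ss_index = {v: i for i, v in enumerate(ss_labels)}
    ss_col = np.array([ss_index[v] for v in phenotypes["service_sire"]], dtype=np.int64)

    data = np.ones(sum(len(r) for r in col_rows) + 2 * n_rec)
    r_idx = np.concatenate(col_rows + [rows, rows]) if col_rows else np.concatenate([rows, rows])
    c_idx = np.concatenate(
        cols + [n_beta + animal - 1, n_beta + n_animals + ss_col]
        if cols
        else [n_beta + animal - 1, n_beta + n_animals + ss_col]
    )
    W = sp.coo_matrix(
        (data, (r_idx, c_idx)), shape=(n_rec, n_beta + n_animals + ss_labels.size)
    ).tocsr()

    y_raw = phenotypes["y"]
    y = np.where(y_raw.isna(), -1, y_raw.fillna(0).to_numpy()).astype(np.int8)
    if not np.isin(y, (-1, 0, 1)).all():
        raise ValueError("y must be 0/1 or missing")
    return ModelDesign(
        W=W,
        y=y,
        n_beta=n_beta,
        n_animals=n_animals,
        n_ss=int(ss_labels.size),
        beta_labels=labels,
        ss_labels=ss_labels,
        animal_column=animal - 1,
    )


# --------------------------------------------------------------------------
# state and samplers


@dataclass
class GibbsState:
    z: np.ndarray
    beta: np.ndarray
    a: np.ndarray
    ss: np.ndarray
    sigma2_a: float
    sigma2_ss: float
    sigma2_e: float = 1.0  # fixed: probit identification

    @classmethod
    def initial(cls, design: ModelDesign, config: GibbsConfig) -> "GibbsState":
        return cls(
            z=np.where(design.y == 1, 0.8, -0.8) * (design.y >= 0),
            beta=np.zeros(design.n_beta),
            a=np.zeros(design.n_animals),
            ss=np.zeros(design.n_ss),
            sigma2_a=config.start_sigma2_a,
            sigma2_ss=config.start_sigma2_ss,
        )

    def theta(self) -> np.ndarray:
        return np.concatenate([self.beta, self.a, self.ss])


def truncated_liability_draw(
    eta: np.ndarray, y: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Inverse-CDF draw of z ~ N(eta, 1) truncated by the sign constraint.

    Works on the survival/CDF side nearest the truncation point, which keeps
    the transform well conditioned even for |eta| far beyond 6. y = -1
    (missing outcome) yields an untruncated draw.
    """
    u = np.clip(u, 1e-16, 1.0 - 1e-16)
    z = np.empty_like(eta)
    pos = y == 1
    neg = y == 0
    mis = y == -1
    if pos.any():
        # t = z - eta, truncated to (-eta, inf): invert the survival function
        tail = np.maximum(u[pos] * ndtr(eta[pos]), 1e-300)
        z[pos] = eta[pos] - ndtri(tail)
    if neg.any():
        # t truncated to (-inf, -eta]: invert the CDF
        tail = np.maximum(u[neg] * ndtr(-eta[neg]), 1e-300)
        z[neg] = eta[neg] + ndtri(tail)
    if mis.any():
        z[mis] = eta[mis] + ndtri(u[mis])
    return z


def sample_liabilities(
    state: GibbsState, design: ModelDesign, rng: np.random.Generator
) -> np.ndarray:
    """One data-augmentation pass: redraw every record's latent liability."""
    eta = design.W @ state.theta()
    state.z = truncated_liability_draw(eta, design.y, rng.random(design.n_records))
    return state.z


@njit(cache=False)
def _location_sweep(
    indptr, indices, data, diag_wtw, r, theta, free,
    nb, na, h_indptr, h_indices, h_data, h_diag,
    lam_a, lam_ss, normals,
):  # pragma: no cover - exercised through sample_location
    n = theta.shape[0]
    for i in range(n):
        if not free[i]:
            theta[i] = 0.0
            continue
        acc = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            acc += data[k] * theta[indices[k]]
        d = diag_wtw[i]
        if nb <= i < nb + na:
            ia = i - nb
            pen = 0.0
            for k in range(h_indptr[ia], h_indptr[ia + 1]):
                pen += h_data[k] * theta[nb + h_indices[k]]
            acc += lam_a * pen
            d += lam_a * h_diag[ia]
        elif i >= nb + na:
            acc += lam_ss * theta[i]
            d += lam_ss
        mean = (r[i] - acc + d * theta[i]) / d
        theta[i] = mean + normals[i] / np.sqrt(d)


class _Workspace:
    """Precomputed cross-product structures shared across sweeps."""

    def __init__(self, design: ModelDesign, h_inv: sp.spmatrix):
        W = design.W
        self.WtW = (W.T @ W).tocsr()
        self.WtW.sort_indices()
        self.diag_wtw = self.WtW.diagonal().copy()
        self.Wt = W.T.tocsr()
        H = sp.csr_matrix(h_inv)
        if H.shape != (design.n_animals, design.n_animals):
            raise ValueError("H^-1 dimension does not match the animal block")
        H.sort_indices()
        self.H = H
        self.h_diag = H.diagonal().copy()
        free = np.ones(design.n_coef, dtype=np.bool_)
        beta_zero = self.diag_wtw[: design.n_beta] <= 0
        if beta_zero.any():
            import warnings

            warnings.warn(
                "fixed-effect level(s) without observations constrained to 0",
                stacklevel=2,
            )
            free[: design.n_beta][beta_zero] = False
        self.free = free


def sample_location(
    state: GibbsState,
    design: ModelDesign,
    h_inv: sp.spmatrix,
    rng: np.random.Generator,
    workspace: _Workspace | None = None,
) -> GibbsState:
    """One full single-site sweep over (beta, a, ss) at the current z.

    Each coefficient is drawn from its exact normal full conditional given
    all other effects, the liabilities, and the current variances; beta has
    a flat prior, a is penalised by H^-1/sigma2_a, ss by I/sigma2_ss.
    """
    ws = workspace or _Workspace(design, h_inv)
    theta = state.theta()
    r = ws.Wt @ state.z
    _location_sweep(
        ws.WtW.indptr, ws.WtW.indices, ws.WtW.data, ws.diag_wtw, r, theta, ws.free,
        design.n_beta, design.n_animals,
        ws.H.indptr, ws.H.indices, ws.H.data, ws.h_diag,
        1.0 / state.sigma2_a, 1.0 / state.sigma2_ss,
        rng.standard_normal(design.n_coef),
    )
    sl_b, sl_a, sl_s = design.slices()
    state.beta = theta[sl_b]
    state.a = theta[sl_a]
    state.ss = theta[sl_s]
    return state


def sample_variances(
    state: GibbsState,
    h_inv: sp.spmatrix,
    priors: dict[str, tuple[float, float]],
    rng: np.random.Generator,
) -> GibbsState:
    """Draw (sigma2_a, sigma2_ss) from scaled inverse chi-square conditionals.

    sigma2 ~ (q + df0*scale0) / chi2_{n + df0} with q the quadratic form
    a' H^-1 a (respectively ss'ss). The residual variance is never sampled.
    """
    df_a, s_a = priors["a"]
    df_ss, s_ss = priors["ss"]
    q_a = float(state.a @ (h_inv @ state.a))
    q_ss = float(state.ss @ state.ss)
    state.sigma2_a = max(
        (q_a + df_a * s_a) / rng.chisquare(state.a.size + df_a), _VARIANCE_FLOOR
    )
    state.sigma2_ss = max(
        (q_ss + df_ss * s_ss) / rng.chisquare(state.ss.size + df_ss), _VARIANCE_FLOOR
    )
    return state


def heritability(
    sigma2_a: float | np.ndarray,
    sigma2_ss: float | np.ndarray,
    include_service_sire: bool = True,
) -> float | np.ndarray:
    """Liability-scale heritability h2 = sigma2_a / (sigma2_a [+ sigma2_ss] + 1).

    The service-sire variance sits in the phenotypic denominator by default;
    the alternative denominator excluding it is available by flag, and the
    choice is echoed in run metadata.
    """
    denom = sigma2_a + 1.0 + (sigma2_ss if include_service_sire else 0.0)
    return sigma2_a / denom


# --------------------------------------------------------------------------
# the chain


@dataclass
class PosteriorSummary:
    """Posterior means, SDs and 95% equal-tail intervals of the variance
    parameters and heritability, thinned traces, and posterior-mean effects."""

    summary: pd.DataFrame
    traces: dict[str, np.ndarray]
    gebv: np.ndarray  # posterior mean additive effect per pedigree animal
    beta_mean: np.ndarray
    ss_mean: np.ndarray
    metadata: dict = field(default_factory=dict)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.traces)


def _summarise(traces: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for k, v in traces.items():
        lo, hi = np.quantile(v, [0.025, 0.975])
        rows.append((k, v.mean(), v.std(ddof=1), lo, hi))
    return pd.DataFrame(
        rows, columns=["parameter", "mean", "sd", "q2.5", "q97.5"]
    ).set_index("parameter")


def run_gibbs(
    design: ModelDesign,
    h_inv: sp.spmatrix,
    config: GibbsConfig,
) -> PosteriorSummary:
    """Run the full chain: liabilities -> location -> variances each iteration.

    Stores thinned post-burn-in samples of the variance components and the
    per-sample liability-scale heritability; the posterior mean of ``a`` is
    accumulated over the same retained samples. Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ws = _Workspace(design, h_inv)
    state = GibbsState.initial(design, config)
    priors = {"a": config.resolved_prior("a"), "ss": config.resolved_prior("ss")}

    kept_s2a: list[float] = []
    kept_s2ss: list[float] = []
    kept_h2: list[float] = []
    a_sum = np.zeros(design.n_animals)
    beta_sum = np.zeros(design.n_beta)
    ss_sum = np.zeros(design.n_ss)
    n_kept = 0

    for it in range(config.n_iter):
        sample_liabilities(state, design, rng)
        sample_location(state, design, h_inv, rng, workspace=ws)
        sample_variances(state, h_inv, priors, rng)
        if state.sigma2_a > _DIVERGENCE_LIMIT or state.sigma2_ss > _DIVERGENCE_LIMIT:
            raise RuntimeError(
                f"divergent chain at iteration {it}: sigma2_a={state.sigma2_a:.3e}, "
                f"sigma2_ss={state.sigma2_ss:.3e}"
            )
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            kept_s2a.append(state.sigma2_a)
            kept_s2ss.append(state.sigma2_ss)
            kept_h2.append(
                float(
                    heritability(
                        state.sigma2_a,
                        state.sigma2_ss,
                        config.h2_includes_service_sire,
                    )
                )
            )
            a_sum += state.a
            beta_sum += state.beta
            ss_sum += state.ss
            n_kept += 1

    traces = {
        "sigma2_a": np.array(kept_s2a),
        "sigma2_ss": np.array(kept_s2ss),
        "h2": np.array(kept_h2),
    }
    return PosteriorSummary(
        summary=_summarise(traces),
        traces=traces,
        gebv=a_sum / n_kept,
        beta_mean=beta_sum / n_kept,
        ss_mean=ss_sum / n_kept,
        metadata={
            "n_iter": config.n_iter,
            "burn_in": config.burn_in,
            "thin": config.thin,
            "seed": config.seed,
            "n_retained": n_kept,
            "h2_formula": (
                "sigma2_a / (sigma2_a + sigma2_ss + 1)"
                if config.h2_includes_service_sire
                else "sigma2_a / (sigma2_a + 1)"
            ),
            "priors": {k: list(v) for k, v in priors.items()},
            "residual_variance": 1.0,
            "beta_labels": design.beta_labels,
        },
    )


# --------------------------------------------------------------------------
# convergence diagnostics


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of the mean of a single chain (classical autocorrelation-based)."""
    import arviz as az

    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.allclose(x, x[0]):
        return float("nan")
    return float(az.ess(x[None, :], method="mean"))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    Segment means are compared with standard errors based on each segment's
    effective sample size.
    """
    x = np.asarray(x, dtype=float)
    a = x[: max(int(first * x.size), 2)]
    b = x[-max(int(last * x.size), 2):]
    se2 = 0.0
    for seg in (a, b):
        ess = effective_sample_size(seg)
        if not np.isfinite(ess) or ess <= 0:
            return float("nan")
        se2 += seg.var(ddof=1) / ess
    return float((a.mean() - b.mean()) / np.sqrt(se2))


def convergence_diagnostics(
    traces: dict[str, np.ndarray],
    plot_path=None,
    min_samples: int = 50,
) -> pd.DataFrame:
    """ESS and Geweke z per trace; optional trace-plot file.

    Traces shorter than ``min_samples`` (or constant) are flagged unreliable.
    """
    rows = []
    for name, x in traces.items():
        x = np.asarray(x, dtype=float)
        constant = x.size == 0 or np.allclose(x, x[0])
        ess = float("nan") if constant else effective_sample_size(x)
        gz = float("nan") if constant else geweke_z(x)
        reliable = x.size >= min_samples and np.isfinite(ess)
        rows.append((name, x.size, ess, gz, reliable))
    report = pd.DataFrame(
        rows, columns=["parameter", "n_samples", "ess", "geweke_z", "reliable"]
    ).set_index("parameter")
    if plot_path is not None:
        from .plots import trace_plot

        trace_plot(traces, plot_path)
    return report
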