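"""Methylation-state calling from bisulfite conversion counts.

At each cytosine, bisulfite sequencing yields `k` converted reads out of `n`
total; unmethylated cytosines convert, methylated ones resist. The converted
counts across all sites of a dataset are modelled as a three-component
mixture:

- a beta-binomial for fully **methylated** sites (low converted fraction),
- a beta-binomial for fully **unmethylated** sites (high converted fraction),
- a discrete uniform on {0..n} for an **undetermined** third state,
  absorbing sites that fit neither (pmf 1/(n+1) given the site's coverage).

Component parameters and mixing weights are fitted by expectation
maximization over all sites of a dataset. Each site is then assigned the
posterior probability of the three states; if every state has posterior
above a small threshold (default 1e-4) no state is confidently excluded and
the position is discarded, otherwise the arg-max state is called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, logsumexp

from regkit.intervals import COUNT_TABLE_COLUMNS

_LOG_SHAPE_BOUNDS = (np.log(1e-3), np.log(1e4))

STATE_NAMES = ("methylated", "unmethylated", "undetermined")


@dataclass(frozen=True)
class Thresholds:
    """Shared decision thresholds for calling, filtering and annotation.

    tau         -- posterior discard threshold: a site is kept only if at
                   least one state has posterior <= tau (default 1e-4).
    p_max       -- empirical p-value cutoff for motif matches (default 0.05).
    bits_min    -- information content (bits) above which a motif column is
                   "highly informative" for variant consequences (default 1.5).
    pseudocount -- PWM probability regularizer, as a fraction of each column
                   total spread according to background composition.
    """

    tau: float = 1e-4
    p_max: float = 0.05
    bits_min: float = 1.5
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 < self.tau < 1 / 3):
            raise ValueError("tau must lie in (0, 1/3)")
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must lie in (0, 1)")
        if not (0 <= self.bits_min <= 2):
            raise ValueError("bits_min must lie in [0, 2]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


@dataclass(frozen=True)
class MethylationSite:
    contig: str
    pos: int
    strand: str
    k: int  # converted reads
    n: int  # total reads

    def __post_init__(self) -> None:
        if self.n < 1 or not (0 <= self.k <= self.n):
            raise ValueError(f"require 0 <= k <= n, n >= 1; got k={self.k}, n={self.n}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class MethylationModel:
    """Parameters of the three-state conversion-count mixture.

    (alpha_m, beta_m) shape the methylated component, (alpha_u, beta_u) the
    unmethylated one; `weights` = (pi_m, pi_u, pi_0) are the mixing
    proportions of (methylated, unmethylated, undetermined). Because
    converted reads indicate *un*methylation, identifiability requires the
    methylated component to have the lower mean converted fraction.
    """

    alpha_m: float
    beta_m: float
    alpha_u: float
    beta_u: float
    weights: tuple[float, float, float] = (0.45, 0.45, 0.10)

    def __post_init__(self) -> None:
        for name in ("alpha_m", "beta_m", "alpha_u", "beta_u"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be 3 non-negatives summing to 1")
        if self.mean_methylated > self.mean_unmethylated:
            raise ValueError(
                "methylated component must have the lower mean converted "
                "fraction; swap the components"
            )

    @property
    def mean_methylated(self) -> float:
        """Mean converted fraction of the methylated component."""
        return self.alpha_m / (self.alpha_m + self.beta_m)

    @property
    def mean_unmethylated(self) -> float:
        return self.alpha_u / (self.alpha_u + self.beta_u)


@dataclass(frozen=True)
class MethylationCall:
    site: MethylationSite
    posteriors: tuple[float, float, float]
    status: str  # "called" | "discarded"
    state: str | None  # one of STATE_NAMES when called
    level: float  # methylation level (n - k) / n


def merge_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum converted/total counts across replicate count tables.

    Positions are keyed by (contig, pos, strand); a position reported on two
    different strands is a data inconsistency (a cytosine lies on exactly
    one strand) and raises.
    """
    if not tables:
        raise ValueError("no tables to merge")
    df = pd.concat(tables, ignore_index=True)
    if len(df) == 0:
        return df
    merged = (
        df.groupby(["contig", "pos", "strand"], as_index=False, sort=True)[
            ["converted", "total"]
        ]
        .sum()
        .reindex(columns=COUNT_TABLE_COLUMNS)
    )
    dup = merged.duplicated(subset=["contig", "pos"], keep=False)
    if dup.any():
        rows = merged.loc[dup, ["contig", "pos"]].drop_duplicates()
        raise ValueError(
            "conflicting strands at position(s): "
            + ", ".join(f"{c}:{p}" for c, p in rows.itertuples(index=False))
        )
    return merged


def betabinom_logpmf(k, n, alpha: float, beta: float):
    """Beta-binomial log-pmf via log-gamma functions.

    log C(n, k) + B(k + alpha, n - k + beta) - B(alpha, beta), vectorized
    over k and n.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("shape parameters must be strictly positive")
    k = np.asarray(k)
    n = np.asarray(n)
    if (k < 0).any() or (k > n).any():
        raise ValueError("require 0 <= k <= n")
    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return log_choose + betaln(k + alpha, n - k + beta) - betaln(alpha, beta)


def _component_logpmfs(k, n, model: MethylationModel) -> np.ndarray:
    """Per-site log-pmf under each of the three components; shape (N, 3)."""
    k = np.asarray(k)
    n = np.asarray(n)
    return np.stack(
        [
            betabinom_logpmf(k, n, model.alpha_m, model.beta_m),
            betabinom_logpmf(k, n, model.alpha_u, model.beta_u),
            -np.log(n + 1.0),
        ],
        axis=-1,
    )


def _as_kn(sites) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sites, pd.DataFrame):
        return sites["converted"].to_numpy(), sites["total"].to_numpy()
    k = np.array([s.k for s in sites])
    n = np.array([s.n for s in sites])
    return k, n


def mixture_loglik(sites, model: MethylationModel) -> float:
    """Total log-likelihood of the sites under the three-state mixture."""
    k, n = _as_kn(sites)
    if k.size == 0:
        raise ValueError("empty site list")
    lp = _component_logpmfs(k, n, model)
    with np.errstate(divide="ignore"):
        logw = np.log(np.asarray(model.weights))
    return float(logsumexp(lp + logw, axis=-1).sum())


def posteriors(site, model: MethylationModel) -> np.ndarray:
    """Posterior probability of (methylated, unmethylated, undetermined)."""
    if isinstance(site, MethylationSite):
        k, n = np.array([site.k]), np.array([site.n])
        return _posterior_matrix(k, n, model)[0]
    k, n = _as_kn(site)
    return _posterior_matrix(k, n, model)


def _posterior_matrix(k, n, model: MethylationModel) -> np.ndarray:
    lp = _component_logpmfs(k, n, model)
    with np.errstate(divide="ignore"):
        logw = np.log(np.asarray(model.weights))
    joint = lp + logw
    return np.exp(joint - logsumexp(joint, axis=-1, keepdims=True))


def _moment_init(k: np.ndarray, n: np.ndarray) -> MethylationModel:
    """Method-of-moments start: fit each beta-binomial to the lower/upper
    tercile of the converted fractions (deterministic)."""
    frac = k / n
    lo, hi = np.quantile(frac, [1 / 3, 2 / 3])

    def mom(mask: np.ndarray) -> tuple[float, float]:
        f = frac[mask] if mask.any() else frac
        mu = float(np.clip(f.mean(), 1e-3, 1 - 1e-3))
        var = float(f.var())
        # beta moments: concentration from variance, floored for stability
        conc = mu * (1 - mu) / max(var, 1e-6) - 1
        conc = float(np.clip(conc, 0.1, 1e3))
        return mu * conc, (1 - mu) * conc

    a_m, b_m = mom(frac <= lo)
    a_u, b_u = mom(frac >= hi)
    if a_m / (a_m + b_m) > a_u / (a_u + b_u):
        (a_m, b_m), (a_u, b_u) = (a_u, b_u), (a_m, b_m)
    return MethylationModel(a_m, b_m, a_u, b_u, (0.45, 0.45, 0.10))


def _fit_component_shapes(
    k: np.ndarray, n: np.ndarray, resp: np.ndarray, a0: float, b0: float
) -> tuple[float, float]:
    """Maximize the responsibility-weighted beta-binomial log-likelihood in
    (log alpha, log beta); no closed form exists."""
    if resp.sum() < 1e-12:
        return a0, b0

    def nll(x):
        a, b = np.exp(x)
        return -float(resp @ betabinom_logpmf(k, n, a, b))

    res = minimize(
        nll,
        x0=np.log([a0, b0]),
        method="L-BFGS-B",
        bounds=[_LOG_SHAPE_BOUNDS] * 2,
    )
    a, b = np.exp(res.x)
    return float(a), float(b)


def em_fit(
    sites,
    init: MethylationModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[MethylationModel, list[float]]:
    """Fit the three-state mixture by EM across all sites of a dataset.

    Returns the fitted model (components swapped post hoc if needed so the
    methylated one has the lower mean converted fraction) and the
    log-likelihood trajectory, which is non-decreasing.

    The E- and M-steps operate on the unique (k, n) pairs weighted by their
    multiplicity, so runtime scales with the number of distinct count pairs
    rather than the number of sites. `seed` is accepted for interface
    uniformity; the default initialization is deterministic.
    """
    del seed  # deterministic given (sites, init)
    if tol <= 0:
        raise ValueError("tol must be positive")
    k_all, n_all = _as_kn(sites)
    if k_all.size < 3:
        raise ValueError("need at least 3 sites to fit the mixture")
    pairs, counts = np.unique(np.column_stack([k_all, n_all]), axis=0, return_counts=True)
    k, n = pairs[:, 0].astype(float), pairs[:, 1].astype(float)
    w = counts.astype(float)
    total = w.sum()

    model = init if init is not None else _moment_init(k_all, n_all)
    loglik_prev = None
    trajectory: list[float] = []
    for _ in range(max_iter):
        # E-step
        lp = _component_logpmfs(k, n, model)
        with np.errstate(divide="ignore"):
            logw = np.log(np.asarray(model.weights))
        joint = lp + logw
        site_ll = logsumexp(joint, axis=-1)
        loglik = float(w @ site_ll)
        trajectory.append(loglik)
        resp = np.exp(joint - site_ll[:, None]) * w[:, None]
        # M-step
        weights = resp.sum(axis=0) / total
        a_m, b_m = _fit_component_shapes(k, n, resp[:, 0], model.alpha_m, model.beta_m)
        a_u, b_u = _fit_component_shapes(k, n, resp[:, 1], model.alpha_u, model.beta_u)
        model = _ordered_model(a_m, b_m, a_u, b_u, weights)
        if loglik_prev is not None and abs(loglik - loglik_prev) <= tol * abs(loglik_prev):
            break
        loglik_prev = loglik
    trajectory.append(mixture_loglik(sites, model))

    lo, hi = np.exp(_LOG_SHAPE_BOUNDS)
    at_bound = any(
        not (lo * 1.001 < v < hi * 0.999)
        for v in (model.alpha_m, model.beta_m, model.alpha_u, model.beta_u)
    )
    collapsed = abs(model.mean_methylated - model.mean_unmethylated) < 1e-3
    if at_bound or collapsed:
        warnings.warn(
            "a beta-binomial component collapsed (shapes at bounds or both "
            "components identical); the data may not support two distinct "
            "components",
            RuntimeWarning,
            stacklevel=2,
        )
    return model, trajectory


def _ordered_model(a_m, b_m, a_u, b_u, weights) -> MethylationModel:
    """Apply the identifiability convention: methylated component has the
    lower mean converted fraction (swap components and weights otherwise)."""
    w = np.clip(np.asarray(weights, float), 0, None)
    w = w / w.sum()
    if a_m / (a_m + b_m) > a_u / (a_u + b_u):
        (a_m, b_m, a_u, b_u) = (a_u, b_u, a_m, b_m)
        w = w[[1, 0, 2]]
    return MethylationModel(
        float(a_m), float(b_m), float(a_u), float(b_u), tuple(float(x) for x in w)
    )


def call_states(
    sites, model: MethylationModel, thresholds: Thresholds = Thresholds()
) -> list[MethylationCall]:
    """Call a methylation state per site, or discard it.

    A site is discarded iff *all three* posteriors exceed tau — i.e. no
    state can be confidently excluded. Otherwise the arg-max state is
    called, ties broken in the order methylated > unmethylated >
    undetermined. The methylation level (n - k)/n is reported regardless.
    """
    if isinstance(sites, pd.DataFrame):
        site_objs = [
            MethylationSite(r.contig, r.pos, r.strand, r.converted, r.total)
            for r in sites.itertuples(index=False)
        ]
    else:
        site_objs = list(sites)
    k, n = _as_kn(site_objs)
    if k.size == 0:
        return []
    post = _posterior_matrix(k, n, model)
    calls = []
    for s, p in zip(site_objs, post):
        discarded = p.min() > thresholds.tau
        calls.append(
            MethylationCall(
                site=s,
                posteriors=tuple(p),
                status="discarded" if discarded else "called",
                state=None if discarded else STATE_NAMES[int(np.argmax(p))],
                level=(s.n - s.k) / s.n,
            )
        )
    return calls


CALLS_COLUMNS = [
    "contig", "pos", "strand", "converted", "total",
    "p_methylated", "p_unmethylated", "p_undetermined",
    "status", "state", "level",
]


def calls_to_frame(calls: list[MethylationCall]) -> pd.DataFrame:
    rows = [
        (
            c.site.contig, c.site.pos, c.site.strand, c.site.k, c.site.n,
            *c.posteriors, c.status, c.state or ".", c.level,
        )
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALLS_COLUMNS)
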