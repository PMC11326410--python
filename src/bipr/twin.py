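"""Classical twin-design variance decomposition (ACE / ADE and submodels).

Phenotypic variance is decomposed into additive genetic (A), shared
environmental (C) or non-additive genetic/dominance (D), and unique
environmental (E) sources. Monozygotic (MZ) pairs share A (and D)
entirely; dizygotic (DZ) pairs share half of A and a quarter of D; C is
common to both twins of a pair; E is unshared. With twins reared
together only three components are identifiable at once, and the family
(ACE vs ADE) is chosen from the observed intra-pair correlations:
``r_MZ > 2 r_DZ`` points to dominance (ADE), otherwise to shared
environment (ACE). A DE model is biologically implausible and never fit.

Models are fit by maximum likelihood on complete pairs, assuming a
bivariate normal per pair with common mean and covariance

    V        = a^2 + c^2 (+ d^2) + e^2
    cov_MZ   = a^2 + c^2           (ACE)   or  a^2 + d^2          (ADE)
    cov_DZ   = a^2/2 + c^2         (ACE)   or  a^2/2 + d^2/4      (ADE)

Paths are estimated as raw coefficients and squared into components, so
nonnegativity holds by construction. Nested submodels are tested by the
likelihood-ratio chi-square on the change in -2LL; the non-nested AE vs
CE choice uses AIC = chi2(vs saturated) - 2 df(vs saturated), lower
better. Confidence intervals for standardized components come from the
profile likelihood (-2LL rise of 3.841).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TwinCorrelations",
    "intrapair_correlations",
    "choose_family",
    "ModelFit",
    "fit_twin_model",
    "fit_saturated",
    "SaturatedFit",
    "select_model",
    "profile_ci",
]

_CHI2_95_DF1 = stats.chi2.ppf(0.95, 1)  # 3.841...


# ---------------------------------------------------------------------------
# correlations and family choice


@dataclass(frozen=True)
class TwinCorrelations:
    r_mz: float
    r_dz: float
    df_mz: int
    df_dz: int
    p_mz: float
    p_dz: float


def _pearson_one_sided(y1: np.ndarray, y2: np.ndarray) -> tuple[float, int, float]:
    n = y1.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs per zygosity")
    if y1.std() == 0 or y2.std() == 0:
        return float("nan"), n - 2, float("nan")
    r = float(np.corrcoef(y1, y2)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return r, df, 0.0 if r > 0 else 1.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(stats.t.sf(t, df))  # one-sided: H1 r > 0
    return r, df, p


def _split_pairs(table: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = table[table["zygosity"] == zyg][["y1", "y2"]].dropna()
        out[zyg] = sub.to_numpy(dtype=float)
    return out


def intrapair_correlations(table: pd.DataFrame) -> TwinCorrelations:
    """Pearson intra-pair correlation per zygosity with one-sided p-values.

    Pairs are used as given (no double entry); p-values test positive
    familial resemblance via ``t = r sqrt(df / (1 - r^2))``, df = pairs - 2.
    """
    pairs = _split_pairs(table)
    r_mz, df_mz, p_mz = _pearson_one_sided(pairs["MZ"][:, 0], pairs["MZ"][:, 1])
    r_dz, df_dz, p_dz = _pearson_one_sided(pairs["DZ"][:, 0], pairs["DZ"][:, 1])
    return TwinCorrelations(r_mz, r_dz, df_mz, df_dz, p_mz, p_dz)


def choose_family(corrs: TwinCorrelations) -> str:
    """ADE when r_MZ exceeds twice r_DZ, else ACE (equality -> ACE)."""
    return "ADE" if corrs.r_mz > 2.0 * corrs.r_dz else "ACE"


# ---------------------------------------------------------------------------
# maximum-likelihood fitting

_LOG_2PI = np.log(2.0 * np.pi)


def _m2ll_biv(data: np.ndarray, mu: float, v: float, cov: float) -> float:
    """-2 log likelihood of pairs under N([mu,mu], [[v,cov],[cov,v]])."""
    det = v * v - cov * cov
    if det <= 0 or v <= 0:
        return np.inf
    d1 = data[:, 0] - mu
    d2 = data[:, 1] - mu
    quad = (v * (d1 * d1 + d2 * d2) - 2.0 * cov * d1 * d2) / det
    n = data.shape[0]
    return float(n * (2.0 * _LOG_2PI + np.log(det)) + quad.sum())


def _model_cov(family: str, a2: float, m2: float, e2: float) -> tuple[float, float, float]:
    v = a2 + m2 + e2
    if family == "ADE":
        return v, a2 + m2, 0.5 * a2 + 0.25 * m2
    return v, a2 + m2, 0.5 * a2 + m2


_FAMILY_PATHS = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}


@dataclass
class ModelFit:
    """A fitted twin variance-component model.

    ``a2``, ``c2``, ``d2``, ``e2`` are the standardized components
    (fractions of total variance, summing to 1); paths absent from the
    model are zero. ``chi2_vs_saturated`` and ``aic`` are filled in by
    :func:`select_model`.
    """

    family: str
    model: str
    mu: float
    paths: dict[str, float]
    a2: float
    c2: float
    d2: float
    e2: float
    total_var: float
    minus2ll: float
    n_params: int
    chi2_vs_saturated: float = np.nan
    df_chi2: int = 0
    p_vs_saturated: float = np.nan
    aic: float = np.nan
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def components(self) -> dict[str, float]:
        return {"a2": self.a2, "c2": self.c2, "d2": self.d2, "e2": self.e2}


def _moment_components(pairs: dict[str, np.ndarray], family: str, sd0: float) -> dict[str, float]:
    """Method-of-moments component guesses from sample (co)variances."""
    def cov_of(z):
        d = pairs[z]
        if d.shape[0] < 2:
            return 0.0
        mu = d.mean()
        return float(((d[:, 0] - mu) * (d[:, 1] - mu)).mean())

    v = sd0**2
    cmz, cdz = cov_of("MZ"), cov_of("DZ")
    if family == "ADE":
        a2 = 4.0 * cdz - cmz
        m2 = 2.0 * cmz - 4.0 * cdz
        key = "d"
    else:
        a2 = 2.0 * (cmz - cdz)
        m2 = 2.0 * cdz - cmz
        key = "c"
    a2 = min(max(a2, 0.0), v)
    m2 = min(max(m2, 0.0), v)
    e2 = max(v - a2 - m2, 0.05 * v)
    return {"a": a2, key: m2, "e": e2}


def _m2ll_given(pairs, mu, family, a2, m2, e2) -> float:
    v, cov_mz, cov_dz = _model_cov(family, a2, m2, e2)
    total = 0.0
    for zyg, cov in (("MZ", cov_mz), ("DZ", cov_dz)):
        if pairs[zyg].size:
            total += _m2ll_biv(pairs[zyg], mu, v, cov)
    return total


def fit_twin_model(
    table: pd.DataFrame,
    model: str,
    family: str | None = None,
    n_starts: int = 5,
    e_floor: float = 1e-6,
) -> ModelFit:
    """Fit a twin model by maximum likelihood on complete pairs.

    Parameters
    ----------
    model
        One of ``ACE, ADE, AE, CE, E``.
    family
        The umbrella family (``ACE`` or ``ADE``); needed only to
        disambiguate the DZ covariance of an AE/E submodel fit within
        ADE (where it makes no difference, since d is fixed at 0) —
        defaults to ACE semantics.
    n_starts
        Deterministic multi-start count for the quasi-Newton optimizer.
    e_floor
        Lower bound on the |e| path as a fraction of the phenotypic SD,
        keeping the covariance matrix nonsingular for degenerate data.
    """
    model = model.upper()
    if model not in _FAMILY_PATHS:
        raise ValueError(f"unknown model {model!r}")
    family = (family or ("ADE" if "D" in model else "ACE")).upper()
    pairs = _split_pairs(table)
    n_total = sum(p.shape[0] for p in pairs.values())
    free = _FAMILY_PATHS[model]
    if n_total < len(free) + 1:
        raise ValueError(f"{n_total} pairs are too few for {model}")

    allvals = np.concatenate([p.ravel() for p in pairs.values() if p.size])
    mu0 = float(allvals.mean())
    sd0 = float(allvals.std()) or 1.0
    efloor = e_floor * sd0

    def unpack(theta):
        mu = theta[0]
        vals = dict.fromkeys(("a", "c", "d", "e"), 0.0)
        for name, val in zip(free, theta[1:]):
            vals[name] = val
        m = vals["d"] if family == "ADE" else vals["c"]
        return mu, vals["a"] ** 2, m * m, vals["e"] ** 2, vals

    def objective(theta):
        mu, a2, m2, e2 = unpack(theta)[:4]
        if e2 < efloor**2:
            e2 = efloor**2
        return _m2ll_given(pairs, mu, family, a2, m2, e2)

    # deterministic multi-start: a method-of-moments start, an equal-split
    # start, and seeded perturbations of the moment start
    k = len(free)
    moments = _moment_components(pairs, family, sd0)
    floor2 = max(efloor**2, 1e-4 * sd0**2)
    base = np.empty(1 + k)
    base[0] = mu0
    base[1:] = [np.sqrt(max(moments.get(p, 0.0), floor2)) for p in free]
    equal = base.copy()
    equal[1:] = sd0 / np.sqrt(k)
    rng = np.random.default_rng(12345)
    starts = [base, equal] + [
        base * (1.0 + 0.3 * rng.standard_normal(base.size)) for _ in range(max(n_starts - 2, 0))
    ]

    best = None
    for s in starts:
        res = optimize.minimize(objective, s, method="BFGS", options={"gtol": 1e-10})
        res = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 10_000})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"{model} fit failed to converge")

    mu, a2, m2, e2, vals = unpack(best.x)
    e2 = max(e2, 0.0)
    v = a2 + m2 + e2
    if v <= 0:
        raise RuntimeError(f"{model} fit degenerate: zero total variance")
    c2 = m2 if family == "ACE" else 0.0
    d2 = m2 if family == "ADE" else 0.0
    return ModelFit(
        family=family,
        model=model,
        mu=mu,
        paths={p: abs(vals[p]) for p in free},
        a2=a2 / v,
        c2=c2 / v,
        d2=d2 / v,
        e2=e2 / v,
        total_var=v,
        minus2ll=float(best.fun),
        n_params=1 + k,
    )


@dataclass(frozen=True)
class SaturatedFit:
    """Per-zygosity unconstrained (mean, variance, covariance): 6 parameters."""

    moments: dict[str, tuple[float, float, float]]
    minus2ll: float
    n_params: int = 6


def fit_saturated(table: pd.DataFrame) -> SaturatedFit:
    """Closed-form ML fit of the saturated model.

    Per zygosity the mean is common to both twins of a pair, with a free
    variance and intra-pair covariance (ML normalization, i.e. divide by
    the pair count). The saturated -2LL lower-bounds every structured
    model's on the same data.
    """
    pairs = _split_pairs(table)
    moments = {}
    m2ll = 0.0
    for zyg, data in pairs.items():
        if data.shape[0] < 3:
            raise ValueError(f"need >= 3 complete {zyg} pairs")
        mu = float(data.mean())
        d1 = data[:, 0] - mu
        d2 = data[:, 1] - mu
        v = float((d1 @ d1 + d2 @ d2) / (2 * data.shape[0]))
        c = float((d1 @ d2) / data.shape[0])
        if v * v - c * c <= 0:
            raise ValueError(f"singular {zyg} covariance in saturated fit")
        moments[zyg] = (mu, v, c)
        m2ll += _m2ll_biv(data, mu, v, c)
    return SaturatedFit(moments=moments, minus2ll=m2ll)


def _attach_saturated(fit: ModelFit, sat: SaturatedFit) -> ModelFit:
    fit.chi2_vs_saturated = fit.minus2ll - sat.minus2ll
    fit.df_chi2 = sat.n_params - fit.n_params
    fit.p_vs_saturated = float(stats.chi2.sf(max(fit.chi2_vs_saturated, 0.0), fit.df_chi2))
    fit.aic = fit.chi2_vs_saturated - 2.0 * fit.df_chi2
    return fit


def _lrt_p(sub: ModelFit, full: ModelFit) -> float:
    chi2 = max(sub.minus2ll - full.minus2ll, 0.0)
    df = full.n_params - sub.n_params
    return float(stats.chi2.sf(chi2, df))


def select_model(
    table: pd.DataFrame, family: str | None = None, alpha: float = 0.05
) -> tuple[ModelFit, pd.DataFrame]:
    """Drop-one-path model selection within a family.

    Starting from the full ACE (or ADE) model, each path is dropped in
    turn and tested by the likelihood-ratio chi-square against the full
    model; a path is retained iff dropping it significantly worsens fit
    (p < ``alpha``). When both single-path submodels of ACE survive
    (AE and CE, non-nested), the lower AIC versus the saturated model
    wins. If family is not given it is chosen from the observed twin
    correlations. Returns the best fit and the comparison table.
    """
    if family is None:
        family = choose_family(intrapair_correlations(table))
    family = family.upper()
    sat = fit_saturated(table)

    def fit(model):
        return _attach_saturated(fit_twin_model(table, model, family=family), sat)

    fits: dict[str, ModelFit] = {}
    if family == "ACE":
        for m in ("ACE", "AE", "CE", "E"):
            fits[m] = fit(m)
        full = fits["ACE"]
        drop_c_ok = _lrt_p(fits["AE"], full) >= alpha
        drop_a_ok = _lrt_p(fits["CE"], full) >= alpha
        if drop_c_ok and drop_a_ok:
            best = fits["AE"] if fits["AE"].aic <= fits["CE"].aic else fits["CE"]
        elif drop_c_ok:
            best = fits["AE"]
        elif drop_a_ok:
            best = fits["CE"]
        else:
            best = full
        if best.model in ("AE", "CE") and _lrt_p(fits["E"], best) >= alpha:
            best = fits["E"]
    elif family == "ADE":
        for m in ("ADE", "AE", "E"):
            fits[m] = fit(m)
        full = fits["ADE"]
        best = fits["AE"] if _lrt_p(fits["AE"], full) >= alpha else full
        if best.model == "AE" and _lrt_p(fits["E"], best) >= alpha:
            best = fits["E"]
    else:
        raise ValueError(f"family must be ACE or ADE, got {family!r}")

    rows = [
        (m, f.minus2ll, f.n_params, f.chi2_vs_saturated, f.df_chi2, f.p_vs_saturated, f.aic)
        for m, f in fits.items()
    ]
    comparison = pd.DataFrame(
        rows, columns=["model", "minus2ll", "n_params", "chi2_vs_sat", "df", "p", "aic"]
    )
    return best, comparison


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


def _profile_m2ll(table: pd.DataFrame, fit: ModelFit, component: str, g: float) -> float:
    """Minimum -2LL with the standardized ``component`` fixed at ``g``."""
    pairs = _split_pairs(table)
    family = fit.family
    comp_to_path = {"a2": "a", "c2": "c", "d2": "d", "e2": "e"}
    path = comp_to_path[component]
    free = [p for p in _FAMILY_PATHS[fit.model] if p != path]
    if path not in _FAMILY_PATHS[fit.model]:
        raise ValueError(f"{component} is not free in model {fit.model}")

    def components_from(g, s):
        # fractions: constrained component g; remainder split by s in [0,1]
        rem = 1.0 - g
        fr = dict.fromkeys(("a", "c", "d", "e"), 0.0)
        fr[path] = g
        if len(free) == 1:
            fr[free[0]] = rem
        else:
            fr[free[0]] = rem * s
            fr[free[1]] = rem * (1.0 - s)
        a2 = fr["a"]
        m2 = fr["d"] if family == "ADE" else fr["c"]
        e2 = fr["e"]
        return a2, m2, e2

    def objective(theta):
        mu, logv = theta[0], theta[1]
        s = 1.0 / (1.0 + np.exp(-theta[2])) if len(free) == 2 else 0.0
        v = np.exp(logv)
        a2, m2, e2 = components_from(g, s)
        return _m2ll_given(pairs, mu, family, a2 * v, m2 * v, e2 * v)

    x0 = [fit.mu, np.log(fit.total_var)]
    if len(free) == 2:
        f0, f1 = fit.components[free[0] + "2"], fit.components[free[1] + "2"]
        tot = f0 + f1
        s0 = f0 / tot if tot > 0 else 0.5
        s0 = min(max(s0, 1e-6), 1 - 1e-6)
        x0.append(np.log(s0 / (1 - s0)))
    res = optimize.minimize(objective, x0, method="BFGS", options={"gtol": 1e-9})
    res = optimize.minimize(objective, res.x, method="Nelder-Mead",
                            options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 2000})
    return float(res.fun)


def profile_ci(
    table: pd.DataFrame, fit: ModelFit, component: str, level: float = 0.95
) -> tuple[float, float, bool]:
    """Profile-likelihood CI for a standardized variance component.

    Bounds are where the constrained -2LL rises by the chi-square(1)
    critical value (3.841 at 95%) above its minimum, refitting all free
    parameters at each constrained value; bounds are clipped to [0, 1].
    The third return value flags a bound reported at the boundary
    because the rise was never bracketed.
    """
    crit = stats.chi2.ppf(level, 1)
    ghat = fit.components[component]
    m2ll_hat = min(fit.minus2ll, _profile_m2ll(table, fit, component, min(max(ghat, 1e-9), 1 - 1e-9)))
    target = m2ll_hat + crit

    def excess(g):
        return _profile_m2ll(table, fit, component, g) - target

    eps = 1e-9
    clipped = False
    lo_edge, hi_edge = eps, 1.0 - eps
    if excess(lo_edge) <= 0:
        lo = 0.0
        clipped = clipped or ghat > eps
    else:
        lo = float(optimize.brentq(excess, lo_edge, max(ghat, 2 * eps), xtol=1e-5))
    if excess(hi_edge) <= 0:
        hi = 1.0
        clipped = True
    else:
        hi = float(optimize.brentq(excess, min(ghat, 1 - 2 * eps), hi_edge, xtol=1e-5))
    return lo, hi, clipped
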