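"""Environmental-buffering analysis: Gaussian GLMs with AICc model averaging.

Annual mean egg volume (optionally z-scored across species and years) is
modelled as a Gaussian, identity-link GLM of species (Sp), perfect-synchrony
indicator (Sync), winter NAO index (W_NAO), and optionally year and a
closure-phase indicator, with two-way interactions among the first three.
Candidates are compared by the small-sample Akaike criterion

    AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1)

where k counts all estimated parameters, i.e. intercept, slope terms, and
the residual variance.  The log-likelihood is the maximized Gaussian
likelihood with the ML variance estimate RSS/n, so that AICc values are
consistent with the likelihood actually maximized.  Models within
``delta <= 4`` AICc of the best are averaged with renormalized Akaike
weights using full (zero-substitution) averaging; a term's unconditional
variance combines within-model sampling variance and between-model spread.
An effect is reported as significant when its 95% CI excludes zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError

MAIN_EFFECTS = ("Sp", "Sync", "W_NAO", "Year", "Closure")
INTERACTIONS = ("Sp:Sync", "Sp:W_NAO", "Sync:W_NAO")
_TERM_ORDER = {t: i for i, t in enumerate(MAIN_EFFECTS + INTERACTIONS)}

Z_CRIT = 1.959963984540054  # normal 97.5% quantile for Wald intervals


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: a hierarchical set of terms."""

    terms: frozenset

    def __post_init__(self) -> None:
        unknown = self.terms - set(MAIN_EFFECTS) - set(INTERACTIONS)
        if unknown:
            raise ValueError(f"unknown term(s): {sorted(unknown)}")
        for t in self.terms & set(INTERACTIONS):
            a, b = t.split(":")
            if a not in self.terms or b not in self.terms:
                raise ValueError(f"interaction {t} without both main effects")

    @property
    def name(self) -> str:
        ordered = sorted(self.terms, key=_TERM_ORDER.__getitem__)
        return " + ".join(ordered) if ordered else "1"

    def __iter__(self):
        return iter(sorted(self.terms, key=_TERM_ORDER.__getitem__))


@dataclass(frozen=True)
class ModelFit:
    spec: ModelSpec
    terms: tuple  # design column names, intercept first
    coefficients: np.ndarray
    se: np.ndarray
    ci: np.ndarray  # (p, 2)
    loglik: float
    k: int  # slope terms + intercept + residual variance
    n: int
    aicc: float


@dataclass
class ModelTable:
    """Fits sorted ascending by AICc, with delta-AICc and Akaike weights."""

    fits: list
    delta: np.ndarray
    weight: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [f.spec.name for f in self.fits],
                "k": [f.k for f in self.fits],
                "loglik": [f.loglik for f in self.fits],
                "aicc": [f.aicc for f in self.fits],
                "delta_aicc": self.delta,
                "weight": self.weight,
            }
        )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion; undefined unless n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc correction undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _design_matrix(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(data))}
    base = {
        "Sp": (data["species"] == "gull").to_numpy(float),
        "Sync": data["sync"].to_numpy(float),
        "W_NAO": data["wnao"].to_numpy(float),
    }
    if "Year" in spec.terms:
        yr = data["year"].to_numpy(float)
        base["Year"] = yr - yr.mean()  # centered continuous year
    if "Closure" in spec.terms:
        base["Closure"] = data["phase"].to_numpy(float)
    for t in spec:
        if ":" in t:
            a, b = t.split(":")
            cols[t] = base[a] * base[b]
        else:
            cols[t] = base[t]
    return np.column_stack(list(cols.values())), list(cols)


def fit_gaussian_glm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Maximum-likelihood Gaussian identity-link fit of one candidate.

    The log-likelihood uses the ML residual variance RSS/n; standard errors
    and Wald 95% CIs use the conventional unbiased variance RSS/(n-p), as
    in standard GLM software.
    """
    X, names = _design_matrix(data, spec)
    y = data["response"].to_numpy(float)
    n, p = X.shape
    k = p + 1  # + residual variance
    if n <= k + 1:
        raise InsufficientDataError(f"n={n} too small for k={k} parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {p}) for terms {names[1:]}"
        )
    res = sm.OLS(y, X).fit()
    # res.llf is the Gaussian loglik at sigma^2 = RSS/n (the MLE)
    ci = np.column_stack(
        [res.params - Z_CRIT * res.bse, res.params + Z_CRIT * res.bse]
    )
    return ModelFit(
        spec=spec,
        terms=tuple(names),
        coefficients=res.params,
        se=res.bse,
        ci=ci,
        loglik=float(res.llf),
        k=k,
        n=n,
        aicc=aicc(float(res.llf), k, n),
    )


def candidate_specs(include_year: bool = False,
                    include_closure: bool = False) -> list[ModelSpec]:
    """All hierarchical subsets of {Sp, Sync, W_NAO} with 2-way interactions.

    Optionally adds Year and/or Closure as main effects to every candidate
    that already has at least one term (and as stand-alone candidates).
    """
    core = ("Sp", "Sync", "W_NAO")
    specs = []
    for mains in itertools.chain.from_iterable(
        itertools.combinations(core, r) for r in range(len(core) + 1)
    ):
        allowed = [i for i in INTERACTIONS
                   if all(m in mains for m in i.split(":"))]
        for r in range(len(allowed) + 1):
            for inter in itertools.combinations(allowed, r):
                terms = set(mains) | set(inter)
                if include_year:
                    terms.add("Year")
                if include_closure:
                    terms.add("Closure")
                specs.append(ModelSpec(frozenset(terms)))
    return specs


def model_selection(data: pd.DataFrame, specs=None) -> ModelTable:
    """Fit every candidate, sort by AICc, attach delta and Akaike weights."""
    if specs is None:
        specs = candidate_specs()
    if not specs:
        raise ValueError("no candidate models supplied")
    fits = sorted((fit_gaussian_glm(data, s) for s in specs), key=lambda f: f.aicc)
    a = np.array([f.aicc for f in fits])
    delta = a - a[0]
    w = np.exp(-delta / 2)
    return ModelTable(fits=fits, delta=delta, weight=w / w.sum())


def model_average(table: ModelTable, threshold: float = 4.0) -> pd.DataFrame:
    """Full (zero-substitution) averaging over the delta <= threshold set.

    Weights are renormalized within the retained set.  For each term, a
    model not containing it contributes estimate 0 with variance 0; the
    unconditional variance is sum_i w_i (se_i^2 + (b_i - b_bar)^2).
    Returns a frame with columns term, estimate, ci_lo, ci_hi, significant.
    """
    keep = table.delta <= threshold
    fits = [f for f, m in zip(table.fits, keep) if m]
    w = table.weight[keep]
    w = w / w.sum()

    terms: list[str] = []
    for f in fits:
        terms += [t for t in f.terms if t not in terms]
    rows = []
    for t in terms:
        b = np.zeros(len(fits))
        se = np.zeros(len(fits))
        for i, f in enumerate(fits):
            if t in f.terms:
                j = f.terms.index(t)
                b[i] = f.coefficients[j]
                se[i] = f.se[j]
        est = float(np.sum(w * b))
        var = float(np.sum(w * (se**2 + (b - est) ** 2)))
        lo, hi = est - Z_CRIT * np.sqrt(var), est + Z_CRIT * np.sqrt(var)
        rows.append(
            {
                "term": t,
                "estimate": est,
                "ci_lo": lo,
                "ci_hi": hi,
                "significant": is_significant(est, (lo, hi)),
            }
        )
    return pd.DataFrame(rows)


def is_significant(coefficient: float, ci) -> bool:
    """True iff the CI excludes zero (boundary counts as overlapping)."""
    lo, hi = ci
    if lo > hi:
        raise ValueError(f"invalid CI [{lo}, {hi}]")
    return bool(lo > 0 or hi < 0)


def code_synchrony(sync_result, years) -> np.ndarray:
    """Binary indicator per requested year: 1 where phi_t = 1, else 0.

    Years outside the phi time axis (the first and last years of the
    source series) are coded 0.
    """
    years = np.asarray(years, dtype=int)
    phi_by_year = dict(zip(np.asarray(sync_result.times, int), sync_result.phi_t))
    return np.array(
        [1 if abs(phi_by_year.get(int(y), 0.0) - 1.0) < 1e-12 else 0 for y in years],
        dtype=int,
    )


def build_model_frame(
    series_by_species: dict,
    env: pd.DataFrame,
    sync_result,
    closure_year: int,
    standardize: bool = True,
) -> pd.DataFrame:
    """Assemble the one-row-per-species-per-year modelling frame.

    ``env`` must have columns ``year`` and ``wnao``.  The response is the
    annual mean egg volume, z-scored globally across both species when
    ``standardize`` (the default, which puts species on a common scale).
    """
    wnao = dict(zip(env["year"].astype(int), env["wnao"].astype(float)))
    rows = []
    for species, s in series_by_species.items():
        sync = code_synchrony(sync_result, s.years)
        for y, v, b in zip(s.years, s.mean_volume_cm3, sync):
            if int(y) not in wnao:
                raise InsufficientDataError(f"no environmental index for year {int(y)}")
            rows.append(
                {
                    "species": species,
                    "year": int(y),
                    "response": float(v),
                    "sync": int(b),
                    "wnao": wnao[int(y)],
                    "phase": int(int(y) >= closure_year),
                }
            )
    df = pd.DataFrame(rows)
    if standardize:
        df["response"] = (df["response"] - df["response"].mean()) / df["response"].std(ddof=1)
    return df


def phase_slopes(data: pd.DataFrame) -> pd.DataFrame:
    """Per-species, per-phase W_NAO slopes from the Sp x W_NAO x Closure model.

    Fits the full three-way factorial and reports each species' W_NAO slope
    in each closure phase (estimate, SE, Wald z p-value), plus the gull's
    between-phase slope contrast.  The contrast, not any derived
    "buffering percentage", is the reported quantity: percentage summaries
    depend on an arbitrary denominator and are left to interpretation.
    """
    for sp in ("gull", "shearwater"):
        for ph in (0, 1):
            nseg = ((data["species"] == sp) & (data["phase"] == ph)).sum()
            if nseg < 3:
                raise InsufficientDataError(
                    f"{sp}, phase {ph}: only {nseg} year(s); need >= 3 per phase"
                )
    g = (data["species"] == "gull").to_numpy(float)
    w = data["wnao"].to_numpy(float)
    ph = data["phase"].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(data)), g, w, ph, g * w, g * ph, w * ph, g * w * ph]
    )
    names = ["(Intercept)", "Sp", "W_NAO", "Closure", "Sp:W_NAO",
             "Sp:Closure", "W_NAO:Closure", "Sp:W_NAO:Closure"]
    res = sm.OLS(data["response"].to_numpy(float), X).fit()
    cov = np.asarray(res.cov_params())

    def combo(vec):
        vec = np.asarray(vec, float)
        est = float(vec @ res.params)
        se = float(np.sqrt(vec @ cov @ vec))
        from scipy import stats as _st

        p = float(2 * _st.norm.sf(abs(est / se))) if se > 0 else float("nan")
        return est, se, p

    iW, iSW, iWP, iSWP = (names.index(t) for t in
                          ("W_NAO", "Sp:W_NAO", "W_NAO:Closure", "Sp:W_NAO:Closure"))
    rows = []
    for sp_val, sp_name in ((0.0, "shearwater"), (1.0, "gull")):
        for ph_val, ph_name in ((0.0, "before"), (1.0, "after")):
            vec = np.zeros(len(names))
            vec[iW] = 1
            vec[iSW] = sp_val
            vec[iWP] = ph_val
            vec[iSWP] = sp_val * ph_val
            est, se, p = combo(vec)
            rows.append({"species": sp_name, "phase": ph_name, "term": "W_NAO slope",
                         "estimate": est, "se": se, "p": p})
    vec = np.zeros(len(names))
    vec[iWP] = 1
    vec[iSWP] = 1
    est, se, p = combo(vec)
    rows.append({"species": "gull", "phase": "after-before", "term": "W_NAO slope contrast",
                 "estimate": est, "se": se, "p": p})
    return pd.DataFrame(rows)
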