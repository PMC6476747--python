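"""Candidate GLMM sets, AICc ranking, Akaike weights and model averaging.

Candidates are all subsets of the fixed-term atoms plus their two-way
interactions that respect marginality (an interaction requires both main
effects), always including the null (intercept + random effect) model.  All
models are fitted by maximum likelihood (never REML) so that AICc values are
comparable across fixed-effect structures.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy

from . import glmm

__all__ = [
    "CandidateSpec",
    "FittedCandidate",
    "enumerate_candidates",
    "terms_to_formula",
    "fit_candidates",
    "aicc",
    "akaike_weights",
    "rank_models",
    "model_average",
]

DEFAULT_ATOMS = ("habitat", "month", "group_size")


@dataclass
class CandidateSpec:
    """What to fit: response, family, fixed-term atoms, random grouping."""

    response: str
    family: str  # gaussian | poisson
    atoms: tuple = DEFAULT_ATOMS
    random: str = "site_id"
    categorical: tuple = ("habitat", "month")

    def __post_init__(self):
        if self.family not in ("gaussian", "poisson"):
            raise ValueError("family must be 'gaussian' or 'poisson'")


def enumerate_candidates(atoms=DEFAULT_ATOMS) -> list[tuple]:
    """All marginality-respecting fixed-term sets, null model included.

    Interactions are only available between atoms whose main effects are both
    in the model; returns sorted tuples of term strings (``a:b`` denotes an
    interaction), deterministic order.
    """
    atoms = tuple(atoms)
    out = []
    for r in range(len(atoms) + 1):
        for mains in itertools.combinations(atoms, r):
            inters = [
                f"{a}:{b}" for a, b in itertools.combinations(sorted(mains), 2)
            ]
            for s in range(len(inters) + 1):
                for chosen in itertools.combinations(inters, s):
                    out.append(tuple(sorted(mains) + sorted(chosen)))
    # stable, readable order: by size then lexicographically
    out.sort(key=lambda t: (len(t), t))
    return out


def terms_to_formula(terms, categorical=("habitat", "month")) -> str:
    """Patsy RHS for a term tuple; categorical atoms get C() wrappers."""

    def wrap(atom: str) -> str:
        return f"C({atom})" if atom in categorical else atom

    parts = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            parts.append(f"{wrap(a)}:{wrap(b)}")
        else:
            parts.append(wrap(term))
    return "1" if not parts else "1 + " + " + ".join(parts)


@dataclass
class FittedCandidate:
    terms: tuple
    formula: str
    k: int
    n: int
    loglik: float
    aicc: float
    converged: bool
    coef: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    delta: float = float("nan")
    weight: float = float("nan")

    @property
    def model_id(self) -> str:
        return "null" if not self.terms else "+".join(self.terms)


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1); undefined for n <= k+1."""
    if n <= k + 1:
        warnings.warn(f"AICc undefined for n={n}, k={k}")
        return float("nan")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights from AICc values; sums to 1 over the candidate set."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - np.nanmin(a)
    w = np.exp(-0.5 * delta)
    w = np.where(np.isfinite(w), w, 0.0)
    return w / w.sum()


def fit_candidates(data: pd.DataFrame, spec: CandidateSpec) -> list[FittedCandidate]:
    """Fit every candidate model by ML and attach AICc, delta and weight."""
    d = data.dropna(subset=[spec.response]).reset_index(drop=True)
    if d[spec.random].nunique() < 2:
        raise ValueError("need at least 2 levels of the random grouping factor")
    y = d[spec.response].to_numpy(dtype=float)
    groups = d[spec.random].to_numpy()
    n = len(d)
    fits: list[FittedCandidate] = []
    warm = None
    for terms in enumerate_candidates(spec.atoms):
        formula = terms_to_formula(terms, spec.categorical)
        dm = patsy.dmatrix(formula, d, return_type="matrix")
        names = dm.design_info.column_names
        X = np.asarray(dm)
        converged = True
        try:
            if spec.family == "gaussian":
                fit = glmm.fit_lmm(y, X, groups)
                k = X.shape[1] + 2  # + sigma2_group, sigma2_resid
            else:
                fit = glmm.fit_poisson_glmm(y, X, groups)
                k = X.shape[1] + 1  # + sigma_group
            converged = fit.converged
            ll = fit.loglik
            coef = dict(zip(names, np.asarray(fit.beta, dtype=float)))
            se = dict(zip(names, np.asarray(fit.se_beta, dtype=float)))
        except Exception as exc:  # noqa: BLE001 - record and move on
            warnings.warn(f"candidate {terms} failed: {exc}")
            converged, ll, k = False, float("nan"), X.shape[1] + 2
            coef, se = {}, {}
        fits.append(
            FittedCandidate(
                terms=terms,
                formula=formula,
                k=k,
                n=n,
                loglik=ll,
                aicc=aicc(ll, k, n) if np.isfinite(ll) else float("nan"),
                converged=converged,
                coef=coef,
                se=se,
            )
        )
    good = [f for f in fits if np.isfinite(f.aicc) and f.converged]
    if good:
        best = min(f.aicc for f in good)
        weights = akaike_weights([f.aicc for f in good])
        for f, w in zip(good, weights):
            f.delta = f.aicc - best
            f.weight = float(w)
    return fits


def rank_models(fits) -> pd.DataFrame:
    """Ranking table (model, k, logLik, AICc, dAICc, weight), best first."""
    rows = [
        {
            "model": f.model_id,
            "k": f.k,
            "logLik": f.loglik,
            "AICc": f.aicc,
            "dAICc": f.delta,
            "weight": f.weight,
            "converged": f.converged,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["AICc", "model"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)


def model_average(fits, delta_max: float = 2.0) -> pd.DataFrame:
    """Conditional (natural) model averaging of the dAICc < ``delta_max`` set.

    Weights are renormalised within the set; a coefficient is averaged over
    the models that contain it, and its unconditional SE combines the
    within-model variance with the between-model spread
    (``sum_m w_m * sqrt(se_m^2 + (b_m - b_bar)^2)``).
    Non-convergent candidates are excluded.
    """
    cand = [
        f
        for f in fits
        if f.converged and np.isfinite(f.delta) and f.delta < delta_max
    ]
    if not cand:
        raise ValueError("no converged model within the averaging window")
    w = np.array([f.weight for f in cand])
    w = w / w.sum()
    names: list[str] = []
    for f in cand:
        for name in f.coef:
            if name not in names:
                names.append(name)
    rows = []
    for name in names:
        present = [(wi, f) for wi, f in zip(w, cand) if name in f.coef]
        wp = np.array([wi for wi, _ in present])
        wp = wp / wp.sum()
        betas = np.array([f.coef[name] for _, f in present])
        ses = np.array([f.se[name] for _, f in present])
        bbar = float(wp @ betas)
        use = float(wp @ np.sqrt(ses**2 + (betas - bbar) ** 2))
        rows.append(
            {
                "term": name,
                "estimate": bbar,
                "unconditional_se": use,
                "n_models": len(present),
                "weight_sum": float(sum(wi for wi, _ in present)),
            }
        )
    return pd.DataFrame(rows)
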