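"""Survival stratification by topic mixture.

Patients are split by how strongly a topic contributes to their profile: the
35th percentile of P(topic|sample) across the cohort is the threshold, and
the binary "upregulated" flag (strictly above the threshold) enters a Cox
proportional-hazards fit ``h(t|x) = b0(t) exp(Σ_i b_i (x_i − x̄_i))``, whose
``exp(coef)`` is the hazard ratio of flagged vs unflagged patients.
Kaplan-Meier curves visualize the same stratification, and cluster-level
prognosis is the fraction of patients alive three years after diagnosis,
standardized against size-matched random patient draws.

The Cox partial likelihood is maximized by Newton iteration with Breslow
handling of tied event times; lifetimes come from days-to-death for deceased
patients and days-to-last-follow-up (censored) for living ones.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_lifetime",
    "clean_stage",
    "build_survival_table",
    "upregulation_feature",
    "cox_fit",
    "BreslowCoxPH",
    "kaplan_meier",
    "cluster_prognosis",
]

_GDC_ALIASES = {
    "demographic.vital_status": "vital_status",
    "demographic.days_to_last_follow_up": "days_to_last_follow_up",
    "diagnoses.days_to_last_follow_up": "days_to_last_follow_up",
    "demographic.days_to_death": "days_to_death",
    "demographic.gender": "gender",
    "diagnoses.age_at_diagnosis": "age_at_diagnosis",
    "diagnoses.ajcc_pathologic_stage": "stage",
}


def compute_lifetime(
    vital_status: pd.Series, days_to_last_follow_up: pd.Series, days_to_death: pd.Series
) -> pd.DataFrame:
    """Lifetime in days and event indicator from vital status.

    Alive patients contribute their follow-up time censored (event 0); dead
    patients their days-to-death (event 1). Records missing the field their
    status requires, or with a nonpositive lifetime, are dropped and listed
    in ``df.attrs['dropped']``.
    """
    status = vital_status.astype(str).str.strip().str.lower()
    follow = pd.to_numeric(days_to_last_follow_up, errors="coerce")
    death = pd.to_numeric(days_to_death, errors="coerce")
    alive = status == "alive"
    lifetime = np.where(alive, follow, death)
    event = np.where(alive, 0, 1)
    out = pd.DataFrame({"lifetime": lifetime, "event": event}, index=vital_status.index)
    valid = np.isfinite(out["lifetime"]) & (out["lifetime"] > 0)
    dropped = out.index[~valid].tolist()
    if dropped:
        warnings.warn(f"dropped {len(dropped)} records with missing/nonpositive lifetime")
    out = out.loc[valid]
    out["lifetime"] = out["lifetime"].astype(float)
    out["event"] = out["event"].astype(int)
    out.attrs["dropped"] = dropped
    return out


def clean_stage(raw_stage):
    """Canonicalize tumor stage to one of stage i/ii/iii/iv.

    Trailing sub-stage letters are stripped ("stage ia" becomes "stage i");
    anything not mapping to the four stages becomes missing (NaN).
    """
    def _one(value):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return np.nan
        m = re.fullmatch(r"\s*stage\s+(iv|iii|ii|i)[a-z]*\s*", str(value).lower())
        return f"stage {m.group(1)}" if m else np.nan

    if isinstance(raw_stage, pd.Series):
        return raw_stage.map(_one)
    return _one(raw_stage)


def build_survival_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Survival table from a GDC-style clinical frame (aliases accepted)."""
    df = clinical.rename(columns=_GDC_ALIASES)
    for col in ("vital_status",):
        if col not in df:
            raise ValueError(f"clinical table lacks required column {col!r}")
    life = compute_lifetime(
        df["vital_status"],
        df.get("days_to_last_follow_up", pd.Series(np.nan, index=df.index)),
        df.get("days_to_death", pd.Series(np.nan, index=df.index)),
    )
    out = life
    if "stage" in df:
        out = out.join(clean_stage(df["stage"]).rename("stage"))
    for col in ("age_at_diagnosis", "gender"):
        if col in df:
            out = out.join(df[col])
    return out


def upregulation_feature(topic_weights, percentile: float = 35.0) -> np.ndarray:
    """Binary per-sample flag: topic weight strictly above its 35th percentile.

    The threshold uses linear interpolation between order statistics; the
    flag is rank-based, hence invariant to monotone transforms of the
    weights. Constant weights flag nobody (a warning is emitted).
    """
    w = np.asarray(topic_weights.to_numpy() if isinstance(topic_weights, pd.Series) else topic_weights, dtype=float)
    thr = np.percentile(w, percentile)
    flags = (w > thr).astype(int)
    if flags.sum() == 0 and np.unique(w).size == 1:
        warnings.warn("constant topic weights: no sample flagged as upregulated")
    return flags


@dataclass
class _CoxResult:
    coef: np.ndarray
    se: np.ndarray
    covariates: list[str]


def _cox_newton(X: np.ndarray, time: np.ndarray, event: np.ndarray, names,
                tol: float = 1e-8, max_iter: int = 200) -> _CoxResult:
    """Newton maximization of the Breslow partial likelihood."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    order = np.argsort(-time, kind="stable")  # decreasing time: cumulative risk sets
    Xs, ts, es = Xc[order], time[order], event[order]

    def _loglik(b: np.ndarray) -> float:
        eta = Xs @ b
        shift = eta.max()
        cw = np.cumsum(np.exp(eta - shift))
        ll = 0.0
        i = 0
        while i < n:
            j = i
            while j + 1 < n and ts[j + 1] == ts[i]:
                j += 1
            d = es[i : j + 1].sum()
            if d > 0:
                ll += eta[i : j + 1][es[i : j + 1] == 1].sum() - d * (np.log(cw[j]) + shift)
            i = j + 1
        return float(ll)

    beta = np.zeros(p)
    ll_old = _loglik(beta)
    for it in range(max_iter):
        eta = Xs @ beta
        eta -= eta.max()
        w = np.exp(eta)
        # running sums over the risk set {i: t_i >= t}
        cw = np.cumsum(w)
        cwx = np.cumsum(w[:, None] * Xs, axis=0)
        cwxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        # Breslow: all events at a tied time share the same risk set, which is
        # automatic here because the cumulative sums include the ties
        i = 0
        while i < n:
            j = i
            while j + 1 < n and ts[j + 1] == ts[i]:
                j += 1
            d = es[i : j + 1].sum()
            if d > 0:
                sw, swx, swxx = cw[j], cwx[j], cwxx[j]
                xbar = swx / sw
                grad += Xs[i : j + 1][es[i : j + 1] == 1].sum(axis=0) - d * xbar
                hess -= d * (swxx / sw - np.outer(xbar, xbar))
            i = j + 1
        if not np.all(np.isfinite(grad)):
            raise RuntimeError("Cox likelihood diverged (possible complete separation)")
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular information matrix in Cox fit") from None
        # damped Newton: halve the step until the likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            beta_new = beta - scale * step
            ll_new = _loglik(beta_new)
            if ll_new >= ll_old - 1e-12:
                break
            scale /= 2
        if np.abs(beta_new).max() > 50:
            worst = names[int(np.argmax(np.abs(beta_new)))]
            raise RuntimeError(
                f"monotone partial likelihood: covariate {worst!r} separates the risk sets"
            )
        beta, ll_old = beta_new, ll_new
        if np.linalg.norm(grad) < tol:
            break
    else:
        raise RuntimeError("Cox Newton iteration did not converge")
    if np.abs(beta).max() > 10:
        # the gradient also vanishes when the likelihood is monotone in a
        # coefficient, so convergence at an extreme value means separation
        worst = names[int(np.argmax(np.abs(beta)))]
        raise RuntimeError(
            f"monotone partial likelihood: covariate {worst!r} separates the risk sets"
        )
    with np.errstate(invalid="raise"):
        try:
            se = np.sqrt(np.diag(np.linalg.inv(-hess)))
        except (np.linalg.LinAlgError, FloatingPointError):
            raise RuntimeError("singular information matrix in Cox fit") from None
    return _CoxResult(beta, se, list(names))


class BreslowCoxPH:
    """Cox proportional-hazards model, Breslow ties, Newton solver.

    Scikit-learn-style estimator: ``fit(X, durations, events)`` with ``X`` an
    ``(n, p)`` design (DataFrame or array). Fitted attributes: ``coef_``,
    ``hazard_ratios_`` (= exp(coef)), ``se_``, ``p_values_``, ``summary_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "BreslowCoxPH":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, durations, events) -> "BreslowCoxPH":
        from scipy.stats import norm

        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            names = [f"x{i}" for i in range(Xa.shape[1])]
        t = np.asarray(durations, dtype=float)
        e = np.asarray(events, dtype=int)
        if e.sum() < 2:
            raise ValueError("need at least two observed events")
        const = [names[j] for j in range(Xa.shape[1]) if np.unique(Xa[:, j]).size == 1]
        if const:
            raise ValueError(f"constant covariate(s): {const}")
        res = _cox_newton(Xa, t, e, names, self.tol, self.max_iter)
        self.covariates_ = res.covariates
        self.coef_ = res.coef
        self.se_ = res.se
        self.hazard_ratios_ = np.exp(res.coef)
        z = res.coef / res.se
        self.p_values_ = 2 * norm.sf(np.abs(z))
        self.summary_ = pd.DataFrame(
            {
                "coef": self.coef_,
                "exp(coef)": self.hazard_ratios_,
                "se(coef)": self.se_,
                "p": self.p_values_,
            },
            index=pd.Index(self.covariates_, name="covariate"),
        )
        return self


def cox_fit(table: pd.DataFrame, covariate_names: list[str]) -> pd.DataFrame:
    """Fit the hazard of ``table`` (lifetime, event) on the named covariates.

    Returns the per-covariate summary with coefficient, hazard ratio
    exp(coef), standard error, and Wald p-value.
    """
    model = BreslowCoxPH()
    model.fit(table[covariate_names], table["lifetime"], table["event"])
    return model.summary_


def kaplan_meier(table: pd.DataFrame, groups: pd.Series | None = None) -> dict:
    """Product-limit survival step functions, one per group.

    Censored subjects leave the risk set without a step. Returns a mapping
    group -> DataFrame with columns ``time`` and ``survival``.
    """
    from lifelines import KaplanMeierFitter

    if groups is None:
        groups = pd.Series("all", index=table.index)
    out = {}
    for name, idx in table.groupby(groups.loc[table.index]).groups.items():
        sub = table.loc[idx]
        if len(sub) == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(sub["lifetime"], sub["event"])
        sf = km.survival_function_
        out[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def cluster_prognosis(
    table: pd.DataFrame,
    clusters: pd.Series,
    horizon_days: float = 1095.0,
    n_random: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fraction of each cluster surviving past the horizon, with a Z-score.

    Subjects censored before the horizon are not evaluable and are excluded
    (their count is reported). The Z-score standardizes the cluster's
    fraction against ``n_random`` random same-size patient draws from the
    whole cohort; clusters with no evaluable subject get no Z (NaN).
    """
    rng = np.random.default_rng(seed)
    life = table["lifetime"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    survived = life >= horizon_days
    evaluable = survived | (event == 1)

    def _fraction(mask: np.ndarray) -> tuple[float, int]:
        ev = mask & evaluable
        n_ev = int(ev.sum())
        return (float((survived & ev).sum() / n_ev) if n_ev else np.nan, n_ev)

    labels = clusters.loc[table.index]
    rows = []
    n = len(table)
    for name in sorted(labels.unique(), key=str):
        mask = (labels == name).to_numpy()
        size = int(mask.sum())
        frac, n_ev = _fraction(mask)
        null = []
        for _ in range(n_random):
            pick = np.zeros(n, dtype=bool)
            pick[rng.choice(n, size=size, replace=False)] = True
            f, ne = _fraction(pick)
            if ne:
                null.append(f)
        null = np.asarray(null, dtype=float)
        if np.isnan(frac) or null.size == 0:
            z = np.nan
        else:
            sd = null.std()
            if sd <= 1e-12:  # degenerate null (e.g. the whole cohort)
                z = 0.0 if abs(frac - null.mean()) <= 1e-9 else np.nan
            else:
                z = float((frac - null.mean()) / sd)
        rows.append(
            {
                "cluster": name,
                "n": size,
                "n_evaluable": n_ev,
                "fraction_surviving": frac,
                "z_score": z,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
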