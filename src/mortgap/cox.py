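"""Stratified Cox proportional-hazards engine for age-band counting-process data.

The model maximises the partial likelihood with Breslow tie handling over
records of the form (stratum, t_start, t_stop, event, covariates), where the
timescale is time since study entry, delayed entry within a stratum is encoded
by t_start, and the risk set at an event time t within a stratum is
{records with t_start < t <= t_stop}. Proportionality is assumed only within
strata (sex x 5-year age-at-risk band).

Follows the statsmodels convention: ``StratifiedCoxModel`` is built from a
records table, ``fit()`` performs Newton-Raphson with step-halving and returns
a ``StratifiedCoxResults`` carrying estimates, their covariance, diagnostics
and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._vocab import CATEGORY_LEVELS, EDUCATION_REFERENCE
from .floated import FloatedVariances, float_variances, floated_ci

__all__ = ["StratifiedCoxModel", "StratifiedCoxResults", "fit_stratified_cox", "rr_table"]


class ConvergenceWarning(UserWarning):
    pass


def _ordered_levels(name: str, values: pd.Series) -> list:
    known = CATEGORY_LEVELS.get(name)
    observed = set(values.dropna().unique())
    if known is not None and observed <= set(known):
        return [l for l in known if l in observed]
    return sorted(observed, key=str)


class _PartialLikelihood:
    """Breslow stratified partial likelihood with O(n) risk-set bookkeeping.

    Risk sums at the E unique event times of each stratum are accumulated with
    difference arrays: each record adds its weight at the first event slot it
    covers and removes it after the last, so S0/S1/S2 at every event time come
    from bincounts and one cumulative sum per covariate (pair).
    """

    def __init__(self, X: np.ndarray, t_start: np.ndarray, t_stop: np.ndarray,
                 event: np.ndarray, stratum: np.ndarray):
        codes, strata = pd.factorize(stratum)
        n, p = X.shape
        self.p = p
        A_parts, B_parts, X_parts = [], [], []
        slot_parts, d_parts = [], []
        offset = 0
        self.n_events = int(event.sum())
        self.sum_x_events = X[event].sum(axis=0) if p else np.zeros(0)
        self.eta_events_X = X[event]
        self.dropped_strata = []
        for s, label in enumerate(strata):
            m = codes == s
            ts, tp, ev = t_start[m], t_stop[m], event[m]
            ut = np.unique(tp[ev])
            E = len(ut)
            if E == 0:
                self.dropped_strata.append(label)
                continue
            a = np.searchsorted(ut, ts, side="right")
            b1 = np.searchsorted(ut, tp, side="right")
            keep = a < b1
            A_parts.append(offset + a[keep])
            B_parts.append(offset + b1[keep])
            X_parts.append(X[m][keep])
            es = offset + np.searchsorted(ut, tp[ev])
            slot_parts.append(es)
            offset += E + 1
        self.M = offset
        if self.M == 0:
            raise ValueError("no events in any stratum; model is not estimable")
        self.A = np.concatenate(A_parts)
        self.B = np.concatenate(B_parts)
        self.X = np.vstack(X_parts) if p else np.zeros((len(self.A), 0))
        all_slots = np.concatenate(slot_parts)
        self.slots, self.d = np.unique(all_slots, return_counts=True)
        self.d = self.d.astype(float)

    def _cum(self, w: np.ndarray) -> np.ndarray:
        diff = np.bincount(self.A, weights=w, minlength=self.M)
        diff -= np.bincount(self.B, weights=w, minlength=self.M)
        return np.cumsum(diff)

    def eval(self, beta: np.ndarray, order: int = 2):
        p = self.p
        eta = self.X @ beta if p else np.zeros(len(self.X))
        w = np.exp(eta)
        S0 = self._cum(w)[self.slots]
        if np.any(S0 <= 0):
            raise FloatingPointError("empty risk set at an event time")
        ll = float((self.eta_events_X @ beta).sum() - (self.d * np.log(S0)).sum()) if p \
            else float(-(self.d * np.log(S0)).sum())
        if order == 0 or p == 0:
            return ll, np.zeros(p), np.zeros((p, p))
        K = len(self.slots)
        S1 = np.empty((K, p))
        for j in range(p):
            S1[:, j] = self._cum(w * self.X[:, j])[self.slots]
        U = S1 / S0[:, None]
        grad = self.sum_x_events - (self.d[:, None] * U).sum(axis=0)
        if order == 1:
            return ll, grad, np.zeros((p, p))
        S2 = np.empty((K, p, p))
        for j in range(p):
            wj = w * self.X[:, j]
            for k in range(j, p):
                arr = self._cum(wj * self.X[:, k])[self.slots]
                S2[:, j, k] = arr
                S2[:, k, j] = arr
        V = S2 / S0[:, None, None] - np.einsum("ki,kj->kij", U, U)
        H = -np.einsum("k,kij->ij", self.d, V)
        return ll, grad, H


class StratifiedCoxModel:
    """Cox model for a categorical exposure, stratified by (sex, age band).

    Parameters
    ----------
    records
        Output of :func:`mortgap.lexis.lexis_split` (optionally recoded by
        :func:`mortgap.lexis.prepare_cause`): one row per participant-band.
    exposure
        Name of the categorical exposure column; dummy-coded against
        ``reference``. ``None`` fits an adjustment-only model.
    reference
        Reference level; defaults to tertiary education for ``education`` and
        to the first observed level otherwise.
    adjust
        Extra covariates: numeric columns enter linearly (centred), string /
        categorical columns are dummy-coded against their first level.
    """

    def __init__(self, records: pd.DataFrame, exposure: str | None = "education",
                 reference: str | None = None, adjust: tuple[str, ...] = (),
                 stratum_col: str = "stratum", ties: str = "breslow"):
        if ties not in ("breslow",):
            raise NotImplementedError("only Breslow tie handling is implemented")
        self.records = records
        self.exposure = exposure
        self.adjust = tuple(adjust)

        used = ([exposure] if exposure else []) + list(self.adjust)
        for c in used:
            if c not in records.columns:
                raise ValueError(f"records lack model column {c!r}")
            if records[c].isna().any():
                raise ValueError(
                    f"missing values in model column {c!r}; drop those rows first")

        cols: list[np.ndarray] = []
        names: list[str] = []
        self.exposure_levels: list | None = None
        self.reference = None
        if exposure is not None:
            levels = _ordered_levels(exposure, records[exposure])
            if len(levels) < 2:
                raise ValueError(
                    f"exposure {exposure!r} has fewer than two observed levels")
            if reference is None:
                reference = EDUCATION_REFERENCE if (
                    exposure == "education" and EDUCATION_REFERENCE in levels) else levels[0]
            if reference not in levels:
                raise ValueError(f"reference level {reference!r} not observed")
            self.exposure_levels = levels
            self.reference = reference
            vals = records[exposure]
            for level in levels:
                if level == reference:
                    continue
                names.append(f"{exposure}={level}")
                cols.append((vals == level).to_numpy(dtype=float))
        for name in self.adjust:
            col = records[name]
            if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
                x = col.to_numpy(dtype=float)
                names.append(name)
                cols.append(x - x.mean())
            else:
                levels = _ordered_levels(name, col.astype(object))
                for level in levels[1:]:
                    names.append(f"{name}={level}")
                    cols.append((col == level).to_numpy(dtype=float))

        X = np.column_stack(cols) if cols else np.zeros((len(records), 0))
        # Drop exact-duplicate columns (e.g. the exposure also passed as an
        # adjustment) so nested models with redundant terms stay estimable.
        keep: list[int] = []
        for j in range(X.shape[1]):
            if not any(np.array_equal(X[:, j], X[:, k]) for k in keep):
                keep.append(j)
        if len(keep) < X.shape[1]:
            dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
            warnings.warn(f"dropping duplicated design columns: {dropped}")
        self.names = [names[j] for j in keep]
        self.X = X[:, keep]

        self._pl = _PartialLikelihood(
            self.X,
            records["t_start"].to_numpy(dtype=float),
            records["t_stop"].to_numpy(dtype=float),
            records["event"].to_numpy(dtype=bool),
            records[stratum_col].to_numpy(),
        )
        # Events per exposure level (reference included), for reporting.
        if exposure is not None:
            ev = records.loc[records["event"].astype(bool), exposure]
            self.events_by_level = {l: int((ev == l).sum()) for l in self.exposure_levels}
        else:
            self.events_by_level = {}

    def fit(self, max_iter: int = 50, tol_loglik: float = 1e-9, tol_grad: float = 1e-6,
            beta_cap: float = 15.0) -> "StratifiedCoxResults":
        p = self.X.shape[1]
        pl = self._pl
        beta = np.zeros(p)
        ll, g, H = pl.eval(beta, order=2)
        loglik_null = pl.eval(np.zeros(p), order=0)[0]
        converged = p == 0
        msgs: list[str] = []
        iterations = 0
        for iterations in range(1, max_iter + 1):
            if p == 0:
                break
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-H, g, rcond=None)[0]
                msgs.append("singular information matrix; least-squares step")
            # Expected gain of the full Newton step; at the optimum this hits
            # the floating-point noise floor of the summed log-likelihood.
            decrement = float(g @ step)
            slack = 1e-10 * (abs(ll) + 1.0)
            lam = 1.0
            accepted = False
            for _ in range(25):
                cand = np.clip(beta + lam * step, -beta_cap, beta_cap)
                ll_new, g_new, H_new = pl.eval(cand, order=2)
                if np.isfinite(ll_new) and ll_new >= ll - slack:
                    accepted = True
                    break
                lam /= 2.0
            if not accepted:  # no ascent direction left beyond numerical noise
                converged = decrement < tol_loglik * (abs(ll) + 1.0)
                break
            delta = ll_new - ll
            beta, ll, g, H = cand, ll_new, g_new, H_new
            if np.max(np.abs(g)) < tol_grad and abs(delta) < tol_loglik * (abs(ll) + 1.0):
                converged = True
                break
            if decrement < tol_loglik * (abs(ll) + 1.0):
                converged = True
                break
        if p and np.any(np.abs(beta) >= beta_cap * 0.999):
            msgs.append("possible separation: a coefficient reached the cap; "
                        "its estimate and CI are unreliable")
            warnings.warn(msgs[-1], ConvergenceWarning)
        if not converged and p:
            warnings.warn("Newton-Raphson did not converge", ConvergenceWarning)

        if p:
            try:
                cov = np.linalg.inv(-H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(-H)
                msgs.append("singular information matrix; covariance from pseudo-inverse")
        else:
            cov = np.zeros((0, 0))
        return StratifiedCoxResults(
            model=self,
            params=pd.Series(beta, index=self.names, dtype=float),
            cov=pd.DataFrame(cov, index=self.names, columns=self.names),
            loglik=ll, loglik_null=loglik_null,
            n_events=pl.n_events, n_records=len(self.records),
            iterations=iterations, converged=bool(converged),
            score_norm=float(np.max(np.abs(g))) if p else 0.0,
            messages=msgs,
        )


@dataclass
class StratifiedCoxResults:
    """Fitted stratified Cox model: log rate ratios and diagnostics."""

    model: StratifiedCoxModel
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    loglik_null: float
    n_events: int
    n_records: int
    iterations: int
    converged: bool
    score_norm: float
    messages: list[str] = field(default_factory=list)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    @property
    def lr_chi2(self) -> float:
        """Likelihood-ratio statistic against the null (all coefficients zero)."""
        return 2.0 * (self.loglik - self.loglik_null)

    def conf_int(self, z: float = 1.959963984540054) -> pd.DataFrame:
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def exposure_log_rr(self) -> pd.Series:
        """Log rate ratios per exposure level, reference = 0, in level order."""
        if self.model.exposure is None:
            raise ValueError("model has no exposure")
        vals = {}
        for level in self.model.exposure_levels:
            name = f"{self.model.exposure}={level}"
            vals[level] = 0.0 if level == self.model.reference else float(self.params[name])
        return pd.Series(vals)

    def contrast_log_rr(self, contrast: tuple) -> float:
        lr = self.exposure_log_rr()
        a, b = contrast
        return float(lr[a] - lr[b])

    def floated_variances(self) -> FloatedVariances:
        """Group-specific variances over the exposure levels (reference included)."""
        if self.model.exposure is None:
            raise ValueError("model has no exposure")
        levels = self.model.exposure_levels
        ref = self.model.reference
        others = [l for l in levels if l != ref]
        names = [f"{self.model.exposure}={l}" for l in others]
        V = self.cov.loc[names, names].to_numpy()
        return float_variances(V, levels=[ref] + others)

    def rr_table(self, floated: bool = True, z: float = 1.959963984540054) -> pd.DataFrame:
        """Rate ratios with group-specific (floated) confidence intervals.

        The reference level has RR exactly 1 and, with floating, its own CI.
        Without floating the reference CI is undefined and conventional Wald
        intervals are used for the other levels.
        """
        log_rr = self.exposure_log_rr()
        rows = []
        fv = None
        if floated:
            try:
                fv = self.floated_variances()
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"floated variances unavailable ({exc}); "
                              "falling back to conventional CIs")
        for level in self.model.exposure_levels:
            beta = log_rr[level]
            if fv is not None:
                var = fv.variance_of(level)
                lo, hi = floated_ci(beta, var, z=z)
            elif level == self.model.reference:
                lo = hi = np.nan
            else:
                se = self.bse[f"{self.model.exposure}={level}"]
                lo, hi = np.exp(beta - z * se), np.exp(beta + z * se)
            rows.append({"level": level, "rr": float(np.exp(beta)),
                         "lower": lo, "upper": hi,
                         "n_events": self.model.events_by_level.get(level, 0)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Stratified Cox proportional hazards (Breslow ties, delayed entry)",
            f"records: {self.n_records}   events: {self.n_events}   "
            f"loglik: {self.loglik:.4f}   LR chi2 vs null: {self.lr_chi2:.2f}",
            f"converged: {self.converged} in {self.iterations} iterations "
            f"(max |score| = {self.score_norm:.2e})",
            "",
            f"{'term':<32}{'log RR':>10}{'SE':>10}{'RR':>8}{'95% CI':>20}",
        ]
        ci = self.conf_int()
        for name in self.params.index:
            b, se = self.params[name], self.bse[name]
            lo, hi = np.exp(ci.loc[name, "lower"]), np.exp(ci.loc[name, "upper"])
            lines.append(f"{name:<32}{b:>10.4f}{se:>10.4f}{np.exp(b):>8.3f}"
                         f"{f'({lo:.3f}, {hi:.3f})':>20}")
        for msg in self.messages:
            lines.append(f"note: {msg}")
        return "\n".join(lines)


def fit_stratified_cox(records: pd.DataFrame, exposure: str = "education",
                       reference_level: str | None = None,
                       adjustment: tuple[str, ...] = (), **fit_kwargs
                       ) -> StratifiedCoxResults:
    """Functional wrapper: build and fit a :class:`StratifiedCoxModel`."""
    model = StratifiedCoxModel(records, exposure=exposure, reference=reference_level,
                               adjust=tuple(adjustment))
    return model.fit(**fit_kwargs)


def rr_table(fit: StratifiedCoxResults, floated: FloatedVariances | None = None,
             z: float = 1.959963984540054) -> pd.DataFrame:
    """Rate-ratio table from a fit plus (optionally precomputed) floated variances."""
    if floated is None:
        return fit.rr_table(floated=True, z=z)
    log_rr = fit.exposure_log_rr()
    rows = []
    for level in fit.model.exposure_levels:
        beta = log_rr[level]
        lo, hi = floated_ci(beta, floated.variance_of(level), z=z)
        rows.append({"level": level, "rr": float(np.exp(beta)), "lower": lo, "upper": hi,
                     "n_events": fit.model.events_by_level.get(level, 0)})
    return pd.DataFrame(rows)
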