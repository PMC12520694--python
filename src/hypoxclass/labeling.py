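"""Two-component Gaussian-mixture labeling and the all-sets consensus rule.

Each gene set's score distribution across cells is fit with a univariate
two-component Gaussian mixture by EM; the component with the larger mean
is the "high" (hypoxia-active) group.  A cell is a high-confidence
hypoxic cell iff it falls in the high group for *every* gene set, a
high-confidence normoxic cell iff it falls in the low group for every
set, and low-confidence otherwise.  Because Gaussian mixtures are
equivariant under positive affine maps, rescaling any score column
cannot change the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .scoring import ScoreMatrix

__all__ = [
    "GMMFit",
    "LabelTable",
    "fit_gmm_1d",
    "posterior_high",
    "consensus_label",
    "label_cells",
    "HC_HYPOXIC",
    "HC_NORMOXIC",
    "LOW_CONF",
]

HC_HYPOXIC = "HC_HYPOXIC"
HC_NORMOXIC = "HC_NORMOXIC"
LOW_CONF = "LOW_CONF"

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GMMFit:
    means: np.ndarray          # shape (2,)
    variances: np.ndarray      # shape (2,), floored
    weights: np.ndarray        # shape (2,), sum to 1
    log_likelihood: float
    n_iter: int
    converged: bool
    ll_path: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    @property
    def high_component(self) -> int:
        """Index of the larger-mean component; mean ties broken by larger weight."""
        if self.means[0] == self.means[1]:
            return int(np.argmax(self.weights))
        return int(np.argmax(self.means))


def _log_pdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def _em(x, means, variances, weights, var_floor, tol, max_iter):
    """Plain EM on a 1-D 2-component Gaussian mixture; returns params + ll path."""
    n = x.size
    ll_path = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (log-sum-exp for stability)
        log_comp = np.stack(
            [np.log(weights[k]) + _log_pdf(x, means[k], variances[k]) for k in range(2)]
        )
        mx = log_comp.max(axis=0)
        log_norm = mx + np.log(np.exp(log_comp - mx).sum(axis=0))
        ll = float(log_norm.sum())
        ll_path.append(ll)
        resp = np.exp(log_comp - log_norm)
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp @ x) / nk
        variances = np.maximum(
            (resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk, var_floor
        )
        if ll - prev_ll < tol and it > 1:
            converged = True
            break
        prev_ll = ll
    return means, variances, weights, float(ll_path[-1]), it, converged, np.asarray(ll_path)


def fit_gmm_1d(
    values: np.ndarray,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GMMFit:
    """Fit a 2-component univariate Gaussian mixture by EM.

    Initialization: one deterministic start from a 30th/70th-percentile
    quantile split, plus ``n_init - 1`` seeded random restarts (means at
    two random data points).  The best-likelihood fit is kept.  Variances
    are floored at ``1e-6 * sample variance`` so EM cannot collapse onto
    a single point.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 10:
        raise ValidationError("need at least 10 values to fit a mixture")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite score values")
    s2 = float(np.var(x))
    if s2 == 0.0:
        raise ValidationError("degenerate score distribution: all values identical")
    var_floor = 1e-6 * s2

    q30, q70 = np.quantile(x, [0.30, 0.70])
    inits = [(np.array([q30, q70]), np.array([s2, s2]), np.array([0.5, 0.5]))]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_init - 1)):
        mu = rng.choice(x, size=2, replace=False)
        inits.append((mu.astype(np.float64), np.array([s2, s2]), np.array([0.5, 0.5])))

    best = None
    for mu0, v0, w0 in inits:
        if mu0[0] == mu0[1]:
            mu0 = mu0 + np.array([-1e-6, 1e-6]) * max(1.0, abs(mu0[0]))
        fit = _em(x, mu0.copy(), v0.copy(), w0.copy(), var_floor, tol, max_iter)
        if best is None or fit[3] > best[3]:
            best = fit
    means, variances, weights, ll, n_iter, converged, ll_path = best
    return GMMFit(means, variances, weights, ll, n_iter, converged, ll_path)


def posterior_high(fit: GMMFit, values: np.ndarray) -> np.ndarray:
    """Posterior probability of the larger-mean component for each value."""
    x = np.asarray(values, dtype=np.float64).ravel()
    log_comp = np.stack(
        [np.log(fit.weights[k]) + _log_pdf(x, fit.means[k], fit.variances[k]) for k in range(2)]
    )
    mx = log_comp.max(axis=0)
    log_norm = mx + np.log(np.exp(log_comp - mx).sum(axis=0))
    return np.exp(log_comp[fit.high_component] - log_norm)


@dataclass
class LabelTable:
    """Per-cell consensus hypoxia status with per-set provenance.

    ``status`` is HC_HYPOXIC iff every per-set group is HIGH, HC_NORMOXIC
    iff every group is LOW, and LOW_CONF otherwise; the three statuses
    partition the cells.
    """

    cell_ids: list[str]
    set_names: list[str]
    status: np.ndarray            # array of status strings, length n_cells
    per_set_high: np.ndarray      # bool, cells x K
    posterior_high: np.ndarray    # float, cells x K

    def counts(self) -> dict[str, int]:
        return {s: int((self.status == s).sum()) for s in (HC_HYPOXIC, HC_NORMOXIC, LOW_CONF)}

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"cell_id": self.cell_ids, "status": self.status})
        for k, name in enumerate(self.set_names):
            df[f"group_{name}"] = np.where(self.per_set_high[:, k], "HIGH", "LOW")
        for k, name in enumerate(self.set_names):
            df[f"posterior_{name}"] = self.posterior_high[:, k]
        return df

    @classmethod
    def from_frame(cls, df) -> "LabelTable":
        set_names = [c[len("group_"):] for c in df.columns if c.startswith("group_")]
        per_set = np.stack([(df[f"group_{n}"] == "HIGH").to_numpy() for n in set_names], axis=1)
        post = np.stack([df[f"posterior_{n}"].to_numpy(float) for n in set_names], axis=1)
        return cls(list(df["cell_id"].astype(str)), set_names,
                   df["status"].to_numpy(dtype=object), per_set, post)


def consensus_label(
    scores: ScoreMatrix,
    fits: dict[str, GMMFit],
    posterior_cut: float = 0.5,
) -> LabelTable:
    """Apply the all-sets consensus rule given one mixture fit per set."""
    missing = [n for n in scores.set_names if n not in fits]
    if missing:
        raise ValidationError(f"no mixture fit for sets: {missing}")
    k_sets = len(scores.set_names)
    n = len(scores.cell_ids)
    post = np.empty((n, k_sets))
    for k, name in enumerate(scores.set_names):
        post[:, k] = posterior_high(fits[name], scores.scores[:, k])
    high = post > posterior_cut
    status = np.full(n, LOW_CONF, dtype=object)
    status[high.all(axis=1)] = HC_HYPOXIC
    status[(~high).all(axis=1)] = HC_NORMOXIC
    return LabelTable(list(scores.cell_ids), list(scores.set_names), status, high, post)


def label_cells(
    scores: ScoreMatrix,
    seed: int = 0,
    posterior_cut: float = 0.5,
    n_init: int = 5,
) -> tuple[LabelTable, dict[str, GMMFit]]:
    """Fit one mixture per gene-set column and apply the consensus rule.

    The master seed expands to per-set seeds by set index so runs are
    reproducible regardless of fit order.
    """
    fits: dict[str, GMMFit] = {}
    for k, name in enumerate(scores.set_names):
        set_seed = (int(seed) * 100003 + k) % (2**31 - 1)
        fits[name] = fit_gmm_1d(scores.scores[:, k], seed=set_seed, n_init=n_init)
    return consensus_label(scores, fits, posterior_cut), fits
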