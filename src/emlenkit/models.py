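"""Maximum-likelihood orientation models and AICc selection.

Ten candidate models for the circular distribution of a sample of
orientation directions, from uniform (no preferred direction) through
unimodal, axial, and general bimodal behaviour. Every model is a
constrained two-component von Mises mixture

    f(theta) = lam * vM(theta; q1, k1) + (1 - lam) * vM(theta; q2, k2)

with mean directions q1, q2, concentrations k1, k2 >= 0 and mixing
weight lam in [0, 1]. The candidates differ only in which of the five
parameters are free:

====  ==========================================  =
id    constraints                                 K
====  ==========================================  =
M1    k1 = k2 = 0 (uniform)                       0
M2A   lam = 1; q1, k1 free (unimodal)             2
M2B   k2 = 0, lam = 0.5; q1, k1 free              2
M2C   k2 = 0, lam free in [0.5, 1]; q1, k1 free   3
M3A   q2 = q1 + 180, k2 = k1, lam = 0.5           2
M3B   q2 = q1 + 180, lam = 0.5; k1, k2 free       3
M4A   q2 = q1 + 180, k2 = k1; lam free            3
M4B   q2 = q1 + 180; k1, k2, lam free             4
M5A   k2 = k1; q1, q2, lam free                   4
M5B   all five free                               5
====  ==========================================  =

Free mixing weights are bounded in [0.5, 1] so the first component is
always the dominant mode (resolves label switching). Fitted models are
compared by the small-sample-corrected Akaike information criterion
AICc = -2 lnL + 2K + 2K(K+1)/(n - K - 1) and its normalized Akaike
weights.

The entry points follow the statsmodels shape: build an
:class:`OrientationModel` from the data, call :meth:`~OrientationModel.fit`
for one candidate (returning an :class:`OrientationFit`) or
:meth:`~OrientationModel.select` for the full ranked ten-model
comparison (returning a :class:`ModelSelectionResults` with a
``summary()`` table).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .angles import normalize_angle
from .circstats import circ_mean_r

__all__ = [
    "MODEL_IDS",
    "ModelSpec",
    "OrientationModel",
    "OrientationFit",
    "ModelSelectionResults",
    "vm_log_density",
    "model_loglik",
    "fit_model",
    "select_models",
]

KAPPA_MAX = 227.0  # beyond this the von Mises is numerically degenerate

MODEL_IDS = ["M1", "M2A", "M2B", "M2C", "M3A", "M3B", "M4A", "M4B", "M5A", "M5B"]


@dataclass(frozen=True)
class ModelSpec:
    """Constraint set of one orientation model.

    ``free`` lists the free parameters among (q1, k1, q2, k2, lam);
    ``K = len(free)``. ``expand`` maps a free-parameter vector to the
    full (q1, k1, q2, k2, lam) tuple.
    """

    id: str
    free: tuple[str, ...]
    description: str

    @property
    def K(self) -> int:
        return len(self.free)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        out = []
        for name in self.free:
            if name in ("q1", "q2"):
                out.append((None, None))  # periodic, unconstrained
            elif name in ("k1", "k2"):
                out.append((0.0, KAPPA_MAX))
            elif name == "lam":
                out.append((0.5, 1.0))
        return out

    def expand(self, x) -> tuple[float, float, float, float, float]:
        v = dict(zip(self.free, x))
        q1 = v.get("q1", 0.0)
        k1 = v.get("k1", 0.0)
        mid = self.id
        if mid == "M1":
            return (0.0, 0.0, 0.0, 0.0, 0.5)
        if mid == "M2A":
            return (q1, k1, q1, 0.0, 1.0)
        if mid == "M2B":
            return (q1, k1, q1, 0.0, 0.5)
        if mid == "M2C":
            return (q1, k1, q1, 0.0, v["lam"])
        if mid == "M3A":
            return (q1, k1, q1 + 180.0, k1, 0.5)
        if mid == "M3B":
            return (q1, k1, q1 + 180.0, v["k2"], 0.5)
        if mid == "M4A":
            return (q1, k1, q1 + 180.0, k1, v["lam"])
        if mid == "M4B":
            return (q1, k1, q1 + 180.0, v["k2"], v["lam"])
        if mid == "M5A":
            return (q1, k1, v["q2"], k1, v["lam"])
        if mid == "M5B":
            return (q1, k1, v["q2"], v["k2"], v["lam"])
        raise ValueError(f"unknown model id {mid!r}")


_SPECS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", (), "uniform"),
    "M2A": ModelSpec("M2A", ("q1", "k1"), "unimodal"),
    "M2B": ModelSpec("M2B", ("q1", "k1"), "symmetric modified unimodal"),
    "M2C": ModelSpec("M2C", ("q1", "k1", "lam"), "modified unimodal"),
    "M3A": ModelSpec("M3A", ("q1", "k1"), "homogeneous symmetric bimodal"),
    "M3B": ModelSpec("M3B", ("q1", "k1", "k2"), "symmetric bimodal"),
    "M4A": ModelSpec("M4A", ("q1", "k1", "lam"), "homogeneous axial bimodal"),
    "M4B": ModelSpec("M4B", ("q1", "k1", "k2", "lam"), "axial bimodal"),
    "M5A": ModelSpec("M5A", ("q1", "k1", "q2", "lam"), "homogeneous bimodal"),
    "M5B": ModelSpec("M5B", ("q1", "k1", "q2", "k2", "lam"), "bimodal"),
}


def get_spec(model_id: str) -> ModelSpec:
    try:
        return _SPECS[model_id]
    except KeyError:
        raise ValueError(f"unknown model id {model_id!r}; one of {MODEL_IDS}")


def vm_log_density(theta, q: float, kappa: float):
    """Log density of the von Mises distribution at ``theta`` degrees.

    kappa * cos(theta - q) - ln(2 pi I0(kappa)), evaluated stably via
    the exponentially scaled Bessel function for large kappa.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    d = np.deg2rad(np.asarray(theta, dtype=float) - q)
    # ln I0(k) = ln i0e(k) + k
    return kappa * np.cos(d) - math.log(2.0 * math.pi) - (
        math.log(special.i0e(kappa)) + kappa
    )


def model_loglik(params, spec: ModelSpec | str, data) -> float:
    """Log-likelihood of the full parameter tuple under one model.

    ``params`` is (q1, k1, q2, k2, lam); the constraint set of ``spec``
    must hold (checked loosely: concentrations in range, lam in [0,1]).
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    q1, k1, q2, k2, lam = params
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lam must be in [0, 1]")
    if k1 < 0 or k2 < 0:
        raise ValueError("concentrations must be >= 0")
    th = np.asarray(data, dtype=float)
    if th.size == 0:
        raise ValueError("empty sample")
    if lam >= 1.0:
        return float(np.sum(vm_log_density(th, q1, k1)))
    la = math.log(lam) + vm_log_density(th, q1, k1) if lam > 0 else -np.inf
    lb = math.log(1.0 - lam) + vm_log_density(th, q2, k2)
    if lam <= 0.0:
        return float(np.sum(lb))
    return float(np.sum(np.logaddexp(la, lb)))


def _kappa_moment(r: float) -> float:
    """Moment (ML) estimate of the von Mises concentration from the
    mean resultant length, by the standard piecewise approximation."""
    r = min(max(r, 0.0), 0.999)
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    return float(min(max(k, 0.05), KAPPA_MAX))


def _axis_estimate(th_deg: np.ndarray) -> tuple[float, float]:
    """Axis (mode pair) orientation and concentration from the doubled
    angles, for starting axial/bimodal fits."""
    th2 = np.deg2rad(2.0 * th_deg)
    C, S = np.mean(np.cos(th2)), np.mean(np.sin(th2))
    axis = normalize_angle(np.rad2deg(np.arctan2(S, C)) / 2.0)
    r2 = float(np.hypot(C, S))
    return axis, _kappa_moment(r2)


def _start_points(spec: ModelSpec, data, rng: np.random.Generator):
    """Data-driven multi-start list over the free parameters.

    Mean-direction starts come from the sample circular mean and from
    the sample axis (the mean of the doubled angles), with moment
    estimates of the concentration; mixing-weight starts {0.5, 0.75,
    0.95}. Deliberately restrained: hill-climbing from a dense blind
    grid tends to land in degenerate near-point mixture components
    (the unbounded-likelihood spikes of mixture ML), which are
    numerical artifacts rather than orientation behaviour.
    """
    summ = circ_mean_r(data)
    mu = summ.mean_direction if np.isfinite(summ.mean_direction) else 0.0
    k_mu = _kappa_moment(summ.r)
    axis, k_ax = _axis_estimate(np.asarray(data, dtype=float))
    jitter = normalize_angle(mu + float(rng.uniform(-15.0, 15.0)))

    q1_starts = [mu, axis, normalize_angle(axis + 180.0), jitter]
    k_starts = [0.5, 2.0, k_mu, k_ax]
    lam_starts = [0.5, 0.75, 0.95]

    axes = []
    for name in spec.free:
        if name == "q1":
            axes.append(("q1", q1_starts))
        elif name == "k1":
            axes.append(("k1", k_starts))
        elif name == "k2":
            axes.append(("k2", [2.0, k_ax]))
        elif name == "q2":
            axes.append(("q2_off", [180.0]))
        elif name == "lam":
            axes.append(("lam", lam_starts))
    starts = []
    for combo in itertools.product(*(vals for _, vals in axes)):
        v = dict(zip((n for n, _ in axes), combo))
        if "q2_off" in v:
            v["q2"] = v.pop("q2_off") + v.get("q1", 0.0)
        starts.append([v[name] for name in spec.free])
    return starts


def _neg_loglik(x, spec: ModelSpec, th):
    try:
        return -model_loglik(spec.expand(x), spec, th)
    except (ValueError, FloatingPointError):
        return np.inf


@dataclass(frozen=True)
class OrientationFit:
    """Fitted orientation model.

    ``params`` holds the full (q1_deg, k1, q2_deg, k2, lambda) tuple
    with mean directions normalized into [0, 360). ``delta_aicc`` and
    ``weight`` are populated when the fit is part of a ten-model
    selection.
    """

    model_id: str
    K: int
    n: int
    q1: float
    k1: float
    q2: float
    k2: float
    lam: float
    loglik: float
    aicc: float
    status: str = "ok"
    delta_aicc: float = float("nan")
    weight: float = float("nan")

    @property
    def params(self) -> tuple[float, float, float, float, float]:
        return (self.q1, self.k1, self.q2, self.k2, self.lam)

    def summary(self) -> str:
        lines = [
            f"Orientation model {self.model_id} "
            f"({get_spec(self.model_id).description}), n={self.n}",
            f"  q1={self.q1:7.2f} deg  k1={self.k1:7.3f}  "
            f"q2={self.q2:7.2f} deg  k2={self.k2:7.3f}  lambda={self.lam:5.3f}",
            f"  lnL={self.loglik:.4f}  K={self.K}  AICc={self.aicc:.4f}"
            f"  status={self.status}",
        ]
        return "\n".join(lines)


class OrientationModel:
    """Two-component von Mises mixture family for a circular sample.

    Parameters
    ----------
    data : array-like
        Orientation directions in degrees.

    Examples
    --------
    >>> m = OrientationModel([150, 160, 140, 155, 148, 152, 158, 145])
    >>> fit = m.fit("M2A", seed=0)
    >>> res = m.select(seed=0)   # ranked ten-model AICc table
    """

    def __init__(self, data):
        th = np.asarray(data, dtype=float).ravel()
        if th.size == 0:
            raise ValueError("empty sample")
        if not np.all(np.isfinite(th)):
            raise ValueError("non-finite direction")
        self.data = np.mod(th, 360.0)
        self.n = int(th.size)

    def fit(
        self,
        model_id: str = "M2A",
        seed: int | None = None,
        extra_starts=None,
        n_polish: int = 12,
    ) -> OrientationFit:
        """Fit one candidate model by bounded multi-start ML.

        Data-driven starts are ranked by their raw log-likelihood and
        the best ``n_polish`` are refined with Nelder-Mead under the
        model's bounds; the best refined solution wins. Deterministic
        given ``seed`` (the seed only perturbs one auxiliary starting
        point).
        ``extra_starts`` (free-parameter vectors) are always polished,
        which lets a selection run seed each model with its nested
        submodels' optima.
        """
        spec = get_spec(model_id)
        n = self.n
        if n < spec.K + 2:
            return OrientationFit(
                model_id=model_id, K=spec.K, n=n,
                q1=float("nan"), k1=float("nan"), q2=float("nan"),
                k2=float("nan"), lam=float("nan"),
                loglik=float("nan"), aicc=float("nan"),
                status="skipped_small_n",
            )
        if spec.K == 0:
            lnl = -n * math.log(2.0 * math.pi)
            return OrientationFit(
                model_id="M1", K=0, n=n, q1=float("nan"), k1=0.0,
                q2=float("nan"), k2=0.0, lam=0.5,
                loglik=lnl, aicc=-2.0 * lnl, status="ok",
            )

        rng = np.random.default_rng(seed)
        starts = _start_points(spec, self.data, rng)
        scored = sorted(starts, key=lambda x: _neg_loglik(x, spec, self.data))
        polish = scored[: max(1, n_polish)]
        if extra_starts:
            polish = [list(x) for x in extra_starts] + polish

        bounds = spec.bounds()
        nm_bounds = [
            (-1e6 if lo is None else lo, 1e6 if hi is None else hi)
            for lo, hi in bounds
        ]
        # explicit initial simplex with fixed per-parameter steps:
        # scipy's default scales steps with |x0|, which would make the
        # search depend on the absolute angle values and break rotation
        # equivariance
        steps = {"q1": 30.0, "q2": 30.0, "k1": 1.0, "k2": 1.0, "lam": -0.1}
        best_x, best_f = None, np.inf
        for x0 in polish:
            x0 = np.clip(np.asarray(x0, float),
                         [b[0] for b in nm_bounds], [b[1] for b in nm_bounds])
            simplex = [x0]
            for j, name in enumerate(spec.free):
                v = x0.copy()
                step = steps[name]
                if name == "lam" and v[j] + step < 0.5:
                    step = 0.1
                v[j] = np.clip(v[j] + step, nm_bounds[j][0], nm_bounds[j][1])
                if v[j] == x0[j]:
                    v[j] = np.clip(x0[j] - step, nm_bounds[j][0], nm_bounds[j][1])
                simplex.append(v)
            res = optimize.minimize(
                _neg_loglik, x0, args=(spec, self.data),
                method="Nelder-Mead", bounds=nm_bounds,
                options=dict(xatol=1e-6, fatol=1e-8, maxiter=2000,
                             initial_simplex=np.asarray(simplex)),
            )
            if res.fun < best_f:
                best_f, best_x = float(res.fun), np.asarray(res.x, float)
        q1, k1, q2, k2, lam = spec.expand(best_x)
        lnl = -best_f
        K = spec.K
        aicc = -2.0 * lnl + 2.0 * K + 2.0 * K * (K + 1.0) / (n - K - 1.0)
        return OrientationFit(
            model_id=model_id, K=K, n=n,
            q1=normalize_angle(q1) if np.isfinite(q1) else q1,
            k1=float(k1),
            q2=normalize_angle(q2) if np.isfinite(q2) else q2,
            k2=float(k2), lam=float(lam),
            loglik=lnl, aicc=float(aicc), status="ok",
        )

    def select(self, seed: int | None = None) -> "ModelSelectionResults":
        """Fit all ten candidates and rank them by AICc.

        Models are fitted in nesting order; each model's start list is
        augmented with the optima of its already-fitted submodels, so
        maximized log-likelihoods respect nesting by construction.
        Models whose AICc correction is undefined (n - K - 1 < 1) are
        skipped, excluded from weight normalization, and flagged.
        """
        fits: dict[str, OrientationFit] = {}
        free_optima: dict[str, dict[str, float]] = {}
        for mid in MODEL_IDS:
            spec = get_spec(mid)
            extra = []
            for done_id, vals in free_optima.items():
                cand = _embed_start(done_id, vals, spec)
                if cand is not None:
                    extra.append(cand)
            fit = self.fit(mid, seed=seed, extra_starts=extra)
            fits[mid] = fit
            if fit.status == "ok" and spec.K > 0:
                free_optima[mid] = dict(
                    q1=fit.q1, k1=fit.k1, q2=fit.q2, k2=fit.k2, lam=fit.lam
                )
        return ModelSelectionResults._from_fits(list(fits.values()))


def _embed_start(sub_id: str, vals: dict, spec: ModelSpec):
    """Express a fitted submodel's solution as a start vector for a
    larger model, where the embedding is natural; else None."""
    out = []
    for name in spec.free:
        if name == "lam":
            v = vals["lam"]
            out.append(min(max(v, 0.5), 0.999))
        elif name == "q2":
            q2 = vals["q2"]
            out.append(q2 if np.isfinite(q2) else vals["q1"] + 180.0)
        elif name == "k2":
            out.append(max(vals["k2"], 0.0))
        else:
            v = vals[name]
            if not np.isfinite(v):
                return None
            out.append(v)
    return out if out else None


class ModelSelectionResults:
    """Ranked ten-model AICc comparison for one circular sample.

    Attributes
    ----------
    fits : list of OrientationFit
        Ranked by AICc ascending (ties: smaller K, then model id);
        skipped fits are last. ``delta_aicc`` and Akaike ``weight`` are
        filled in; weights over the fitted models sum to 1.
    """

    def __init__(self, fits: list[OrientationFit]):
        self.fits = fits

    @classmethod
    def _from_fits(cls, fits: list[OrientationFit]) -> "ModelSelectionResults":
        ok = [f for f in fits if f.status == "ok"]
        skipped = [f for f in fits if f.status != "ok"]
        if skipped:
            warnings.warn(
                f"models skipped (sample too small): "
                f"{[f.model_id for f in skipped]}",
                stacklevel=2,
            )
        if not ok:
            raise ValueError("no model could be fitted")
        best_aicc = min(f.aicc for f in ok)
        rel = np.array([math.exp(-0.5 * (f.aicc - best_aicc)) for f in ok])
        weights = rel / rel.sum()
        ranked = []
        for f, w in zip(ok, weights):
            ranked.append(replace(f, delta_aicc=f.aicc - best_aicc, weight=float(w)))
        ranked.sort(key=lambda f: (f.aicc, f.K, f.model_id))
        return cls(ranked + skipped)

    @property
    def best(self) -> OrientationFit:
        return self.fits[0]

    @property
    def weights(self) -> dict[str, float]:
        return {f.model_id: f.weight for f in self.fits}

    def table(self) -> pd.DataFrame:
        """The comparison as a DataFrame (model_table.tsv schema)."""
        rows = []
        for f in self.fits:
            rows.append(
                dict(
                    model_id=f.model_id, K=f.K,
                    q1_deg=f.q1, k1=f.k1, q2_deg=f.q2, k2=f.k2,
                    **{"lambda": f.lam},
                    lnL=f.loglik, AICc=f.aicc,
                    delta_AICc=f.delta_aicc, weight=f.weight,
                    status=f.status,
                )
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.table().copy()
        for c in df.columns:
            if df[c].dtype.kind == "f":
                df[c] = df[c].round(3)
        return (
            f"Orientation model selection (n={self.fits[0].n})\n"
            + df.to_string(index=False)
        )


def fit_model(data, model_id: str, seed: int | None = None) -> OrientationFit:
    """Functional wrapper: fit one orientation model to a sample."""
    return OrientationModel(data).fit(model_id, seed=seed)


def select_models(data, seed: int | None = None) -> ModelSelectionResults:
    """Functional wrapper: the full ranked ten-model comparison."""
    return OrientationModel(data).select(seed=seed)
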