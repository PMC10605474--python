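"""Allele sizing from molecule intermarker distances.

Two-step algorithm: (1) outlier removal by one-dimensional DBSCAN with the
radius chosen automatically at the knee of the sorted k-nearest-neighbour
distance curve; (2) univariate Gaussian mixture fits with one and two
components, the two-component model being selected only when its BIC is
strictly lower AND both component weights exceed a threshold (default 25%).
Component means/SDs are converted from bp to repeat units against the locus'
reference intermarker distance.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import DBSCAN

from .errors import (
    AllOutliersError,
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)
from .locus_io import DistanceSet, LocusSpec

logger = logging.getLogger(__name__)

ZYGOSITY_SINGLE = "single-component (reported homozygous)"
ZYGOSITY_TWO = "two alleles"


@dataclass(frozen=True)
class SizingConfig:
    """Tuning knobs of the sizing pipeline.

    All unstated algorithmic parameters are pinned here so that a run is
    fully reproducible from (data, config).
    """

    min_samples: int = 5
    knee_sensitivity: float = 1.0
    weight_threshold: float = 0.25
    n_restarts: int = 10
    em_tol: float = 1e-6
    max_iter: int = 500
    variance_floor_frac: float = 1e-6
    min_molecules: int = 10
    seed: int = 0
    expanded_threshold_repeats: float = 250.0
    normal_threshold_repeats: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.weight_threshold < 0.5:
            raise ValidationError("weight_threshold must be in (0, 0.5)")
        if self.min_samples < 1 or self.n_restarts < 1 or self.max_iter < 1:
            raise ValidationError("min_samples, n_restarts and max_iter must be positive")
        if self.em_tol <= 0 or self.variance_floor_frac <= 0 or self.knee_sensitivity <= 0:
            raise ValidationError("em_tol, variance_floor_frac and knee_sensitivity must be > 0")
        if self.min_molecules < 2 * self.min_samples:
            warnings.warn(
                f"min_molecules ({self.min_molecules}) < 2*min_samples "
                f"({2 * self.min_samples}); density filtering may be unstable",
                stacklevel=2,
            )


@dataclass
class GaussianComponent:
    """One mixture component, in bp and (once converted) in repeat units."""

    mean_bp: float
    sd_bp: float
    weight: float
    mean_repeats: float | None = None
    sd_repeats: float | None = None

    def with_repeats(self, locus: LocusSpec) -> "GaussianComponent":
        return replace(
            self,
            mean_repeats=bp_to_repeats(self.mean_bp, locus),
            sd_repeats=self.sd_bp / locus.motif_length_bp,
        )


@dataclass
class MixtureFit:
    """A fitted k-component univariate Gaussian mixture."""

    k: int
    components: list[GaussianComponent]
    loglik: float
    bic: float
    n: int
    converged: bool

    @property
    def weights(self) -> list[float]:
        return [c.weight for c in self.components]


@dataclass
class SizingResult:
    sample_id: str
    selected: MixtureFit
    alleles: list[GaussianComponent]
    zygosity_label: str
    n_total: int
    n_kept: int
    n_outliers: int
    epsilon_used: float
    instability_ratios: list[float | None]
    classifications: list[str]
    bic_k1: float
    bic_k2: float | None = None
    fits: dict[int, MixtureFit] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.selected.k


def bp_to_repeats(distance_bp: float, locus: LocusSpec) -> float:
    """Convert an intermarker distance (bp) to repeat units.

    May be negative for contracted reference alleles; never clamped.
    Integer presentation uses round-half-to-even at report time only.
    """
    return (distance_bp - locus.reference_distance_bp) / locus.motif_length_bp


def repeats_to_bp(repeats: float, locus: LocusSpec) -> float:
    return locus.reference_distance_bp + repeats * locus.motif_length_bp


def k_distance_curve(distances: Sequence[float], min_samples: int) -> np.ndarray:
    """Sorted distance of every point to its min_samples-th nearest neighbour.

    Exact computation (full pairwise matrix); sample sizes here are tens to
    hundreds of molecules, so O(n^2) is immaterial.
    """
    x = np.asarray(distances, dtype=float)
    n = x.size
    if n < min_samples + 1:
        raise InsufficientDataError(
            f"need at least {min_samples + 1} points for a {min_samples}-distance curve, got {n}"
        )
    diffs = np.abs(x[:, None] - x[None, :])
    diffs.sort(axis=1)
    kdist = diffs[:, min_samples]  # column 0 is the self-distance
    kdist.sort()
    return kdist


def find_knee_index(y: np.ndarray, sensitivity: float = 1.0) -> int | None:
    """Knee of a convex increasing curve (Kneedle, offline variant).

    The curve is normalised to the unit square, mirrored into a concave
    increasing curve, and the first difference-curve maximum whose prominence
    survives the sensitivity threshold is reported (index in the ORIGINAL
    orientation).  Returns None when no knee exists (e.g. a flat curve).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3 or y.max() == y.min():
        return None
    x_n = np.linspace(0.0, 1.0, n)
    y_n = (y - y.min()) / (y.max() - y.min())
    # convex increasing -> concave increasing: flip vertically then horizontally
    y_t = (1.0 - y_n)[::-1]
    diff = y_t - x_n
    maxima = [i for i in range(1, n - 1) if diff[i - 1] < diff[i] and diff[i] >= diff[i + 1]]
    if not maxima:
        return None
    step = sensitivity * np.abs(np.diff(x_n)).mean()
    for j, m in enumerate(maxima):
        threshold = diff[m] - step
        end = maxima[j + 1] if j + 1 < len(maxima) else n
        for i in range(m + 1, end):
            if diff[i] < threshold:
                return n - 1 - m  # map back through the horizontal flip
    return None


def knee_epsilon(
    distances: Sequence[float],
    min_samples: int = 5,
    sensitivity: float = 1.0,
) -> float:
    """DBSCAN radius at the knee of the sorted k-distance curve.

    Falls back to the maximum k-distance (outlier removal effectively
    disabled) when the curve has no knee.
    """
    kdist = k_distance_curve(distances, min_samples)
    idx = find_knee_index(kdist, sensitivity)
    if idx is None:
        logger.warning("no knee found on the k-distance curve; using max k-distance")
        return float(kdist[-1])
    eps = float(kdist[idx])
    if eps <= 0:
        # duplicate-heavy data can put the knee at a zero k-distance
        positive = kdist[kdist > 0]
        eps = float(positive[0]) if positive.size else float(kdist[-1])
        logger.warning("knee at zero k-distance; widening epsilon to %.3f", eps)
    return eps


def dbscan_filter(
    distances: Sequence[float],
    epsilon: float,
    min_samples: int = 5,
) -> tuple[list[float], list[float]]:
    """Split distances into clustered (kept) and noise (removed) points.

    Standard DBSCAN in one dimension; a core point has >= min_samples
    neighbours within epsilon, counting itself.  Input order is preserved
    within each output list.
    """
    if epsilon <= 0:
        raise ValidationError(f"epsilon must be > 0, got {epsilon}")
    x = np.asarray(distances, dtype=float).reshape(-1, 1)
    labels = DBSCAN(eps=epsilon, min_samples=min_samples).fit(x).labels_
    kept = [float(v) for v, lab in zip(x.ravel(), labels) if lab != -1]
    removed = [float(v) for v, lab in zip(x.ravel(), labels) if lab == -1]
    if not kept:
        raise AllOutliersError(
            "density filtering removed every observation; inspect epsilon "
            f"(epsilon={epsilon}, min_samples={min_samples})"
        )
    return kept, removed


def _gaussian_loglik(x: np.ndarray, mean: float, var: float) -> float:
    return float(np.sum(-0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)))


def _mixture_loglik(x: np.ndarray, means, vars_, weights) -> tuple[float, np.ndarray]:
    """Total log-likelihood and per-point per-component log joint densities."""
    log_dens = (
        np.log(weights)[None, :]
        - 0.5 * np.log(2 * np.pi * np.asarray(vars_))[None, :]
        - 0.5 * (x[:, None] - np.asarray(means)[None, :]) ** 2 / np.asarray(vars_)[None, :]
    )
    ll = float(np.sum(logsumexp(log_dens, axis=1)))
    return ll, log_dens


def _em_once(
    x: np.ndarray,
    means: np.ndarray,
    vars_: np.ndarray,
    weights: np.ndarray,
    var_floor: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, log_dens = _mixture_loglik(x, means, vars_, weights)
        resp = np.exp(log_dens - logsumexp(log_dens, axis=1, keepdims=True))
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        vars_ = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        vars_ = np.maximum(vars_, var_floor)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * max(abs(ll_prev), 1e-12):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    ll_final, _ = _mixture_loglik(x, means, vars_, weights)
    return means, vars_, weights, ll_final, converged


def fit_gmm(distances: Sequence[float], k: int, config: SizingConfig | None = None) -> MixtureFit:
    """Maximum-likelihood univariate Gaussian mixture with k in {1, 2}.

    Restart 0 initialises from equal-count blocks of the sorted data; the
    remaining restarts draw random responsibilities from the config seed.
    The best restart by log-likelihood wins.  BIC = (3k-1) ln(n) - 2 loglik.
    """
    if k not in (1, 2):
        raise ValidationError(f"unsupported number of components k={k}; must be 1 or 2")
    config = config or SizingConfig()
    x = np.asarray(distances, dtype=float)
    n = x.size
    if n < 2 * k:
        raise InsufficientDataError(f"need at least {2 * k} points to fit k={k}, got {n}")
    sample_var = float(x.var())
    if sample_var == 0.0 and k == 2:
        raise DegenerateDataError("all distances identical; a two-component fit is undefined")
    var_floor = max(config.variance_floor_frac * sample_var, 1e-12)

    if k == 1:
        mean = float(x.mean())
        var = max(sample_var, var_floor)
        ll = _gaussian_loglik(x, mean, var)
        bic = (3 * k - 1) * math.log(n) - 2 * ll
        comp = GaussianComponent(mean_bp=mean, sd_bp=math.sqrt(var), weight=1.0)
        return MixtureFit(k=1, components=[comp], loglik=ll, bic=bic, n=n, converged=True)

    rng = np.random.default_rng(config.seed)
    best: tuple[float, tuple] | None = None
    xs = np.sort(x)
    for restart in range(config.n_restarts):
        if restart == 0:
            blocks = np.array_split(xs, k)
            means = np.array([b.mean() for b in blocks])
            vars_ = np.maximum(np.array([b.var() for b in blocks]), var_floor)
            weights = np.array([b.size / n for b in blocks])
        else:
            resp = rng.dirichlet(np.ones(k), size=n)
            nk = np.maximum(resp.sum(axis=0), 1e-12)
            weights = nk / n
            means = (resp * x[:, None]).sum(axis=0) / nk
            vars_ = np.maximum(
                (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk, var_floor
            )
        means, vars_, weights, ll, converged = _em_once(
            x, means, vars_, weights, var_floor, config.em_tol, config.max_iter
        )
        if best is None or ll > best[0]:
            best = (ll, (means, vars_, weights, converged))
    assert best is not None
    ll, (means, vars_, weights, converged) = best
    order = np.argsort(means)
    comps = [
        GaussianComponent(
            mean_bp=float(means[i]), sd_bp=float(math.sqrt(vars_[i])), weight=float(weights[i])
        )
        for i in order
    ]
    bic = (3 * k - 1) * math.log(n) - 2 * ll
    return MixtureFit(k=k, components=comps, loglik=ll, bic=bic, n=n, converged=converged)


def _pack_params(fit: MixtureFit) -> np.ndarray:
    if fit.k == 1:
        c = fit.components[0]
        return np.array([c.mean_bp, math.log(c.sd_bp)])
    c1, c2 = fit.components
    w = min(max(c1.weight, 1e-9), 1 - 1e-9)
    return np.array(
        [c1.mean_bp, c2.mean_bp, math.log(c1.sd_bp), math.log(c2.sd_bp), math.log(w / (1 - w))]
    )


def _loglik_at(params: np.ndarray, x: np.ndarray, k: int) -> float:
    if k == 1:
        means, vars_, weights = [params[0]], [math.exp(2 * params[1])], [1.0]
    else:
        w1 = 1.0 / (1.0 + math.exp(-params[4]))
        means = params[:2]
        vars_ = np.exp(2 * params[2:4])
        weights = [w1, 1.0 - w1]
    ll, _ = _mixture_loglik(x, means, vars_, weights)
    return ll


def component_mean_standard_errors(fit: MixtureFit, distances: Sequence[float]) -> list[float]:
    """Standard errors (bp) of the fitted component means.

    Computed from the observed information matrix of the mixture MLE
    (finite-difference Hessian over means, log-SDs and logit weight).  For
    overlapping components this is materially larger than the naive
    sd/sqrt(n*weight), which assumes known component membership.
    """
    x = np.asarray(distances, dtype=float)
    params = _pack_params(fit)
    npar = params.size
    scale = np.maximum(np.abs(params) * 1e-5, 1e-5)
    hess = np.zeros((npar, npar))
    for i in range(npar):
        for j in range(i, npar):
            ei = np.zeros(npar)
            ej = np.zeros(npar)
            ei[i] = scale[i]
            ej[j] = scale[j]
            val = (
                _loglik_at(params + ei + ej, x, fit.k)
                - _loglik_at(params + ei - ej, x, fit.k)
                - _loglik_at(params - ei + ej, x, fit.k)
                + _loglik_at(params - ei - ej, x, fit.k)
            ) / (4 * scale[i] * scale[j])
            hess[i, j] = hess[j, i] = val
    cov = np.linalg.pinv(-hess)
    n_means = fit.k
    ses = np.sqrt(np.maximum(np.diag(cov)[:n_means], 0.0))
    return [float(s) for s in ses]


def select_model(fit1: MixtureFit, fit2: MixtureFit, weight_threshold: float = 0.25) -> MixtureFit:
    """Prefer the two-component fit iff its BIC is strictly lower AND both
    component weights exceed the threshold; ties favour parsimony."""
    if fit1.k != 1 or fit2.k != 2:
        raise ValidationError("select_model expects (fit1.k, fit2.k) == (1, 2)")
    if fit2.bic < fit1.bic and min(fit2.weights) > weight_threshold:
        return fit2
    return fit1


def classify_allele(mean_repeats: float, config: SizingConfig) -> str:
    if mean_repeats >= config.expanded_threshold_repeats:
        return "expanded"
    if mean_repeats < config.normal_threshold_repeats:
        return "normal"
    return "intermediate"


def size_sample(
    dset: DistanceSet,
    locus: LocusSpec,
    config: SizingConfig | None = None,
) -> SizingResult:
    """Full per-sample pipeline: knee epsilon -> DBSCAN -> GMM k=1/k=2 ->
    model selection -> repeat-unit conversion and per-allele annotation."""
    config = config or SizingConfig()
    n_total = len(dset)
    if n_total < config.min_molecules:
        raise InsufficientDataError(
            f"sample {dset.sample_id}: {n_total} molecules < min_molecules={config.min_molecules}"
        )
    epsilon = knee_epsilon(dset.distances_bp, config.min_samples, config.knee_sensitivity)
    kept, removed = dbscan_filter(dset.distances_bp, epsilon, config.min_samples)

    fit1 = fit_gmm(kept, 1, config)
    fit2 = None
    if len(kept) >= 4 and float(np.var(kept)) > 0:
        fit2 = fit_gmm(kept, 2, config)
        selected = select_model(fit1, fit2, config.weight_threshold)
    else:
        selected = fit1

    alleles = [c.with_repeats(locus) for c in selected.components]
    alleles.sort(key=lambda c: c.mean_repeats)
    ratios: list[float | None] = [
        (c.sd_repeats / c.mean_repeats) if c.mean_repeats and c.mean_repeats > 0 else None
        for c in alleles
    ]
    return SizingResult(
        sample_id=dset.sample_id,
        selected=selected,
        alleles=alleles,
        zygosity_label=ZYGOSITY_TWO if selected.k == 2 else ZYGOSITY_SINGLE,
        n_total=n_total,
        n_kept=len(kept),
        n_outliers=len(removed),
        epsilon_used=epsilon,
        instability_ratios=ratios,
        classifications=[classify_allele(c.mean_repeats, config) for c in alleles],
        bic_k1=fit1.bic,
        bic_k2=fit2.bic if fit2 is not None else None,
        fits={1: fit1, **({2: fit2} if fit2 is not None else {})},
    )
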