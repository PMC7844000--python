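"""Cell-cycle deconvolution from single-nucleus Hoechst intensities.

An adaptation of the Dean-Jett-Fox DNA-content model for imaging data:
G1 (2N) nuclei form a Gaussian peak at ``mu_g1``, G2/M (4N) nuclei a
second Gaussian at a fixed position ratio (default 2x), S-phase nuclei
are spread between the peaks, and all measurements share a single noise
SD across the intensity range. The model is fitted to solvent-control
cells by minimizing a binned negative log-likelihood with the
Nelder-Mead simplex, then applied to treated wells.

Classification uses 2-SD bands around the fitted peaks: below the G1
band is Sub-G1 (apoptotic/fragmented), between the bands is S, above
the G2 band is >4N (polyploid/aggregates). Band-edge ties resolve to
the inner (peak) class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ValidationError

PHASES = ("sub_g1", "g1", "s", "g2", "over_4n")


@dataclass(frozen=True)
class CellCycleModel:
    """Fitted two-peak DNA-content mixture.

    ``w_g1 + w_s + w_g2 <= 1``; residual mass covers Sub-G1/>4N tails
    outside the fitted components.
    """

    mu_g1: float
    sigma: float
    w_g1: float
    w_s: float
    w_g2: float
    peak_ratio: float = 2.0

    def __post_init__(self):
        if self.mu_g1 <= 0 or self.sigma <= 0 or self.peak_ratio <= 1:
            raise ValidationError("mu_g1, sigma must be positive; peak_ratio > 1")
        w = (self.w_g1, self.w_s, self.w_g2)
        if any(not 0 <= x <= 1 for x in w) or sum(w) > 1 + 1e-9:
            raise ValidationError("component weights must lie in [0,1], sum <= 1")

    @property
    def mu_g2(self) -> float:
        return self.peak_ratio * self.mu_g1


@dataclass(frozen=True)
class CellCycleProfile:
    """Phase fractions; always sums to 1."""

    sub_g1: float
    g1: float
    s: float
    g2: float
    over_4n: float

    def __post_init__(self):
        vals = self.as_array()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValidationError("fractions must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValidationError(f"fractions sum to {vals.sum()!r}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.sub_g1, self.g1, self.s, self.g2, self.over_4n])


# ---------------------------------------------------------------------------
# fitting

def _bin_probs(edges: np.ndarray, mu: float, sigma: float,
               w: np.ndarray, ratio: float) -> np.ndarray:
    """Exact per-bin mass of the mixture plus a uniform debris background.

    The background component (weight ``w[3]``) spans the whole histogram
    range and absorbs Sub-G1 debris and >4N events, which would otherwise
    inflate the shared noise SD.
    """
    mu2 = ratio * mu
    g1 = np.diff(stats.norm.cdf(edges, mu, sigma))
    g2 = np.diff(stats.norm.cdf(edges, mu2, sigma))
    u = np.diff(np.clip(edges, mu, mu2)) / (mu2 - mu)
    bg = np.diff(edges) / (edges[-1] - edges[0])
    return w[0] * g1 + w[1] * u + w[2] * g2 + w[3] * bg


def _softmax4(a: np.ndarray) -> np.ndarray:
    z = np.append(a, 0.0)
    e = np.exp(z - z.max())
    return e / e.sum()


def fit_model(intensities, peak_ratio: float = 2.0, n_bins: int = 256,
              maxiter: int = 4000, xatol: float = 1e-6, fatol: float = 1e-6,
              init: dict | None = None) -> CellCycleModel:
    """Fit the DNA-content mixture to solvent-control intensities.

    All free parameters (G1 peak position, shared noise SD, component
    weights) are optimized simultaneously with Nelder-Mead on a binned
    negative log-likelihood; the G2 peak position stays locked at
    ``peak_ratio * mu_g1``. Initialization is deterministic (histogram
    mode for the peak, 10% CV for the SD, coarse band counts for the
    weights; ``init`` can override ``mu_g1``/``sigma``), so refits on
    identical data give identical parameters.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0 or np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValidationError("intensities must be positive finite values")
    if x.size < 200:
        warnings.warn(f"only {x.size} cells; fit may be unstable "
                      "(>= 200 recommended)")

    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def objective(theta: np.ndarray) -> float:
        mu = np.exp(theta[0])
        sigma = np.exp(theta[1])
        w = _softmax4(theta[2:])
        p = _bin_probs(edges, mu, sigma, w, peak_ratio)
        p = np.clip(p, 1e-300, None)
        p = p / p.sum()
        return -float(counts @ np.log(p))

    # G1 peak init: histogram mode, but if G2 dominates the culture the
    # mode sits at ratio*mu_g1 — try both readings, keep the better one.
    mode = centers[np.argmax(counts)]
    init = init or {}
    candidates = [mode, mode / peak_ratio]
    if "mu_g1" in init:
        candidates = [float(init["mu_g1"])]
    best = None
    for mu0 in candidates:
        if mu0 <= 0:
            continue
        sigma0 = float(init.get("sigma", 0.1 * mu0))
        # coarse band counts -> weight init
        in_g1 = np.abs(x - mu0) <= 2 * sigma0
        in_g2 = np.abs(x - peak_ratio * mu0) <= 2 * sigma0
        in_s = (~in_g1) & (~in_g2) & (x > mu0) & (x < peak_ratio * mu0)
        n = x.size
        n_bg = n - in_g1.sum() - in_g2.sum() - in_s.sum()
        w0 = np.maximum(
            np.array([in_g1.sum(), in_s.sum(), in_g2.sum(), n_bg]) / n, 1e-3)
        a = np.log(w0 / w0[3])
        theta0 = np.array([np.log(mu0), np.log(sigma0), a[0], a[1], a[2]])
        res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": xatol,
                                         "fatol": fatol})
        if best is None or res.fun < best.fun:
            best = res

    if not best.success:
        raise FitError("Nelder-Mead did not converge",
                       best_params=best.x,
                       diagnostics={"nll": float(best.fun),
                                    "message": best.message,
                                    "nit": int(best.nit)})
    mu = float(np.exp(best.x[0]))
    sigma = float(np.exp(best.x[1]))
    w = _softmax4(best.x[2:])  # w[3] = residual debris mass, not stored
    if not (x.min() <= mu <= x.max()):
        raise FitError(f"fitted G1 peak {mu:.4g} outside data range",
                       best_params=best.x)
    return CellCycleModel(mu_g1=mu, sigma=sigma, w_g1=float(w[0]),
                          w_s=float(w[1]), w_g2=float(w[2]),
                          peak_ratio=peak_ratio)


# ---------------------------------------------------------------------------
# classification

def classify_cells(intensities, model: CellCycleModel,
                   band_width_sd: float = 2.0) -> np.ndarray:
    """Assign each nucleus a phase label from fixed SD bands.

    With ``mu_g2 = peak_ratio * mu_g1`` and half-width ``k = band_width_sd
    * sigma``: below ``mu_g1 - k`` is Sub-G1; within ``k`` of a peak is
    that peak's phase (edges inclusive); strictly between the bands is S;
    above ``mu_g2 + k`` is >4N. Raises when the bands overlap and the S
    band is undefined.
    """
    x = np.asarray(intensities, dtype=float)
    k = band_width_sd * model.sigma
    mu1, mu2 = model.mu_g1, model.mu_g2
    if mu2 - k <= mu1 + k:
        raise ValidationError(
            f"G1 and G2 bands overlap (mu_g2 - mu_g1 = {mu2 - mu1:.4g} <= "
            f"{2 * k:.4g}); S band undefined")
    out = np.empty(x.shape, dtype=object)
    out[x < mu1 - k] = "sub_g1"
    out[np.abs(x - mu1) <= k] = "g1"
    out[(x > mu1 + k) & (x < mu2 - k)] = "s"
    out[np.abs(x - mu2) <= k] = "g2"
    out[x > mu2 + k] = "over_4n"
    return out


def profile(labels) -> CellCycleProfile:
    """Phase fractions from per-cell labels."""
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValidationError("cannot profile zero cells")
    n = labels.size
    counts = {p: int(np.sum(labels == p)) for p in PHASES}
    if sum(counts.values()) != n:
        bad = set(labels) - set(PHASES)
        raise ValidationError(f"unknown phase labels {bad}")
    return CellCycleProfile(*(counts[p] / n for p in PHASES))


# ---------------------------------------------------------------------------
# generative form (shared with the synthetic-screen generator)

def sample_intensities(model: CellCycleModel, n: int,
                       rng: np.random.Generator,
                       frac_sub_g1: float = 0.0, frac_over_4n: float = 0.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Draw nuclei intensities from the model's generative mixture.

    G1 and G2 nuclei are Gaussian around their peaks, S-phase nuclei are
    uniform between the peaks, Sub-G1 debris sits below the G1 band and
    >4N events above the G2 band. Component weights are the model weights
    rescaled to leave room for the requested tail fractions. Returns
    (intensities, true phase labels).
    """
    if frac_sub_g1 + frac_over_4n >= 1:
        raise ValidationError("tail fractions must sum below 1")
    w_core = np.array([model.w_g1, model.w_s, model.w_g2])
    w_core = w_core / w_core.sum() * (1 - frac_sub_g1 - frac_over_4n)
    probs = np.array([frac_sub_g1, w_core[0], w_core[1], w_core[2],
                      frac_over_4n])
    idx = rng.choice(5, size=n, p=probs)
    mu1, mu2, s = model.mu_g1, model.mu_g2, model.sigma
    x = np.empty(n)
    lo = max(0.15 * mu1, mu1 - 8 * s)
    x[idx == 0] = rng.uniform(lo, mu1 - 3 * s, np.sum(idx == 0))
    x[idx == 1] = rng.normal(mu1, s, np.sum(idx == 1))
    x[idx == 2] = rng.uniform(mu1, mu2, np.sum(idx == 2))
    x[idx == 3] = rng.normal(mu2, s, np.sum(idx == 3))
    x[idx == 4] = rng.uniform(mu2 + 3 * s, mu2 + 0.5 * mu1, np.sum(idx == 4))
    x = np.clip(x, 1e-6, None)
    labels = np.array(PHASES, dtype=object)[idx]
    return x, labels
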