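"""Simulation of replicate preference profiles with controlled correlation.

Structures are rarely solved twice, so measurement error in a predicted
profile is emulated rather than measured: each site's preference vector is
resampled as a multinomial of size ``n`` (100 by convention) and perturbed
with additive Gaussian noise of scale σ, then clamped at zero and
renormalized over the 20 amino acids. Larger σ lowers the Pearson
correlation between replicate and source; :func:`calibrate_sigma` inverts
this monotone relation by bisection to hit a target correlation (0.60 is
the conventional operating point, comparable to replicate correlations in
large-scale mutagenesis experiments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import PreferenceProfile, ValidationError

__all__ = ["ReplicateSimParams", "simulate_replicate", "profile_correlation",
           "calibrate_sigma"]


@dataclass(frozen=True)
class ReplicateSimParams:
    """Noise-model parameters: multinomial size n, Gaussian scale σ, and the
    number of replicates drawn per profile."""

    n_multinomial: int = 100
    sigma: float = 0.0
    n_replicates: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_multinomial < 1:
            raise ValueError("n_multinomial must be ≥ 1")
        if self.sigma < 0:
            raise ValueError("sigma must be ≥ 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be ≥ 2")


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def simulate_replicate(profile: PreferenceProfile, params: ReplicateSimParams,
                       rng=None, max_retries: int = 100) -> PreferenceProfile:
    """Draw one noisy replicate of ``profile``.

    Per site: a multinomial sample of size n centered at the source row is
    converted to fractions, per-amino-acid Gaussian noise of scale σ is
    added, negatives are clamped to 0 and the row renormalized. A site whose
    post-clamp row sums to 0 has its noise resampled (bounded retries).
    """
    profile.validate()
    gen = _rng(rng if rng is not None else params.seed)
    p = profile.values
    m = gen.multinomial(params.n_multinomial, p) / params.n_multinomial
    if params.sigma > 0:
        x = m + gen.normal(0.0, params.sigma, size=m.shape)
    else:
        x = m.copy()
    np.clip(x, 0.0, None, out=x)
    sums = x.sum(axis=1)
    tries = 0
    while np.any(sums <= 0):
        if tries >= max_retries:
            raise ValidationError(
                "replicate simulation: a site's row summed to 0 after "
                f"{max_retries} noise resamples"
            )
        bad = sums <= 0
        x[bad] = np.clip(
            m[bad] + gen.normal(0.0, params.sigma, size=(bad.sum(), p.shape[1])),
            0.0, None,
        )
        sums = x.sum(axis=1)
        tries += 1
    values = x / sums[:, None]
    return PreferenceProfile(profile.protein_id, list(profile.sites), values)


def profile_correlation(a: PreferenceProfile, b: PreferenceProfile) -> float:
    """Pearson correlation over all L×20 entries, flattened."""
    if a.values.shape != b.values.shape:
        raise ValidationError("profiles have different dimensions")
    x = a.values.ravel()
    y = b.values.ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("profile correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def calibrate_sigma(profile: PreferenceProfile, target_r: float,
                    params: ReplicateSimParams | None = None, rng=None,
                    n_probe: int = 20, sigma_max: float = 1.0,
                    tol: float = 0.01, max_iter: int = 60) -> float:
    """Find σ so the mean replicate-to-source correlation equals ``target_r``.

    The mean correlation over ``n_probe`` replicates is evaluated with common
    random numbers (fixed multinomial and noise draws, scaled by σ), making
    it a deterministic monotone-decreasing function of σ that bisection can
    invert to within ``tol``. Targets above the σ=0 multinomial ceiling or
    below the σ=sigma_max floor raise an error reporting the reachable range.
    """
    if not 0.0 < target_r < 1.0:
        raise ValueError("target_r must lie strictly between 0 and 1")
    profile.validate()
    if params is None:
        params = ReplicateSimParams()
    gen = _rng(rng)
    p = profile.values
    n = params.n_multinomial
    M = gen.multinomial(n, p, size=(n_probe,) + p.shape[:1]).reshape(
        n_probe, *p.shape) / n
    Z = gen.standard_normal((n_probe,) + p.shape)
    src = p.ravel()
    src_c = src - src.mean()
    src_norm = np.sqrt((src_c**2).sum())
    if src_norm == 0:
        raise ValidationError("cannot calibrate against a zero-variance profile")

    def mean_corr(sigma: float) -> float:
        rs = np.empty(n_probe)
        for k in range(n_probe):
            x = np.clip(M[k] + sigma * Z[k], 0.0, None)
            s = x.sum(axis=1)
            dead = s <= 0
            if np.any(dead):  # fall back to the multinomial fractions
                x[dead] = M[k][dead]
                s = x.sum(axis=1)
            rep = (x / s[:, None]).ravel()
            rep_c = rep - rep.mean()
            rs[k] = float(rep_c @ src_c / (np.sqrt((rep_c**2).sum()) * src_norm))
        return float(rs.mean())

    c_lo = mean_corr(0.0)
    if abs(c_lo - target_r) <= tol:
        return 0.0
    c_hi = mean_corr(sigma_max)
    if not (c_hi < target_r < c_lo):
        raise ValidationError(
            f"target correlation {target_r} unreachable: achievable range is "
            f"[{c_hi:.3f}, {c_lo:.3f}] for sigma in [0, {sigma_max}]"
        )
    lo, hi = 0.0, sigma_max
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c = mean_corr(mid)
        if abs(c - target_r) <= 0.5 * tol or hi - lo < 1e-9:
            break
        if c > target_r:
            lo = mid
        else:
            hi = mid
    return mid
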