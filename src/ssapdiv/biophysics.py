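"""Stability-to-fitness models: from ΔΔG matrices to preference profiles.

Three biophysical models map a mutation's change in folding free energy
(ΔΔG, kcal/mol) to the protein's folding probability Pf, the fitness proxy:

* ``threshold`` — Boltzmann sigmoid, Pf = e^{−ΔG/kT} / (1 + e^{−ΔG/kT}) with
  ΔG = ΔΔG + ΔG_wt. A protein performs optimally above a minimal stability;
  destabilizing mutations past the threshold reduce fitness.
* ``maximum`` — exponential decay, Pf = α·e^{−λ·ΔΔG}: any stabilization is
  favorable (strong selection for stability).
* ``optimum`` — Gaussian, Pf = α·e^{−λ·ΔΔG²}: fitness peaks at the wildtype
  stability and both directions of change are unfavorable.

Site preferences follow by normalizing Pf over the 20 amino acids,
π_{r,a} = Pf(ΔΔG_{r,a}) / Σ_j Pf(ΔΔG_{r,j}); the scale α cancels, and for
the maximum model the row is exactly the softmax of −λ·ΔΔG. All
normalizations run in log space so a single large destabilizing outlier
cannot flush a row to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .io_formats import DdgMatrix, PreferenceProfile

__all__ = ["FitnessModelSpec", "folding_probability", "log_folding_probability",
           "ddg_to_preferences"]

_MODELS = ("threshold", "maximum", "optimum")


@dataclass(frozen=True)
class FitnessModelSpec:
    """Parameters of a stability-to-fitness model.

    kT defaults to 0.593 kcal/mol (≈298 K, matching kcal/mol energies); λ
    defaults to 1.0 for the power models; α is a positive scale that cancels
    under preference normalization; dG_wt is the wildtype folding free
    energy used by the threshold model (0 by default — the common
    marginal-stability approximation, exposed for sensitivity analyses).
    """

    model: str = "threshold"
    kT: float = 0.593
    lam: float = 1.0
    alpha: float = 1.0
    dg_wt: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.kT <= 0 or self.lam <= 0 or self.alpha <= 0:
            raise ValueError("kT, lambda and alpha must all be positive")

    @property
    def n_exponent(self) -> int | None:
        if self.model == "maximum":
            return 1
        if self.model == "optimum":
            return 2
        return None


def log_folding_probability(ddg, spec: FitnessModelSpec):
    """log Pf for scalar or array ΔΔG (kcal/mol), computed overflow-safely."""
    x = np.asarray(ddg, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("ΔΔG input must be finite")
    if spec.model == "threshold":
        # Pf = 1 / (1 + e^{(ΔΔG + ΔG_wt)/kT})
        return -np.logaddexp(0.0, (x + spec.dg_wt) / spec.kT)
    if spec.model == "maximum":
        return math.log(spec.alpha) - spec.lam * x
    return math.log(spec.alpha) - spec.lam * x**2


def folding_probability(ddg, spec: FitnessModelSpec):
    """Folding probability Pf; always > 0, and ≤ 1 for the threshold model."""
    out = np.exp(log_folding_probability(ddg, spec))
    return float(out) if np.isscalar(ddg) else out


def ddg_to_preferences(ddg: DdgMatrix, spec: FitnessModelSpec) -> PreferenceProfile:
    """Normalize per-site folding probabilities into a preference profile.

    Each row is the log-sum-exp-normalized Pf vector, so the output is
    independent of α and never underflows for finite ΔΔG.
    """
    ddg.validate()
    logpf = log_folding_probability(ddg.values, spec)
    values = softmax(logpf, axis=1)
    return PreferenceProfile(ddg.protein_id, list(ddg.sites), values).validate()
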