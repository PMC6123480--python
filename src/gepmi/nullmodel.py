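"""Inter-individual similarity null models.

For a target sample, the similarities between it and samples from all other
individuals form its inter-individual similarity distribution.  A parametric
family is fitted to these values by maximum likelihood (beta by default —
the family that fits Jaccard similarities on [0,1] best in practice, with
gamma, normal and [0,1]-truncated normal as competitors selected by the
one-sample Kolmogorov–Smirnov statistic).  The p-value for an observed
query→target similarity s is the fitted survival function,

    p = Pr(X >= s | H0),

under the null hypothesis that the query comes from a different individual
than the target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateDataError, InsufficientDataError, ModelSelectionError

FAMILIES = ("beta", "gamma", "truncated_normal_01", "normal")
#: tie-break preference when KS statistics are equal (best first)
FAMILY_PREFERENCE = {"beta": 0, "gamma": 1, "truncated_normal_01": 2, "normal": 3}

DEFAULT_MIN_FIT = 30
DEFAULT_CLIP_EPSILON = 1e-6


@dataclass
class NullDistribution:
    """A fitted inter-individual similarity distribution for one target."""

    target_sample_id: str
    family: str
    params: dict[str, float]
    n_fit: int
    ks_statistic: float = math.nan
    ks_pvalue: float = math.nan
    clip_epsilon: float = DEFAULT_CLIP_EPSILON

    def frozen(self):
        """The corresponding scipy frozen distribution."""
        p = self.params
        if self.family == "beta":
            return stats.beta(p["shape_alpha"], p["shape_beta"])
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        if self.family == "normal":
            return stats.norm(p["mean"], p["sd"])
        if self.family == "truncated_normal_01":
            a = (0.0 - p["mean"]) / p["sd"]
            b = (1.0 - p["mean"]) / p["sd"]
            return stats.truncnorm(a, b, loc=p["mean"], scale=p["sd"])
        raise ValueError(f"unknown family {self.family!r}")

    def sf(self, x):
        out = self.frozen().sf(x)
        return float(out) if np.ndim(out) == 0 else out

    def cdf(self, x):
        out = self.frozen().cdf(x)
        return float(out) if np.ndim(out) == 0 else out

    def to_json(self) -> str:
        doc = {
            "target_sample_id": self.target_sample_id,
            "family": self.family,
            "params": self.params,
            "n_fit": self.n_fit,
            "ks_statistic": self.ks_statistic,
            "ks_pvalue": self.ks_pvalue,
            "clip_epsilon": self.clip_epsilon,
        }
        return json.dumps(doc, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NullDistribution":
        doc = json.loads(text)
        return cls(**doc)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "NullDistribution":
        return cls.from_json(Path(path).read_text())


def _validate(values: np.ndarray, min_fit: int) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if values.size < min_fit:
        raise InsufficientDataError(
            f"need at least {min_fit} values to fit a null, got {values.size}"
        )
    if (values < 0).any() or (values > 1).any():
        raise ValueError("similarity values must lie in [0, 1]")
    return values


def fit_distribution(
    values,
    family: str = "beta",
    clip_epsilon: float = DEFAULT_CLIP_EPSILON,
    min_fit: int = DEFAULT_MIN_FIT,
    target_sample_id: str = "",
) -> NullDistribution:
    """Maximum-likelihood fit of one family to similarity values in [0,1].

    For beta and gamma the values are first clipped to
    ``[clip_epsilon, 1 - clip_epsilon]`` (their log-likelihoods diverge at
    the boundary).  Optimisation is initialised from method-of-moments
    estimates and is deterministic.  The KS goodness of fit against the
    original (unclipped) values is attached to the result.
    """
    values = _validate(values, min_fit)
    mean = float(np.mean(values))
    var = float(np.var(values))
    clipped = np.clip(values, clip_epsilon, 1.0 - clip_epsilon)
    if float(np.var(clipped)) == 0.0:
        raise DegenerateDataError(
            f"zero variance after clipping for target {target_sample_id!r}"
        )
    sd = math.sqrt(float(np.var(clipped)))
    cmean = float(np.mean(clipped))
    cvar = float(np.var(clipped))

    if family == "beta":
        common = cmean * (1.0 - cmean) / cvar - 1.0
        a0 = max(cmean * common, 1e-3)
        b0 = max((1.0 - cmean) * common, 1e-3)
        a, b, _, _ = stats.beta.fit(clipped, a0, b0, floc=0.0, fscale=1.0)
        params = {"shape_alpha": float(a), "shape_beta": float(b)}
    elif family == "gamma":
        a0 = max(cmean * cmean / cvar, 1e-3)
        scale0 = cvar / cmean
        a, _, scale = stats.gamma.fit(clipped, a0, floc=0.0, scale=scale0)
        params = {"shape": float(a), "scale": float(scale)}
    elif family == "normal":
        mu, sigma = stats.norm.fit(values)
        if sigma == 0.0:
            raise DegenerateDataError("zero variance")
        params = {"mean": float(mu), "sd": float(sigma)}
    elif family == "truncated_normal_01":
        params = _fit_truncnorm01(values, mean, max(math.sqrt(var), 1e-6))
    else:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")

    dist = NullDistribution(
        target_sample_id=target_sample_id,
        family=family,
        params=params,
        n_fit=int(values.size),
        clip_epsilon=clip_epsilon,
    )
    d, p = ks_goodness_of_fit(values, dist)
    dist.ks_statistic = d
    dist.ks_pvalue = p
    return dist


def _fit_truncnorm01(values: np.ndarray, mu0: float, sigma0: float) -> dict[str, float]:
    """MLE of a normal truncated to [0,1], parameterised by (mu, log sigma)."""

    def nll(theta):
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        a = (0.0 - mu) / sigma
        b = (1.0 - mu) / sigma
        ll = stats.truncnorm.logpdf(values, a, b, loc=mu, scale=sigma)
        if not np.isfinite(ll).all():
            return 1e12
        return -float(np.sum(ll))

    res = optimize.minimize(
        nll,
        x0=[mu0, math.log(sigma0)],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
    )
    mu, log_sigma = res.x
    return {"mean": float(mu), "sd": float(math.exp(log_sigma))}


def ks_goodness_of_fit(values, dist: NullDistribution) -> tuple[float, float]:
    """One-sample KS statistic and asymptotic p-value against a fitted null.

    Parameters are estimated from the same data, so the p-value is
    conservative (Lilliefors effect); the statistic is still a valid basis
    for comparing candidate families on identical data.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    result = stats.kstest(values, dist.cdf)
    return float(result.statistic), float(result.pvalue)


def select_family(
    values,
    clip_epsilon: float = DEFAULT_CLIP_EPSILON,
    min_fit: int = DEFAULT_MIN_FIT,
    target_sample_id: str = "",
) -> NullDistribution:
    """Fit all candidate families and return the one with the smallest KS D.

    Ties are broken by the fixed preference order
    beta > gamma > truncated_normal_01 > normal.
    """
    values = _validate(values, min_fit)
    fits: list[NullDistribution] = []
    errors: list[str] = []
    for family in FAMILIES:
        try:
            fits.append(
                fit_distribution(
                    values,
                    family=family,
                    clip_epsilon=clip_epsilon,
                    min_fit=min_fit,
                    target_sample_id=target_sample_id,
                )
            )
        except (DegenerateDataError, ValueError) as exc:
            errors.append(f"{family}: {exc}")
    if not fits:
        raise ModelSelectionError("every family failed to fit: " + "; ".join(errors))
    return min(fits, key=lambda d: (d.ks_statistic, FAMILY_PREFERENCE[d.family]))


def p_value(similarity: float, dist: NullDistribution) -> float:
    """Upper-tail p-value Pr(X >= similarity) under the fitted null."""
    if not 0.0 <= similarity <= 1.0:
        raise ValueError(f"similarity must be in [0, 1], got {similarity}")
    return dist.sf(similarity)
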