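"""Fragment-length distributions.

Recombined tracts transferred by conjugation span roughly three orders of
magnitude (a few kb up to ~1 Mb), so the distribution of the length L of the
fragment covering a selected marker is a first-class model ingredient: the
precision of pooled mapping is governed by its harmonic mean
mu = 1 / E(1/L), which is dominated by the short end of the distribution.

Supported families:

``fixed``
    Degenerate at one length.
``log_uniform``
    log(L) uniform on [log(low), log(high)] — the natural "three orders of
    magnitude" prior.
``log_normal``
    log(L) normal with given mean/sd (natural log).
``empirical``
    Explicit lengths with optional weights, e.g. measured tract lengths.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

_FAMILIES = ("fixed", "log_uniform", "log_normal", "empirical")


@dataclass(frozen=True)
class FragmentLengthDistribution:
    """Distribution of recombined-fragment lengths in bases.

    Parameters
    ----------
    family:
        One of ``fixed``, ``log_uniform``, ``log_normal``, ``empirical``.
    length:
        Fixed length (family ``fixed``).
    low, high:
        Bounds in bases (family ``log_uniform``).
    log_mean, log_sd:
        Natural-log location/scale (family ``log_normal``).
    lengths, weights:
        Support and optional weights (family ``empirical``).
    """

    family: str
    length: float | None = None
    low: float | None = None
    high: float | None = None
    log_mean: float | None = None
    log_sd: float | None = None
    lengths: Sequence[float] | None = None
    weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if self.family == "fixed":
            if self.length is None or self.length <= 0:
                raise ValueError("fixed family requires length > 0")
        elif self.family == "log_uniform":
            if self.low is None or self.high is None or not (0 < self.low <= self.high):
                raise ValueError("log_uniform requires 0 < low <= high")
        elif self.family == "log_normal":
            if self.log_mean is None or self.log_sd is None or self.log_sd < 0:
                raise ValueError("log_normal requires log_mean and log_sd >= 0")
        else:
            ls = np.asarray(self.lengths, dtype=float)
            if ls.size == 0 or np.any(ls <= 0):
                raise ValueError("empirical requires positive lengths")
            if self.weights is not None:
                ws = np.asarray(self.weights, dtype=float)
                if ws.shape != ls.shape or np.any(ws < 0) or ws.sum() == 0:
                    raise ValueError("weights must match lengths, be >= 0, not all zero")

    # -- sampling ---------------------------------------------------------
    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` lengths (float bases)."""
        if self.family == "fixed":
            return np.full(size, float(self.length))
        if self.family == "log_uniform":
            u = rng.uniform(np.log(self.low), np.log(self.high), size=size)
            return np.exp(u)
        if self.family == "log_normal":
            return np.exp(rng.normal(self.log_mean, self.log_sd, size=size))
        ls = np.asarray(self.lengths, dtype=float)
        ws = None
        if self.weights is not None:
            ws = np.asarray(self.weights, dtype=float)
            ws = ws / ws.sum()
        idx = rng.choice(ls.size, size=size, p=ws)
        return ls[idx]

    # -- moments ----------------------------------------------------------
    def harmonic_mean(self) -> float:
        """mu = 1 / E(1/L), in closed form per family."""
        if self.family == "fixed":
            return float(self.length)
        if self.family == "log_uniform":
            a, b = float(self.low), float(self.high)
            if a == b:
                return a
            # E(1/L) for L log-uniform on [a, b]: (1/a - 1/b) / log(b/a)
            return float(np.log(b / a) / (1.0 / a - 1.0 / b))
        if self.family == "log_normal":
            # E(1/L) = exp(-m + s^2/2) for log L ~ N(m, s^2)
            return float(np.exp(self.log_mean - self.log_sd**2 / 2.0))
        ls = np.asarray(self.lengths, dtype=float)
        if self.weights is None:
            ws = np.full(ls.size, 1.0 / ls.size)
        else:
            ws = np.asarray(self.weights, dtype=float)
            ws = ws / ws.sum()
        return float(1.0 / np.sum(ws / ls))

    def mean(self) -> float:
        """Arithmetic mean E(L)."""
        if self.family == "fixed":
            return float(self.length)
        if self.family == "log_uniform":
            a, b = float(self.low), float(self.high)
            if a == b:
                return a
            return float((b - a) / np.log(b / a))
        if self.family == "log_normal":
            return float(np.exp(self.log_mean + self.log_sd**2 / 2.0))
        ls = np.asarray(self.lengths, dtype=float)
        if self.weights is None:
            return float(ls.mean())
        ws = np.asarray(self.weights, dtype=float)
        return float(np.sum(ws * ls) / ws.sum())

    def max_length(self) -> float:
        if self.family == "fixed":
            return float(self.length)
        if self.family == "log_uniform":
            return float(self.high)
        if self.family == "log_normal":
            return float("inf")
        return float(np.max(np.asarray(self.lengths, dtype=float)))


def harmonic_mean(lengths) -> float:
    """Harmonic mean mu = 1/mean(1/L) of a list of positive lengths."""
    ls = np.asarray(lengths, dtype=float)
    if ls.size == 0:
        raise ValueError("empty length list")
    if np.any(ls <= 0):
        raise ValueError("all lengths must be > 0")
    return float(1.0 / np.mean(1.0 / ls))
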