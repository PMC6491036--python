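"""Fast symmetric alpha-stable log-density via characteristic-function FFT.

The symmetric stable density with stability index a in (0, 2] and unit
scale has characteristic function exp(-|t|^a).  For a < 2 the density is
recovered on a fine grid by inverting the characteristic function with a
single FFT; off-grid evaluation interpolates, and the far tail uses the
classical power-law asymptote f(x) ~ Gamma(1+a) sin(pi a / 2) / pi *
|x|^-(1+a).  The a = 2 boundary is the exact Gaussian N(0, 2).

This sampler-support code is deliberately tiny: the MCMC needs millions
of log-density evaluations per run, which rules out quadrature on every
call; one FFT per index update amortises to microseconds per point.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["StableDensity"]

_LOG_TINY = -745.0  # log of the smallest positive double


class StableDensity:
    """Vectorised log-pdf of the standard symmetric stable distribution."""

    def __init__(self, index: float, n_fft: int = 1 << 15, dt: float = 0.02):
        if not 0.5 < index <= 2.0:
            raise ValueError("stability index must lie in (0.5, 2]")
        self.index = float(index)
        if self.index == 2.0:
            self._gaussian = True
            return
        self._gaussian = False
        t = np.arange(n_fft) * dt
        phi = np.exp(-(t**self.index))
        # f(x_j) = (dt/pi) * Re sum_k phi_k exp(2i pi k j / n) - half phi_0
        f = (dt / math.pi) * (np.fft.ifft(phi).real * n_fft - 0.5)
        m = n_fft // 2
        self._x = (2.0 * math.pi / (n_fft * dt)) * np.arange(m)
        tail_c = math.gamma(1.0 + self.index) * math.sin(
            math.pi * self.index / 2.0
        ) / math.pi
        self._log_tail_c = math.log(max(tail_c, 1e-300))
        # the discrete transform aliases mass from the periodic images at
        # x +/- P (P = 2 pi / dt); those sit deep in the power-law regime,
        # so their contribution is removable analytically
        period = 2.0 * math.pi / dt
        alias = tail_c * (
            (period - self._x) ** -(1.0 + self.index)
            + (period + self._x) ** -(1.0 + self.index)
        )
        self._logf = np.log(np.clip(f[:m] - alias, 1e-300, None))
        # switch to the one-term asymptote where it meets the grid
        with np.errstate(divide="ignore"):
            tail = self._log_tail_c - (1.0 + self.index) * np.log(self._x)
        ok = np.nonzero((self._x > 8.0) & (np.abs(tail - self._logf) < 0.02))[0]
        self._x_switch = float(self._x[ok[0]]) if ok.size else float(self._x[-1])

    def logpdf(self, z) -> np.ndarray:
        """Log-density at standardized points z (scale 1)."""
        z = np.abs(np.asarray(z, dtype=float))
        if self._gaussian:
            return -(z**2) / 4.0 - 0.5 * math.log(4.0 * math.pi)
        out = np.interp(z, self._x, self._logf)
        far = z > self._x_switch
        if np.any(far):
            out = np.where(
                far,
                self._log_tail_c - (1.0 + self.index) * np.log(np.maximum(z, 1e-300)),
                out,
            )
        return np.maximum(out, _LOG_TINY)

    def logpdf_scaled(self, x, scale) -> np.ndarray:
        """Log-density of scale * Z at x (elementwise scales allowed)."""
        scale = np.asarray(scale, dtype=float)
        return self.logpdf(np.asarray(x, float) / scale) - np.log(scale)
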