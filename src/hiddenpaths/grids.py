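"""Paired time/frequency sampling for filter transforms.

Convention: ``fhat(omega) = int dt exp(-i omega t) f(t)`` with inverse
``f(t) = (1/2pi) int domega exp(i omega t) fhat(omega)``.  The inverse is
implemented as the exact Riemann sum with the frequency step Delta-omega /
(2 pi), which for the conjugate FFT grid is an inverse DFT divided by the
time step.  Two useful consequences:

* at ``oversample == 1`` the zero-frequency value equals the time-bin sum
  ``dt * sum_t f(t)`` *identically* (a DFT identity), so time-integrated
  effective weights and the omega=0 filters agree to machine precision;
* ``oversample > 1`` evaluates the transform on a denser and wider omega
  grid (conjugate to an internal time step ``dt / oversample``) and keeps
  every ``oversample``-th time bin, shrinking the truncation error near
  t = 0 caused by slowly decaying 1/omega^2 kernel tails by the same factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrequencyGrid"]


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform time bins t_k = k dt, k < n_time, and the conjugate omega grid.

    ``omegas`` has ``n_time * oversample`` entries in FFT order (symmetric
    about 0 up to the Nyquist convention) with spacing
    ``2 pi / (n_time * oversample * dt_fine)`` where ``dt_fine = dt / oversample``.
    """

    dt: float
    n_time: int
    oversample: int = 1
    times: np.ndarray = field(init=False, repr=False)
    omegas: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_time < 2 or self.oversample < 1:
            raise ValueError("require dt > 0, n_time >= 2, oversample >= 1")
        object.__setattr__(self, "times", np.arange(self.n_time) * self.dt)
        object.__setattr__(
            self, "omegas", 2.0 * np.pi * np.fft.fftfreq(self.n_fft, self.dt_fine)
        )

    @property
    def dt_fine(self) -> float:
        return self.dt / self.oversample

    @property
    def n_fft(self) -> int:
        return self.n_time * self.oversample

    @property
    def domega(self) -> float:
        return 2.0 * np.pi / (self.n_fft * self.dt_fine)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrequencyGrid)
            and self.dt == other.dt
            and self.n_time == other.n_time
            and self.oversample == other.oversample
        )

    def __hash__(self) -> int:
        return hash((self.dt, self.n_time, self.oversample))

    # ------------------------------------------------------------------
    def hermitian_defect(self, values: np.ndarray) -> float:
        """Max |fhat(-omega) - conj(fhat(omega))| over paired grid frequencies.

        The Nyquist bin of an even-length grid has no negative partner (it is
        its own mirror) and is excluded: a continuous transform sampled there
        legitimately carries an imaginary part of order the truncation error.
        """
        values = np.asarray(values)
        if not values.size:
            return 0.0
        mirrored = np.conj(values[(-np.arange(self.n_fft)) % self.n_fft])
        defect = np.abs(values - mirrored)
        if self.n_fft % 2 == 0:
            defect[self.n_fft // 2] = 0.0
        return float(np.max(defect))

    def symmetrize(self, values: np.ndarray) -> np.ndarray:
        """Project onto the Hermitian-symmetric part (real inverse transform)."""
        mirrored = np.conj(values[(-np.arange(self.n_fft)) % self.n_fft])
        return 0.5 * (values + mirrored)

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        """(1/2pi) sum_omega exp(i omega t) fhat(omega) domega on the time bins.

        ``values`` must be sampled on :attr:`omegas` along axis 0; the result
        is complex and sampled on :attr:`times` (callers take the real part
        after checking the imaginary residue).
        """
        values = np.asarray(values, dtype=complex)
        if values.shape[0] != self.n_fft:
            raise ValueError(
                f"frequency axis has length {values.shape[0]}, grid expects {self.n_fft}"
            )
        if self.n_fft % 2 == 0:
            # the Nyquist bin has no negative partner; a real output requires
            # it to be real (Hermitian completion convention)
            values = values.copy()
            values[self.n_fft // 2] = values[self.n_fft // 2].real
        fine = np.fft.ifft(values, axis=0) / self.dt_fine
        return fine[:: self.oversample][: self.n_time]
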