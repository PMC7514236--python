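"""Sample entropy, coarse graining, and the averaged multiscale measure.

Sample entropy of a series x of length N is

    SampEn(m, r, N) = -ln( A / B )

where B counts pairs of distinct length-m templates whose Chebyshev
(max-coordinate) distance is <= r, and A counts the pairs that remain
within r when both templates are extended to length m+1.  Self-matches are
excluded; both counts run over the N-m templates for which the extension
exists (the standard convention).  Natural logarithm, so entropies are in
nats.

The multiscale measure coarse-grains x over non-overlapping windows of
length tau = 1..tau_max, computes SampEn at each scale with the tolerance
r fixed at ``r_factor * std`` of the *scale-1* series, and averages the
finite per-scale entropies into a single value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, LengthError

try:  # pragma: no cover - exercised implicitly by every entropy call
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _sampen_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Vectorized template-pair counts (B for length m, A for length m+1)."""
    n = x.size - m  # number of templates with a length-(m+1) extension
    if n < 2:
        return 0, 0
    # running Chebyshev distance over the first m coordinates
    d = np.abs(x[:n, None] - x[None, :n])
    for k in range(1, m):
        np.maximum(d, np.abs(x[k : k + n, None] - x[None, k : k + n]), out=d)
    iu = np.triu_indices(n, k=1)
    within_m = d[iu] <= r
    b = int(np.count_nonzero(within_m))
    np.maximum(d, np.abs(x[m : m + n, None] - x[None, m : m + n]), out=d)
    a = int(np.count_nonzero(d[iu] <= r))
    return a, b


if _HAVE_NUMBA:

    @njit(cache=False)
    def _sampen_counts_numba(x, m, r):  # pragma: no cover - jitted
        n = x.shape[0] - m
        a = 0
        b = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                ok = True
                for k in range(m):
                    if abs(x[i + k] - x[j + k]) > r:
                        ok = False
                        break
                if ok:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b


def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    if _HAVE_NUMBA:
        a, b = _sampen_counts_numba(x, m, r)
        return int(a), int(b)
    return _sampen_counts_numpy(x, m, r)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_factor: float = 0.15) -> float:
    """Sample entropy of a 1-D series, in nats.

    Parameters
    ----------
    x : array-like
        The series.  Must have more than ``m + 1`` samples.
    m : int
        Embedding (template) length.
    r : float, optional
        Similarity tolerance, in the units of ``x``.  When omitted it is
        set to ``r_factor * std(x)``.
    r_factor : float
        Tolerance as a fraction of the series' standard deviation, used
        only when ``r`` is not given.

    Returns
    -------
    float
        ``-ln(A/B)``; ``+inf`` when no template pair extends within
        tolerance (A == 0, the defined sentinel) or no length-m pair
        matches at all (B == 0).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("sample_entropy expects a 1-D series")
    if m < 1:
        raise ValueError("m must be >= 1")
    if x.size <= m + 1:
        raise LengthError(f"series of length {x.size} too short for m={m}")
    if r is None:
        r = r_factor * float(np.std(x))
    if r <= 0:
        raise DegenerateInputError(
            f"tolerance r={r} must be positive (constant input?)"
        )
    a, b = _sampen_counts(x, m, float(r))
    if a == 0 or b == 0:
        return float("inf")
    return float(-np.log(a / b)) + 0.0  # +0.0 normalizes -0.0 when A == B


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Average ``x`` over non-overlapping windows of length ``tau``.

    Output length is ``floor(N / tau)``; trailing samples that do not fill
    a window are dropped.  ``tau=1`` returns the series unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    n = x.size // tau
    if n < 1:
        raise LengthError(f"series of length {x.size} shorter than tau={tau}")
    if tau == 1:
        return x.copy()
    return x[: n * tau].reshape(n, tau).mean(axis=1)


@dataclass
class MSEResult:
    """Per-scale sample entropies and their average for one epoch.

    ``per_scale[t-1]`` is the entropy at scale t (NaN when that scale was
    degenerate: too short, or no template pair within tolerance);
    ``mean_entropy`` averages the finite scales; ``n_missing`` counts the
    degenerate ones.
    """

    per_scale: np.ndarray
    mean_entropy: float
    tau_max: int

    @property
    def n_missing(self) -> int:
        return int(np.count_nonzero(~np.isfinite(self.per_scale)))


def multiscale_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.15,
                       tau_max: int = 10) -> MSEResult:
    """Multiscale sample entropy of one epoch.

    The tolerance is fixed once, ``r = r_factor * std(x)`` of the scale-1
    epoch, and reused at every scale (fixed-r convention).  Scales whose
    coarse-grained series is too short or yields no matching template pair
    are recorded as NaN and excluded from the mean.
    """
    x = np.asarray(x, dtype=np.float64)
    sd = float(np.std(x))
    if sd <= 0:
        raise DegenerateInputError("zero-variance epoch")
    r = r_factor * sd
    per_scale = np.full(tau_max, np.nan)
    for tau in range(1, tau_max + 1):
        try:
            y = coarse_grain(x, tau)
            e = sample_entropy(y, m=m, r=r)
        except (LengthError, DegenerateInputError):
            continue
        if np.isfinite(e):
            per_scale[tau - 1] = e
    finite = per_scale[np.isfinite(per_scale)]
    mean = float(finite.mean()) if finite.size else float("nan")
    return MSEResult(per_scale=per_scale, mean_entropy=mean, tau_max=tau_max)


def batch_multiscale_entropy(epochs: np.ndarray, m: int = 2,
                             r_factor: float = 0.15,
                             tau_max: int = 10) -> np.ndarray:
    """Per-scale entropies for a stack of epochs.

    Parameters
    ----------
    epochs : ndarray, shape (n_epochs, n_samples)

    Returns
    -------
    ndarray, shape (n_epochs, tau_max)
        NaN marks degenerate scales (including whole zero-variance epochs).
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=np.float64))
    out = np.full((epochs.shape[0], tau_max), np.nan)
    for i, ep in enumerate(epochs):
        try:
            out[i] = multiscale_entropy(ep, m=m, r_factor=r_factor,
                                        tau_max=tau_max).per_scale
        except DegenerateInputError:
            continue
    return out
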