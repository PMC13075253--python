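"""Independent reference implementations used as test oracles.

Each oracle is written as a direct transcription of the defining formula
(loops, normal equations, two-trajectory integration) and shares no code
with the package paths it checks.
"""

import numpy as np


def brute_force_unbiased_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """O(N * max_lag) unbiased autocorrelation, normalised at lag 0."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    N = len(xc)
    a = np.empty(max_lag + 1)
    for m in range(max_lag + 1):
        s = 0.0
        for i in range(N - m):
            s += xc[i] * xc[i + m]
        a[m] = s / (N - m)
    return a / a[0]


def normal_equations_ols(y: np.ndarray, X: np.ndarray):
    """OLS via explicit normal equations: beta, SE, residual SS, R2."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    df = len(y) - X.shape[1]
    cov = (ssr / df) * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    sst = float(np.sum((y - y.mean()) ** 2))
    return beta, se, ssr, 1.0 - ssr / sst


def trapezoid_spectral_arc(v: np.ndarray, fs: float, fc: float = 10.0, amp_th: float = 0.05) -> float:
    """Arc length of the normalised magnitude spectrum, summed point by point."""
    nfft = int(2 ** np.ceil(np.log2(len(v)) + 4))
    freqs = np.arange(nfft) * (fs / nfft)
    mag = np.abs(np.fft.fft(np.asarray(v, dtype=float), nfft))
    mag = mag / mag.max()
    keep = freqs <= fc
    f, m = freqs[keep], mag[keep]
    above = np.flatnonzero(m >= amp_th)
    f, m = f[above[0] : above[-1] + 1], m[above[0] : above[-1] + 1]
    span = f[-1] - f[0]
    total = 0.0
    for i in range(1, len(f)):
        df = (f[i] - f[i - 1]) / span
        dm = m[i] - m[i - 1]
        total += np.hypot(df, dm)
    return -total


def lorenz_series(n: int, dt: float = 0.01, transient: int = 1000) -> np.ndarray:
    """RK4-integrated Lorenz trajectory (sigma=10, rho=28, beta=8/3)."""
    s, r, b = 10.0, 28.0, 8.0 / 3.0

    def f(u):
        x, y, z = u
        return np.array([s * (y - x), x * (r - z) - y, x * y - b * z])

    def step(u):
        k1 = f(u)
        k2 = f(u + dt / 2 * k1)
        k3 = f(u + dt / 2 * k2)
        k4 = f(u + dt * k3)
        return u + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    u = np.array([1.0, 1.0, 1.0])
    out = np.empty((n + transient, 3))
    for i in range(n + transient):
        u = step(u)
        out[i] = u
    return out[transient:]


def benettin_lyapunov(n_steps: int = 60000, dt: float = 0.01, renorm: int = 10, d0: float = 1e-8) -> float:
    """Largest Lyapunov exponent of the Lorenz flow by two-trajectory
    perturbation growth with periodic renormalisation (per unit time)."""
    s, r, b = 10.0, 28.0, 8.0 / 3.0

    def f(u):
        x, y, z = u
        return np.array([s * (y - x), x * (r - z) - y, x * y - b * z])

    def step(u):
        k1 = f(u)
        k2 = f(u + dt / 2 * k1)
        k3 = f(u + dt / 2 * k2)
        k4 = f(u + dt * k3)
        return u + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

    u = np.array([1.0, 1.0, 1.0])
    for _ in range(1000):
        u = step(u)
    v = u + np.array([d0, 0.0, 0.0])
    lsum, cnt = 0.0, 0
    for i in range(n_steps):
        u = step(u)
        v = step(v)
        if (i + 1) % renorm == 0:
            d = np.linalg.norm(v - u)
            lsum += np.log(d / d0)
            cnt += 1
            v = u + (v - u) * (d0 / d)
    return lsum / (cnt * renorm * dt)


def histogram_ami(x: np.ndarray, lag: int, bins: int = 64) -> float:
    """Mutual information between x(t) and x(t+lag), direct double loop on
    the joint histogram."""
    a, b = x[:-lag], x[lag:]
    h, _, _ = np.histogram2d(a, b, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mi = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                mi += p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
    return mi
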