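"""Difference-of-coherence testing, FDR correction and spectral Granger causality.

Difference of coherence (DoC)
    Condition coherences are compared per frequency through the Fisher
    z-transform: ``z(f) = [atanh C_A - atanh C_B] / sqrt(1/(2K_A - 2) +
    1/(2K_B - 2))`` with K the trial counts.  The squared statistic is
    referred to a chi-squared distribution with one degree of freedom,
    so the two-tailed 0.05 significance boundary is chi2 = 3.84.  A
    label-permutation test is provided as an assumption-free check.

Spectral Granger causality
    Two backends: a parametric route fitting a vector autoregression
    (order chosen by BIC) followed by the Geweke frequency-domain
    decomposition, and a nonparametric route factorizing the
    trial-averaged cross-spectral density matrix with Wilson's
    algorithm.  Both return non-negative spectra on a shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spectral import CoherenceResult, _coherence_from_sums

__all__ = [
    "DoCResult",
    "GrangerResult",
    "doc_critical_value",
    "doc_test",
    "doc_permutation_pvalues",
    "bh_correct",
    "granger_spectrum",
    "granger_null_threshold",
    "fit_var",
    "geweke_spectra",
]


# ---------------------------------------------------------------------------
# difference of coherence


@dataclass
class DoCResult:
    """Per-frequency coherence difference with chi-squared significance."""

    delta: np.ndarray  # C_A - C_B
    chi2: np.ndarray
    p: np.ndarray  # two-tailed, from chi2(1)
    freqs: np.ndarray
    k_a: int
    k_b: int
    alpha: float
    significant: np.ndarray  # chi2 > critical value at alpha

    @property
    def chi2_critical(self) -> float:
        return doc_critical_value(self.alpha)


def doc_critical_value(alpha: float = 0.05) -> float:
    """Upper-``alpha`` critical value of chi-squared with 1 df (3.84 at 0.05)."""
    return float(stats.chi2.ppf(1.0 - alpha, df=1))


def doc_test(
    coh_a: CoherenceResult, coh_b: CoherenceResult, alpha: float = 0.05
) -> DoCResult:
    """Difference-of-coherence test between two conditions.

    Swapping the conditions negates ``delta`` and leaves ``chi2`` and
    ``p`` unchanged (the two-tailed convention via the squared
    statistic).
    """
    if not np.allclose(coh_a.freqs, coh_b.freqs):
        raise ValueError("frequency grids of the two conditions differ")
    k_a, k_b = coh_a.n_trials, coh_b.n_trials
    if k_a < 2 or k_b < 2:
        raise ValueError("DoC requires >= 2 trials per condition")
    ca = np.clip(coh_a.coherence, 0.0, 1.0 - 1e-12)
    cb = np.clip(coh_b.coherence, 0.0, 1.0 - 1e-12)
    se = np.sqrt(1.0 / (2 * k_a - 2) + 1.0 / (2 * k_b - 2))
    z = (np.arctanh(ca) - np.arctanh(cb)) / se
    chi2 = z**2
    p = stats.chi2.sf(chi2, df=1)
    crit = doc_critical_value(alpha)
    return DoCResult(
        delta=coh_a.coherence - coh_b.coherence,
        chi2=chi2,
        p=np.clip(p, np.finfo(float).tiny, 1.0),
        freqs=coh_a.freqs.copy(),
        k_a=k_a,
        k_b=k_b,
        alpha=alpha,
        significant=chi2 > crit,
    )


def doc_permutation_pvalues(
    xa: np.ndarray,
    ya: np.ndarray,
    xb: np.ndarray,
    yb: np.ndarray,
    n_perm: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label-permutation DoC p-values from per-trial complex coefficients.

    ``xa, ya``: arrays of shape (K_A, ...) with the complex spectral
    coefficients of the two channels under condition A (trials along
    axis 0); likewise ``xb, yb`` for condition B.  Returns the observed
    ``delta`` and two-tailed permutation p-values of matching shape.
    """
    rng = rng or np.random.default_rng()
    k_a = xa.shape[0]

    def _coh(x, y):
        sxy = np.sum(x * np.conj(y), axis=0)
        sxx = np.sum(np.abs(x) ** 2, axis=0)
        syy = np.sum(np.abs(y) ** 2, axis=0)
        return _coherence_from_sums(sxy, sxx, syy)

    observed = _coh(xa, ya) - _coh(xb, yb)
    x_all = np.concatenate([xa, xb], axis=0)
    y_all = np.concatenate([ya, yb], axis=0)
    n = x_all.shape[0]
    count = np.zeros_like(observed, dtype=float)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        d = _coh(x_all[perm[:k_a]], y_all[perm[:k_a]]) - _coh(
            x_all[perm[k_a:]], y_all[perm[k_a:]]
        )
        count += np.abs(d) >= np.abs(observed)
    p = (count + 1.0) / (n_perm + 1.0)
    return observed, p


def bh_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject_mask, adjusted_p)``.  Empty input yields empty
    arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# Granger causality


@dataclass
class GrangerResult:
    """Directional causality spectra; both directions non-negative."""

    freqs: np.ndarray
    gxy: np.ndarray  # x -> y
    gyx: np.ndarray  # y -> x
    method: str
    order: int | None = None  # VAR order (parametric backend)
    sigma: np.ndarray | None = None  # residual covariance (parametric)
    converged: bool = True


def _as_trials(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2:
        raise ValueError("expected (n_trials, n_samples) arrays")
    return a - a.mean(axis=1, keepdims=True)


def fit_var(
    z: np.ndarray, order: int | None = None, max_order: int = 20
) -> tuple[np.ndarray, np.ndarray, int]:
    """Least-squares VAR fit on multi-trial data.

    ``z`` has shape (n_trials, n_dim, n_samples).  The lagged design is
    stacked across trials (no regression across trial boundaries).  If
    ``order`` is None it is selected by BIC over 1..max_order.  Returns
    ``(A, Sigma, order)`` with ``A`` of shape (order, n_dim, n_dim)
    mapping lag-p state to the current state.
    """
    n_tr, n_dim, n_t = z.shape
    if order is not None:
        orders = [order]
    else:
        orders = range(1, min(max_order, n_t // 4) + 1)
    best = None
    for p in orders:
        rows, targets = [], []
        for k in range(n_tr):
            lagged = np.concatenate(
                [z[k][:, p - lag - 1 : n_t - lag - 1].T for lag in range(p)], axis=1
            )
            rows.append(lagged)
            targets.append(z[k][:, p:].T)
        X = np.concatenate(rows, axis=0)  # (N, n_dim*p)
        Y = np.concatenate(targets, axis=0)  # (N, n_dim)
        coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient VAR design at order {p}; not enough data"
            )
        resid = Y - X @ coef
        n_obs = X.shape[0]
        sigma = resid.T @ resid / (n_obs - X.shape[1])
        det = np.linalg.det(sigma)
        if det <= 0:
            raise np.linalg.LinAlgError("singular residual covariance in VAR fit")
        bic = np.log(det) + np.log(n_obs) * (p * n_dim**2) / n_obs
        if best is None or bic < best[0]:
            A = coef.T.reshape(n_dim, p, n_dim).transpose(1, 0, 2)
            best = (bic, A, sigma, p)
    _, A, sigma, p = best
    # stability check: companion-matrix spectral radius
    comp = np.zeros((p * n_dim, p * n_dim))
    comp[:n_dim] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[n_dim:, :-n_dim] = np.eye((p - 1) * n_dim)
    radius = np.max(np.abs(np.linalg.eigvals(comp)))
    if radius >= 1.0:
        raise np.linalg.LinAlgError(f"unstable VAR fit (spectral radius {radius:.3f})")
    return A, sigma, p


def geweke_spectra(
    A: np.ndarray, sigma: np.ndarray, freqs: np.ndarray, sampling_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Geweke frequency-domain causality of a bivariate VAR.

    Closed form given coefficients ``A`` (order, 2, 2) and residual
    covariance ``sigma``; also serves as the analytic oracle when fed
    the true generating coefficients.
    """
    freqs = np.asarray(freqs, dtype=float)
    p = A.shape[0]
    gxy = np.empty(len(freqs))
    gyx = np.empty(len(freqs))
    sxx, syy_r = sigma[0, 0], sigma[1, 1]
    sxy = sigma[0, 1]
    for i, f in enumerate(freqs):
        w = np.exp(-2j * np.pi * f * np.arange(1, p + 1) / sampling_rate)
        af = np.eye(2, dtype=complex) - np.tensordot(w, A, axes=(0, 0))
        h = np.linalg.inv(af)
        s = h @ sigma @ h.conj().T
        # x -> y: reduce S_yy by the part of H_yx carrying x's own innovation
        gxy[i] = np.log(s[1, 1].real / (s[1, 1].real - (sxx - sxy**2 / syy_r) * np.abs(h[1, 0]) ** 2))
        gyx[i] = np.log(s[0, 0].real / (s[0, 0].real - (syy_r - sxy**2 / sxx) * np.abs(h[0, 1]) ** 2))
    return np.maximum(gxy, 0.0), np.maximum(gyx, 0.0)


def _csd_matrix(
    x: np.ndarray, y: np.ndarray, sampling_rate: float, nperseg: int
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged one-sided cross-spectral density matrix (F, 2, 2)."""
    f, pxx = sps.welch(x, fs=sampling_rate, nperseg=nperseg, detrend="constant")
    _, pyy = sps.welch(y, fs=sampling_rate, nperseg=nperseg, detrend="constant")
    _, pxy = sps.csd(x, y, fs=sampling_rate, nperseg=nperseg, detrend="constant")
    if x.ndim > 1:
        pxx, pyy, pxy = pxx.mean(axis=0), pyy.mean(axis=0), pxy.mean(axis=0)
    # Welch returns one-sided densities (interior bins doubled); the
    # factorization needs the two-sided spectrum.  scipy's csd computes
    # E[conj(X) Y]; our convention is S_xy = E[X conj(Y)].
    pxy = np.conj(pxy)
    for p in (pxx, pyy, pxy):
        p[1:-1] /= 2.0
    S = np.empty((len(f), 2, 2), dtype=complex)
    S[:, 0, 0] = pxx
    S[:, 1, 1] = pyy
    S[:, 0, 1] = pxy
    S[:, 1, 0] = np.conj(pxy)
    # demeaning/detrending notches the DC bin; extrapolate from the
    # first interior bin so the global factorization is not distorted
    S[0] = S[1].real
    return f, S


def wilson_factorize(
    S: np.ndarray, n_iter: int = 200, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Wilson's spectral-matrix factorization ``S(f) = H Sigma H*``.

    ``S`` is the one-sided CSD on a uniform grid of ``F = nfft/2 + 1``
    frequencies (0 .. Nyquist inclusive).  Returns the causal transfer
    function ``H`` (F, m, m) with H(0) = I, the innovation covariance
    ``Sigma`` and a convergence flag.
    """
    F, m, _ = S.shape
    nfft = 2 * (F - 1)
    # two-sided extension: S(-f) = S(f)* (Hermitian spectra of real data)
    S2 = np.empty((nfft, m, m), dtype=complex)
    S2[:F] = S
    S2[F:] = np.conj(S[-2:0:-1])

    # initial guess: Cholesky of the lag-zero covariance
    gamma = np.real(np.fft.ifft(S2, axis=0))
    gamma0 = gamma[0]
    gamma0 = 0.5 * (gamma0 + gamma0.T) + 1e-12 * np.trace(gamma0) / m * np.eye(m)
    try:
        h0 = np.linalg.cholesky(gamma0).T  # upper triangular
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("rank-deficient spectral matrix") from err
    psi = np.tile(h0[None, :, :], (nfft, 1, 1)).astype(complex)

    eye = np.eye(m)
    converged = False
    for _ in range(n_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ S2 @ np.conj(np.transpose(psi_inv, (0, 2, 1))) + eye
        # "plus" operator: keep the causal part of g
        gam = np.fft.ifft(g, axis=0)
        gam[0] = np.triu(0.5 * gam[0])
        # zero the anti-causal lags
        gam[nfft // 2 :] = 0.0
        gp = np.fft.fft(gam, axis=0)
        psi_new = psi @ gp
        delta = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-300)
        psi = psi_new
        if delta < tol:
            converged = True
            break

    a0 = np.real(np.fft.ifft(psi, axis=0)[0])
    sigma = a0 @ a0.T
    h = psi @ np.linalg.inv(a0)
    return h[:F], sigma, converged


def granger_spectrum(
    trials_x: np.ndarray,
    trials_y: np.ndarray,
    method: str = "var",
    sampling_rate: float = 1.0,
    freqs: np.ndarray | None = None,
    order: int | None = None,
    max_order: int = 20,
    nperseg: int | None = None,
) -> GrangerResult:
    """Bivariate spectral Granger causality between paired trials.

    ``trials_x`` / ``trials_y`` are (n_trials, n_samples) arrays (or
    1-D single trials) assumed stationary over the analysis window.
    ``method`` is ``"var"`` (parametric, BIC order selection, Geweke
    decomposition) or ``"nonparametric"`` (Welch CSD + Wilson
    factorization).
    """
    x = _as_trials(trials_x)
    y = _as_trials(trials_y)
    if x.shape != y.shape:
        raise ValueError("trials_x and trials_y must have matching shapes")
    if method == "var":
        z = np.stack([x, y], axis=1)  # (K, 2, T)
        A, sigma, p = fit_var(z, order=order, max_order=max_order)
        if freqs is None:
            freqs = np.linspace(0.0, sampling_rate / 2.0, 129)
        gxy, gyx = geweke_spectra(A, sigma, freqs, sampling_rate)
        return GrangerResult(np.asarray(freqs, float), gxy, gyx, "var", order=p, sigma=sigma)
    if method == "nonparametric":
        if nperseg is None:
            nperseg = min(x.shape[1], 256)
        nperseg = int(2 ** np.floor(np.log2(nperseg)))
        f, S = _csd_matrix(x, y, sampling_rate, nperseg)
        h, sigma, converged = wilson_factorize(S)
        if not converged:
            raise RuntimeError("Wilson factorization did not converge")
        sxx, syy = sigma[0, 0], sigma[1, 1]
        sxy = sigma[0, 1]
        s_full = h @ sigma @ np.conj(np.transpose(h, (0, 2, 1)))
        syy_spec = s_full[:, 1, 1].real
        sxx_spec = s_full[:, 0, 0].real
        with np.errstate(divide="ignore", invalid="ignore"):
            gxy = np.log(syy_spec / (syy_spec - (sxx - sxy**2 / syy) * np.abs(h[:, 1, 0]) ** 2))
            gyx = np.log(sxx_spec / (sxx_spec - (syy - sxy**2 / sxx) * np.abs(h[:, 0, 1]) ** 2))
        gxy = np.maximum(np.nan_to_num(gxy), 0.0)
        gyx = np.maximum(np.nan_to_num(gyx), 0.0)
        if freqs is not None:
            freqs = np.asarray(freqs, dtype=float)
            gxy = np.interp(freqs, f, gxy)
            gyx = np.interp(freqs, f, gyx)
            f = freqs
        return GrangerResult(f, gxy, gyx, "nonparametric", sigma=sigma, converged=converged)
    raise ValueError(f"unknown method {method!r}")


def granger_null_threshold(
    trials_x: np.ndarray,
    trials_y: np.ndarray,
    method: str = "var",
    sampling_rate: float = 1.0,
    freqs: np.ndarray | None = None,
    n_shuffle: int = 20,
    quantile: float = 0.95,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> float:
    """Trial-shuffle null for causality spectra.

    Breaks the x-y pairing by circularly shifting the trial order of y,
    recomputes both causality spectra and returns the requested
    quantile of all null values (a single scalar threshold).
    """
    rng = rng or np.random.default_rng()
    x = _as_trials(trials_x)
    y = _as_trials(trials_y)
    if x.shape[0] < 2:
        raise ValueError("trial-shuffle null requires >= 2 trials")
    null_vals = []
    for _ in range(n_shuffle):
        perm = rng.permutation(x.shape[0])
        # reject permutations that keep too many pairs intact
        while np.mean(perm == np.arange(len(perm))) > 0.2:
            perm = rng.permutation(x.shape[0])
        res = granger_spectrum(
            x, y[perm], method=method, sampling_rate=sampling_rate, freqs=freqs, **kwargs
        )
        null_vals.append(np.concatenate([res.gxy, res.gyx]))
    return float(np.quantile(np.concatenate(null_vals), quantile))
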