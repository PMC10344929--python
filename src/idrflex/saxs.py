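"""Small-angle X-ray scattering: forward model and primary analyses.

Contents
--------
* :func:`debye_profile` — Debye sum over dummy beads with unit form
  factors; the forward model used to score conformer pools against
  experimental curves.
* :func:`guinier_fit` — iteratively windowed ln I(q) vs q^2 fit with the
  q*Rg < 1.3 convention appropriate for flexible particles.
* :func:`pr_transform` — regularized indirect Fourier transform to the
  real-space pair-distance distribution p(r), with a Dmax scan.
* :func:`kratky_dimensionless` — (q Rg)^2 I/I0 vs q Rg.
* :func:`chi2_reduced` and :func:`cormap_test` — the two goodness-of-fit
  statistics used for all data-model comparisons; CorMap uses the exact
  longest-run (Schilling) distribution, one-tailed.

q is handled in nm^-1 throughout.  The text reader flags files whose
largest q is below 1 as probably Angstrom^-1 and converts when asked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.spatial.distance import pdist

__all__ = [
    "ScatteringProfile",
    "GuinierResult",
    "PrResult",
    "FitQuality",
    "read_dat",
    "debye_profile",
    "guinier_fit",
    "pr_transform",
    "kratky_dimensionless",
    "chi2_reduced",
    "cormap_test",
    "longest_run_pvalue",
    "profile_from_pr",
]


@dataclass
class ScatteringProfile:
    """One-dimensional scattering curve I(q) with optional 1-sigma errors."""

    q: np.ndarray  # nm^-1, strictly increasing
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ValueError("q and I must be equal-length 1-D arrays")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return len(self.q)

    def scaled(self, factor: float) -> "ScatteringProfile":
        return ScatteringProfile(
            self.q,
            self.I * factor,
            None if self.sigma is None else self.sigma * factor,
        )


@dataclass
class GuinierResult:
    Rg: float  # nm
    I0: float
    fit_window: tuple[float, float]  # (q_min, q_max) nm^-1
    qRg_limit: float
    n_points: int


@dataclass
class PrResult:
    r: np.ndarray  # nm, [0, Dmax]
    p: np.ndarray
    Dmax: float
    Rg: float
    I0: float
    regularization: float
    chi2: float


@dataclass
class FitQuality:
    chi2_reduced: float
    cormap_longest_run: int
    cormap_p: float
    n_points: int
    all_zero: bool = False


def read_dat(path, assume_nm: bool | None = None) -> ScatteringProfile:
    """Read a 3-column (q, I, sigma) text file, tolerant of headers.

    ``assume_nm=None`` applies a heuristic: files whose maximum q is
    below 1 are taken to be in Angstrom^-1 and converted to nm^-1.
    Pass ``True``/``False`` to override.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                continue
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                continue
            rows.append(vals)
    if not rows:
        raise ValueError(f"no numeric data found in {path}")
    arr = np.array([r + [np.nan] * (3 - len(r)) for r in rows])
    arr = arr[arr[:, 0] > 0]
    q, I = arr[:, 0], arr[:, 1]
    sigma = arr[:, 2] if not np.all(np.isnan(arr[:, 2])) else None
    if assume_nm is None:
        assume_nm = q.max() >= 1.0
    if not assume_nm:
        q = q * 10.0  # A^-1 -> nm^-1
    order = np.argsort(q)
    q, I = q[order], I[order]
    if sigma is not None:
        sigma = sigma[order]
    keep = np.concatenate([[True], np.diff(q) > 0])
    return ScatteringProfile(q[keep], I[keep], None if sigma is None else sigma[keep])


# ---------------------------------------------------------------------------
# forward model


def debye_profile(c, q_grid: np.ndarray) -> ScatteringProfile:
    """Debye scattering of a bead conformer or weighted ensemble.

    I(q) = sum_ij f_i f_j sin(q r_ij)/(q r_ij) with unit form factors,
    so I(0) = n^2 for an n-bead conformer.  Ensembles give the
    volume-fraction weighted average of member profiles.
    """
    from .chains import Conformer, Ensemble

    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    if isinstance(c, Ensemble):
        I = np.zeros_like(q)
        for w, member in zip(c.weights, c.conformers):
            I += w * debye_profile(member, q).I
        return ScatteringProfile(q, I)
    if not isinstance(c, Conformer):
        raise TypeError("expected Conformer or Ensemble")
    n = len(c)
    if n == 0:
        raise ValueError("empty conformer")
    if n == 1:
        return ScatteringProfile(q, np.ones_like(q))
    r = pdist(c.coordinates)  # nm
    # sin(x)/x = sinc(x/pi); sum over unordered pairs twice + diagonal n
    x = np.outer(q, r)
    I = n + 2.0 * np.sinc(x / np.pi).sum(axis=1)
    return ScatteringProfile(q, I)


# ---------------------------------------------------------------------------
# Guinier


def guinier_fit(p: ScatteringProfile, qRg_limit: float = 1.3) -> GuinierResult:
    """Weighted linear fit of ln I on q^2 with a self-consistent window.

    The window upper edge is tightened iteratively so that
    q_max * Rg <= qRg_limit.  Requires at least 5 points inside the
    final window; a non-negative slope (no Guinier decay) is an error.
    """
    q, I, sigma = p.q, p.I, p.sigma
    if np.any(I <= 0):
        keep = I > 0
        q, I = q[keep], I[keep]
        sigma = None if sigma is None else sigma[keep]
    n_all = len(q)
    if n_all < 5:
        raise ValueError("too few points for Guinier fit")
    hi = n_all
    for _ in range(100):
        qq = q[:hi] ** 2
        y = np.log(I[:hi])
        if sigma is not None:
            w = (I[:hi] / sigma[:hi]) ** 2  # error propagation ln I
        else:
            w = np.ones_like(y)
        W = np.sum(w)
        xm = np.sum(w * qq) / W
        ym = np.sum(w * y) / W
        cov = np.sum(w * (qq - xm) * (y - ym))
        var = np.sum(w * (qq - xm) ** 2)
        slope = cov / var
        intercept = ym - slope * xm
        if slope >= 0:
            raise ValueError("non-negative Guinier slope; no decay at low q")
        rg = float(np.sqrt(-3.0 * slope))
        new_hi = int(np.searchsorted(q, qRg_limit / rg, side="right"))
        new_hi = max(new_hi, 5)
        if new_hi >= hi:
            break
        hi = new_hi
    if hi < 5:
        raise ValueError("fewer than 5 points below the qRg limit")
    return GuinierResult(
        Rg=rg,
        I0=float(np.exp(intercept)),
        fit_window=(float(q[0]), float(q[hi - 1])),
        qRg_limit=qRg_limit,
        n_points=hi,
    )


# ---------------------------------------------------------------------------
# p(r) indirect Fourier transform


def _spline_design(dmax: float, knots_per_nm: float, r_fine: np.ndarray):
    """Interior cubic B-spline basis on [0, dmax] vanishing at both ends."""
    n_knots = max(int(np.ceil(knots_per_nm * dmax)) + 1, 6)
    t_int = np.linspace(0.0, dmax, n_knots)
    k = 3
    t = np.concatenate([[0.0] * k, t_int, [dmax] * k])
    n_basis = len(t) - k - 1
    B = np.empty((len(r_fine), n_basis - 2))
    B2 = np.empty_like(B)
    for j in range(1, n_basis - 1):  # drop first/last -> p(0)=p(Dmax)=0
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        sp = BSpline(t, coef, k)
        B[:, j - 1] = sp(r_fine)
        B2[:, j - 1] = sp.derivative(2)(r_fine)
    return B, B2


def _ift_solve(
    prof: ScatteringProfile,
    dmax: float,
    alpha: float,
    knots_per_nm: float,
    n_r: int = 301,
    nonneg_iters: int = 8,
):
    r = np.linspace(0.0, dmax, n_r)
    dr = r[1] - r[0]
    B, B2 = _spline_design(dmax, knots_per_nm, r)
    # I(q) = 4 pi int p(r) sinc(qr) dr ; trapezoid weights
    w_r = np.full(n_r, dr)
    w_r[[0, -1]] = dr / 2
    qr = np.outer(prof.q, r)
    K = np.sinc(qr / np.pi)  # sin(qr)/(qr), ->1 at r=0
    A = 4.0 * np.pi * (K * w_r) @ B
    sig = prof.sigma if prof.sigma is not None else np.full(len(prof), 1.0)
    Aw = A / sig[:, None]
    yw = prof.I / sig
    # normalize the weighted data so the regularization weight alpha is
    # dimensionless and every result is invariant to a common rescaling
    # of I and sigma
    y_norm = np.linalg.norm(yw)
    if y_norm <= 0:
        raise ValueError("degenerate profile: zero weighted intensity")
    yw = yw / y_norm
    R = (B2 * w_r[:, None]).T @ B2  # roughness (second-derivative norm)
    R = R * (np.trace(Aw.T @ Aw) / max(np.trace(R), 1e-300))
    lhs0 = Aw.T @ Aw + alpha * R
    rhs = Aw.T @ yw
    pen = np.zeros(B.shape[1])
    c = np.linalg.solve(lhs0, rhs)
    beta = 10.0 * np.trace(lhs0) / max(B.shape[1], 1)
    for _ in range(nonneg_iters):
        pr = B @ c
        neg = pr < 0
        if not np.any(neg):
            break
        Bn = B[neg]
        lhs = lhs0 + beta * (Bn.T @ Bn)
        c = np.linalg.solve(lhs, rhs)
        beta *= 4.0
    c = c * y_norm  # undo the normalization
    pr = np.clip(B @ c, 0.0, None)
    fit = A @ c
    dof = max(len(prof) - B.shape[1], 1)
    chi2 = float(np.sum(((prof.I - fit) / sig) ** 2) / dof)
    return r, pr, chi2, fit


def _auto_alpha(prof, dmax, knots_per_nm):
    """Largest alpha whose chi^2 stays within 10% of the least-smooth fit."""
    alphas = np.logspace(-8, 2, 16)
    chis = []
    for a in alphas:
        _, _, chi2, _ = _ift_solve(prof, dmax, a, knots_per_nm)
        chis.append(chi2)
    chis = np.array(chis)
    best = chis.min()
    tol = max(best * 1.10, best + 0.05)
    ok = np.nonzero(chis <= tol)[0]
    return float(alphas[ok[-1]]) if len(ok) else float(alphas[np.argmin(chis)])


def pr_transform(
    p: ScatteringProfile,
    dmax_scan: tuple[float, float] | float,
    regularization: float | None = None,
    knots_per_nm: float = 3.0,
    support_fraction: float = 0.01,
) -> PrResult:
    """Indirect Fourier transform of I(q) to the p(r) distribution.

    p(r) is expanded in cubic B-splines anchored to zero at r = 0 and
    r = Dmax, fitted by regularized weighted least squares (second-
    derivative roughness penalty, soft nonnegativity, regularization
    weight by L-curve unless given).  When a (min, max) range is given,
    the curve is first inverted on the generous upper support and Dmax
    is taken where the recovered distribution has decayed for good
    below ``support_fraction`` of its peak (an analyst's decay
    criterion, robust where chi^2 differences between long supports are
    below their own sampling scatter); the transform is then re-solved
    on [0, Dmax].  Rg and I0 follow from the moments of p(r):
    Rg^2 = int r^2 p dr / (2 int p dr), I0 = 4 pi int p dr.
    """
    if p.sigma is None:
        raise ValueError("pr_transform requires a profile with errors")

    def solve(dmax):
        alpha = (
            regularization
            if regularization is not None
            else _auto_alpha(p, dmax, knots_per_nm)
        )
        r, pr, chi2, _ = _ift_solve(p, dmax, alpha, knots_per_nm)
        return dmax, alpha, r, pr, chi2

    if np.isscalar(dmax_scan):
        dmax, alpha, r, pr, chi2 = solve(float(dmax_scan))
    else:
        lo, hi = dmax_scan
        if not 0 < lo < hi:
            raise ValueError("dmax range must be positive and increasing")
        _, _, r0, pr0, chi2_hi = solve(float(hi))
        if not np.isfinite(chi2_hi) or pr0.max() <= 0:
            raise ValueError("p(r) inversion failed on the scan range")
        above = np.nonzero(pr0 > support_fraction * pr0.max())[0]
        detected = float(r0[above[-1]]) if len(above) else hi
        dmax, alpha, r, pr, chi2 = solve(float(np.clip(detected, lo, hi)))
        if chi2 > max(5.0 * chi2_hi, chi2_hi + 1.0):
            raise ValueError(
                f"no acceptable fit in the Dmax range: chi2 {chi2:.3g} at "
                f"detected Dmax {dmax:.3g} vs {chi2_hi:.3g} at {hi:.3g}"
            )
    total = np.trapezoid(pr, r)
    if total <= 0:
        raise ValueError("degenerate p(r): nonpositive integral")
    rg = float(np.sqrt(np.trapezoid(r**2 * pr, r) / (2.0 * total)))
    return PrResult(
        r=r, p=pr, Dmax=float(dmax), Rg=rg, I0=float(4.0 * np.pi * total),
        regularization=float(alpha), chi2=float(chi2),
    )


def profile_from_pr(
    r: np.ndarray, pr: np.ndarray, q: np.ndarray, sigma_frac: float = 0.01
) -> ScatteringProfile:
    """Forward Fourier transform of a p(r) curve (round-trip utility)."""
    qr = np.outer(q, r)
    K = np.sinc(qr / np.pi)
    I = 4.0 * np.pi * np.trapezoid(K * pr, r, axis=1)
    return ScatteringProfile(q, I, np.abs(I) * sigma_frac + 1e-12)


def kratky_dimensionless(
    p: ScatteringProfile, Rg: float, I0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless Kratky transform: ((q Rg), (q Rg)^2 I(q)/I(0))."""
    if Rg <= 0 or I0 <= 0:
        raise ValueError("Rg and I0 must be positive")
    x = p.q * Rg
    return x, x**2 * p.I / I0


# ---------------------------------------------------------------------------
# goodness of fit


def _common_grid(model: ScatteringProfile, data: ScatteringProfile) -> np.ndarray:
    """Model intensities on the data grid (linear interpolation inside
    the model's q support; extrapolation is refused)."""
    if np.array_equal(model.q, data.q):
        return model.I
    if data.q[0] < model.q[0] - 1e-12 or data.q[-1] > model.q[-1] + 1e-12:
        raise ValueError("data q range extends beyond model; cannot interpolate")
    return np.interp(data.q, model.q, model.I)


def chi2_reduced(
    model: ScatteringProfile, data: ScatteringProfile, n_params: int = 1
) -> float:
    """Reduced chi^2 with an analytically fitted scalar intensity scale.

    chi^2 = sum((I_d - s I_m)/sigma)^2 / (n - n_params), where s
    minimizes the sum; n_params counts s plus any model parameters.
    """
    if data.sigma is None:
        raise ValueError("data profile must carry errors")
    Im = _common_grid(model, data)
    dof = len(data) - n_params
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")
    w = 1.0 / data.sigma**2
    s = np.sum(w * data.I * Im) / np.sum(w * Im**2)
    return float(np.sum(w * (data.I - s * Im) ** 2) / dof)


@lru_cache(maxsize=None)
def _no_long_run_prob(n: int, m: int) -> float:
    """P(longest run <= m) for n fair two-valued trials.

    A binary string is a first-symbol choice (factor 2) times a
    composition of n into run lengths of size <= m; with
    d(n) = C_m(n)/2^n the composition count obeys
    d(n) = sum_{j=1..min(m,n)} d(n-j) / 2^j, d(0) = 1, and
    P(longest <= m) = 2 d(n).
    """
    if m <= 0:
        return 0.0 if n > 0 else 1.0
    d = np.zeros(n + 1)
    d[0] = 1.0
    for i in range(1, n + 1):
        jmax = min(m, i)
        d[i] = sum(d[i - j] / 2.0**j for j in range(1, jmax + 1))
    return float(min(2.0 * d[n], 1.0))


def longest_run_pvalue(longest: int, n: int) -> float:
    """One-tailed exact p-value P(longest same-sign run >= observed)
    among all 2^n equiprobable sign sequences (Schilling distribution)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if longest <= 1:
        return 1.0
    if longest > n:
        return 0.0
    return min(max(1.0 - _no_long_run_prob(n, longest - 1), 0.0), 1.0)


def cormap_test(model: ScatteringProfile, data: ScatteringProfile) -> FitQuality:
    """Correlation-map goodness of fit over the full q range.

    Residual signs (data minus scale-fitted model) are reduced to their
    longest same-sign run; the p-value is the exact probability of a
    run at least that long in n fair signs.  Zero residuals inherit the
    previous sign (the first sign if leading).  If every residual is
    exactly zero the test is uninformative: p = 1 with a flag.
    """
    if len(data) < 10:
        raise ValueError("cormap needs at least 10 points")
    Im = _common_grid(model, data)
    if data.sigma is not None:
        w = 1.0 / data.sigma**2
        s = np.sum(w * data.I * Im) / np.sum(w * Im**2)
    else:
        s = np.sum(data.I * Im) / np.sum(Im**2)
    resid = data.I - s * Im
    # residuals at floating-point rounding scale count as exact ties
    tol = 1e-10 * np.max(np.abs(data.I))
    signs = np.where(np.abs(resid) <= tol, 0.0, np.sign(resid))
    if np.all(signs == 0):
        chi2 = 0.0 if data.sigma is not None else float("nan")
        return FitQuality(
            chi2_reduced=chi2, cormap_longest_run=0, cormap_p=1.0,
            n_points=len(data), all_zero=True,
        )
    # ties inherit the previous sign; leading zeros take the first sign
    first = signs[signs != 0][0]
    out = np.empty_like(signs)
    prev = first
    for i, sg in enumerate(signs):
        if sg == 0:
            sg = prev
        out[i] = sg
        prev = sg
    runs = np.diff(np.concatenate([[0], np.nonzero(np.diff(out))[0] + 1, [len(out)]]))
    longest = int(runs.max())
    p = longest_run_pvalue(longest, len(out))
    chi2 = chi2_reduced(model, data) if data.sigma is not None else float("nan")
    return FitQuality(
        chi2_reduced=chi2, cormap_longest_run=longest, cormap_p=p,
        n_points=len(data),
    )
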