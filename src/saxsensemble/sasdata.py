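"""Experimental SAXS data handling and real-space inversion.

Covers reading SASBDB-style ``.dat`` intensity files and GNOM-style ``.out``
distance-distribution files, Guinier analysis with a self-consistent qRg
window, a regularized indirect Fourier transform (IFT), a standardized
maximum-dimension (dmax) selection rule based on releasing the P(dmax) = 0
endpoint constraint, rebinning of P(r) curves to a 1 A grid, and simple
data-quality diagnostics (the smallest reliably characterizable dmax is
pi / q_min).

The IFT parameterizes P(r) as a histogram on a uniform 1 A grid over
[0, dmax] with P(0) = P(dmax) = 0, and solves a sigma-weighted linear least
squares with a second-difference (curvature) Tikhonov penalty alpha,
optionally under non-negativity.  When alpha is not given it is chosen by
the discrepancy principle: the largest alpha whose regularized fit still has
reduced chi^2 <= 1 (the smoothest P(r) consistent with the data).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .scattering import DistanceDistribution, IntensityProfile

# average amino-acid residue masses, Da (monomer minus water)
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01528


@dataclass
class GuinierResult:
    rg: float
    i0: float
    q_window: tuple[float, float]
    n_points: int
    n_skipped_low_q: int
    rg_err: float = 0.0

    @property
    def max_qrg(self) -> float:
        return self.q_window[1] * self.rg

    def summary(self) -> str:
        return (f"Guinier fit: Rg = {self.rg:.2f} ± {self.rg_err:.2f} Å, "
                f"I(0) = {self.i0:.4g}, window q = [{self.q_window[0]:.4g}, "
                f"{self.q_window[1]:.4g}] Å⁻¹ ({self.n_points} points, "
                f"{self.n_skipped_low_q} skipped at low q), "
                f"max qRg = {self.max_qrg:.2f}")


@dataclass
class IFTResult:
    pr: DistanceDistribution
    rg: float
    i0: float
    dmax: float
    regularization: float
    fit_chi2: float

    def summary(self) -> str:
        return (f"IFT: dmax = {self.dmax:.1f} Å, Rg = {self.rg:.2f} Å, "
                f"I(0) = {self.i0:.4g}, alpha = {self.regularization:.3g}, "
                f"fit χ² = {self.fit_chi2:.3f}")


@dataclass
class QualityReport:
    q_min: float
    q_max: float
    dmax_limit: float
    n_guinier_points: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"q_min": self.q_min, "q_max": self.q_max,
                "dmax_limit": self.dmax_limit,
                "n_guinier_points": self.n_guinier_points,
                "notes": self.notes}


# ---------------------------------------------------------------------------
# readers / writers


def read_iq(path) -> IntensityProfile:
    """Read a 2/3-column ASCII intensity file (q, I[, sigma]).

    '#'-prefixed and non-numeric header/footer lines are tolerated.
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            try:
                vals = [float(x) for x in parts]
            except ValueError:
                continue
            if len(vals) < 2:
                continue
            rows.append(vals[:3])
            ncols = min(ncols or 3, len(vals))
    if not rows:
        raise ValueError(f"{path}: no numeric data rows")
    q = np.array([r[0] for r in rows])
    i = np.array([r[1] for r in rows])
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"{path}: q values not strictly increasing")
    sigma = None
    if ncols >= 3:
        sigma = np.array([r[2] for r in rows])
        if (sigma < 0).any():
            raise ValueError(f"{path}: negative sigma values")
    return IntensityProfile(q_grid=q, intensity=i, sigma=sigma, label=str(path))


def write_gnom_out(pr: DistanceDistribution, path,
                   fit: IntensityProfile | None = None) -> None:
    """Write a minimal GNOM-style .out file (distance-distribution block)."""
    with open(path, "w") as fh:
        fh.write("  #### Distance distribution function of particle ####\n\n")
        if fit is not None:
            fh.write("      S          J EXP       ERROR       J REG       I REG\n\n")
            sig = fit.sigma if fit.sigma is not None else np.zeros(fit.n_points)
            for q, ii, ss in zip(fit.q_grid, fit.intensity, sig):
                fh.write(f"  {q:.6E}   {ii:.6E}   {ss:.6E}   {ii:.6E}   {ii:.6E}\n")
            fh.write("\n")
        fh.write("           Distance distribution  function of particle\n\n")
        fh.write("       R          P(R)      ERROR\n\n")
        err = pr.errors if pr.errors is not None else np.zeros_like(pr.p)
        for r, p, e in zip(pr.r_grid, pr.p, err):
            fh.write(f"  {r:.4E}  {p:.4E}  {e:.4E}\n")
        fh.write("\n  Reciprocal space: Rg and I(0) from GNOM-style output\n")


def read_gnom_out(path):
    """Read the P(r) block (and fit block if present) from a GNOM-style .out.

    Returns ``(DistanceDistribution, IntensityProfile or None, metadata)``;
    dmax is the last r with non-zero P(r) (or the grid end if all zero).
    """
    with open(path) as fh:
        lines = fh.readlines()
    pr_rows, fit_rows = [], []
    state = None
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if tokens[:3] == ["R", "P(R)", "ERROR"]:
            state = "pr"
            continue
        if tokens[:2] == ["S", "J"] and "REG" in tokens:
            state = "fit"
            continue
        if not tokens:
            continue
        try:
            vals = [float(x) for x in tokens]
        except ValueError:
            if state == "pr" and pr_rows:
                state = None
            continue
        if state == "pr" and len(vals) >= 2:
            if len(vals) < 3:
                raise ValueError(f"{path}:{lineno}: truncated P(r) row: {line.rstrip()!r}")
            pr_rows.append(vals[:3])
        elif state == "fit" and len(vals) >= 2:
            fit_rows.append((vals[0], vals[-1]))
    if not pr_rows:
        raise ValueError(f"{path}: no distance-distribution block found")
    r = np.array([v[0] for v in pr_rows])
    p = np.array([v[1] for v in pr_rows])
    e = np.array([v[2] for v in pr_rows])
    nz = np.flatnonzero(p != 0)
    dmax = float(r[nz[-1]]) if len(nz) else float(r[-1])
    pr = DistanceDistribution(r_grid=r, p=p, errors=e, dmax=dmax)
    fit = None
    if fit_rows:
        fq = np.array([v[0] for v in fit_rows])
        fi = np.array([v[1] for v in fit_rows])
        order = np.argsort(fq)
        fit = IntensityProfile(q_grid=fq[order], intensity=fi[order],
                               label=f"{path} regularized fit")
    spacing = float(np.median(np.diff(r))) if len(r) > 1 else 0.0
    meta = {"n_points": len(r), "spacing": spacing, "dmax": dmax}
    return pr, fit, meta


def rebin_pr(pr: DistanceDistribution, target_width: float = 1.0) -> DistanceDistribution:
    """Rebin a P(r) curve to a uniform grid by linear interpolation.

    Values and errors are interpolated point-wise (errors are *not*
    area-rescaled); on smooth inputs the integral is preserved to ~1%.
    """
    dr = np.diff(pr.r_grid)
    if len(dr) and not np.allclose(dr, dr[0], rtol=1e-6, atol=1e-9):
        raise ValueError("source grid not uniform")
    if pr.dmax > 0 and target_width > pr.dmax / 4:
        raise ValueError(f"target width {target_width} too coarse for dmax {pr.dmax}")
    new_r = np.arange(pr.r_grid[0], pr.r_grid[-1] + target_width / 2, target_width)
    new_p = np.interp(new_r, pr.r_grid, pr.p)
    new_e = None
    if pr.errors is not None:
        new_e = np.interp(new_r, pr.r_grid, pr.errors)
    return DistanceDistribution(r_grid=new_r, p=new_p, errors=new_e,
                                dmax=pr.dmax, normalization=pr.normalization)


# ---------------------------------------------------------------------------
# Guinier


def guinier_fit(profile: IntensityProfile, max_qrg: float = 1.3,
                n_skip_low_q: int = 0, max_iter: int = 50) -> GuinierResult:
    """Guinier analysis: line fit on (q^2, ln I) over a self-consistent window.

    The window starts at index ``n_skip_low_q`` and extends while
    q * Rg <= max_qrg; since Rg is unknown a priori, the window is iterated
    from an initial estimate until stable.
    """
    q = profile.q_grid
    i = profile.intensity
    n = len(q)
    if n - n_skip_low_q < 5:
        raise ValueError("fewer than 5 points after skipping")

    def fit_window(end):
        qs = q[n_skip_low_q:end]
        js = i[n_skip_low_q:end]
        if (js <= 0).any():
            raise ValueError("non-positive intensity inside Guinier window")
        slope, intercept = np.polyfit(qs**2, np.log(js), 1)
        if slope >= 0:
            raise ValueError("non-negative Guinier slope; no Rg")
        # standard error of the slope for the Rg uncertainty
        resid = np.log(js) - (slope * qs**2 + intercept)
        dof = max(len(qs) - 2, 1)
        sxx = ((qs**2 - (qs**2).mean()) ** 2).sum()
        slope_err = math.sqrt((resid**2).sum() / dof / sxx) if sxx > 0 else 0.0
        return slope, intercept, slope_err

    end = min(n, n_skip_low_q + 10)
    prev_end = -1
    for _ in range(max_iter):
        slope, intercept, slope_err = fit_window(end)
        rg = math.sqrt(-3.0 * slope)
        new_end = n_skip_low_q + int(np.searchsorted(q[n_skip_low_q:] * rg,
                                                     max_qrg, side="right"))
        new_end = max(new_end, n_skip_low_q + 5)
        new_end = min(new_end, n)
        if new_end == end:
            break
        if new_end == prev_end:  # 2-cycle; settle on the smaller window
            end = min(end, new_end)
            slope, intercept, slope_err = fit_window(end)
            rg = math.sqrt(-3.0 * slope)
            break
        prev_end, end = end, new_end
    else:
        raise ValueError("Guinier window iteration did not converge")
    rg = math.sqrt(-3.0 * slope)
    rg_err = 1.5 * slope_err / rg if rg > 0 else 0.0
    return GuinierResult(
        rg=rg, i0=float(np.exp(intercept)),
        q_window=(float(q[n_skip_low_q]), float(q[end - 1])),
        n_points=end - n_skip_low_q, n_skipped_low_q=n_skip_low_q,
        rg_err=rg_err)


# ---------------------------------------------------------------------------
# IFT


def _ift_design(q: np.ndarray, r_nodes: np.ndarray) -> np.ndarray:
    """sinc design matrix A[i, j] = sin(q_i r_j)/(q_i r_j)."""
    return np.sinc(q[:, None] * r_nodes[None, :] / np.pi)


def _solve_ift(q, i_obs, sigma, dmax, alpha, nonneg, fix_endpoint=True,
               bin_width=1.0):
    m = int(round(dmax / bin_width))
    r_full = np.arange(m + 1) * bin_width
    # unknowns: interior nodes, plus the dmax endpoint when released
    hi = m if fix_endpoint else m + 1
    r_free = r_full[1:hi]
    a = _ift_design(q, r_free) / sigma[:, None]
    b = i_obs / sigma
    n_free = len(r_free)
    # second differences over the full vector (zero-padded endpoints)
    d2 = np.zeros((m - 1, n_free))
    for j in range(1, m):
        row = j - 1
        for off, c in ((-1, 1.0), (0, -2.0), (1, 1.0)):
            col = j + off - 1
            if 0 <= col < n_free:
                d2[row, col] = c
    stacked = np.vstack([a, math.sqrt(alpha) * d2])
    rhs = np.concatenate([b, np.zeros(m - 1)])
    if nonneg:
        x, _ = _scipy_nnls(stacked, rhs, maxiter=max(2000, 30 * n_free))
    else:
        x, *_ = np.linalg.lstsq(stacked, rhs, rcond=None)
    p_full = np.zeros(m + 1)
    p_full[1:hi] = x
    fit = _ift_design(q, r_full) @ p_full
    chi2 = float((((fit - i_obs) / sigma) ** 2).mean())
    return r_full, p_full, chi2


def ift(profile: IntensityProfile, dmax: float, alpha: float | None = None,
        nonneg: bool = True, bin_width: float = 1.0,
        error_samples: int = 16, error_seed: int = 0) -> IFTResult:
    """Regularized indirect Fourier transform of I(q) to P(r).

    P(r) is a histogram on [0, dmax] (``bin_width`` spacing) with
    P(0) = P(dmax) = 0, solved by sigma-weighted least squares with a
    second-difference smoothness penalty; ``alpha=None`` selects the penalty
    by the discrepancy principle (largest alpha with reduced chi^2 <= 1).
    Per-bin P(r) errors are estimated by Monte Carlo: the inversion is
    repeated on ``error_samples`` noise-resampled copies of the data (set 0
    to skip).
    """
    if dmax < 10:
        raise ValueError("dmax < 10 Å is not a protein-scale inversion")
    if alpha is not None and alpha <= 0:
        raise ValueError("alpha must be positive")
    if profile.sigma is None or (profile.sigma <= 0).any():
        raise ValueError("IFT requires positive sigma on every point")
    q, i_obs, sigma = profile.q_grid, profile.intensity, profile.sigma
    if alpha is None:
        alpha = _discrepancy_alpha(q, i_obs, sigma, dmax, nonneg, bin_width)
    r, p, chi2 = _solve_ift(q, i_obs, sigma, dmax, alpha, nonneg,
                            bin_width=bin_width)
    errors = None
    if error_samples > 0:
        rng = np.random.default_rng(error_seed)
        samples = np.empty((error_samples, len(p)))
        for k in range(error_samples):
            perturbed = i_obs + rng.standard_normal(len(q)) * sigma
            _, samples[k], _ = _solve_ift(q, perturbed, sigma, dmax, alpha,
                                          nonneg, bin_width=bin_width)
        errors = samples.std(axis=0)
    pr = DistanceDistribution(r_grid=r, p=p, errors=errors, dmax=dmax)
    total = p.sum()
    rg = float(np.sqrt((p * r**2).sum() / (2 * total))) if total > 0 else 0.0
    return IFTResult(pr=pr, rg=rg, i0=float(total), dmax=dmax,
                     regularization=alpha, fit_chi2=chi2)


def _discrepancy_alpha(q, i_obs, sigma, dmax, nonneg, bin_width=1.0) -> float:
    """Largest alpha on a log scan whose regularized fit keeps chi^2 <= 1."""
    # scale-aware bracket: alpha has units of (weighted residual / p)^2,
    # so anchor the scan to (sigma / I)^2
    i_scale = max(np.abs(i_obs).max(), 1e-30)
    alphas = np.logspace(-8, 8, 33) * (sigma.mean() / i_scale) ** 2
    best = None
    best_chi2 = None
    for a in alphas:
        _, _, chi2 = _solve_ift(q, i_obs, sigma, dmax, a, nonneg, bin_width=bin_width)
        if chi2 <= 1.0:
            best = a
        if best_chi2 is None or chi2 < best_chi2:
            best_chi2, fallback = chi2, a
    return best if best is not None else fallback


def select_dmax(profile: IntensityProfile, alpha: float | None = None,
                dmax_range: tuple[float, float] = (40.0, 240.0),
                released_fraction: float = 0.01, nonneg: bool = True,
                bin_width: float = 1.0):
    """Standardized dmax selection by endpoint release.

    Scans candidate dmax values on a 2 A grid; for each, solves the IFT with
    and without the P(dmax) = 0 constraint and measures the released endpoint
    value relative to the P(r) peak.  Returns the smallest dmax whose
    released endpoint stays below ``released_fraction`` of the peak.
    """
    if profile.sigma is None:
        raise ValueError("dmax selection requires sigma")
    q, i_obs, sigma = profile.q_grid, profile.intensity, profile.sigma
    lo, hi = dmax_range
    sanity = math.pi / q[0]
    candidates = np.arange(lo, hi + 1e-9, 2.0)
    diagnostics = []
    chosen = None
    for dmax in candidates:
        a = alpha if alpha is not None else _discrepancy_alpha(
            q, i_obs, sigma, dmax, nonneg, bin_width)
        _, p_fixed, chi2 = _solve_ift(q, i_obs, sigma, dmax, a, nonneg,
                                      fix_endpoint=True, bin_width=bin_width)
        _, p_free, _ = _solve_ift(q, i_obs, sigma, dmax, a, nonneg,
                                  fix_endpoint=False, bin_width=bin_width)
        peak = p_free.max()
        rel = float(p_free[-1] / peak) if peak > 0 else np.inf
        diagnostics.append({"dmax": float(dmax), "released_endpoint_fraction": rel,
                            "chi2": chi2, "alpha": a,
                            "exceeds_qmin_limit": bool(dmax > sanity)})
        if chosen is None and rel < released_fraction:
            chosen = float(dmax)
            break
    if chosen is None:
        warnings.warn("no candidate dmax satisfied the endpoint-release rule; "
                      "returning the largest candidate")
        chosen = float(candidates[-1])
    return chosen, diagnostics


# ---------------------------------------------------------------------------
# diagnostics / composition


def data_quality(profile: IntensityProfile, rg_hint: float,
                 max_qrg: float = 1.3, n_skip: int = 0) -> QualityReport:
    """q range, the pi/q_min dmax limit and the Guinier-region point count."""
    q = profile.q_grid
    q_min, q_max = float(q[0]), float(q[-1])
    dmax_limit = math.pi / q_min
    in_window = (np.arange(len(q)) >= n_skip) & (q * rg_hint <= max_qrg)
    notes = []
    n_guinier = int(in_window.sum())
    if n_guinier < 20:
        notes.append(f"only {n_guinier} points in the Guinier region")
    return QualityReport(q_min=q_min, q_max=q_max, dmax_limit=dmax_limit,
                         n_guinier_points=n_guinier, notes=notes)


def mass_from_sequence(sequence: str) -> float:
    """Average (not monoisotopic) mass in Da: residue masses plus one water."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        total = sum(RESIDUE_MASS[aa] for aa in sequence.upper())
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from None
    return total + WATER_MASS
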