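"""NNLS ensemble selection against P(r) or I(q) targets.

The model is linear: the experimental curve b is approximated by a
non-negative combination of per-conformer profiles (columns of A),

    min || A x - b ||_2   subject to  x >= 0,

optionally with rows pre-multiplied by 1/sigma (error weighting).  The
non-zero coefficients, renormalized to sum to one, are the population
fractions of the selected conformers.  NNLS tends empirically to return
sparse solutions — a handful of conformers out of pools of hundreds to
thousands — which is relied on as behaviour, not a guarantee.

`EnsembleNNLS` is the model object (built from a pool of profiles and a
target); `fit()` returns an `EnsembleFitResult` carrying fractions, the
composite profile, the goodness of fit and ensemble statistics such as the
r.m.s. fraction-weighted <Rg> = sqrt(sum f_i Rg_i^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .scattering import DistanceDistribution, IntensityProfile

#: raw coefficients below this fraction of the largest are numerical dust
ZERO_FRACTION = 1e-8


def nnls_solve(design_columns, target, weights=None) -> np.ndarray:
    """Non-negative least squares: min ||Ax - b|| s.t. x >= 0.

    ``design_columns`` is a sequence of 1-D arrays (one per candidate
    profile) on the same grid as ``target``; ``weights`` (typically 1/sigma)
    multiply the rows of both sides before solving.
    """
    a = np.column_stack([np.asarray(c, dtype=float) for c in design_columns])
    b = np.asarray(target, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"grid mismatch: {a.shape[0]} rows vs {b.shape[0]} target points")
    if not np.any(b):
        raise ValueError("all-zero target")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        a = a * w[:, None]
        b = b * w
    x, _ = _scipy_nnls(a, b)
    return x


def scale_and_chi2(model_iq: IntensityProfile, expt_iq: IntensityProfile):
    """Optimal scale and reduced chi-square of a model curve against data.

    c = sum(Im Ie / s^2) / sum(Im^2 / s^2) minimizes the weighted SSR;
    chi^2 = sum((c Im - Ie)^2 / s^2) / (N - 1), one dof spent on the scale.
    Returns (scale, chi2, weighted_residuals).
    """
    if expt_iq.sigma is None:
        raise ValueError("experimental profile has no sigma")
    if model_iq.n_points != expt_iq.n_points or not np.allclose(
            model_iq.q_grid, expt_iq.q_grid):
        raise ValueError("model and experiment on different q grids")
    n = expt_iq.n_points
    if n < 2:
        raise ValueError("need at least 2 points")
    s = expt_iq.sigma
    if (s <= 0).any():
        raise ValueError("non-positive sigma")
    im, ie = model_iq.intensity, expt_iq.intensity
    scale = float((im * ie / s**2).sum() / (im**2 / s**2).sum())
    resid = (scale * im - ie) / s
    chi2 = float((resid**2).sum() / (n - 1))
    return scale, chi2, resid


def composite_profile(profiles, fractions):
    """Fraction-weighted point-wise sum of aligned profiles (model curve)."""
    fractions = np.asarray(fractions, dtype=float)
    if len(profiles) != len(fractions):
        raise ValueError("profiles and fractions differ in length")
    first = profiles[0]
    if isinstance(first, IntensityProfile):
        grid0 = first.q_grid
        stack = []
        for p in profiles:
            if not np.allclose(p.q_grid, grid0):
                raise ValueError("profiles on mismatched q grids")
            stack.append(p.intensity)
        combo = (np.column_stack(stack) * fractions).sum(axis=1)
        return IntensityProfile(q_grid=grid0.copy(), intensity=combo,
                                label="composite")
    grid0 = first.r_grid
    stack = []
    for p in profiles:
        if len(p.r_grid) != len(grid0) or not np.allclose(p.r_grid, grid0):
            raise ValueError("profiles on mismatched r grids")
        stack.append(p.p)
    combo = (np.column_stack(stack) * fractions).sum(axis=1)
    dmax = max(p.dmax for p in profiles)
    return DistanceDistribution(r_grid=grid0.copy(), p=combo, dmax=dmax)


@dataclass
class EnsembleFitResult:
    """Selected members, fractions and diagnostics of one NNLS ensemble fit."""

    member_ids: np.ndarray
    fractions: np.ndarray
    target_kind: str                      # 'pr' | 'iq'
    error_weighted: bool
    composite: object                     # DistanceDistribution | IntensityProfile
    chi2: float
    residual_norm: float
    rg_rms: float | None = None
    dmax_mean: float | None = None
    dmax_max: tuple[float, float] | None = None   # (A, fraction)
    member_rg: np.ndarray | None = None
    member_dmax: np.ndarray | None = None
    scale: float | None = None
    weighted_residuals: np.ndarray | None = None

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    def rg_histogram(self):
        """(Rg, fraction) pairs of the selected members, Rg-sorted."""
        if self.member_rg is None:
            raise ValueError("member Rg values not attached")
        order = np.argsort(self.member_rg)
        return np.column_stack([np.asarray(self.member_rg)[order],
                                self.fractions[order]])

    def summary(self) -> str:
        lines = [
            "NNLS ensemble fit",
            "=" * 46,
            f"target:           {self.target_kind}"
            f"{' (error-weighted)' if self.error_weighted else ''}",
            f"members selected: {self.n_members}",
            f"chi^2:            {self.chi2:.4g}",
        ]
        if self.rg_rms is not None:
            lines.append(f"<Rg> (r.m.s.):    {self.rg_rms:.2f} Å")
        if self.dmax_mean is not None:
            lines.append(f"<dmax>:           {self.dmax_mean:.1f} Å")
        if self.dmax_max is not None:
            lines.append(f"max dmax:         {self.dmax_max[0]:.1f} Å "
                         f"({100 * self.dmax_max[1]:.0f}%)")
        lines.append("-" * 46)
        lines.append(f"{'member':>8s} {'fraction':>10s}"
                     + (f" {'Rg (Å)':>9s}" if self.member_rg is not None else ""))
        for k in np.argsort(self.fractions)[::-1]:
            row = f"{int(self.member_ids[k]):>8d} {self.fractions[k]:>10.4f}"
            if self.member_rg is not None:
                row += f" {self.member_rg[k]:>9.2f}"
            lines.append(row)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "target_kind": self.target_kind,
            "error_weighted": self.error_weighted,
            "member_ids": [int(i) for i in self.member_ids],
            "fractions": [float(f) for f in self.fractions],
            "chi2": float(self.chi2),
            "scale": None if self.scale is None else float(self.scale),
            "rg_rms": None if self.rg_rms is None else float(self.rg_rms),
            "dmax_mean": None if self.dmax_mean is None else float(self.dmax_mean),
            "dmax_max": None if self.dmax_max is None else
                [float(self.dmax_max[0]), float(self.dmax_max[1])],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class EnsembleNNLS:
    """NNLS ensemble model: pool profiles vs one experimental target.

    Parameters
    ----------
    pool_profiles : sequence of DistanceDistribution or IntensityProfile
        Candidate per-conformer profiles, already on the target grid.
    target : DistanceDistribution or IntensityProfile
        Experimental curve to decompose.
    error_weighted : bool
        Pre-multiply rows by 1/sigma of the target (requires errors).
    member_rg, member_dmax : arrays, optional
        Per-conformer Rg and dmax for ensemble statistics.
    """

    def __init__(self, pool_profiles, target, error_weighted: bool = False,
                 member_rg=None, member_dmax=None):
        if len(pool_profiles) == 0:
            raise ValueError("empty pool")
        self.pool_profiles = list(pool_profiles)
        self.target = target
        self.error_weighted = error_weighted
        self.member_rg = None if member_rg is None else np.asarray(member_rg, float)
        self.member_dmax = None if member_dmax is None else np.asarray(member_dmax, float)
        if isinstance(target, IntensityProfile):
            self.target_kind = "iq"
            self._grid = target.q_grid
            self._b = target.intensity
            self._sigma = target.sigma
            self._columns = [p.intensity for p in self.pool_profiles]
        else:
            self.target_kind = "pr"
            self._grid = target.r_grid
            self._b = target.p
            self._sigma = target.errors
            self._columns = [p.p for p in self.pool_profiles]
        for c in self._columns:
            if len(c) != len(self._grid):
                raise ValueError("pool profile not on the target grid; interpolate first")
        if error_weighted and self._sigma is None:
            raise ValueError("error weighting requested but target has no errors")

    def fit(self) -> EnsembleFitResult:
        weights = None
        if self.error_weighted:
            sig = np.where(self._sigma > 0, self._sigma, np.inf)
            weights = 1.0 / sig
        x = nnls_solve(self._columns, self._b, weights=weights)
        x = np.where(x < ZERO_FRACTION * x.max(), 0.0, x) if x.max() > 0 else x
        keep = np.flatnonzero(x > 0)
        if len(keep) == 0:
            raise ValueError("NNLS selected no members")
        fractions = x[keep] / x[keep].sum()
        combo = composite_profile([self.pool_profiles[i] for i in keep], x[keep])
        # goodness of fit on the target grid
        if self.target_kind == "iq" and self._sigma is not None:
            scale, chi2, resid = scale_and_chi2(combo, self.target)
        else:
            sigma = self._sigma if self._sigma is not None else np.ones_like(self._b)
            sigma = np.where(sigma > 0, sigma, 1.0)
            model_vals = combo.p if self.target_kind == "pr" else combo.intensity
            resid = (model_vals - self._b) / sigma
            chi2 = float((resid**2).sum() / max(len(self._b) - 1, 1))
            scale = None
        rnorm = float(np.linalg.norm(
            (np.column_stack(self._columns)[:, keep] @ x[keep]) - self._b))
        rg_rms = dmax_mean = dmax_max = None
        m_rg = m_dmax = None
        if self.member_rg is not None:
            m_rg = self.member_rg[keep]
            rg_rms = float(np.sqrt((fractions * m_rg**2).sum()))
        if self.member_dmax is not None:
            m_dmax = self.member_dmax[keep]
            dmax_mean = float((fractions * m_dmax).sum())
            k = int(np.argmax(m_dmax))
            dmax_max = (float(m_dmax[k]), float(fractions[k]))
        return EnsembleFitResult(
            member_ids=keep, fractions=fractions, target_kind=self.target_kind,
            error_weighted=self.error_weighted, composite=combo, chi2=chi2,
            residual_norm=rnorm, rg_rms=rg_rms, dmax_mean=dmax_mean,
            dmax_max=dmax_max, member_rg=m_rg, member_dmax=m_dmax,
            scale=scale, weighted_residuals=resid)


def fit_ensemble(pool_profiles, target, error_weighted: bool = False,
                 member_rg=None, member_dmax=None) -> EnsembleFitResult:
    """Functional wrapper over :class:`EnsembleNNLS`."""
    return EnsembleNNLS(pool_profiles, target, error_weighted=error_weighted,
                        member_rg=member_rg, member_dmax=member_dmax).fit()


def ensemble_stats(fractions, rg_values, dmax_values=None):
    """(rg_rms, dmax_mean, (dmax_max, fraction), rg_histogram) for given weights."""
    f = np.asarray(fractions, dtype=float)
    rg = np.asarray(rg_values, dtype=float)
    rg_rms = float(np.sqrt((f * rg**2).sum() / f.sum()))
    hist = np.column_stack([rg, f])[np.argsort(rg)]
    if dmax_values is None:
        return rg_rms, None, None, hist
    dm = np.asarray(dmax_values, dtype=float)
    dmax_mean = float((f * dm).sum() / f.sum())
    k = int(np.argmax(dm))
    return rg_rms, dmax_mean, (float(dm[k]), float(f[k] / f.sum())), hist


def refit_union(fit_list, pool_profiles_iq, target_iq: IntensityProfile,
                extra_profiles=None, extra_ids=None, member_rg=None,
                member_dmax=None, extra_rg=None, extra_dmax=None) -> EnsembleFitResult:
    """Refit the union of members selected by earlier fits against I(q).

    ``pool_profiles_iq`` are per-conformer intensity profiles on the target
    grid, indexed consistently with the member ids of the fits in
    ``fit_list``; ``extra_profiles`` (e.g. the unmodified predicted
    structure) are appended with ids from ``extra_ids`` (default: negative).
    """
    if not isinstance(target_iq, IntensityProfile):
        raise ValueError("union refit target must be an intensity profile")
    union: list[int] = sorted({int(i) for fr in fit_list for i in fr.member_ids})
    profiles = [pool_profiles_iq[i] for i in union]
    ids = list(union)
    rg = None if member_rg is None else [member_rg[i] for i in union]
    dm = None if member_dmax is None else [member_dmax[i] for i in union]
    if extra_profiles:
        for k, p in enumerate(extra_profiles):
            profiles.append(p)
            ids.append(extra_ids[k] if extra_ids is not None else -(k + 1))
            if rg is not None:
                rg.append(extra_rg[k] if extra_rg is not None else np.nan)
            if dm is not None:
                dm.append(extra_dmax[k] if extra_dmax is not None else np.nan)
    if not profiles:
        raise ValueError("empty union")
    res = fit_ensemble(profiles, target_iq,
                       member_rg=rg, member_dmax=dm)
    # remap positional ids back to pool/extra ids
    res.member_ids = np.array([ids[i] for i in res.member_ids])
    return res
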